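"""Pairwise/multiple alignment, identity and evolutionary-distance primitives.

Sequences handled here are short nucleotide sequences (pre-miRNA hairpins of
~70-100 nt, mature miRNAs of ~22 nt, coding exon concatenations of a few kb).
Optimal affine-gap alignment is delegated to Biopython's ``PairwiseAligner``;
identity bookkeeping, the center-star multiple alignment and the closed-form
evolutionary distances (p, JC69, TN93) are implemented here.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align

GAP = "-"
_VALID = set("ACGTUNacgtun")

COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

PURINES = frozenset("AGag")
PYRIMIDINES = frozenset("CTUctu")


class InvalidSequenceError(ValueError):
    """A sequence contains residues outside the nucleotide alphabet."""


class SaturationError(ValueError):
    """A distance correction's logarithm argument is non-positive."""


class UndefinedIdentityError(ValueError):
    """No countable columns to compute an identity over."""


def revcomp(seq: str) -> str:
    """Reverse complement (T/U aware; preserves case)."""
    return seq.translate(COMPLEMENT)[::-1]


def check_sequence(seq: str, name: str = "sequence") -> None:
    bad = set(seq) - _VALID
    if bad:
        raise InvalidSequenceError(f"{name} contains invalid residues: {sorted(bad)!r}")


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap nucleotide scoring; defaults suit ~85%-identical precursors."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0   # cost of a gap of length 1
    gap_extend: float = -1.0  # cost of each further gapped column

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class PairwiseAlignment:
    """A gapped pair; ``a_start``/``b_start`` etc. are 0-based half-open local hit
    coordinates on the ungapped inputs (the full span in global mode)."""

    a: str
    b: str
    score: float
    mode: str
    a_start: int = 0
    a_end: int = 0
    b_start: int = 0
    b_end: int = 0

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("gapped strings must have equal length")

    @property
    def columns(self) -> int:
        return len(self.a)


def _aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = scheme.match
    al.mismatch_score = scheme.mismatch
    al.open_gap_score = scheme.gap_open
    al.extend_gap_score = scheme.gap_extend
    return al


def _gap_run_score(n: int, scheme: ScoringScheme) -> float:
    if n == 0:
        return 0.0
    return scheme.gap_open + (n - 1) * scheme.gap_extend


def align_pair(
    a: str,
    b: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    mode: str = "global",
) -> PairwiseAlignment:
    """Optimal affine-gap alignment of two nucleotide sequences.

    ``mode`` is ``"global"`` (Needleman-Wunsch/Gotoh) or ``"local"``
    (Smith-Waterman). Ties between co-optimal alignments are broken
    deterministically (first alignment in Biopython's traceback order).
    """
    if mode not in ("global", "local"):
        raise ValueError(f"unknown mode {mode!r}")
    check_sequence(a, "a")
    check_sequence(b, "b")
    if mode == "local" and (not a or not b):
        raise InvalidSequenceError("local alignment requires non-empty sequences")
    # Biopython rejects empty sequences; the all-gap global alignment is trivial.
    if not a or not b:
        other = a or b
        n = len(other)
        score = _gap_run_score(n, scheme)
        return PairwiseAlignment(
            a=a + GAP * (n if not a else 0),
            b=b + GAP * (n if not b else 0),
            score=score,
            mode=mode,
            a_end=len(a),
            b_end=len(b),
        )
    al = _aligner(scheme, mode)
    aln = al.align(a.upper(), b.upper())[0]
    ga, gb = str(aln[0]), str(aln[1])
    if mode == "local":
        (a0, a1), (b0, b1) = aln.coordinates[0][[0, -1]], aln.coordinates[1][[0, -1]]
    else:
        a0, a1, b0, b1 = 0, len(a), 0, len(b)
    return PairwiseAlignment(
        a=ga, b=gb, score=float(aln.score), mode=mode,
        a_start=int(a0), a_end=int(a1), b_start=int(b0), b_end=int(b1),
    )


def _counted_bounds(rows: Sequence[str]) -> tuple[int, int]:
    """Column range [lo, hi) excluding terminal-gap-only overhangs of any row."""
    lo, hi = 0, len(rows[0])
    for r in rows:
        nz = [i for i, c in enumerate(r) if c != GAP]
        if not nz:
            continue
        lo = max(lo, nz[0])
        hi = min(hi, nz[-1] + 1)
    return lo, hi


def _pair_identity(a: str, b: str) -> float:
    lo, hi = _counted_bounds((a, b))
    if hi <= lo:
        raise UndefinedIdentityError("no countable columns")
    matches = sum(
        1 for i in range(lo, hi) if a[i] == b[i] and a[i] != GAP
    )
    return 100.0 * matches / (hi - lo)


def percent_identity(aln: PairwiseAlignment | Sequence[str]) -> float:
    """Percent identity over counted columns.

    Internal gap columns count in the denominator; terminal overhangs (columns
    inside a leading/trailing gap run of any row) are excluded. For more than
    two rows, the mean over all unordered pairs is returned.
    """
    if isinstance(aln, PairwiseAlignment):
        rows: Sequence[str] = (aln.a, aln.b)
    else:
        rows = list(aln)
    if len(rows) < 2:
        raise ValueError("need at least two rows")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("rows must have equal gapped length")
    vals = [_pair_identity(x, y) for x, y in itertools.combinations(rows, 2)]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Center-star multiple alignment
# ---------------------------------------------------------------------------

def center_star_msa(
    seqs: Sequence[str], scheme: ScoringScheme = DEFAULT_SCHEME
) -> list[str]:
    """Center-star multiple alignment.

    The center is the sequence maximizing the summed pairwise global score;
    every other sequence is merged against it with "once a gap, always a gap".
    Returns gapped rows in input order.
    """
    seqs = list(seqs)
    if len(seqs) == 1:
        warnings.warn("center_star_msa called with a single sequence")
        return [seqs[0]]
    if len(seqs) < 1:
        raise ValueError("need at least one sequence")
    n = len(seqs)
    scores = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        s = align_pair(seqs[i], seqs[j], scheme).score
        scores[i, j] = scores[j, i] = s
    center = int(np.argmax(scores.sum(axis=1)))
    # Align everything to the center, then merge gap patterns column-wise.
    pairs = []
    for j in range(n):
        if j == center:
            continue
        pairs.append((j, align_pair(seqs[center], seqs[j], scheme)))
    # master gap pattern: positions between center residues hold the max gap run
    # length needed by any pairwise alignment.
    c_len = len(seqs[center])
    gap_before = np.zeros(c_len + 1, dtype=int)
    for _, p in pairs:
        pos = 0
        run = 0
        for ch in p.a:
            if ch == GAP:
                run += 1
            else:
                gap_before[pos] = max(gap_before[pos], run)
                run = 0
                pos += 1
        gap_before[c_len] = max(gap_before[c_len], run)
    rows: list[str | None] = [None] * n
    center_row = []
    for pos in range(c_len + 1):
        center_row.append(GAP * gap_before[pos])
        if pos < c_len:
            center_row.append(seqs[center][pos])
    rows[center] = "".join(center_row)
    for j, p in pairs:
        out = []
        pos = 0  # center residue index
        k = 0    # column in pairwise alignment
        for pos in range(c_len + 1):
            # gapped chars of `other` sitting before center residue `pos`
            ins = []
            while k < len(p.a) and p.a[k] == GAP:
                ins.append(p.b[k]); k += 1
            ins += [GAP] * (gap_before[pos] - len(ins))
            out.extend(ins)
            if pos < c_len:
                out.append(p.b[k]); k += 1
        rows[j] = "".join(out)
    assert len({len(r) for r in rows}) == 1  # type: ignore[arg-type]
    return rows  # type: ignore[return-value]


def sum_of_pairs_score(rows: Sequence[str], scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Sum over unordered pairs of the induced pairwise alignment scores."""
    total = 0.0
    for a, b in itertools.combinations(rows, 2):
        # drop columns gapped in both rows, then score runs
        cols = [(x, y) for x, y in zip(a, b) if not (x == GAP and y == GAP)]
        score = 0.0
        run = 0
        for x, y in cols:
            if x == GAP or y == GAP:
                run += 1
            else:
                score += _gap_run_score(run, scheme)
                run = 0
                score += scheme.match if x == y else scheme.mismatch
        score += _gap_run_score(run, scheme)
        total += score
    return total


# ---------------------------------------------------------------------------
# Evolutionary distances
# ---------------------------------------------------------------------------

_RNA2DNA = str.maketrans("Uu", "Tt")


def _substitution_counts(a: str, b: str) -> tuple[int, int, int, int, dict[str, int]]:
    """(sites, transitions_AG, transitions_CT, transversions, base counts) over
    gap-free columns."""
    base_counts: dict[str, int] = {x: 0 for x in "ACGT"}
    n = p1 = p2 = q = 0
    for x, y in zip(a.upper().translate(_RNA2DNA), b.upper().translate(_RNA2DNA)):
        if x not in base_counts or y not in base_counts:
            continue
        n += 1
        base_counts[x] += 1
        base_counts[y] += 1
        if x == y:
            continue
        pair = {x, y}
        if pair == {"A", "G"}:
            p1 += 1
        elif pair == {"C", "T"}:
            p2 += 1
        else:
            q += 1
    return n, p1, p2, q, base_counts


def evolutionary_distance(a: str, b: str, model: str = "TN93") -> float:
    """Pairwise evolutionary distance (substitutions/site) from a gapped pair.

    ``model`` is one of ``p`` (p-distance), ``JC69`` or ``TN93``. Gap or
    ambiguous columns are dropped. Raises :class:`SaturationError` when a
    correction's logarithm argument is non-positive.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned (equal gapped length)")
    n, p1, p2, q, counts = _substitution_counts(a, b)
    if n == 0:
        raise UndefinedIdentityError("no comparable columns")
    p = (p1 + p2 + q) / n
    model = model.upper().replace("-DISTANCE", "")
    if model in ("P", "P-DIST", "PDIST"):
        return p
    if model == "JC69":
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            raise SaturationError("JC69 saturated")
        return -0.75 * math.log(arg)
    if model != "TN93":
        raise ValueError(f"unknown model {model!r}")
    tot = sum(counts.values())
    fA, fC, fG, fT = (counts[x] / tot for x in "ACGT")
    gR, gY = fA + fG, fC + fT
    P1, P2, Q = p1 / n, p2 / n, q / n
    if min(fA, fC, fG, fT) == 0:
        # degenerate composition: fall back to JC69 behaviour via its formula
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            raise SaturationError("TN93 saturated (degenerate composition)")
        return -0.75 * math.log(arg)
    k1 = 2 * fA * fG / gR
    k2 = 2 * fC * fT / gY
    k3 = 2 * (gR * gY - fA * fG * gY / gR - fC * fT * gR / gY)
    w1 = 1.0 - P1 / k1 - Q / (2 * gR)
    w2 = 1.0 - P2 / k2 - Q / (2 * gY)
    w3 = 1.0 - Q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise SaturationError("TN93 saturated")
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


# ---------------------------------------------------------------------------
# Family conservation summaries
# ---------------------------------------------------------------------------

@dataclass
class ConservationSummary:
    """Per-family cross-species identity summary (precursor vs mature region)."""

    family: str
    n_sequences: int
    precursor_length: int
    mature_identity: float
    stemloop_identity: float


def conservation_summary(
    families: dict[str, list[tuple[str, tuple[int, int]]]],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[ConservationSummary]:
    """Summarize conservation per miRNA family.

    ``families`` maps family id to a list of ``(precursor_seq, (mature_start,
    mature_end))`` with 0-based half-open mature intervals. For each family the
    mean pairwise identity of the full precursors and of the mature
    subsequences is reported (families with fewer than two members are skipped
    with a warning). Identities come from optimal pairwise alignments, so the
    result does not depend on a pre-built MSA.
    """
    out: list[ConservationSummary] = []
    for fam, members in families.items():
        if len(members) < 2:
            warnings.warn(f"family {fam!r} has <2 sequences; skipped")
            continue
        for seq, (ms, me) in members:
            if not (0 <= ms < me <= len(seq)):
                raise ValueError(f"family {fam!r}: mature interval out of range")
        pre_ids, mat_ids = [], []
        for (sa, ia), (sb, ib) in itertools.combinations(members, 2):
            pre_ids.append(percent_identity(align_pair(sa, sb, scheme)))
            mat_ids.append(
                percent_identity(align_pair(sa[ia[0]:ia[1]], sb[ib[0]:ib[1]], scheme))
            )
        out.append(
            ConservationSummary(
                family=fam,
                n_sequences=len(members),
                precursor_length=round(np.mean([len(s) for s, _ in members])),
                mature_identity=float(np.mean(mat_ids)),
                stemloop_identity=float(np.mean(pre_ids)),
            )
        )
    return out


def distance_matrix(
    seqs: dict[str, str], model: str = "TN93", scheme: ScoringScheme = DEFAULT_SCHEME,
    aligned: bool = False, saturation_cap: float | None = None,
) -> "pd.DataFrame":
    """Square distance matrix over named sequences.

    If ``aligned`` the inputs are rows of one MSA; otherwise each pair is
    aligned globally first. ``saturation_cap`` replaces saturated distances by
    a fixed ceiling instead of raising (useful for bootstrap resampling).
    """
    import pandas as pd

    names = list(seqs)
    d = pd.DataFrame(0.0, index=names, columns=names)
    for x, y in itertools.combinations(names, 2):
        if aligned:
            a, b = seqs[x], seqs[y]
        else:
            p = align_pair(seqs[x], seqs[y], scheme)
            a, b = p.a, p.b
        try:
            v = evolutionary_distance(a, b, model)
        except SaturationError:
            if saturation_cap is None:
                raise
            v = saturation_cap
        d.loc[x, y] = d.loc[y, x] = v
    return d
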