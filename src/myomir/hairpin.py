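"""Hairpin verification by base-pair maximization.

A candidate pre-miRNA must fold into a single stem-loop with a long stem, a
modest terminal loop, and a mostly paired mature arm to be processable by the
Drosha/Dicer machinery. This module scores that shape from a maximum
Watson-Crick(+GU) base-pairing structure computed by dynamic programming
(no pseudoknots, minimum loop separation). Base-pair counts are exact and
testable against exhaustive structure enumeration; no free energies are
computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import InvalidSequenceError

_PAIRS = {
    ("A", "T"), ("T", "A"), ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"), ("G", "U"), ("U", "G"),
}


def can_pair(x: str, y: str, allow_gu: bool = True) -> bool:
    x, y = x.upper(), y.upper()
    if not allow_gu and {x, y} in ({"G", "T"}, {"G", "U"}):
        return False
    return (x, y) in _PAIRS


@dataclass
class FoldResult:
    """A secondary structure: dot-bracket string and 1-based pair list."""

    dotbracket: str
    pairs: list[tuple[int, int]]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def fold_maxpair(seq: str, min_loop: int = 3, allow_gu: bool = True) -> FoldResult:
    """Maximum base-pairing structure (Nussinov dynamic programming).

    Pairs require at least ``min_loop`` unpaired nucleotides between partners;
    pseudoknots are excluded by construction. Among co-optimal tracebacks, the
    pair maximizing ``j - i`` (outermost pairing) is preferred.
    """
    s = seq.upper().replace("U", "T")
    if any(c not in "ACGTN" for c in s):
        raise InvalidSequenceError(f"invalid residues in {seq!r}")
    n = len(s)
    if n < min_loop + 2:
        raise ValueError(f"sequence shorter than min_loop + 2 ({min_loop + 2})")
    # D[i][j]: max pairs over the inclusive subsequence i..j
    D = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = D[i][j - 1]  # j unpaired
            for k in range(i, j - min_loop):
                if can_pair(s[k], s[j], allow_gu):
                    left = D[i][k - 1] if k > i else 0
                    inner = D[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    cand = left + inner + 1
                    if cand > best:
                        best = cand
            D[i][j] = best
    pairs: list[tuple[int, int]] = []

    def traceback(i: int, j: int) -> None:
        while j > i:
            if j - i < min_loop + 1:
                return
            if D[i][j] == D[i][j - 1]:
                # check whether pairing j achieves the same optimum; prefer the
                # pairing with smallest k (maximal j - k) when it ties.
                paired = None
                for k in range(i, j - min_loop):
                    if can_pair(s[k], s[j], allow_gu):
                        left = D[i][k - 1] if k > i else 0
                        inner = D[k + 1][j - 1] if k + 1 <= j - 1 else 0
                        if left + inner + 1 == D[i][j]:
                            paired = k
                            break
                if paired is None:
                    j -= 1
                    continue
                k = paired
            else:
                k = None
                for kk in range(i, j - min_loop):
                    if can_pair(s[kk], s[j], allow_gu):
                        left = D[i][kk - 1] if kk > i else 0
                        inner = D[kk + 1][j - 1] if kk + 1 <= j - 1 else 0
                        if left + inner + 1 == D[i][j]:
                            k = kk
                            break
                assert k is not None
            pairs.append((k, j))
            if k > i:
                traceback(i, k - 1)
            i, j = k + 1, j - 1

    traceback(0, n - 1)
    pairs = sorted((min(a, b), max(a, b)) for a, b in pairs)
    db = ["."] * n
    for a, b in pairs:
        db[a], db[b] = "(", ")"
    return FoldResult(dotbracket="".join(db), pairs=[(a + 1, b + 1) for a, b in pairs])


def enumerate_max_pairs(seq: str, min_loop: int = 3, allow_gu: bool = True) -> int:
    """Brute-force maximum pair count by exhaustive structure enumeration.

    Exponential; intended as an independent oracle for short sequences
    (<= ~16 nt).
    """
    s = seq.upper().replace("U", "T")

    # Enumerate complete pair sets recursively over sorted position tuples;
    # nesting keeps pairs either inside or outside, so no pseudoknots arise.
    def enum(positions: tuple[int, ...]) -> int:
        if len(positions) < min_loop + 2:
            return 0
        first = positions[0]
        rest = positions[1:]
        # first unpaired
        best_n = enum(rest)
        # first paired with a partner far enough in sequence space
        for idx, partner in enumerate(rest):
            if partner - first <= min_loop:
                continue
            if can_pair(s[first], s[partner], allow_gu):
                inner = tuple(p for p in rest[:idx] )
                outer = tuple(p for p in rest[idx + 1:])
                # no pseudoknots: remaining pairs must be entirely inside or
                # entirely outside (first, partner); since we only track index
                # sets of a contiguous problem this holds by splitting:
                best_n = max(best_n, 1 + enum(inner) + enum(outer))
        return best_n

    return enum(tuple(range(len(s))))


@dataclass
class HairpinVerdict:
    """Shape compliance of a folded candidate precursor."""

    compliant: bool
    stem_length: int
    terminal_loop: int
    mature_paired_fraction: float
    n_stem_loops: int
    details: dict = field(default_factory=dict)


def _helices(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group pairs into exactly-stacked helices (1-based pairs)."""
    helices: list[list[tuple[int, int]]] = []
    ps = sorted(pairs)
    used: set[tuple[int, int]] = set()
    pairset = set(ps)
    for p in ps:
        if p in used:
            continue
        helix = [p]
        used.add(p)
        i, j = p
        while (i + 1, j - 1) in pairset and (i + 1, j - 1) not in used:
            i, j = i + 1, j - 1
            helix.append((i, j))
            used.add((i, j))
        helices.append(helix)
    return helices


def hairpin_verdict(
    seq: str,
    fold: FoldResult | None = None,
    mature: tuple[int, int] | None = None,
    min_stem: int = 18,
    max_loop: int = 20,
    min_paired: float = 0.6,
    bulge_tol: int = 6,
    min_helix_stem: int = 2,
    min_helix_loop: int = 3,
    min_loop: int = 3,
) -> HairpinVerdict:
    """Judge whether a fold is a canonical single-stem pre-miRNA hairpin.

    ``mature`` is a 0-based half-open interval on ``seq``. Compliance requires
    exactly one stem-loop, a stem of at least ``min_stem`` paired positions in
    one bulge-tolerant run, a terminal loop of at most ``max_loop`` unpaired nt
    and at least ``min_paired`` of mature positions paired.

    Base-pair maximization has no energy model, so it decorates real hairpins
    with marginal helices a thermodynamic fold would reject; two noise filters
    compensate. Helices below ``min_helix_stem`` stacked pairs are ignored
    entirely; stem-loop counting (and the terminal-loop measurement) considers
    only helices of at least ``min_helix_loop`` stacked pairs, so a 2-stack
    coincidence near the apex does not split one hairpin into two. The
    terminal loop is the number of *unpaired* positions enclosed by the
    innermost substantial pair.
    """
    if fold is None:
        fold = fold_maxpair(seq, min_loop=min_loop)
    helices = _helices(fold.pairs)
    pairs = sorted(p for h in helices for p in h if len(h) >= min_helix_stem)
    loop_pairs = sorted(p for h in helices for p in h if len(h) >= min_helix_loop)
    if not pairs or not loop_pairs:
        return HairpinVerdict(False, 0, len(seq), 0.0, 0)
    # bulge-tolerant stem runs: chain consecutive pairs when the unpaired gap
    # across both strands stays within bulge_tol
    runs: list[list[tuple[int, int]]] = []
    cur = [pairs[0]]
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if i2 > i1 and j2 < j1 and (i2 - i1 - 1) + (j1 - j2 - 1) <= bulge_tol:
            cur.append((i2, j2))
        else:
            runs.append(cur)
            cur = [(i2, j2)]
    runs.append(cur)
    stem_len = max(len(r) for r in runs)
    # stem-loops: substantial pairs enclosing no other substantial pair
    closing = [
        (i, j) for (i, j) in loop_pairs
        if not any(i < a and b < j for (a, b) in loop_pairs if (a, b) != (i, j))
    ]
    n_stem_loops = len(closing)
    paired_pos = {i for p in pairs for i in p}

    def unpaired_inside(i: int, j: int) -> int:
        return sum(1 for p in range(i + 1, j) if p not in paired_pos)

    terminal_loop = min(unpaired_inside(i, j) for i, j in closing)
    if mature is not None:
        ms, me = mature
        if not (0 <= ms < me <= len(seq)):
            raise ValueError("mature interval out of range")
        mat_positions = range(ms + 1, me + 1)  # 1-based
        frac = sum(1 for p in mat_positions if p in paired_pos) / (me - ms)
    else:
        frac = len(paired_pos) / len(seq)
    ok = (
        n_stem_loops == 1
        and stem_len >= min_stem
        and terminal_loop <= max_loop
        and frac >= min_paired
    )
    return HairpinVerdict(
        compliant=bool(ok),
        stem_length=stem_len,
        terminal_loop=terminal_loop,
        mature_paired_fraction=float(frac),
        n_stem_loops=n_stem_loops,
        details={"n_pairs": fold.n_pairs, "n_runs": len(runs)},
    )
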