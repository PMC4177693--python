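"""Locate pre-miRNA orthologs/paralogs in genome sequences.

A word-seeded local-alignment search (seed-and-extend) against both strands
of each scaffold, thresholded on percent identity and query coverage, then
overlap-consolidated into loci and tabulated into the per-species
families x species matrix (with "-" marking absence).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .alignment import (
    DEFAULT_SCHEME,
    InvalidSequenceError,
    ScoringScheme,
    align_pair,
    revcomp,
)

DEFAULT_MIN_IDENTITY = 80.0
DEFAULT_MIN_COVERAGE = 0.8
DEFAULT_WORD_SIZE = 11


@dataclass
class MirnaLocus:
    """A mapped precursor hit (1-based closed genomic coordinates)."""

    family: str
    species: str
    seqid: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float
    copy_index: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start > end")

    @property
    def label(self) -> str:
        return f"{self.seqid}:{self.start}-{self.end}({self.strand})"


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def read_query_matures(path) -> dict[str, tuple[int, int]]:
    """Parse ``mature=a-b`` (1-based closed) from query FASTA descriptions."""
    out: dict[str, tuple[int, int]] = {}
    for r in SeqIO.parse(str(path), "fasta"):
        for tok in r.description.split():
            if tok.startswith("mature="):
                a, b = tok[len("mature="):].split("-")
                out[r.id] = (int(a) - 1, int(b))  # to 0-based half-open
    return out


def _index_genome(seqs: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    idx: dict[str, list[tuple[str, int]]] = {}
    for sid, seq in seqs.items():
        for i in range(len(seq) - k + 1):
            idx.setdefault(seq[i:i + k], []).append((sid, i))
    return idx


def _merge_windows(wins: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(wins):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _alignment_stats(qseq: str, window: str, scheme: ScoringScheme):
    """Local-align query against a genomic window; returns (identity %,
    coverage, window_start, window_end) of the best local hit."""
    p = align_pair(qseq, window, scheme, mode="local")
    cols = p.columns
    if cols == 0:
        return 0.0, 0.0, 0, 0
    matches = sum(1 for x, y in zip(p.a, p.b) if x == y and x != "-")
    identity = 100.0 * matches / cols
    coverage = (p.a_end - p.a_start) / len(qseq)
    return identity, coverage, p.b_start, p.b_end


def search_precursors(
    queries: dict[str, str],
    genome: dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    word_size: int = DEFAULT_WORD_SIZE,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    species: str = "?",
) -> list[MirnaLocus]:
    """Seed-and-extend search of each query against both genome strands.

    An exact ``word_size``-mer shared between query and genome seeds a local
    alignment of the query against a window around the seed diagonal; hits
    passing the identity/coverage thresholds are reported in plus-strand
    coordinates (minus-strand hits carry strand "-").
    """
    if word_size < 4:
        raise ValueError("word_size must be >= 4")
    if not (0 <= min_identity <= 100) or not (0 < min_coverage <= 1):
        raise ValueError("thresholds out of range")
    for fam, q in queries.items():
        if len(q) < word_size:
            raise InvalidSequenceError(
                f"query {fam} shorter than word_size {word_size}")
    if not genome or all(not s for s in genome.values()):
        return []
    idx = _index_genome(genome, word_size)
    hits: list[MirnaLocus] = []
    for fam, q in sorted(queries.items()):
        qlen = len(q)
        margin = max(qlen // 2, 20)
        for strand in "+-":
            qs = q if strand == "+" else revcomp(q)
            per_seq: dict[str, list[tuple[int, int]]] = {}
            for i in range(qlen - word_size + 1):
                for sid, j in idx.get(qs[i:i + word_size], ()):
                    lo = max(j - i - margin, 0)
                    hi = min(j - i + qlen + margin, len(genome[sid]))
                    per_seq.setdefault(sid, []).append((lo, hi))
            for sid, wins in per_seq.items():
                for lo, hi in _merge_windows(wins):
                    ident, cov, b0, b1 = _alignment_stats(
                        qs, genome[sid][lo:hi], scheme)
                    if ident >= min_identity and cov >= min_coverage:
                        hits.append(MirnaLocus(
                            family=fam, species=species, seqid=sid,
                            start=lo + b0 + 1, end=lo + b1, strand=strand,
                            identity=ident, coverage=cov,
                        ))
    return hits


def consolidate_loci(hits: list[MirnaLocus]) -> list[MirnaLocus]:
    """Merge same-family hits overlapping >= 50% reciprocally (keep the
    highest identity) and assign copy indices by (seqid, start)."""
    out: list[MirnaLocus] = []
    by_key: dict[tuple[str, str], list[MirnaLocus]] = {}
    for h in hits:
        by_key.setdefault((h.family, h.seqid), []).append(h)
    for (_, _), group in sorted(by_key.items()):
        group = sorted(group, key=lambda h: (h.start, h.end))
        kept: list[MirnaLocus] = []
        for h in group:
            merged = False
            for i, k in enumerate(kept):
                ov = min(h.end, k.end) - max(h.start, k.start) + 1
                if ov > 0 and (
                    ov >= 0.5 * (h.end - h.start + 1)
                    and ov >= 0.5 * (k.end - k.start + 1)
                ):
                    if h.identity > k.identity:
                        kept[i] = h
                    merged = True
                    break
            if not merged:
                kept.append(h)
        out.extend(kept)
    # copy indices within species x family, ordered by (seqid, start)
    fams: dict[tuple[str, str], list[MirnaLocus]] = {}
    for h in out:
        fams.setdefault((h.species, h.family), []).append(h)
    for group in fams.values():
        group.sort(key=lambda h: (h.seqid, h.start))
        for i, h in enumerate(group, 1):
            h.copy_index = i
    return sorted(out, key=lambda h: (h.family, h.seqid, h.start))


def build_locus_matrix(
    loci_by_species: dict[str, list[MirnaLocus]],
    species: list[str],
    families: list[str] | None = None,
) -> pd.DataFrame:
    """Families x species grid of locus lists (empty list = absent)."""
    if families is None:
        families = sorted({
            h.family for loci in loci_by_species.values() for h in loci
        })
    grid = pd.DataFrame(
        [[[] for _ in species] for _ in families],
        index=families, columns=species,
    )
    for sp in species:
        for h in loci_by_species.get(sp, ()):
            grid.loc[h.family, sp].append(h)
    return grid


def locus_matrix_tsv(matrix: pd.DataFrame) -> str:
    """Serialize the grid with "-" for absence (the physical-location table)."""
    lines = ["family\t" + "\t".join(matrix.columns)]
    for fam in matrix.index:
        cells = []
        for sp in matrix.columns:
            loci = matrix.loc[fam, sp]
            cells.append(";".join(h.label for h in loci) if loci else "-")
        lines.append(fam + "\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"


def copy_number_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    return matrix.map(len)


def exhaustive_scan(
    query: str,
    genome: dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    species: str = "?",
    max_rounds: int = 20,
) -> list[MirnaLocus]:
    """Word-free oracle: repeated best local alignment with masking.

    Aligns the query (both strands) against each full scaffold, accepts the
    best hit if it passes the thresholds, masks it out and repeats, so every
    qualifying locus is found regardless of word seeding. Quadratic - use on
    small genomes only.
    """
    hits: list[MirnaLocus] = []
    for sid, seq0 in genome.items():
        for strand in "+-":
            qs = query if strand == "+" else revcomp(query)
            seq = seq0
            for _ in range(max_rounds):
                if len(seq) < 10:
                    break
                ident, cov, b0, b1 = _alignment_stats(qs, seq, scheme)
                if b1 <= b0:
                    break
                if ident >= min_identity and cov >= min_coverage:
                    hits.append(MirnaLocus(
                        family="query", species=species, seqid=sid,
                        start=b0 + 1, end=b1, strand=strand,
                        identity=ident, coverage=cov,
                    ))
                    seq = seq[:b0] + "N" * (b1 - b0) + seq[b1:]
                else:
                    break
    return hits
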