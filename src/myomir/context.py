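"""Classify miRNA loci relative to gene models: intronic (with host gene and
intron index in transcription order), exonic, or intergenic (with nearest
protein-coding neighbors), plus cluster detection by genomic proximity."""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils

from .mapping import MirnaLocus


@dataclass
class GeneModel:
    """A protein-coding gene model; exons sorted by genomic coordinate
    (1-based closed intervals)."""

    gene_id: str
    name: str
    seqid: str
    strand: str
    start: int
    end: int
    biotype: str
    transcripts: dict  # transcript id -> sorted [(exon_start, exon_end), ...]

    def introns(self, tx: str) -> list[tuple[int, int]]:
        exons = self.transcripts[tx]
        return [
            (exons[i][1] + 1, exons[i + 1][0] - 1)
            for i in range(len(exons) - 1)
            if exons[i + 1][0] - exons[i][1] > 1
        ]

    def transcription_intron_index(self, tx: str, genomic_idx: int) -> int:
        n = len(self.introns(tx))
        return genomic_idx + 1 if self.strand == "+" else n - genomic_idx


def read_gene_models(gff_path) -> list[GeneModel]:
    """Load protein-coding gene models from GFF3 (gene/mRNA/exon with
    ID/Parent attributes) via gffutils."""
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        biotype = g.attributes.get("biotype", ["protein_coding"])[0]
        txs: dict[str, list[tuple[int, int]]] = {}
        for t in db.children(g, featuretype="mRNA"):
            exons = sorted(
                (e.start, e.end) for e in db.children(t, featuretype="exon")
            )
            txs[t.id] = exons
        if not txs:
            txs = {g.id + ".t": [(g.start, g.end)]}
        genes.append(GeneModel(
            gene_id=g.id, name=g.attributes.get("Name", [g.id])[0],
            seqid=g.seqid, strand=g.strand, start=g.start, end=g.end,
            biotype=biotype, transcripts=txs,
        ))
    return genes


def read_mirna_features(gff_path) -> list[dict]:
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    out = []
    for f in db.features_of_type("miRNA"):
        out.append({
            "locus_id": f.id, "family": f.attributes.get("Name", [f.id])[0],
            "seqid": f.seqid, "start": f.start, "end": f.end,
            "strand": f.strand,
        })
    return out


@dataclass
class GenomicContext:
    """Where a miRNA locus sits relative to protein-coding gene models."""

    kind: str  # intergenic | intronic | exonic
    host_gene: str | None = None
    intron_index: int | None = None  # 1-based, transcription order
    upstream_gene: str | None = None
    upstream_distance: int | None = None
    downstream_gene: str | None = None
    downstream_distance: int | None = None
    boundary_overlap: bool = False
    mirtron: bool = False


class UnknownSequenceError(ValueError):
    pass


def classify_context(
    locus: MirnaLocus,
    genes: list[GeneModel],
    known_seqids: set[str] | None = None,
) -> GenomicContext:
    """Classify one locus against a species' gene models.

    Intronic requires the locus fully inside an intron of some protein-coding
    transcript (host chosen as that gene; among multi-transcript hosts the
    transcript giving the lowest intron index wins). Overlapping any exon is
    exonic (boundary flag when straddling an exon edge). Otherwise intergenic,
    with nearest protein-coding neighbors on each side; up/downstream are
    defined relative to the locus strand. When ``known_seqids`` is given, a
    locus on an unlisted sequence raises :class:`UnknownSequenceError`
    (gene-free scaffolds are otherwise a legitimate intergenic case).
    """
    if known_seqids is not None and locus.seqid not in known_seqids:
        raise UnknownSequenceError(f"unknown sequence id {locus.seqid}")
    coding = [g for g in genes
              if g.biotype == "protein_coding" and g.seqid == locus.seqid]
    s, e = locus.start, locus.end
    # intronic?
    best: tuple[int, str] | None = None
    mirtron = False
    for g in coding:
        for tx in sorted(g.transcripts):
            for gi, (a, b) in enumerate(g.introns(tx)):
                if a <= s and e <= b:
                    idx = g.transcription_intron_index(tx, gi)
                    cand = (idx, g.name)
                    if best is None or cand < best:
                        best = cand
                        mirtron = (s == a and e == b)
    if best is not None:
        return GenomicContext(
            kind="intronic", host_gene=best[1], intron_index=best[0],
            mirtron=mirtron,
        )
    # exonic?
    for g in coding:
        for tx in sorted(g.transcripts):
            for (a, b) in g.transcripts[tx]:
                if s <= b and a <= e:
                    straddle = s < a or e > b
                    return GenomicContext(
                        kind="exonic", host_gene=g.name,
                        boundary_overlap=straddle,
                    )
    # intergenic: nearest coding gene on each genomic side, then orient by
    # locus strand
    left = [(s - g.end - 1, g) for g in coding if g.end < s]
    right = [(g.start - e - 1, g) for g in coding if g.start > e]
    left_best = min(left, key=lambda t: (t[0], t[1].name), default=None)
    right_best = min(right, key=lambda t: (t[0], t[1].name), default=None)
    if locus.strand == "-":
        up, down = right_best, left_best
    else:
        up, down = left_best, right_best
    return GenomicContext(
        kind="intergenic",
        upstream_gene=up[1].name if up else None,
        upstream_distance=up[0] if up else None,
        downstream_gene=down[1].name if down else None,
        downstream_distance=down[0] if down else None,
    )


@dataclass
class MirnaCluster:
    """Same-scaffold miRNA loci chained by gaps <= max_gap."""

    members: list[MirnaLocus]
    gaps: list[int] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.members[-1].end - self.members[0].start + 1

    @property
    def seqid(self) -> str:
        return self.members[0].seqid


def detect_clusters(loci: list[MirnaLocus], max_gap: int = 50_000) -> list[MirnaCluster]:
    """Single-linkage chaining of loci on one scaffold whose edge-to-edge gap
    is at most ``max_gap`` (default 50 kb, wide enough to keep the broadest
    reported bicistronic spacings in one cluster)."""
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    clusters: list[MirnaCluster] = []
    by_seq: dict[str, list[MirnaLocus]] = {}
    for h in loci:
        by_seq.setdefault(h.seqid, []).append(h)
    for sid in sorted(by_seq):
        group = sorted(by_seq[sid], key=lambda h: (h.start, h.end))
        cur = [group[0]]
        gaps: list[int] = []
        for prev, h in zip(group, group[1:]):
            gap = max(h.start - prev.end - 1, 0)
            if gap <= max_gap:
                cur.append(h)
                gaps.append(gap)
            else:
                clusters.append(MirnaCluster(cur, gaps))
                cur, gaps = [h], []
        clusters.append(MirnaCluster(cur, gaps))
    return clusters
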