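"""Anchored gene-neighborhood (microsynteny) comparison.

For each miRNA locus an anchor protein-coding gene is chosen (the host gene
for intronic loci, the nearest downstream coding gene for intergenic ones)
and a window of up to nine coding genes on each side is extracted in anchor
orientation. Windows from two species are compared through an ortholog map:
shared gene classes, longest colinear run (an order-respecting common
subsequence), orientation agreement and upstream/downstream side switches —
the signature a neighborhood translocation leaves behind.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .alignment import DEFAULT_SCHEME, ScoringScheme, align_pair
from .context import GeneModel, GenomicContext
from .mapping import MirnaLocus


class AnchorUnavailableError(ValueError):
    """No anchor gene exists (e.g. a locus at a scaffold edge with no
    downstream coding gene)."""


@dataclass
class WindowEntry:
    gene: str            # gene name (ortholog-map key)
    orientation: int     # +1 same strand as anchor, -1 opposite
    side: int            # negative upstream of anchor, 0 anchor, positive downstream
    distance: int        # gene-count offset from anchor


@dataclass
class SyntenyWindow:
    species: str
    anchor: str
    anchor_strand: str
    entries: list[WindowEntry]  # ordered in anchor orientation

    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]


@dataclass
class SyntenyScore:
    shared: int
    colinear_run: int
    orientation_agree: int
    side_switches: list[str]
    missing_in_other: list[str]


def select_anchor(
    locus: MirnaLocus, context: GenomicContext, genes: list[GeneModel]
) -> GeneModel:
    """Anchor gene for a locus: host if intronic, nearest downstream coding
    gene if intergenic, the overlapped gene if exonic."""
    by_name = {}
    for g in genes:
        by_name.setdefault(g.name, g)
    if context.kind in ("intronic", "exonic"):
        if context.host_gene is None or context.host_gene not in by_name:
            raise AnchorUnavailableError(f"host gene missing for {locus.family}")
        return by_name[context.host_gene]
    if context.downstream_gene is None:
        raise AnchorUnavailableError(
            f"{locus.family} at {locus.label}: no downstream coding gene")
    return by_name[context.downstream_gene]


def extract_window(
    anchor: GeneModel, genes: list[GeneModel], n: int = 9, species: str = "?"
) -> SyntenyWindow:
    """Up to ``n`` protein-coding genes on each side of the anchor, in anchor
    orientation (windows of minus-strand anchors are flipped so comparisons
    are orientation-normalized)."""
    coding = sorted(
        (g for g in genes if g.biotype == "protein_coding" and g.seqid == anchor.seqid),
        key=lambda g: (g.start, g.end),
    )
    idx = next(i for i, g in enumerate(coding) if g.name == anchor.name)
    left = coding[max(idx - n, 0):idx]
    right = coding[idx + 1:idx + 1 + n]
    entries: list[WindowEntry] = []
    for k, g in enumerate(left):
        entries.append(WindowEntry(g.name, +1 if g.strand == anchor.strand else -1,
                                   side=-1, distance=-(len(left) - k)))
    entries.append(WindowEntry(anchor.name, +1, side=0, distance=0))
    for k, g in enumerate(right):
        entries.append(WindowEntry(g.name, +1 if g.strand == anchor.strand else -1,
                                   side=+1, distance=k + 1))
    if anchor.strand == "-":
        entries = [
            WindowEntry(e.gene, e.orientation, -e.side, -e.distance)
            for e in reversed(entries)
        ]
    return SyntenyWindow(species=species, anchor=anchor.name,
                         anchor_strand=anchor.strand, entries=entries)


@dataclass
class OrthologyMap:
    """Disjoint cross-species gene equivalence classes."""

    classes: dict  # class id -> set of "species:gene" members
    _member_to_class: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._member_to_class = {}
        for cid, members in self.classes.items():
            for m in members:
                if m in self._member_to_class:
                    raise ValueError(f"member {m} in two classes")
                self._member_to_class[m] = cid

    def class_of(self, species: str, gene: str) -> str:
        return self._member_to_class.get(f"{species}:{gene}", f"{species}:{gene}")


def lcs_length(a: list, b: list) -> int:
    """Longest common subsequence length (exact dynamic programming)."""
    m, n = len(a), len(b)
    dp = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m):
        for j in range(n):
            dp[i + 1][j + 1] = (
                dp[i][j] + 1 if a[i] == b[j]
                else max(dp[i][j + 1], dp[i + 1][j])
            )
    return dp[m][n]


def _window_classes(win: SyntenyWindow, omap: OrthologyMap | None):
    """(ordered class list, class -> WindowEntry nearest to anchor)."""
    entries: dict[str, WindowEntry] = {}
    order: list[tuple] = []
    for e in win.entries:
        cid = omap.class_of(win.species, e.gene) if omap else e.gene
        if cid in entries:
            # paralog-ambiguous class: keep the member nearest the anchor
            if abs(e.distance) < abs(entries[cid].distance):
                entries[cid] = e
        else:
            entries[cid] = e
    for e in win.entries:
        cid = omap.class_of(win.species, e.gene) if omap else e.gene
        if entries[cid] is e:
            order.append(cid)
    return order, entries


def compare_windows(
    ref: SyntenyWindow, other: SyntenyWindow, omap: OrthologyMap | None = None
) -> SyntenyScore:
    """Score two anchored windows through the ortholog map.

    ``shared`` counts classes present in both windows (anchor excluded);
    ``colinear_run`` is the LCS of the shared-class orders; orientation
    agreement and side switches are counted over shared classes.
    """
    if not ref.entries or not other.entries:
        raise ValueError("windows must be nonempty")
    r_order, r_entries = _window_classes(ref, omap)
    o_order, o_entries = _window_classes(other, omap)
    anchor_cls = {
        omap.class_of(ref.species, ref.anchor) if omap else ref.anchor,
        omap.class_of(other.species, other.anchor) if omap else other.anchor,
    }
    shared_cls = (set(r_order) & set(o_order)) - anchor_cls
    r_shared = [c for c in r_order if c in shared_cls]
    o_shared = [c for c in o_order if c in shared_cls]
    colinear = lcs_length(r_shared, o_shared)
    agree = sum(
        1 for c in shared_cls
        if r_entries[c].orientation == o_entries[c].orientation
    )
    switches = sorted(
        c for c in shared_cls
        if r_entries[c].side * o_entries[c].side < 0
    )
    missing = sorted(set(r_order) - set(o_order) - anchor_cls)
    return SyntenyScore(
        shared=len(shared_cls), colinear_run=colinear,
        orientation_agree=agree, side_switches=switches,
        missing_in_other=missing,
    )


def build_orthology(
    gene_seqs: dict[str, dict[str, str]],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> OrthologyMap:
    """Reciprocal-best-hit orthology from gene sequences.

    ``gene_seqs``: species -> gene name -> (spliced) sequence. Cross-species
    gene pairs are scored by global alignment; reciprocal best hits are
    single-linked into classes. Quadratic in genes per species - meant for
    neighborhood-scale inputs, and bypassed by the simulator's truth map on
    synthetic runs.
    """
    species = sorted(gene_seqs)
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        parent[find(x)] = find(y)

    for sa, sb in itertools.combinations(species, 2):
        ga, gb = gene_seqs[sa], gene_seqs[sb]
        scores: dict[tuple[str, str], float] = {}
        for na, qa in ga.items():
            for nb, qb in gb.items():
                scores[(na, nb)] = align_pair(qa, qb, scheme).score
        best_ab = {
            na: max(gb, key=lambda nb: (scores[(na, nb)], nb)) for na in ga
        }
        best_ba = {
            nb: max(ga, key=lambda na: (scores[(na, nb)], na)) for nb in gb
        }
        for na, nb in best_ab.items():
            if best_ba[nb] == na:
                union(f"{sa}:{na}", f"{sb}:{nb}")
    classes: dict[str, set[str]] = {}
    for sp in species:
        for name in gene_seqs[sp]:
            m = f"{sp}:{name}"
            classes.setdefault(find(m), set()).add(m)
    return OrthologyMap(classes={f"og{su + 1}": v for su, (_, v) in
                                 enumerate(sorted(classes.items()))})


def orthology_from_truth(truth_classes: dict) -> OrthologyMap:
    """Wrap the simulator's ancestral-gene classes as an OrthologyMap."""
    return OrthologyMap(classes={k: set(v) for k, v in truth_classes.items()})
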