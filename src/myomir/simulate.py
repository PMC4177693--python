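"""Multi-species synthetic genome generator with an event truth log.

Generates, along a given species tree, one small genome per leaf in which
miRNA hairpin loci sit inside host-gene introns or between genes, surrounded
by orthologous protein-coding neighborhoods. Lineages accumulate nucleotide
substitutions with region-specific rates (mature region slowest, hairpin
loop/stem faster, coding exons faster still, intergenic fastest) plus
structural events - duplication, loss, translocation and intronic->intergenic
excision - either drawn Poisson per branch or replayed from a scripted list.
Every event is recorded in a :class:`TruthLog` so downstream inference can be
judged against ground truth.

The substitution engine is Kimura-style (equal base frequencies, configurable
transition bias), applied per region with exact transition probabilities, so
distance estimators have a well-defined expectation. Stem substitutions in
hairpins are compensated on the partner strand with high probability, which
preserves foldability the way covariation does in real pre-miRNAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .alignment import revcomp
from .trees import Node, parse_newick, to_newick

_B2C = {65: 0, 67: 1, 71: 2, 84: 3}
_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class FamilySpec:
    """One miRNA family: where it sits and when it is born.

    ``gain_branch`` names the tree node on whose branch the family appears
    (None = tree root). Intronic families name a host gene and a 1-based
    intron index in transcription order; intergenic families sit in the
    central spacer of their neighborhood at ``offset`` nt.
    """

    name: str
    placement: str  # "intronic" | "intergenic"
    neighborhood: str
    gain_branch: str | None = None
    host: str | None = None
    host_n_exons: int = 8
    host_strand: str = "+"
    intron_index: int = 2  # transcription order
    offset: int = 80
    strand: str = "+"
    seed_like: str | None = None  # copy the seed (mature pos 2-8) of this family

    def __post_init__(self) -> None:
        if self.placement not in ("intronic", "intergenic"):
            raise ConfigurationError(f"bad placement {self.placement!r}")
        if self.placement == "intronic" and not self.host:
            raise ConfigurationError(f"intronic family {self.name} needs a host")


@dataclass
class ScriptedEvent:
    branch: str
    kind: str  # duplication | loss | translocation | excision
    family: str
    detail: dict = field(default_factory=dict)


DEFAULT_TREE = "((speciesA:0.2,speciesB:0.2)ab:0.1,(speciesC:0.2,speciesD:0.2)cd:0.1)root;"


def default_families() -> list[FamilySpec]:
    return [
        FamilySpec("fam-intronic", "intronic", "nb1", host="hostg", intron_index=2),
        FamilySpec("fam-intergenic", "intergenic", "nb2", offset=800),
    ]


@dataclass
class SimulationConfig:
    """Generator settings; defaults emulate the conservation regime of
    muscle-miRNA precursors (mature ~95-100% identical across species,
    precursors ~80-90%).

    Substitution rates are per site per unit branch length; event rates are
    expected events per branch (Poisson). ``scripted_events`` switches the
    generator to deterministic event replay (rates ignored).
    """

    species_tree: str = DEFAULT_TREE
    families: list[FamilySpec] = field(default_factory=default_families)
    n_neighbor_genes: int = 12
    # structural event rates (expected events/branch)
    duplication_rate: float = 0.05
    loss_rate: float = 0.05
    translocation_rate: float = 0.05
    excision_rate: float = 0.02
    # substitution rates (per site per unit branch length)
    rate_mature: float = 0.04
    rate_loop: float = 0.35
    rate_flank_gene: float = 0.5
    rate_intergenic: float = 0.9
    kappa: float = 2.0
    indel_rate: float = 0.02
    loop_indel_rate: float = 0.005
    compensation_prob: float = 0.8
    paralog_burst: tuple[int, int] = (12, 15)
    # geometry
    hairpin_template_length: int = 85
    loop_length: int = 11
    mature_length: int = 22
    mature_offset: int = 5
    exon_length: int = 180
    intron_length: int = 260
    spacer_length: int = 600
    center_spacer_length: int = 4000
    n_exons: int = 3
    dup_neighbor_count: int = 2
    neighbor_names: dict = field(default_factory=dict)  # nbhd -> {"up":[...], "down":[...]}
    scripted_events: list[ScriptedEvent] | None = None
    # 3'UTR set for target prediction
    n_utrs: int = 300
    utr_length: int = 500
    utr_site_plant: int = 25
    n_decoy_matures: int = 20
    seed: int = 0
    preset_name: str | None = None

    def __post_init__(self) -> None:
        rates = [
            self.duplication_rate, self.loss_rate, self.translocation_rate,
            self.excision_rate, self.rate_mature, self.rate_loop,
            self.rate_flank_gene, self.rate_intergenic, self.indel_rate,
            self.loop_indel_rate,
        ]
        if any((r < 0 or not math.isfinite(r)) for r in rates):
            raise ConfigurationError("rates must be finite and >= 0")
        if not (self.rate_mature <= self.rate_loop <= self.rate_intergenic):
            raise ConfigurationError(
                "expected rate_mature <= rate_loop <= rate_intergenic"
            )
        tree = parse_newick(self.species_tree)
        if len(tree.leaves()) < 2:
            raise ConfigurationError("species tree needs >= 2 leaves")
        arm = (self.hairpin_template_length - self.loop_length) // 2
        if self.mature_offset + self.mature_length > arm:
            raise ConfigurationError("mature region does not fit in the 5' arm")


# ---------------------------------------------------------------------------
# Substitution engine (Kimura two-parameter, exact transition probabilities)
# ---------------------------------------------------------------------------

def _k2p_probs(d: float, kappa: float) -> tuple[float, float]:
    """(P_transition, P_each_transversion) after expected distance ``d``."""
    if d <= 0:
        return 0.0, 0.0
    bt = d / (kappa + 2.0)
    at = kappa * bt
    e1 = math.exp(-4.0 * bt)
    e2 = math.exp(-2.0 * (at + bt))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    return max(p_ts, 0.0), max(p_tv, 0.0)


def _seq_to_codes(seq: str) -> np.ndarray:
    a = np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy()
    out = np.zeros(a.size, dtype=np.int8)
    for b, c in _B2C.items():
        out[a == b] = c
    out[~np.isin(a, list(_B2C))] = 0
    return out


def _codes_to_seq(codes: np.ndarray) -> str:
    return _CODES[codes].tobytes().decode()


def evolve_sequence(
    seq: str, distance: float, rng: np.random.Generator, kappa: float = 2.0
) -> str:
    """Evolve a sequence by expected ``distance`` substitutions/site."""
    if not seq or distance <= 0:
        return seq
    codes = _seq_to_codes(seq)
    p_ts, p_tv = _k2p_probs(distance, kappa)
    u = rng.random(codes.size)
    ts = u < p_ts
    tv1 = (~ts) & (u < p_ts + p_tv)
    tv2 = (~ts) & (~tv1) & (u < p_ts + 2 * p_tv)
    out = codes.copy()
    out[ts] = (codes[ts] + 2) % 4
    out[tv1] = (codes[tv1] + 1) % 4
    out[tv2] = (codes[tv2] + 3) % 4
    return _codes_to_seq(out)


def _mutate_with_indels(
    seq: str, distance: float, indel_rate: float, rng: np.random.Generator,
    kappa: float,
) -> str:
    seq = evolve_sequence(seq, distance, rng, kappa)
    if indel_rate <= 0 or len(seq) < 20:
        return seq
    n_ev = rng.poisson(indel_rate * distance * len(seq))
    for _ in range(n_ev):
        L = int(rng.integers(1, 7))
        if rng.random() < 0.5 and len(seq) - L > 10:
            p = int(rng.integers(0, len(seq) - L))
            seq = seq[:p] + seq[p + L:]
        else:
            p = int(rng.integers(0, len(seq)))
            ins = _codes_to_seq(rng.integers(0, 4, size=L).astype(np.int8))
            seq = seq[:p] + ins + seq[p:]
    return seq


def random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


# ---------------------------------------------------------------------------
# Genome model
# ---------------------------------------------------------------------------

@dataclass
class HairpinLocus:
    """A miRNA precursor stored in transcript orientation: 5' arm, loop,
    3' arm (arms equal length, arm3 complementary to arm5 at birth)."""

    family: str
    locus_id: str
    arm5: str
    loop: str
    arm3: str
    strand: str = "+"
    mature_offset: int = 5
    mature_length: int = 22

    @property
    def seq(self) -> str:
        return self.arm5 + self.loop + self.arm3

    @property
    def mature_interval(self) -> tuple[int, int]:
        return self.mature_offset, self.mature_offset + self.mature_length

    @property
    def mature(self) -> str:
        s, e = self.mature_interval
        return self.seq[s:e]

    def clone(self) -> "HairpinLocus":
        return replace(self)


@dataclass
class GeneUnit:
    """A protein-coding gene stored in genomic plus orientation; ``ancestral``
    is the ortholog-class key, ``name`` the per-species instance id. Introns
    are piece lists mixing raw sequence and embedded hairpins."""

    name: str
    ancestral: str
    strand: str
    exons: list[str]
    introns: list[list]  # each: list[str | HairpinLocus]

    def clone(self) -> "GeneUnit":
        return GeneUnit(
            self.name, self.ancestral, self.strand, list(self.exons),
            [[p.clone() if isinstance(p, HairpinLocus) else p for p in intron]
             for intron in self.introns],
        )

    def hairpins(self):
        for gi, intron in enumerate(self.introns):
            for p in intron:
                if isinstance(p, HairpinLocus):
                    yield gi, p

    def transcription_intron_index(self, genomic_index: int) -> int:
        """1-based intron index in transcription order."""
        n = len(self.introns)
        return genomic_index + 1 if self.strand == "+" else n - genomic_index


@dataclass
class Spacer:
    pieces: list  # list[str | HairpinLocus]

    def clone(self) -> "Spacer":
        return Spacer([p.clone() if isinstance(p, HairpinLocus) else p
                       for p in self.pieces])


@dataclass
class Scaffold:
    name: str
    items: list  # list[GeneUnit | Spacer]

    def clone(self) -> "Scaffold":
        return Scaffold(self.name, [it.clone() for it in self.items])


Genome = dict  # scaffold name -> Scaffold


def clone_genome(g: Genome) -> Genome:
    return {k: v.clone() for k, v in g.items()}


def iter_hairpins(genome: Genome):
    """Yield (scaffold, container_list, index, hairpin, host_gene|None,
    genomic_intron_index|None)."""
    for scaf in genome.values():
        for item in scaf.items:
            if isinstance(item, Spacer):
                for i, p in enumerate(item.pieces):
                    if isinstance(p, HairpinLocus):
                        yield scaf, item.pieces, i, p, None, None
            else:
                for gi, intron in enumerate(item.introns):
                    for i, p in enumerate(intron):
                        if isinstance(p, HairpinLocus):
                            yield scaf, intron, i, p, item, gi


# ---------------------------------------------------------------------------
# Truth log
# ---------------------------------------------------------------------------

@dataclass
class TruthEvent:
    branch: str
    kind: str  # gain | duplication | loss | translocation | excision
    family: str
    locus_id: str


@dataclass
class TruthLocus:
    """Ground-truth placement of one emitted miRNA locus."""

    species: str
    family: str
    locus_id: str
    scaffold: str
    start: int  # 1-based closed
    end: int
    strand: str
    kind: str  # intronic | intergenic
    host: str | None
    intron_index: int | None  # transcription order


@dataclass
class TruthLog:
    events: list[TruthEvent] = field(default_factory=list)
    copy_numbers: dict = field(default_factory=dict)  # species -> family -> n
    ortholog_classes: dict = field(default_factory=dict)  # ancestral -> ["sp:gene", ...]
    loci: dict = field(default_factory=dict)  # species -> [TruthLocus]

    def events_for(self, family: str, kinds=("gain", "duplication", "loss")):
        return sorted(
            (e.branch, e.kind) for e in self.events
            if e.family == family and e.kind in kinds
        )

    def replay_copy_numbers(self, tree: Node) -> dict:
        """Replay gain/duplication/loss events down the tree; returns
        species -> family -> copy number."""
        by_branch: dict[str, list[TruthEvent]] = {}
        for e in self.events:
            by_branch.setdefault(e.branch, []).append(e)
        out: dict[str, dict[str, int]] = {}

        def walk(node: Node, state: dict[str, int]) -> None:
            state = dict(state)
            for e in by_branch.get(node.name, ()):
                if e.kind in ("gain", "duplication"):
                    state[e.family] = state.get(e.family, 0) + 1
                elif e.kind == "loss":
                    state[e.family] = state.get(e.family, 0) - 1
            if node.is_leaf:
                out[node.name] = {f: n for f, n in state.items() if n > 0}
            for c in node.children:
                walk(c, state)

        walk(tree, {})
        return out


# ---------------------------------------------------------------------------
# Builder
# ---------------------------------------------------------------------------

class _Simulator:
    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.tree = parse_newick(cfg.species_tree)
        self.truth = TruthLog()
        self.locus_counter: dict[str, int] = {}
        self.clone_counter = 0
        self.templates: dict[str, HairpinLocus] = {}
        self.leaf_genomes: dict[str, Genome] = {}
        self._nbhd_scaffold: dict[str, str] = {}

    # -- templates ----------------------------------------------------------

    def _new_locus_id(self, family: str) -> str:
        self.locus_counter[family] = self.locus_counter.get(family, 0) + 1
        return f"{family}_{self.locus_counter[family]}"

    def build_templates(self) -> None:
        cfg = self.cfg
        arm = (cfg.hairpin_template_length - cfg.loop_length) // 2
        for spec in cfg.families:
            arm5 = random_seq(self.rng, arm)
            loop = random_seq(self.rng, cfg.loop_length, alphabet="AC")
            self.templates[spec.name] = HairpinLocus(
                family=spec.name, locus_id="template",
                arm5=arm5, loop=loop, arm3=revcomp(arm5),
                strand=spec.strand, mature_offset=cfg.mature_offset,
                mature_length=cfg.mature_length,
            )
        # seed sharing (e.g. two families recognizing the same target seed)
        for spec in cfg.families:
            if spec.seed_like:
                src = self.templates[spec.seed_like]
                dst = self.templates[spec.name]
                mo = cfg.mature_offset
                a5 = list(dst.arm5)
                a5[mo + 1: mo + 8] = src.arm5[mo + 1: mo + 8]
                dst.arm5 = "".join(a5)
                dst.arm3 = revcomp(dst.arm5)

    # -- ancestral genome ---------------------------------------------------

    def _make_gene(self, name: str, ancestral: str, strand: str,
                   n_exons: int | None = None,
                   intron_payload: dict | None = None) -> GeneUnit:
        cfg = self.cfg
        ne = n_exons or cfg.n_exons
        exons = [random_seq(self.rng, cfg.exon_length) for _ in range(ne)]
        introns: list[list] = []
        for gi in range(ne - 1):
            if intron_payload and gi in intron_payload:
                introns.append(intron_payload[gi])
            else:
                introns.append([random_seq(self.rng, cfg.intron_length)])
        return GeneUnit(name, ancestral, strand, exons, introns)

    def _neighbor_name(self, nbhd: str, side: str, i: int) -> str:
        names = self.cfg.neighbor_names.get(nbhd, {}).get(side)
        if names and i < len(names):
            return names[i]
        return f"{nbhd}_{side}{i + 1}"

    def build_root_genome(self) -> Genome:
        cfg = self.cfg
        genome: Genome = {}
        nbhds: dict[str, list[FamilySpec]] = {}
        for spec in cfg.families:
            nbhds.setdefault(spec.neighborhood, []).append(spec)
        for si, (nbhd, specs) in enumerate(nbhds.items()):
            scaf_name = f"scaffold_{si + 1}"
            self._nbhd_scaffold[nbhd] = scaf_name
            items: list = [Spacer([random_seq(self.rng, cfg.spacer_length)])]
            for i in reversed(range(cfg.n_neighbor_genes)):
                g = self._make_gene(
                    self._neighbor_name(nbhd, "up", i),
                    self._neighbor_name(nbhd, "up", i),
                    "+" if i % 2 == 0 else "-",
                )
                items.append(g)
                items.append(Spacer([random_seq(self.rng, cfg.spacer_length)]))
            intronic = [s for s in specs if s.placement == "intronic"]
            intergenic = [s for s in specs if s.placement == "intergenic"]
            if intronic:
                host_spec = intronic[0]
                n_ex = host_spec.host_n_exons
                payload: dict[int, list] = {}
                by_intron: dict[int, list[FamilySpec]] = {}
                for s in intronic:
                    gidx = (s.intron_index - 1 if host_spec.host_strand == "+"
                            else (n_ex - 1) - s.intron_index)
                    by_intron.setdefault(gidx, []).append(s)
                for gidx, members in by_intron.items():
                    members = sorted(members, key=lambda s: s.offset)
                    pieces: list = []
                    cursor = 0
                    for s in members:
                        pieces.append(random_seq(self.rng, s.offset - cursor))
                        # placeholder slot: hairpin inserted at gain time
                        pieces.append(("SLOT", s.name))
                        cursor = s.offset + cfg.hairpin_template_length
                    pieces.append(random_seq(self.rng, 200))
                    payload[gidx] = pieces
                items.append(self._make_gene(
                    host_spec.host, host_spec.host, host_spec.host_strand,
                    n_exons=n_ex, intron_payload=payload,
                ))
                items.append(Spacer([random_seq(self.rng, cfg.spacer_length)]))
            if intergenic:
                members = sorted(intergenic, key=lambda s: s.offset)
                pieces: list = []
                cursor = 0
                for s in members:
                    pieces.append(random_seq(self.rng, s.offset - cursor))
                    pieces.append(("SLOT", s.name))
                    cursor = s.offset + cfg.hairpin_template_length
                tail = max(cfg.center_spacer_length - cursor, 200)
                pieces.append(random_seq(self.rng, tail))
                items.append(Spacer(pieces))
            for i in range(cfg.n_neighbor_genes):
                g = self._make_gene(
                    self._neighbor_name(nbhd, "down", i),
                    self._neighbor_name(nbhd, "down", i),
                    "+" if i % 2 == 1 else "-",
                )
                items.append(g)
                items.append(Spacer([random_seq(self.rng, cfg.spacer_length)]))
            genome[scaf_name] = Scaffold(scaf_name, items)
        return genome

    # -- gains --------------------------------------------------------------

    def _apply_gains(self, genome: Genome, node_name: str, is_root: bool) -> None:
        for spec in self.cfg.families:
            target = spec.gain_branch
            if (target is None and is_root) or target == node_name:
                self._insert_gain(genome, spec, node_name)

    def _insert_gain(self, genome: Genome, spec: FamilySpec, branch: str) -> None:
        hp = self.templates[spec.name].clone()
        hp.locus_id = self._new_locus_id(spec.name)
        for scaf in genome.values():
            for item in scaf.items:
                containers = (
                    [item.pieces] if isinstance(item, Spacer) else item.introns
                )
                for cont in containers:
                    for i, p in enumerate(cont):
                        if isinstance(p, tuple) and p == ("SLOT", spec.name):
                            if isinstance(item, GeneUnit):
                                hp.strand = item.strand
                            cont[i] = hp
                            self.truth.events.append(
                                TruthEvent(branch, "gain", spec.name, hp.locus_id))
                            return
        raise ConfigurationError(f"no slot found for family {spec.name}")

    # -- mutation -----------------------------------------------------------

    def _mutate_hairpin(self, hp: HairpinLocus, brlen: float) -> None:
        cfg = self.cfg
        seq = hp.seq
        codes = _seq_to_codes(seq)
        n = codes.size
        arm = len(hp.arm5)
        ms, me = hp.mature_interval
        mature_mask = np.zeros(n, dtype=bool)
        mature_mask[ms:me] = True
        d_loop = cfg.rate_loop * brlen
        d_mat = cfg.rate_mature * brlen
        new = _seq_to_codes(evolve_sequence(seq, d_loop, self.rng, cfg.kappa))
        new_m = _seq_to_codes(evolve_sequence(seq, d_mat, self.rng, cfg.kappa))
        new[mature_mask] = new_m[mature_mask]
        changed = np.nonzero(new != codes)[0]
        # compensatory partner changes keep the stem paired; with equal arms
        # and arm3 = revcomp(arm5), position i pairs with n-1-i
        loop_start, loop_end = arm, arm + len(hp.loop)
        for pos in changed:
            if loop_start <= pos < loop_end:
                continue
            partner = n - 1 - pos
            if partner < 0 or partner >= n or mature_mask[partner]:
                continue
            if self.rng.random() < cfg.compensation_prob:
                new[partner] = 3 - new[pos]  # Watson-Crick complement code
        out = _codes_to_seq(new)
        hp.arm5 = out[:arm]
        loop = out[arm:arm + len(hp.loop)]
        hp.arm3 = out[arm + len(hp.loop):]
        # rare small indels in the terminal loop only
        n_ev = self.rng.poisson(cfg.loop_indel_rate * brlen * len(loop))
        for _ in range(int(n_ev)):
            if len(loop) > 8 and self.rng.random() < 0.5:
                p = int(self.rng.integers(0, len(loop) - 1))
                loop = loop[:p] + loop[p + 1:]
            else:
                p = int(self.rng.integers(0, len(loop)))
                loop = loop[:p] + random_seq(self.rng, 1) + loop[p:]
        hp.loop = loop

    def _burst_hairpin(self, hp: HairpinLocus) -> None:
        """Post-duplication divergence burst outside the mature region,
        stem-compensated so the copy still folds."""
        lo, hi = self.cfg.paralog_burst
        if hi <= 0:
            return
        n_sub = int(self.rng.integers(lo, hi + 1))
        seq = hp.seq
        codes = _seq_to_codes(seq)
        n = codes.size
        arm = len(hp.arm5)
        ms, me = hp.mature_interval
        eligible = [i for i in range(n) if not (ms <= i < me)]
        pos = self.rng.choice(len(eligible), size=min(n_sub, len(eligible)),
                              replace=False)
        loop_start, loop_end = arm, arm + len(hp.loop)
        for idx in pos:
            i = eligible[int(idx)]
            codes[i] = (codes[i] + int(self.rng.integers(1, 4))) % 4
            if loop_start <= i < loop_end:
                continue
            partner = n - 1 - i
            if 0 <= partner < n and not (ms <= partner < me):
                if self.rng.random() < self.cfg.compensation_prob:
                    codes[partner] = 3 - codes[i]
        out = _codes_to_seq(codes)
        hp.arm5, hp.loop, hp.arm3 = (
            out[:arm], out[arm:arm + len(hp.loop)], out[arm + len(hp.loop):]
        )

    def _mutate_genome(self, genome: Genome, brlen: float) -> None:
        cfg = self.cfg
        d_gene = cfg.rate_flank_gene * brlen
        d_inter = cfg.rate_intergenic * brlen

        def do_pieces(pieces: list) -> None:
            for i, p in enumerate(pieces):
                if isinstance(p, HairpinLocus):
                    self._mutate_hairpin(p, brlen)
                elif isinstance(p, str):
                    pieces[i] = _mutate_with_indels(
                        p, d_inter, cfg.indel_rate, self.rng, cfg.kappa
                    )

        for scaf in genome.values():
            for item in scaf.items:
                if isinstance(item, Spacer):
                    do_pieces(item.pieces)
                else:
                    item.exons = [
                        evolve_sequence(e, d_gene, self.rng, cfg.kappa)
                        for e in item.exons
                    ]
                    for intron in item.introns:
                        do_pieces(intron)

    # -- structural events --------------------------------------------------

    def _loci_of(self, genome: Genome, family: str | None = None):
        return [t for t in iter_hairpins(genome)
                if family is None or t[3].family == family]

    def _apply_event(self, genome: Genome, branch: str, kind: str,
                     family: str | None, detail: dict) -> None:
        loci = self._loci_of(genome, family)
        if kind == "excision":
            loci = [t for t in loci if t[4] is not None]
        if detail.get("host"):
            loci = [t for t in loci
                    if t[4] is not None and t[4].name == detail["host"]]
        if not loci:
            return  # nothing eligible in this lineage
        pick = loci[int(self.rng.integers(0, len(loci)))]
        scaf, cont, idx, hp, host, gi = pick
        if kind == "duplication":
            self._duplicate(genome, branch, scaf, hp, host)
        elif kind == "loss":
            cont[idx] = ""
            self.truth.events.append(TruthEvent(branch, "loss", hp.family, hp.locus_id))
        elif kind == "excision":
            cont[idx] = ""
            gidx = scaf.items.index(host)
            target = None
            for j in range(gidx + 1, len(scaf.items)):
                if isinstance(scaf.items[j], Spacer):
                    target = scaf.items[j]
                    break
            if target is None:
                target = Spacer([])
                scaf.items.append(target)
            hp2 = hp  # locus identity preserved
            first = target.pieces[0] if target.pieces and isinstance(target.pieces[0], str) else ""
            cut = min(len(first), 200)
            if first:
                target.pieces[0:1] = [first[:cut], hp2, first[cut:]]
            else:
                target.pieces.insert(0, hp2)
            self.truth.events.append(
                TruthEvent(branch, "excision", hp.family, hp.locus_id))
        elif kind == "translocation":
            self._translocate(branch, scaf, hp, host, detail)
        else:
            raise ConfigurationError(f"unknown event kind {kind!r}")

    def _duplicate(self, genome: Genome, branch: str, scaf: Scaffold,
                   hp: HairpinLocus, host: GeneUnit | None) -> None:
        cfg = self.cfg
        new_hp = hp.clone()
        new_hp.locus_id = self._new_locus_id(hp.family)
        self._burst_hairpin(new_hp)
        self.clone_counter += 1
        suffix = str(self.clone_counter)
        block: list = []
        items = scaf.items
        if host is not None:
            gidx = items.index(host)
            newhost = host.clone()
            newhost.name = f"{host.name}.d{suffix}"
            # swap the duplicated hairpin into the cloned host's intron
            swapped = False
            for intron in newhost.introns:
                for i, p in enumerate(intron):
                    if isinstance(p, HairpinLocus) and p.locus_id == hp.locus_id:
                        intron[i] = new_hp
                        swapped = True
                    elif isinstance(p, HairpinLocus):
                        intron[i] = ""  # sister loci do not co-duplicate here
            if not swapped:
                raise RuntimeError("host clone lost its hairpin")
            block.append(newhost)
            neigh = [it for it in items[gidx + 1:] if isinstance(it, GeneUnit)]
            for g in neigh[:cfg.dup_neighbor_count]:
                gc = g.clone()
                gc.name = f"{g.name}.d{suffix}"
                for intron in gc.introns:
                    for i, p in enumerate(intron):
                        if isinstance(p, HairpinLocus):
                            intron[i] = ""
                block.append(gc)
        else:
            # intergenic: copy the hairpin with a slice of flanking spacer and
            # the nearest downstream neighbor genes
            pad = random_seq(self.rng, 150)
            block.append(Spacer([pad, new_hp, random_seq(self.rng, 150)]))
            anchor_idx = None
            for j, it in enumerate(items):
                if isinstance(it, Spacer) and any(
                    isinstance(p, HairpinLocus) and p.locus_id == hp.locus_id
                    for p in it.pieces
                ):
                    anchor_idx = j
                    break
            start_at = (anchor_idx + 1) if anchor_idx is not None else 0
            neigh = [it for it in items[start_at:] if isinstance(it, GeneUnit)]
            for g in neigh[:cfg.dup_neighbor_count]:
                gc = g.clone()
                gc.name = f"{g.name}.d{suffix}"
                for intron in gc.introns:
                    for i, p in enumerate(intron):
                        if isinstance(p, HairpinLocus):
                            intron[i] = ""
                block.append(gc)
        others = [s for s in genome.values() if s.name != scaf.name]
        target = others[int(self.rng.integers(0, len(others)))] if others else scaf
        insert: list = []
        for b in block:
            insert.append(b)
            insert.append(Spacer([random_seq(self.rng, cfg.spacer_length)]))
        target.items.extend(insert)
        self.truth.events.append(
            TruthEvent(branch, "duplication", hp.family, new_hp.locus_id))

    def _translocate(self, branch: str, scaf: Scaffold, hp: HairpinLocus,
                     host: GeneUnit | None, detail: dict) -> None:
        items = scaf.items
        if host is not None:
            anchor_idx = items.index(host)
        else:
            anchor_idx = next(
                j for j, it in enumerate(items)
                if isinstance(it, Spacer) and any(
                    isinstance(p, HairpinLocus) and p.locus_id == hp.locus_id
                    for p in it.pieces
                )
            )
        gene_names = detail.get("genes")
        moved: list[int] = []
        if gene_names:
            for j, it in enumerate(items):
                if isinstance(it, GeneUnit) and it.ancestral in gene_names:
                    moved.append(j)
        else:
            k = int(self.rng.integers(1, 4))
            downstream = [j for j, it in enumerate(items)
                          if j > anchor_idx and isinstance(it, GeneUnit)]
            moved = downstream[:k]
        if not moved:
            return
        genes = [items[j] for j in moved]
        n_before = sum(1 for j in moved if j < anchor_idx)
        for j in reversed(moved):
            del items[j]
        # re-insert immediately upstream of the anchor
        insert_at = max(anchor_idx - n_before, 0)
        chunk: list = []
        for g in genes:
            chunk.append(g)
            chunk.append(Spacer([random_seq(self.rng, self.cfg.spacer_length)]))
        items[insert_at:insert_at] = chunk
        self.truth.events.append(
            TruthEvent(branch, "translocation", hp.family, hp.locus_id))

    def _branch_events(self, genome: Genome, node: Node) -> None:
        cfg = self.cfg
        if cfg.scripted_events is not None:
            for ev in cfg.scripted_events:
                if ev.branch == node.name:
                    self._apply_event(genome, node.name, ev.kind, ev.family,
                                      ev.detail)
            return
        for kind, rate in (
            ("duplication", cfg.duplication_rate),
            ("loss", cfg.loss_rate),
            ("translocation", cfg.translocation_rate),
            ("excision", cfg.excision_rate),
        ):
            for _ in range(int(self.rng.poisson(rate))):
                self._apply_event(genome, node.name, kind, None, {})

    # -- traversal ----------------------------------------------------------

    def run(self) -> None:
        self.build_templates()

        def walk(node: Node, genome: Genome) -> None:
            if node.parent is not None:
                genome = clone_genome(genome)
                self._mutate_genome(genome, node.length)
                self._branch_events(genome, node)
            self._apply_gains(genome, node.name, is_root=node.parent is None)
            if node.is_leaf:
                self._strip_slots(genome)
                self.leaf_genomes[node.name] = genome
            for c in node.children:
                walk(c, genome)

        root_genome = self.build_root_genome()
        walk(self.tree, root_genome)
        self._fill_truth()

    @staticmethod
    def _strip_slots(genome: Genome) -> None:
        for scaf in genome.values():
            for item in scaf.items:
                conts = [item.pieces] if isinstance(item, Spacer) else item.introns
                for cont in conts:
                    for i, p in enumerate(cont):
                        if isinstance(p, tuple):
                            cont[i] = ""

    def _fill_truth(self) -> None:
        for sp, genome in self.leaf_genomes.items():
            counts: dict[str, int] = {}
            for _, _, _, hp, _, _ in iter_hairpins(genome):
                counts[hp.family] = counts.get(hp.family, 0) + 1
            self.truth.copy_numbers[sp] = counts
            for scaf in genome.values():
                for item in scaf.items:
                    if isinstance(item, GeneUnit):
                        self.truth.ortholog_classes.setdefault(
                            item.ancestral, []).append(f"{sp}:{item.name}")


# ---------------------------------------------------------------------------
# Emission (FASTA / GFF3 / Newick / TSV)
# ---------------------------------------------------------------------------

def _piece_seq(p) -> str:
    if isinstance(p, HairpinLocus):
        return p.seq if p.strand == "+" else revcomp(p.seq)
    if isinstance(p, str):
        return p
    return ""


def render_species(genome: Genome, species: str):
    """Flatten a genome into (sequences, gff_rows, truth_loci)."""
    seqs: dict[str, str] = {}
    rows: list[tuple] = []
    tloci: list[TruthLocus] = []
    for scaf in genome.values():
        parts: list[str] = []
        pos = 1

        def emit_pieces(pieces, host: GeneUnit | None, gidx: int | None) -> None:
            nonlocal pos
            for p in pieces:
                s = _piece_seq(p)
                if isinstance(p, HairpinLocus):
                    strand = p.strand if host is None else host.strand
                    start, end = pos, pos + len(s) - 1
                    rows.append((scaf.name, "miRNA", start, end, strand,
                                 f"ID={p.locus_id};Name={p.family}"))
                    tloci.append(TruthLocus(
                        species, p.family, p.locus_id, scaf.name, start, end,
                        strand,
                        "intronic" if host is not None else "intergenic",
                        host.name if host is not None else None,
                        host.transcription_intron_index(gidx)
                        if host is not None else None,
                    ))
                parts.append(s)
                pos += len(s)

        for item in scaf.items:
            if isinstance(item, Spacer):
                emit_pieces(item.pieces, None, None)
            else:
                gstart = pos
                exon_rows = []
                for ei, exon in enumerate(item.exons):
                    estart = pos
                    parts.append(exon)
                    pos += len(exon)
                    exon_rows.append((estart, pos - 1))
                    if ei < len(item.introns):
                        emit_pieces(item.introns[ei], item, ei)
                gend = pos - 1
                gid = f"{species}:{item.name}"
                rows.append((scaf.name, "gene", gstart, gend, item.strand,
                             f"ID={gid};Name={item.name};biotype=protein_coding"))
                rows.append((scaf.name, "mRNA", gstart, gend, item.strand,
                             f"ID={gid}.t1;Parent={gid}"))
                for k, (a, b) in enumerate(exon_rows):
                    rows.append((scaf.name, "exon", a, b, item.strand,
                                 f"ID={gid}.e{k + 1};Parent={gid}.t1"))
        seqs[scaf.name] = "".join(parts)
    return seqs, rows, tloci


def write_fasta(path, records, width: int = 60) -> None:
    """records: iterable of (id, description, sequence)."""
    with open(path, "w") as fh:
        for rid, desc, seq in records:
            header = f">{rid} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(path, rows) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, ftype, start, end, strand, attrs in rows:
            fh.write(
                f"{seqid}\tmyomir_sim\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )


@dataclass
class FixtureBundle:
    """Paths of one emitted synthetic dataset plus its in-memory truth."""

    out_dir: str
    species: list[str]
    fasta: dict
    gff: dict
    tree_path: str
    queries_path: str
    matures_path: str
    utrs_path: str
    truth_events_path: str
    truth_copies_path: str
    truth_orthologs_path: str
    truth: TruthLog


def _make_utrs(cfg: SimulationConfig, matures: dict, rng: np.random.Generator):
    """Random 3'UTRs with planted 8mer seed sites for every mature in the
    pool, so each miRNA has a non-trivial target set."""
    utrs = {
        f"utr_{i + 1:04d}": random_seq(rng, cfg.utr_length)
        for i in range(cfg.n_utrs)
    }
    ids = list(utrs)
    for name, mat in matures.items():
        seed7 = mat[1:8].upper().replace("U", "T")
        site = revcomp(seed7) + "A"
        chosen = rng.choice(len(ids), size=min(cfg.utr_site_plant, len(ids)),
                            replace=False)
        for ci in chosen:
            uid = ids[int(ci)]
            seq = utrs[uid]
            p = int(rng.integers(0, len(seq) - len(site)))
            utrs[uid] = seq[:p] + site + seq[p + len(site):]
    return utrs


def simulate_dataset(config: SimulationConfig, out_dir) -> FixtureBundle:
    """Run the generator and emit the full fixture bundle to ``out_dir``.

    Writes one FASTA+GFF3 per species, the species tree, the ancestral
    precursor queries (with mature coordinates in the description), the mature
    pool (family matures plus random decoys), a planted-site 3'UTR set, and
    the truth log as three TSVs. Byte-identical for a fixed config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = _Simulator(config)
    sim.run()
    fasta_paths: dict[str, str] = {}
    gff_paths: dict[str, str] = {}
    species = sorted(sim.leaf_genomes)
    for sp in species:
        seqs, rows, tloci = render_species(sim.leaf_genomes[sp], sp)
        fa = out / f"{sp}.fa"
        write_fasta(fa, [(k, "", v) for k, v in seqs.items()])
        gf = out / f"{sp}.gff3"
        write_gff3(gf, rows)
        fasta_paths[sp] = str(fa)
        gff_paths[sp] = str(gf)
        sim.truth.loci[sp] = tloci
    tree_path = out / "species_tree.nwk"
    tree_path.write_text(to_newick(sim.tree) + "\n")
    mo, ml = config.mature_offset, config.mature_length
    queries = [
        (fam, f"mature={mo + 1}-{mo + ml}", hp.seq)
        for fam, hp in sim.templates.items()
    ]
    queries_path = out / "queries.fa"
    write_fasta(queries_path, queries)
    mat_rng = np.random.default_rng(config.seed + 104729)
    matures = {fam: hp.mature for fam, hp in sim.templates.items()}
    for i in range(config.n_decoy_matures):
        matures[f"decoy_{i + 1:02d}"] = random_seq(mat_rng, config.mature_length)
    matures_path = out / "matures.fa"
    write_fasta(matures_path, [(k, "", v) for k, v in matures.items()])
    utrs = _make_utrs(config, matures, mat_rng)
    utrs_path = out / "utrs.fa"
    write_fasta(utrs_path, [(k, "", v) for k, v in utrs.items()])
    ev_path = out / "truth_events.tsv"
    with open(ev_path, "w") as fh:
        fh.write("branch\tevent\tfamily\tlocus_id\n")
        for e in sim.truth.events:
            fh.write(f"{e.branch}\t{e.kind}\t{e.family}\t{e.locus_id}\n")
    families = [s.name for s in config.families]
    cp_path = out / "truth_copies.tsv"
    with open(cp_path, "w") as fh:
        fh.write("species\t" + "\t".join(families) + "\n")
        for sp in species:
            counts = sim.truth.copy_numbers.get(sp, {})
            fh.write(sp + "\t" + "\t".join(
                str(counts.get(f, 0)) for f in families) + "\n")
    og_path = out / "truth_orthologs.tsv"
    with open(og_path, "w") as fh:
        fh.write("class\tmembers\n")
        for anc in sorted(sim.truth.ortholog_classes):
            members = ",".join(sorted(sim.truth.ortholog_classes[anc]))
            fh.write(f"{anc}\t{members}\n")
    return FixtureBundle(
        out_dir=str(out), species=species, fasta=fasta_paths, gff=gff_paths,
        tree_path=str(tree_path), queries_path=str(queries_path),
        matures_path=str(matures_path), utrs_path=str(utrs_path),
        truth_events_path=str(ev_path), truth_copies_path=str(cp_path),
        truth_orthologs_path=str(og_path), truth=sim.truth,
    )


def simulate_precursor_family(
    tree: str | Node,
    rng: np.random.Generator,
    rate_mature: float = 0.04,
    rate_loop: float = 0.35,
    kappa: float = 2.0,
    compensation_prob: float = 0.8,
    hairpin_length: int = 85,
    loop_length: int = 11,
    mature_offset: int = 5,
    mature_length: int = 22,
):
    """Evolve a single precursor family along a tree (no structural events).

    Returns ``{leaf: (sequence, (mature_start, mature_end))}``; a light-weight
    path used for conservation-gradient studies without building genomes.
    """
    if isinstance(tree, str):
        tree = parse_newick(tree)
    cfg = SimulationConfig(
        rate_mature=rate_mature, rate_loop=rate_loop, kappa=kappa,
        compensation_prob=compensation_prob,
        hairpin_template_length=hairpin_length, loop_length=loop_length,
        mature_offset=mature_offset, mature_length=mature_length,
        loop_indel_rate=0.0,
    )
    sim = _Simulator(cfg)
    sim.rng = rng
    arm = (hairpin_length - loop_length) // 2
    arm5 = random_seq(rng, arm)
    root_hp = HairpinLocus(
        "fam", "fam_1", arm5, random_seq(rng, loop_length, "AC"), revcomp(arm5),
        mature_offset=mature_offset, mature_length=mature_length,
    )
    out: dict[str, tuple[str, tuple[int, int]]] = {}

    def walk(node: Node, hp: HairpinLocus) -> None:
        if node.parent is not None:
            hp = hp.clone()
            sim._mutate_hairpin(hp, node.length)
        if node.is_leaf:
            out[node.name] = (hp.seq, hp.mature_interval)
        for c in node.children:
            walk(c, hp)

    walk(tree, root_hp)
    return out


# ---------------------------------------------------------------------------
# The scripted vertebrate preset
# ---------------------------------------------------------------------------

PRESET_TREE = (
    "(lamprey:0.12,(elephant_shark:0.10,((human:0.08,coelacanth:0.08)"
    "sarcopterygii:0.05,(zebrafish:0.09,(tilapia:0.06,(medaka:0.06,"
    "(stickleback:0.05,(tetraodon:0.04,fugu:0.04)tetraodontiformes:0.03)"
    "percomorpha:0.02)ovalentaria:0.02)acanthopterygii:0.04)actinopterygii:0.05)"
    "osteichthyes:0.04)gnathostomes:0.05)vertebrata;"
)

ACANTHOPTERYGII_LEAVES = ("tilapia", "medaka", "stickleback", "tetraodon", "fugu")

MIR214_DOWNSTREAM = [
    "pigc", "tmed5", "suco", "mysm1", "oma1", "prdx6", "myoc", "prrc2c",
    "vamp4", "mettl13", "jun", "ppapdc2",
]


def _preset_families() -> list[FamilySpec]:
    hp = 85
    return [
        FamilySpec("mir-1-2", "intronic", "nb_mib1", host="mib1",
                   host_n_exons=13, intron_index=11, offset=60),
        FamilySpec("mir-133a-1", "intronic", "nb_mib1", host="mib1",
                   host_n_exons=13, intron_index=11, offset=60 + hp + 1800),
        FamilySpec("mir-1-1", "intergenic", "nb_133a2", offset=1500),
        FamilySpec("mir-133a-2", "intergenic", "nb_133a2",
                   offset=1500 + hp + 8900),
        FamilySpec("mir-206", "intergenic", "nb_206",
                   gain_branch="osteichthyes", offset=2000),
        FamilySpec("mir-133b", "intergenic", "nb_206",
                   gain_branch="osteichthyes", offset=2000 + hp + 3900),
        FamilySpec("mir-208", "intronic", "nb_myh6", host="myh6",
                   intron_index=2, offset=80),
        FamilySpec("mir-499", "intronic", "nb_myh7b", host="myh7b",
                   host_strand="-", intron_index=2, offset=80,
                   gain_branch="osteichthyes", seed_like="mir-208"),
        FamilySpec("mir-214", "intronic", "nb_dnm3", host="dnm3",
                   intron_index=3, offset=100, gain_branch="gnathostomes"),
    ]


def _preset_events() -> list[ScriptedEvent]:
    return [
        ScriptedEvent("lamprey", "duplication", "mir-208"),
        ScriptedEvent("human", "duplication", "mir-208"),
        ScriptedEvent("elephant_shark", "loss", "mir-208"),
        ScriptedEvent("actinopterygii", "loss", "mir-208"),
        ScriptedEvent("acanthopterygii", "duplication", "mir-214"),
        ScriptedEvent("zebrafish", "duplication", "mir-499"),
        ScriptedEvent("zebrafish", "duplication", "mir-499"),
        ScriptedEvent("zebrafish", "duplication", "mir-206"),
        ScriptedEvent("zebrafish", "duplication", "mir-133b"),
        ScriptedEvent("tetraodontiformes", "loss", "mir-1-1"),
        ScriptedEvent("tetraodontiformes", "loss", "mir-133a-2"),
        ScriptedEvent("tetraodon", "translocation", "mir-214",
                      {"host": "dnm3",
                       "genes": ["pigc", "tmed5", "suco", "mysm1", "oma1"]}),
    ]


def vertebrate_scenario_preset(seed: int = 0) -> tuple[SimulationConfig, TruthLog]:
    """Deterministic scripted scenario of muscle-miRNA evolution on a 10-leaf
    vertebrate tree.

    Encodes: root origin of the miR-1/133 clusters and miR-208 (with the
    lamprey and mammal miR-208 duplications), miR-206/133b and miR-499 origins
    on the bony-fish stem, miR-208 losses on the cartilaginous and ray-finned
    stems, the miR-214 duplication on the Acanthopterygii stem (the divergent
    "miR-214-par" copy), the zebrafish-specific miR-499 double duplication and
    miR-206/133b duplication, the miR-1-1/133a-2 cluster loss on the
    Tetraodontiformes stem, and a miR-214 neighborhood translocation in
    tetraodon. Returns the config plus a truth-log template carrying the
    scripted event list and the per-species copy numbers they imply.
    """
    cfg = SimulationConfig(
        species_tree=PRESET_TREE,
        families=_preset_families(),
        scripted_events=_preset_events(),
        neighbor_names={"nb_dnm3": {"down": MIR214_DOWNSTREAM}},
        seed=seed,
        preset_name="vertebrate",
    )
    template = TruthLog()
    tree = parse_newick(PRESET_TREE)
    for spec in cfg.families:
        template.events.append(TruthEvent(
            spec.gain_branch or tree.name, "gain", spec.name, ""))
    for ev in _preset_events():
        template.events.append(TruthEvent(ev.branch, ev.kind, ev.family, ""))
    template.copy_numbers = template.replay_copy_numbers(tree)
    return cfg, template


PRESETS = {"vertebrate": vertebrate_scenario_preset}
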