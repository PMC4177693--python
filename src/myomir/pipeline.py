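"""End-to-end orchestration: map precursors, classify contexts, score
synteny, build trees and event scenarios, verify hairpins, and test target
overlap — from one configuration, into one reproducible report bundle.

A run is fully determined by its configuration and seed: every output file
except the timestamped log is byte-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alignment import align_pair, center_star_msa, conservation_summary, revcomp
from .context import classify_context, detect_clusters, read_gene_models
from .hairpin import fold_maxpair, hairpin_verdict
from .mapping import (
    MirnaLocus,
    build_locus_matrix,
    consolidate_loci,
    copy_number_matrix,
    locus_matrix_tsv,
    read_fasta,
    read_query_matures,
    search_precursors,
)
from .phylo import bootstrap_supports, detect_paralog_clade, infer_events
from .simulate import PRESETS, simulate_dataset
from .synteny import (
    AnchorUnavailableError,
    build_orthology,
    compare_windows,
    extract_window,
    orthology_from_truth,
    select_anchor,
)
from .targets import random_pair_null, shared_target_fraction
from .trees import parse_newick, to_newick

log = logging.getLogger("myomir")


@dataclass
class PipelineConfig:
    """Everything a run needs; paths may be filled by a synthetic preset."""

    out_dir: str = "myomir_out"
    seed: int = 0
    synthetic: str | None = None  # preset name; generates inputs under out_dir
    genomes: dict = field(default_factory=dict)  # species -> FASTA path
    annotations: dict = field(default_factory=dict)  # species -> GFF3 path
    tree_path: str | None = None
    queries_path: str | None = None
    matures_path: str | None = None
    utrs_path: str | None = None
    truth_events_path: str | None = None
    truth_orthologs_path: str | None = None
    # mapping
    min_identity: float = 80.0
    min_coverage: float = 0.8
    word_size: int = 11
    # context / synteny
    max_gap: int = 50_000
    window_n: int = 9
    reference_species: str | None = None
    use_truth_orthology: bool = True
    # trees / events
    bootstrap_reps: int = 1000
    support_threshold: float = 50.0
    outgroup_preference: list = field(default_factory=lambda: [
        "human", "coelacanth", "elephant_shark", "lamprey"])
    w_dup: float = 1.0
    w_loss: float = 2.0
    copy_cap: int = 4
    # hairpin
    min_stem: int = 18
    max_loop: int = 20
    min_paired: float = 0.6
    # targets
    focal_pair: list = field(default_factory=lambda: ["mir-208", "mir-499"])
    n_perm: int = 999
    threads: int = 1  # accepted for interface compatibility; results are
    #                   independent of it (all stages are deterministic)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _setup_logging(out: Path, verbose: bool = False) -> None:
    log.setLevel(logging.DEBUG if verbose else logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    log.addHandler(sh)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(fmt)
    log.addHandler(fh)


def _extract_locus_seq(genome: dict, locus: MirnaLocus) -> str:
    s = genome[locus.seqid][locus.start - 1: locus.end]
    return revcomp(s) if locus.strand == "-" else s


def _map_mature_interval(query: str, q_interval: tuple[int, int],
                         locus_seq: str) -> tuple[int, int]:
    """Project the query's mature interval onto a mapped locus sequence via
    global alignment."""
    p = align_pair(query, locus_seq)
    qpos = -1
    lpos = -1
    lo = hi = None
    for qc, lc in zip(p.a, p.b):
        if qc != "-":
            qpos += 1
        if lc != "-":
            lpos += 1
        if qc != "-" and q_interval[0] <= qpos < q_interval[1] and lc != "-":
            if lo is None:
                lo = lpos
            hi = lpos + 1
    if lo is None:  # mature fully deleted in the locus (should not happen)
        return 0, min(len(locus_seq), q_interval[1] - q_interval[0])
    return lo, hi


def _json_dump(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _round(x: float, nd: int = 4) -> float:
    return float(round(float(x), nd))


def run_pipeline(config: PipelineConfig, verbose: bool = False) -> dict:
    """Execute all stages; returns a manifest dict (also written to the
    bundle). Per-family/species failures are recorded and skipped without
    aborting unrelated work."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, verbose)
    errors: list[str] = []
    truth = None
    cfg = config
    if cfg.synthetic:
        if cfg.synthetic not in PRESETS:
            raise ValueError(f"unknown preset {cfg.synthetic!r}")
        log.info("generating synthetic dataset: preset=%s seed=%d",
                 cfg.synthetic, cfg.seed)
        sim_cfg, _ = PRESETS[cfg.synthetic](seed=cfg.seed)
        bundle = simulate_dataset(sim_cfg, out / "fixture")
        truth = bundle.truth
        cfg = replace(
            cfg,
            genomes=bundle.fasta, annotations=bundle.gff,
            tree_path=bundle.tree_path, queries_path=bundle.queries_path,
            matures_path=bundle.matures_path, utrs_path=bundle.utrs_path,
            truth_events_path=bundle.truth_events_path,
            # precursor thresholds sized for the preset's divergence depth
            # plus the post-duplication paralog burst
            min_identity=min(cfg.min_identity, 70.0),
        )
    for sp, p in {**cfg.genomes, **cfg.annotations}.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"missing input for {sp}: {p}")
    for p in (cfg.tree_path, cfg.queries_path):
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"missing required input: {p}")

    species = sorted(cfg.genomes)
    queries = read_fasta(cfg.queries_path)
    q_matures = read_query_matures(cfg.queries_path)
    families = sorted(queries)
    genomes = {sp: read_fasta(cfg.genomes[sp]) for sp in species}

    # -- mapping ------------------------------------------------------------
    log.info("mapping %d precursor families in %d species",
             len(families), len(species))
    loci_by_sp: dict[str, list[MirnaLocus]] = {}
    for sp in species:
        try:
            hits = search_precursors(
                queries, genomes[sp], min_identity=cfg.min_identity,
                min_coverage=cfg.min_coverage, word_size=cfg.word_size,
                species=sp)
            loci_by_sp[sp] = consolidate_loci(hits)
        except Exception as e:  # noqa: BLE001 - stage isolation
            errors.append(f"mapping/{sp}: {e}")
            loci_by_sp[sp] = []
    matrix = build_locus_matrix(loci_by_sp, species, families)
    (out / "locus_matrix.tsv").write_text(locus_matrix_tsv(matrix))
    copy_m = copy_number_matrix(matrix)
    copy_m.to_csv(out / "copy_numbers.tsv", sep="\t")

    # locus sequences + projected mature intervals
    locus_seqs: dict[str, dict[str, tuple[str, tuple[int, int]]]] = {}
    for sp in species:
        for h in loci_by_sp[sp]:
            seq = _extract_locus_seq(genomes[sp], h)
            mi = _map_mature_interval(queries[h.family],
                                      q_matures.get(h.family, (1, 23)), seq)
            locus_seqs.setdefault(h.family, {})[f"{sp}|{h.copy_index}"] = (seq, mi)

    # -- conservation (per family, across species) --------------------------
    log.info("summarizing cross-species conservation")
    cons_input = {
        fam: [v for v in sorted(members.items())]
        for fam, members in locus_seqs.items()
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cons = conservation_summary(
            {f: [v for _, v in m] for f, m in cons_input.items()})
    with open(out / "conservation.tsv", "w") as fh:
        fh.write("family\tn_sequences\tprecursor_length\t"
                 "mature_identity\tstemloop_identity\n")
        for c in sorted(cons, key=lambda c: c.family):
            fh.write(f"{c.family}\t{c.n_sequences}\t{c.precursor_length}\t"
                     f"{c.mature_identity:.1f}\t{c.stemloop_identity:.1f}\n")

    # -- genomic context + clusters -----------------------------------------
    log.info("classifying genomic context")
    gene_models = {sp: read_gene_models(cfg.annotations[sp]) for sp in species
                   if sp in cfg.annotations}
    contexts: dict[tuple[str, str, int], object] = {}
    with open(out / "context.tsv", "w") as fh:
        fh.write("species\tfamily\tcopy\tlocus\tkind\thost\tintron_index\t"
                 "upstream\tup_dist\tdownstream\tdown_dist\tcluster\tspan\n")
        for sp in species:
            genes = gene_models.get(sp, [])
            clusters = detect_clusters(loci_by_sp[sp], cfg.max_gap) \
                if loci_by_sp[sp] else []
            cluster_of = {}
            for ci, cl in enumerate(clusters, 1):
                for m in cl.members:
                    cluster_of[id(m)] = (f"c{ci}", cl.span)
            for h in loci_by_sp[sp]:
                try:
                    ctx = classify_context(h, genes)
                except Exception as e:  # noqa: BLE001
                    errors.append(f"context/{sp}/{h.family}: {e}")
                    continue
                contexts[(sp, h.family, h.copy_index)] = (h, ctx)
                cid, span = cluster_of.get(id(h), ("-", 0))
                fh.write("\t".join(str(x) for x in (
                    sp, h.family, h.copy_index, h.label, ctx.kind,
                    ctx.host_gene or "-", ctx.intron_index or "-",
                    ctx.upstream_gene or "-", ctx.upstream_distance
                    if ctx.upstream_distance is not None else "-",
                    ctx.downstream_gene or "-", ctx.downstream_distance
                    if ctx.downstream_distance is not None else "-",
                    cid, span,
                )) + "\n")

    # -- synteny ------------------------------------------------------------
    log.info("scoring microsynteny windows")
    if truth is not None and cfg.use_truth_orthology:
        omap = orthology_from_truth(truth.ortholog_classes)
    elif cfg.truth_orthologs_path:
        classes = {}
        for line in Path(cfg.truth_orthologs_path).read_text().splitlines()[1:]:
            cid, members = line.split("\t")
            classes[cid] = set(members.split(","))
        omap = orthology_from_truth(classes)
    else:
        log.info("building reciprocal-best-hit orthology from annotations")
        gene_seqs = {}
        for sp in species:
            genome = genomes[sp]
            gene_seqs[sp] = {}
            for g in gene_models.get(sp, []):
                exons = next(iter(g.transcripts.values()))
                seq = "".join(genome[g.seqid][a - 1:b] for a, b in exons)
                gene_seqs[sp][g.name] = seq
        omap = build_orthology(gene_seqs)
    windows: dict[tuple[str, str, int], object] = {}
    for (sp, fam, ci), (h, ctx) in contexts.items():
        try:
            anchor = select_anchor(h, ctx, gene_models.get(sp, []))
            windows[(sp, fam, ci)] = extract_window(
                anchor, gene_models[sp], n=cfg.window_n, species=sp)
        except AnchorUnavailableError as e:
            errors.append(f"synteny/{sp}/{fam}.{ci}: {e}")
    ref_sp = cfg.reference_species
    if ref_sp is None and species:
        # reference = species with the most mapped families
        ref_sp = max(species, key=lambda sp: (int((copy_m[sp] > 0).sum()), sp))
    with open(out / "synteny.tsv", "w") as fh:
        fh.write("ref_species\tother_species\tfamily\tcopy\tshared\t"
                 "colinear_run\torientation_agree\tside_switches\tmissing\n")
        for (sp, fam, ci), win in sorted(windows.items()):
            refwin = windows.get((ref_sp, fam, 1))
            if refwin is None or sp == ref_sp:
                continue
            sc = compare_windows(refwin, win, omap)
            fh.write("\t".join(str(x) for x in (
                ref_sp, sp, fam, ci, sc.shared, sc.colinear_run,
                sc.orientation_agree,
                ",".join(sc.side_switches) or "-",
                ",".join(sc.missing_in_other) or "-",
            )) + "\n")

    # -- trees + paralog clades ---------------------------------------------
    log.info("building precursor trees for multi-copy families")
    (out / "trees").mkdir(exist_ok=True)
    paralog_report = {}
    multi = [f for f in families
             if f in locus_seqs and any(
                 copy_m.loc[f, sp] > 1 for sp in species)]
    for fam in multi:
        members = locus_seqs[fam]
        if len(members) < 4:
            continue
        names = sorted(members)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows = center_star_msa([members[n][0] for n in names])
            msa = dict(zip(names, rows))
            tree = bootstrap_supports(msa, n_reps=cfg.bootstrap_reps,
                                      seed=cfg.seed)
        (out / "trees" / f"{fam}.nwk").write_text(
            to_newick(tree, supports=True) + "\n")
        # putative paralogs: in species with >1 copy, every copy except the
        # one closest to the ancestral query (divergent-copy heuristic)
        paralogs = set()
        for sp in species:
            sp_loci = [h for h in loci_by_sp[sp] if h.family == fam]
            if len(sp_loci) > 1:
                best = max(sp_loci, key=lambda h: h.identity)
                paralogs |= {f"{sp}|{h.copy_index}" for h in sp_loci
                             if h is not best}
        outgroup = None
        for sp in cfg.outgroup_preference:
            cands = [n for n in names if n.startswith(f"{sp}|")]
            if cands and not (set(cands) & paralogs):
                outgroup = cands[0]
                break
        # a clade hypothesis needs paralogs shared by >= 2 species; a
        # single-species duplicate has no subtending edge to support
        if (not paralogs or outgroup is None
                or len({p.split("|")[0] for p in paralogs}) < 2):
            continue
        try:
            verdict = detect_paralog_clade(
                tree, paralogs, outgroup=outgroup,
                support_threshold=cfg.support_threshold)
        except Exception as e:  # noqa: BLE001
            errors.append(f"paralog_clade/{fam}: {e}")
            continue
        paralog_report[fam] = {
            "paralog_leaves": sorted(paralogs),
            "outgroup": outgroup,
            "monophyletic": verdict["monophyletic"],
            "support": verdict["support"],
            "verdict": verdict["verdict"],
        }
    _json_dump(out / "paralog_clades.json", paralog_report)

    # -- event inference -----------------------------------------------------
    log.info("inferring gain/loss/duplication scenarios")
    species_tree = parse_newick(Path(cfg.tree_path).read_text())
    events = infer_events(species_tree, copy_m, w_dup=cfg.w_dup,
                          w_loss=cfg.w_loss, cap=cfg.copy_cap)
    with open(out / "events.tsv", "w") as fh:
        fh.write("branch\tevent\tfamily\tdelta\n")
        for e in events:
            fh.write(f"{e.branch}\t{e.kind}\t{e.family}\t{e.delta:+d}\n")
    event_cmp = None
    if cfg.truth_events_path and Path(cfg.truth_events_path).exists():
        truth_ev: dict[str, list] = {}
        for line in Path(cfg.truth_events_path).read_text().splitlines()[1:]:
            branch, kind, fam, _ = line.split("\t")
            if kind in ("gain", "duplication", "loss"):
                truth_ev.setdefault(fam, []).append((branch, kind))
        inf_ev: dict[str, list] = {}
        for e in events:
            inf_ev.setdefault(e.family, []).append((e.branch, e.kind))
        event_cmp = {
            fam: sorted(inf_ev.get(fam, [])) == sorted(truth_ev.get(fam, []))
            for fam in sorted(set(truth_ev) | set(inf_ev))
        }
        _json_dump(out / "event_comparison.json", {
            "per_family_exact": event_cmp,
            "all_exact": all(event_cmp.values()),
        })

    # -- hairpin verdicts ----------------------------------------------------
    log.info("folding mapped precursors")
    n_compliant = n_total = 0
    with open(out / "hairpins.tsv", "w") as fh:
        fh.write("family\tleaf\tcompliant\tstem_length\tterminal_loop\t"
                 "mature_paired_fraction\tn_stem_loops\tdotbracket\n")
        for fam in sorted(locus_seqs):
            for leaf, (seq, mi) in sorted(locus_seqs[fam].items()):
                try:
                    fold = fold_maxpair(seq)
                    v = hairpin_verdict(
                        seq, fold, mature=mi, min_stem=cfg.min_stem,
                        max_loop=cfg.max_loop, min_paired=cfg.min_paired)
                except Exception as e:  # noqa: BLE001
                    errors.append(f"hairpin/{fam}/{leaf}: {e}")
                    continue
                n_total += 1
                n_compliant += int(v.compliant)
                fh.write("\t".join(str(x) for x in (
                    fam, leaf, int(v.compliant), v.stem_length,
                    v.terminal_loop, f"{v.mature_paired_fraction:.3f}",
                    v.n_stem_loops, fold.dotbracket)) + "\n")

    # -- target overlap -------------------------------------------------------
    overlap_out = None
    if cfg.matures_path and cfg.utrs_path and Path(cfg.utrs_path).exists():
        log.info("testing shared-target overlap for %s", cfg.focal_pair)
        matures = read_fasta(cfg.matures_path)
        utrs = read_fasta(cfg.utrs_path)
        fa, fb = cfg.focal_pair
        if fa in matures and fb in matures:
            stat = shared_target_fraction(matures[fa], matures[fb], utrs)
            focal_seeds = {matures[fa][1:8], matures[fb][1:8]}
            pool = {k: v for k, v in matures.items()
                    if v[1:8] not in focal_seeds}
            try:
                perm = random_pair_null(
                    matures[fa], matures[fb], pool, utrs,
                    n_perm=cfg.n_perm, seed=cfg.seed)
                overlap_out = {
                    "focal_pair": [fa, fb],
                    "n_targets": [stat.n_a, stat.n_b],
                    "intersection": stat.intersection,
                    "shared_fraction": _round(stat.shared_fraction),
                    "jaccard": _round(stat.jaccard),
                    **{k: (_round(v) if isinstance(v, float) else v)
                       for k, v in perm.summary().items()},
                }
                _json_dump(out / "target_overlap.json", overlap_out)
            except ValueError as e:
                errors.append(f"targets: {e}")
        else:
            errors.append(f"targets: focal pair {cfg.focal_pair} not in matures")

    # -- manifest --------------------------------------------------------------
    cfg_dict = config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:16]
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_sha256_16": cfg_hash,
        "species": species,
        "families": families,
        "n_loci": int(sum(len(v) for v in loci_by_sp.values())),
        "hairpin_compliant": [n_compliant, n_total],
        "event_recovery": event_cmp,
        "target_overlap": overlap_out,
        "errors": sorted(errors),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()
                          and p.name != "run.log"),
    }
    _json_dump(out / "manifest.json", manifest)
    log.info("bundle complete: %s (%d loci, %d errors)", out,
             manifest["n_loci"], len(errors))
    return manifest
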