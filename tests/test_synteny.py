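"""Anchored windows, colinearity scoring (with an exact LCS oracle), and
reciprocal-best-hit orthology."""

import numpy as np
import pytest

from myomir.context import GeneModel, classify_context
from myomir.mapping import MirnaLocus
from myomir.simulate import evolve_sequence, random_seq
from myomir.synteny import (
    AnchorUnavailableError,
    OrthologyMap,
    SyntenyWindow,
    WindowEntry,
    build_orthology,
    compare_windows,
    extract_window,
    lcs_length,
    orthology_from_truth,
    select_anchor,
)


def gene(name, seqid, strand, start, length=500):
    return GeneModel(
        gene_id=name, name=name, seqid=seqid, strand=strand,
        start=start, end=start + length - 1, biotype="protein_coding",
        transcripts={f"{name}.t": [(start, start + length - 1)]},
    )


def gene_array(n, seqid="chr1", spacing=1000, origin=1000):
    return [gene(f"g{i:02d}", seqid, "+" if i % 2 else "-",
                 origin + i * spacing) for i in range(n)]


def locus(start, end, strand="+"):
    return MirnaLocus("mir-x", "sp", "chr1", start, end, strand, 100.0, 1.0)


class TestSelectAnchor:
    def test_intronic_locus_anchors_on_host(self):
        genes = gene_array(5)
        h = gene("hostg", "chr1", "+", 20_000)
        ctx = type("C", (), {"kind": "intronic", "host_gene": "hostg",
                             "downstream_gene": None})()
        assert select_anchor(locus(20_100, 20_184), ctx, genes + [h]).name == \
            "hostg"

    def test_intergenic_locus_anchors_on_downstream_gene(self):
        up = gene("gU", "chr1", "+", 1000)
        down = gene("gD", "chr1", "+", 9000)
        loc = locus(3000, 3084)
        ctx = classify_context(loc, [up, down])
        # nearest downstream coding gene is the anchor even though the
        # upstream one is physically closer
        assert select_anchor(loc, ctx, [up, down]).name == "gD"

    def test_scaffold_edge_without_downstream_gene_errors(self):
        up = gene("gU", "chr1", "+", 1000)
        loc = locus(3000, 3084)
        ctx = classify_context(loc, [up])
        with pytest.raises(AnchorUnavailableError):
            select_anchor(loc, ctx, [up])


class TestExtractWindow:
    def test_mid_array_window_has_nine_per_side(self):
        genes = gene_array(25)
        win = extract_window(genes[12], genes, n=9)
        assert len(win.entries) == 19
        assert [e.side for e in win.entries].count(-1) == 9
        assert [e.side for e in win.entries].count(1) == 9

    def test_truncated_at_sequence_edge(self):
        genes = gene_array(3)
        win = extract_window(genes[0], genes, n=9)
        assert len(win.entries) == 3

    def test_minus_strand_anchor_window_is_flipped(self):
        genes = gene_array(7)
        genes[3] = gene("anchor", "chr1", "-", 1000 + 3 * 1000)
        win = extract_window(genes[3], genes, n=2)
        # genomically-right genes become upstream in anchor orientation
        rights = {g.name for g in genes[4:6]}
        ups = {e.gene for e in win.entries if e.side == -1}
        assert ups == rights

    def test_window_order_matches_truth_neighborhoods(self, preset_bundle):
        from myomir.context import read_gene_models

        _, _, bundle = preset_bundle
        sp = "tilapia"
        genes = read_gene_models(bundle.gff[sp])
        t = next(t for t in bundle.truth.loci[sp]
                 if t.family == "mir-214" and t.host == "dnm3")
        anchor = next(g for g in genes if g.name == "dnm3")
        win = extract_window(anchor, genes, n=9, species=sp)
        down = [e.gene for e in win.entries if e.side == 1]
        assert down[:5] == ["pigc", "tmed5", "suco", "mysm1", "oma1"]


def brute_lcs(a, b):
    best = 0
    import itertools

    for r in range(len(a), 0, -1):
        for sub in itertools.combinations(a, r):
            it = iter(b)
            if all(x in it for x in sub):
                return r
    return 0


class TestCompareWindows:
    def _win(self, sp, genes_sides, anchor="anc"):
        entries = []
        for k, (g, side, ori) in enumerate(genes_sides):
            entries.append(WindowEntry(g, ori, side, side * (abs(k) + 1)))
        return SyntenyWindow(species=sp, anchor=anchor, anchor_strand="+",
                             entries=entries)

    def test_self_comparison_is_maximal(self):
        gs = [(f"g{i}", -1 if i < 9 else 1, 1) for i in range(18)]
        w = self._win("a", gs)
        sc = compare_windows(w, w)
        assert sc.shared == 18 and sc.colinear_run == 18
        assert sc.orientation_agree == 18 and not sc.side_switches

    def test_disjoint_windows_share_nothing(self):
        w1 = self._win("a", [(f"x{i}", 1, 1) for i in range(5)])
        w2 = self._win("b", [(f"y{i}", 1, 1) for i in range(5)])
        sc = compare_windows(w1, w2)
        assert sc.shared == 0 and sc.colinear_run == 0

    def test_shared_count_symmetric_colinear_bounded(self, rng):
        pool = [f"g{i}" for i in range(12)]
        for _ in range(20):
            g1 = list(rng.permutation(pool))[:9]
            g2 = list(rng.permutation(pool))[:9]
            w1 = self._win("a", [(g, 1, 1) for g in g1])
            w2 = self._win("b", [(g, 1, 1) for g in g2])
            s12 = compare_windows(w1, w2)
            s21 = compare_windows(w2, w1)
            assert s12.shared == s21.shared
            assert s12.colinear_run <= s12.shared <= 18

    def test_colinear_run_equals_brute_force_lcs(self, rng):
        pool = [f"g{i}" for i in range(10)]
        for _ in range(15):
            a = list(rng.permutation(pool))[:7]
            b = list(rng.permutation(pool))[:7]
            shared = [x for x in a if x in b]
            bshared = [x for x in b if x in shared]
            assert lcs_length(shared, bshared) == brute_lcs(shared, bshared)

    def test_translocated_block_flags_exactly_the_moved_classes(
            self, preset_bundle):
        """The scripted neighborhood translocation in tetraodon is detected
        as side switches of exactly the moved gene classes present in both
        nine-gene windows."""
        from myomir.context import read_gene_models

        _, _, bundle = preset_bundle
        omap = orthology_from_truth(bundle.truth.ortholog_classes)
        wins = {}
        for sp in ("tilapia", "tetraodon"):
            genes = read_gene_models(bundle.gff[sp])
            anchor = next(g for g in genes if g.name == "dnm3")
            wins[sp] = extract_window(anchor, genes, n=9, species=sp)
        sc = compare_windows(wins["tilapia"], wins["tetraodon"], omap)
        moved = {"pigc", "tmed5", "suco", "mysm1", "oma1"}
        switched = {c.split(":")[-1] if ":" in c else c
                    for c in sc.side_switches}
        ref_window_genes = {e.gene for e in wins["tilapia"].entries}
        other_window_genes = {e.gene for e in wins["tetraodon"].entries}
        expect = moved & ref_window_genes & other_window_genes
        assert switched == expect and len(switched) >= 4


class TestBuildOrthology:
    def test_identical_gene_sets_pair_exactly(self, rng):
        genes = {f"g{i}": random_seq(rng, 200) for i in range(5)}
        omap = build_orthology({"spA": genes, "spB": dict(genes)})
        for g in genes:
            assert omap.class_of("spA", g) == omap.class_of("spB", g)

    def test_deleted_gene_leaves_singleton_class(self, rng):
        genes = {f"g{i}": random_seq(rng, 200) for i in range(4)}
        reduced = {k: v for k, v in genes.items() if k != "g0"}
        omap = build_orthology({"spA": genes, "spB": reduced})
        cls = omap.class_of("spA", "g0")
        assert len(omap.classes.get(cls, {f"spA:g0"})) == 1

    def test_member_in_two_classes_rejected(self):
        with pytest.raises(ValueError):
            OrthologyMap(classes={"c1": {"a:x"}, "c2": {"a:x"}})

    @pytest.mark.parametrize("seed", range(5))
    def test_diverged_orthologs_recovered(self, seed):
        """Reciprocal best hits recover >= 95% of true ortholog classes on
        default-rate divergence (scaled: 5 replicates x 8 genes x 3 species)."""
        rng = np.random.default_rng(seed)
        anc = {f"g{i}": random_seq(rng, 200) for i in range(8)}
        gene_seqs = {
            sp: {g: evolve_sequence(s, 0.5 * 0.3, rng)
                 for g, s in anc.items()}
            for sp in ("spA", "spB", "spC")
        }
        omap = build_orthology(gene_seqs)
        good = sum(
            omap.class_of("spA", g) == omap.class_of("spB", g)
            == omap.class_of("spC", g)
            for g in anc
        )
        assert good / len(anc) >= 0.95
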