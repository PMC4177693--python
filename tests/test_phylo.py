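"""Neighbor joining (with dendropy as the independent oracle), bootstrap
supports, paralog-clade detection, and Dollo-style event inference against
the exhaustive event-placement oracle."""

import io
import itertools
import warnings

import dendropy
import numpy as np
import pandas as pd
import pytest

from myomir.phylo import (
    Event,
    bipartitions,
    bootstrap_supports,
    detect_paralog_clade,
    exhaustive_event_search,
    infer_events,
    infer_family_events,
    is_monophyletic,
    nj_tree,
    replay_events,
    root_with_outgroup,
)
from myomir.simulate import evolve_sequence, random_seq
from myomir.trees import Node, parse_newick, to_newick


def path_distance_matrix(tree: Node) -> pd.DataFrame:
    leaves = tree.leaves()

    def dist(a, b):
        anc = {}
        n, d = a, 0.0
        while n is not None:
            anc[id(n)] = d
            d += n.length
            n = n.parent
        n, d = b, 0.0
        while n is not None:
            if id(n) in anc:
                return d + anc[id(n)]
            d += n.length
            n = n.parent
        raise RuntimeError

    names = [l.name for l in leaves]
    m = pd.DataFrame(0.0, index=names, columns=names)
    for x, y in itertools.combinations(leaves, 2):
        m.loc[x.name, y.name] = m.loc[y.name, x.name] = dist(x, y)
    return m


def random_topology(rng, names, blen=(0.05, 0.3)) -> Node:
    nodes = [Node(name=n, length=float(rng.uniform(*blen))) for n in names]
    k = 0
    while len(nodes) > 1:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes))))
        p = Node(name=f"i{k}", length=float(rng.uniform(*blen)))
        k += 1
        p.add(a)
        p.add(b)
        nodes.append(p)
    return nodes[0]


def dendropy_nj_bipartitions(m: pd.DataFrame) -> set:
    src = ["\t".join([""] + list(m.columns))]
    for r in m.index:
        src.append("\t".join([r] + [str(m.loc[r, c]) for c in m.columns]))
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        io.StringIO("\n".join(src)), delimiter="\t")
    dt = pdm.nj_tree()
    taxa = frozenset(m.columns)
    out = set()
    for e in dt.preorder_edge_iter():
        if e.head_node and not e.head_node.is_leaf() and e.tail_node:
            side = frozenset(l.taxon.label for l in e.head_node.leaf_iter())
            if 2 <= len(side) <= len(taxa) - 2:
                out.add(min(side, taxa - side,
                            key=lambda s: (len(s), tuple(sorted(s)))))
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form_branch_lengths(self):
        m = pd.DataFrame(
            [[0, 5, 9], [5, 0, 10], [9, 10, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float)
        t = nj_tree(m)
        lengths = {c.name: c.length for c in t.children}
        assert lengths["A"] == pytest.approx(2.0)
        assert lengths["B"] == pytest.approx(3.0)
        assert lengths["C"] == pytest.approx(7.0)

    def test_additive_five_taxon_matrix_recovered_exactly(self):
        src = parse_newick(
            "((A:0.1,B:0.2)ab:0.05,(C:0.3,(D:0.15,E:0.05)de:0.1)cde:0.07)r;")
        t = nj_tree(path_distance_matrix(src))
        assert bipartitions(t) == bipartitions(src)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_additive_matrices_recovered(self, seed):
        """NJ is consistent on additive distances (random trees <= 8 leaves)."""
        rng = np.random.default_rng(seed)
        src = random_topology(rng, [f"s{i}" for i in
                                    range(int(rng.integers(4, 9)))])
        t = nj_tree(path_distance_matrix(src))
        assert bipartitions(t) == bipartitions(src)

    def test_agrees_with_dendropy_on_noisy_matrices(self, rng):
        for _ in range(5):
            n = 6
            names = [f"t{i}" for i in range(n)]
            base = path_distance_matrix(random_topology(rng, names))
            noise = rng.uniform(0, 0.02, size=base.shape)
            m = base + noise + noise.T
            np.fill_diagonal(m.values, 0.0)
            assert bipartitions(nj_tree(m)) == dendropy_nj_bipartitions(m)

    def test_equal_distances_resolve_deterministically(self):
        m = pd.DataFrame(1.0, index=list("ABCD"), columns=list("ABCD"))
        np.fill_diagonal(m.values, 0.0)
        t1, t2 = nj_tree(m), nj_tree(m)
        assert to_newick(t1) == to_newick(t2)

    def test_asymmetric_matrix_rejected(self):
        m = pd.DataFrame([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        with pytest.raises(ValueError):
            nj_tree(m)


class TestBootstrap:
    def _msa(self, rng, n_taxa=8, length=80, d=0.08):
        anc = random_seq(rng, length)
        return {f"t{i}": evolve_sequence(anc, d * (1 + i % 3), rng)
                for i in range(n_taxa)}

    def test_no_resampling_gives_full_support(self, rng):
        msa = self._msa(rng)
        t = bootstrap_supports(msa, n_reps=5, seed=0, resample=False)
        sup = [n.support for n in t.preorder()
               if n.support is not None]
        assert sup and all(s == 100.0 for s in sup)

    def test_supports_invariant_to_leaf_relabeling(self, rng):
        msa = self._msa(rng)
        t1 = bootstrap_supports(msa, n_reps=50, seed=1)
        renamed = {f"x_{k}": v for k, v in msa.items()}
        t2 = bootstrap_supports(renamed, n_reps=50, seed=1)

        def supmap(t, prefix=""):
            return {
                frozenset(n.name.replace("x_", "") for n in nd.leaves()):
                nd.support
                for nd in t.preorder() if nd.support is not None
            }
        assert supmap(t1) == supmap(t2)

    def test_deep_split_is_strongly_supported(self, rng):
        """Two well-separated clades on an 80 bp alignment get > 50% support
        (mirrors the precursor-alignment depth used for paralog trees)."""
        anc = random_seq(rng, 80)
        a_anc = evolve_sequence(anc, 0.4, rng)
        b_anc = evolve_sequence(anc, 0.4, rng)
        msa = {}
        for i in range(4):
            msa[f"a{i}"] = evolve_sequence(a_anc, 0.03, rng)
            msa[f"b{i}"] = evolve_sequence(b_anc, 0.03, rng)
        hits = 0
        for seed in range(10):
            t = bootstrap_supports(msa, n_reps=100, seed=seed)
            rooted = root_with_outgroup(t, "b0")
            mono, sup = is_monophyletic(rooted, {f"a{i}" for i in range(4)})
            hits += bool(mono and sup and sup > 50)
        assert hits >= 9

    def test_short_alignment_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_supports({"a": "A", "b": "C"}, n_reps=2)


class TestParalogClade:
    def _tree(self):
        # ((p1,p2)90,(q1,(q2,q3)70)60)
        root = Node(name="r")
        a = Node(name="pa", support=90.0)
        a.add(Node(name="p1"))
        a.add(Node(name="p2"))
        b = Node(name="qb", support=60.0)
        b.add(Node(name="q1"))
        c = Node(name="qc", support=70.0)
        c.add(Node(name="q2"))
        c.add(Node(name="q3"))
        b.add(c)
        root.add(a)
        root.add(b)
        return root

    def test_supported_clade_accepted(self):
        v = detect_paralog_clade(self._tree(), {"p1", "p2"})
        assert v["verdict"] and v["support"] == 90.0

    def test_split_paralogs_rejected(self):
        v = detect_paralog_clade(self._tree(), {"p1", "q2"})
        assert not v["monophyletic"] and not v["verdict"]

    def test_threshold_applied(self):
        v = detect_paralog_clade(self._tree(), {"p1", "p2"},
                                 support_threshold=95)
        assert v["monophyletic"] and not v["verdict"]

    def test_all_leaves_rejected(self):
        with pytest.raises(ValueError):
            detect_paralog_clade(self._tree(),
                                 {"p1", "p2", "q1", "q2", "q3"})


class TestInferEvents:
    def test_uniform_single_copy_is_one_root_gain(self):
        tree = parse_newick("((a:1,b:1)ab:1,(c:1,d:1)cd:1)r;")
        ev, cost = infer_family_events(
            tree, {sp: 1 for sp in "abcd"}, "fam")
        assert cost == 0
        assert [(e.branch, e.kind) for e in ev] == [("r", "gain")]

    def test_mir208_like_pattern_root_gain_plus_two_stem_losses(self):
        """Presence in the outgroup and lobe-finned clade with absence in the
        cartilaginous + ray-finned clades forces a root origin with exactly
        one loss on each of those two stems."""
        from myomir.simulate import PRESET_TREE

        tree = parse_newick(PRESET_TREE)
        counts = {sp: 0 for sp in tree.leaf_names()}
        counts.update({"lamprey": 1, "human": 1, "coelacanth": 1})
        ev, cost = infer_family_events(tree, counts, "mir208like")
        got = sorted((e.branch, e.kind) for e in ev)
        assert got == [("actinopterygii", "loss"), ("elephant_shark", "loss"),
                       ("vertebrata", "gain")]
        assert cost == exhaustive_event_search(tree, counts)

    def test_mir214_like_pattern_single_stem_duplication(self):
        from myomir.simulate import ACANTHOPTERYGII_LEAVES, PRESET_TREE

        tree = parse_newick(PRESET_TREE)
        counts = {sp: 1 for sp in tree.leaf_names()}
        counts["lamprey"] = 0
        for sp in ACANTHOPTERYGII_LEAVES:
            counts[sp] = 2
        ev, cost = infer_family_events(tree, counts, "mir214like")
        dups = [e.branch for e in ev if e.kind == "duplication"]
        gains = [e.branch for e in ev if e.kind == "gain"]
        assert dups == ["acanthopterygii"] and gains == ["gnathostomes"]
        assert not [e for e in ev if e.kind == "loss"]
        assert cost == exhaustive_event_search(tree, counts)

    @pytest.mark.parametrize("seed", range(15))
    def test_cost_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_topology(rng, [f"s{i}" for i in
                                     range(int(rng.integers(3, 8)))])
        counts = {f"s{i}": int(rng.integers(0, 4))
                  for i in range(len(tree.leaves()))}
        if max(counts.values()) == 0:
            counts["s0"] = 1
        ev, cost = infer_family_events(tree, counts, "f", cap=3)
        assert cost == pytest.approx(exhaustive_event_search(tree, counts,
                                                             cap=3))

    @pytest.mark.parametrize("seed", range(8))
    def test_replay_reproduces_observed_copy_numbers(self, seed):
        rng = np.random.default_rng(100 + seed)
        tree = random_topology(rng, [f"s{i}" for i in range(6)])
        cm = pd.DataFrame(
            rng.integers(0, 4, size=(3, 6)),
            index=["f1", "f2", "f3"], columns=[f"s{i}" for i in range(6)])
        ev = infer_events(tree, cm)
        got = replay_events(tree, ev)
        for f in cm.index:
            if cm.loc[f].max() == 0:
                continue
            assert (got.loc[f].reindex(cm.columns) == cm.loc[f]).all()

    def test_cap_violation_raises(self):
        tree = parse_newick("(a:1,b:1)r;")
        with pytest.raises(Exception):
            infer_family_events(tree, {"a": 9, "b": 1}, "f", cap=4)

    def test_scenario_flips_when_losses_cheaper_than_duplications(self):
        """Weight sensitivity (ancestral-duplication-plus-loss vs convergent
        duplications): with the default weights (loss costlier than
        duplication) two-copy species separated by a single-copy lineage are
        explained by convergent stem duplications; making losses cheaper than
        duplications flips the optimum to one ancestral duplication followed
        by a loss in the intervening lineage."""
        tree = parse_newick("(((a:1,b:1)ab:1,c:1)abc:1,(d:1,e:1)de:1)r;")
        counts = {"a": 2, "b": 2, "c": 1, "d": 2, "e": 2}
        ev, _ = infer_family_events(tree, counts, "f", w_dup=1, w_loss=2)
        assert sorted(e.branch for e in ev if e.kind == "duplication") == \
            ["ab", "de"]
        assert not [e for e in ev if e.kind == "loss"]
        ev2, _ = infer_family_events(tree, counts, "f", w_dup=1, w_loss=0.5)
        assert [e.branch for e in ev2 if e.kind == "duplication"] == ["r"]
        assert [e.branch for e in ev2 if e.kind == "loss"] == ["c"]
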