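"""Generator contracts: configuration validation, determinism, no-evolution
identity, Poisson event counts, conservation gradient, truth-log replay and
coordinate validity of the emitted annotations."""

import itertools
from dataclasses import replace

import numpy as np
import pytest

from myomir.mapping import read_fasta
from myomir.simulate import (
    ConfigurationError,
    FamilySpec,
    ScriptedEvent,
    SimulationConfig,
    simulate_dataset,
    simulate_precursor_family,
    vertebrate_scenario_preset,
)
from myomir.trees import parse_newick


def tiny_config(**kw) -> SimulationConfig:
    base = dict(
        species_tree="((spA:0.1,spB:0.1)ab:0.05,spC:0.15)root;",
        n_neighbor_genes=3,
        exon_length=90, intron_length=120, spacer_length=200,
        center_spacer_length=900,
        n_utrs=20, utr_length=200, utr_site_plant=4, n_decoy_matures=3,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_config(loss_rate=-0.1)

    def test_rate_gradient_enforced(self):
        with pytest.raises(ConfigurationError):
            tiny_config(rate_mature=0.5, rate_loop=0.1)

    def test_tree_without_branch_lengths_rejected(self):
        with pytest.raises(Exception):
            tiny_config(species_tree="((a,b),c);")

    def test_single_leaf_tree_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_config(species_tree="(a:1);")

    def test_intronic_family_requires_host(self):
        with pytest.raises(ConfigurationError):
            FamilySpec("f", "intronic", "nb")


class TestNoEvolutionAndDeterminism:
    def test_zero_rates_give_identical_genomes(self, tmp_path):
        cfg = tiny_config(
            species_tree="(spA:0.1,spB:0.1)root;",
            duplication_rate=0, loss_rate=0, translocation_rate=0,
            excision_rate=0, rate_mature=0, rate_loop=0, rate_flank_gene=0,
            rate_intergenic=0, indel_rate=0, loop_indel_rate=0,
        )
        b = simulate_dataset(cfg, tmp_path / "o")
        fa = read_fasta(b.fasta["spA"])
        fb = read_fasta(b.fasta["spB"])
        assert fa == fb
        assert {e.kind for e in b.truth.events} == {"gain"}
        assert all(e.branch == "root" for e in b.truth.events)

    def test_same_seed_reproduces_identical_bytes(self, tmp_path):
        paths = []
        for d in ("x", "y"):
            b = simulate_dataset(tiny_config(seed=5), tmp_path / d)
            paths.append(b)
        for sp in paths[0].species:
            assert (open(paths[0].fasta[sp], "rb").read()
                    == open(paths[1].fasta[sp], "rb").read())
            assert (open(paths[0].gff[sp], "rb").read()
                    == open(paths[1].gff[sp], "rb").read())
        assert (open(paths[0].truth_events_path).read()
                == open(paths[1].truth_events_path).read())

    def test_different_seed_changes_sequences(self, tmp_path):
        b1 = simulate_dataset(tiny_config(seed=1), tmp_path / "a")
        b2 = simulate_dataset(tiny_config(seed=2), tmp_path / "b")
        assert (open(b1.fasta["spA"]).read() != open(b2.fasta["spA"]).read())


class TestEventStatistics:
    def test_duplication_count_matches_poisson_expectation(self, tmp_path):
        """Mean realized duplications per branch within 3 standard errors of
        the configured Poisson mean."""
        rate = 1.0
        n_rep = 120
        counts = []
        for i in range(n_rep):
            cfg = tiny_config(
                species_tree="(spA:0.05,spB:0.05)root;",
                duplication_rate=rate, loss_rate=0, translocation_rate=0,
                excision_rate=0, seed=1000 + i,
            )
            b = simulate_dataset(cfg, tmp_path / f"r{i}")
            counts.append(sum(
                1 for e in b.truth.events
                if e.kind == "duplication" and e.branch == "spA"))
        mean = np.mean(counts)
        se = np.sqrt(rate / n_rep)  # Poisson variance = mean
        assert abs(mean - rate) < 3 * se


class TestConservationGradient:
    def test_mature_loop_intergenic_identity_ordering(self, rng):
        """Region identities follow the configured rate gradient on average
        (scaled-down; the acceptance suite runs the 100-replicate version)."""
        from myomir.alignment import percent_identity, align_pair
        from myomir.simulate import evolve_sequence, random_seq

        wins = 0
        n = 30
        for _ in range(n):
            anc_m = random_seq(rng, 150)
            anc_i = random_seq(rng, 150)
            m1 = evolve_sequence(anc_m, 0.04 * 0.4, rng)
            i1 = evolve_sequence(anc_i, 0.9 * 0.4, rng)
            idm = percent_identity(align_pair(anc_m, m1))
            idi = percent_identity(align_pair(anc_i, i1))
            wins += idm >= idi
        assert wins / n >= 0.95


class TestTruthReplayAndCoordinates:
    @pytest.mark.parametrize("seed", [3, 11, 29])
    def test_replay_matches_emitted_copy_numbers(self, tmp_path, seed):
        cfg = tiny_config(seed=seed, duplication_rate=0.4, loss_rate=0.3,
                          translocation_rate=0.2, excision_rate=0.2)
        b = simulate_dataset(cfg, tmp_path / f"s{seed}")
        tree = parse_newick(cfg.species_tree)
        replay = b.truth.replay_copy_numbers(tree)
        for sp in b.species:
            emitted = {f: n for f, n in b.truth.copy_numbers[sp].items() if n}
            assert replay.get(sp, {}) == emitted

    def test_every_locus_id_in_gff_appears_in_truth_log(self, tmp_path):
        cfg = tiny_config(seed=8, duplication_rate=0.5)
        b = simulate_dataset(cfg, tmp_path / "o")
        logged = {e.locus_id for e in b.truth.events}
        for sp in b.species:
            for line in open(b.gff[sp]):
                if "\tmiRNA\t" in line:
                    lid = line.rsplit("ID=", 1)[1].split(";")[0]
                    assert lid in logged

    @pytest.mark.parametrize("seed", [1, 17])
    def test_gff_features_lie_within_their_sequences(self, tmp_path, seed):
        cfg = tiny_config(seed=seed, duplication_rate=0.4, excision_rate=0.3)
        b = simulate_dataset(cfg, tmp_path / f"g{seed}")
        for sp in b.species:
            seqs = read_fasta(b.fasta[sp])
            for line in open(b.gff[sp]):
                if line.startswith("#"):
                    continue
                f = line.split("\t")
                seqid, start, end, strand = f[0], int(f[3]), int(f[4]), f[6]
                assert seqid in seqs
                assert 1 <= start <= end <= len(seqs[seqid])
                assert strand in "+-"


class TestVertebratePreset:
    def test_tree_has_ten_leaves_with_named_clades(self):
        cfg, _ = vertebrate_scenario_preset()
        tree = parse_newick(cfg.species_tree)
        assert len(tree.leaves()) == 10
        for clade in ("gnathostomes", "osteichthyes", "actinopterygii",
                      "acanthopterygii", "tetraodontiformes"):
            tree.find(clade)

    def test_exactly_one_mir208_loss_on_each_fish_stem(self, preset_bundle):
        _, _, bundle = preset_bundle
        losses = [e.branch for e in bundle.truth.events
                  if e.family == "mir-208" and e.kind == "loss"]
        assert sorted(losses) == ["actinopterygii", "elephant_shark"]

    def test_zebrafish_carries_three_mir499_copies(self, preset_bundle):
        _, _, bundle = preset_bundle
        assert bundle.truth.copy_numbers["zebrafish"]["mir-499"] == 3

    def test_mir214_doubled_in_acanthopterygii_single_elsewhere(
            self, preset_bundle):
        _, _, bundle = preset_bundle
        cn = bundle.truth.copy_numbers
        for sp in ("tilapia", "medaka", "stickleback", "tetraodon", "fugu"):
            assert cn[sp]["mir-214"] == 2
        assert cn["zebrafish"]["mir-214"] == 1

    def test_template_copy_numbers_match_emitted(self, preset_bundle):
        cfg, template, bundle = preset_bundle
        for sp, expected in template.copy_numbers.items():
            emitted = {f: n for f, n in bundle.truth.copy_numbers[sp].items()
                       if n}
            assert emitted == expected

    def test_mir208_and_mir499_share_their_seed(self, preset_bundle):
        _, _, bundle = preset_bundle
        matures = read_fasta(bundle.matures_path)
        assert matures["mir-208"][1:8] == matures["mir-499"][1:8]


class TestPrecursorFamilyHelper:
    def test_leaf_count_and_mature_interval(self, rng):
        fam = simulate_precursor_family(
            "((a:0.1,b:0.1)ab:0.1,c:0.2)r;", rng)
        assert set(fam) == {"a", "b", "c"}
        for seq, (ms, me) in fam.values():
            assert 0 <= ms < me <= len(seq) and me - ms == 22
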