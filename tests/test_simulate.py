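"""Synthetic generator: determinism, null behaviour, planted structure."""

import numpy as np
import pytest

from bowspace.exceptions import InvalidInputError
from bowspace.simulate import (
    BenchmarkConfig,
    draw_compatibility,
    make_benchmark,
    null_config,
    simulate_feature_selection,
    simulate_ligands,
    simulate_network,
    simulate_proteins,
)

SMALL = dict(n_proteins=40, n_ligands=50, n_pool_proteins=15, n_pool_ligands=20,
             length_range=(30, 60), interaction_density=0.05, known_density=0.08)


def config(**kw):
    merged = {**SMALL, **kw}
    return BenchmarkConfig(**merged)


class TestConfigValidation:
    def test_counts_must_be_positive(self):
        with pytest.raises(InvalidInputError):
            config(n_proteins=0)

    def test_length_range_floor(self):
        with pytest.raises(InvalidInputError):
            config(length_range=(2, 10))

    def test_rates_in_unit_interval(self):
        with pytest.raises(InvalidInputError):
            config(signal=1.2)

    def test_negative_mode_names(self):
        with pytest.raises(InvalidInputError):
            config(negative_mode="bogus")


class TestProteins:
    def test_seed_determinism(self):
        a, ca = simulate_proteins(config(seed=3))
        b, cb = simulate_proteins(config(seed=3))
        assert [s.residues for s in a] == [s.residues for s in b]
        np.testing.assert_array_equal(ca, cb)

    def test_lengths_within_range(self):
        seqs, _ = simulate_proteins(config(seed=1))
        assert all(30 <= s.n <= 60 for s in seqs)

    def test_high_concentration_approaches_uniform_profiles(self):
        """Class profiles flatten as the Dirichlet concentration grows."""
        def profile_spread(conc):
            cfg = config(seed=0, composition_concentration=conc,
                         n_protein_classes=4, n_druggable_classes=2,
                         druggable_hydro_bias=0.0)
            seqs, classes = simulate_proteins(cfg, n=200)
            comps = np.zeros((4, 20))
            for s, c in zip(seqs, classes):
                comps[c] += np.bincount(s.indices(), minlength=20)
            comps /= comps.sum(axis=1, keepdims=True)
            return comps.std(axis=0).mean()

        assert profile_spread(1e6) < profile_spread(2.0) / 3

    def test_single_class_single_profile(self):
        seqs, classes = simulate_proteins(
            config(seed=0, n_protein_classes=1, n_druggable_classes=1))
        assert set(classes) == {0}


class TestLigands:
    def test_zero_flip_rate_reproduces_prototypes(self):
        cfg = config(seed=2, bit_flip_rate=0.0, n_ligand_prototypes=4,
                     n_druglike_prototypes=2)
        fps, protos = simulate_ligands(cfg, n=30)
        mat = fps.to_numpy()
        for proto in range(4):
            rows = mat[protos == proto]
            if len(rows) > 1:
                assert (rows == rows[0]).all()

    def test_half_flip_rate_decouples_from_prototype(self):
        def within_between_gap(flip):
            cfg = config(seed=2, bit_flip_rate=flip, n_ligand_prototypes=2,
                         n_druglike_prototypes=1)
            fps, protos = simulate_ligands(cfg, n=80)
            mat = fps.to_numpy().astype(float)
            same, diff = [], []
            for i in range(0, 80, 2):
                for j in range(i + 1, min(i + 4, 80)):
                    ham = np.mean(mat[i] != mat[j])
                    (same if protos[i] == protos[j] else diff).append(ham)
            return np.mean(diff) - np.mean(same)

        assert within_between_gap(0.02) > 0.1
        assert abs(within_between_gap(0.5)) < 0.05

    def test_seed_determinism(self):
        a, _ = simulate_ligands(config(seed=4))
        b, _ = simulate_ligands(config(seed=4))
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())


class TestNetwork:
    def test_null_edge_count_binomial(self):
        """signal = 0 is Erdos-Renyi: edge count within 3 SD of n_p n_l density."""
        cfg = config(seed=5, signal=0.0, n_proteins=100, n_ligands=100)
        classes = np.zeros(100, dtype=int)
        protos = np.zeros(100, dtype=int)
        net = simulate_network(cfg, classes, protos)
        expected = 100 * 100 * cfg.interaction_density
        sd = np.sqrt(expected * (1 - cfg.interaction_density))
        assert abs(len(net) - expected) < 3 * sd

    def test_full_signal_concentrates_on_compatible_blocks(self):
        cfg = config(seed=6, signal=1.0, specificity_bonus=12.0,
                     n_protein_classes=4, n_ligand_prototypes=6,
                     n_druggable_classes=2, n_druglike_prototypes=3,
                     specificity_fill=1.0, class_affinity_sd=0.0,
                     prototype_affinity_sd=0.0)
        compat = draw_compatibility(cfg)
        rng = np.random.default_rng(0)
        classes = rng.integers(4, size=120)
        protos = rng.integers(6, size=120)
        net = simulate_network(cfg, classes, protos,
                               [f"P{i}" for i in range(120)],
                               [f"L{j}" for j in range(120)], compat=compat)
        spec = compat.specific
        incompatible = sum(
            1 for p, l in net.edges
            if spec[classes[int(p[1:])], protos[int(l[1:])]] == 0)
        assert incompatible / max(len(net), 1) < 0.05

    def test_seed_determinism(self):
        cfg = config(seed=7)
        classes = np.zeros(20, dtype=int)
        protos = np.zeros(25, dtype=int)
        a = simulate_network(cfg, classes, protos)
        b = simulate_network(cfg, classes, protos)
        assert a.edges == b.edges


class TestBenchmark:
    @pytest.fixture(scope="class")
    def bench(self):
        return make_benchmark(config(seed=9))

    def test_feature_matrix_shape(self, bench):
        assert bench.X.shape[1] == 439
        assert len(bench.pairs) == len(bench.y) == bench.X.shape[0]

    def test_balanced_labels(self, bench):
        assert abs(bench.y.sum() - (1 - bench.y).sum()) <= 1

    def test_no_labelled_pair_in_known_network(self, bench):
        """Leakage control: a pair's own edge never feeds its MACCSP average."""
        labelled = {(p.protein_id, p.ligand_id) for p in bench.pairs}
        assert not labelled & bench.known_network.edges

    def test_split_and_folds_cover_everything(self, bench):
        n = len(bench.pairs)
        union = np.sort(np.concatenate([bench.split.train, bench.split.test]))
        np.testing.assert_array_equal(union, np.arange(n))
        fold_union = np.sort(np.concatenate([te for _, te in bench.folds]))
        np.testing.assert_array_equal(fold_union, np.arange(n))

    def test_pool_mode_keeps_entities_disjoint(self):
        bench = make_benchmark(config(seed=9, negative_mode="pool"))
        pos_entities = {p.protein_id for p in bench.pairs if p.label == 1} | {
            p.ligand_id for p in bench.pairs if p.label == 1}
        for pair in bench.pairs:
            if pair.label == 0:
                assert pair.protein_id not in pos_entities
                assert pair.ligand_id not in pos_entities

    def test_manifest_reflects_config(self, bench):
        manifest = bench.manifest
        assert manifest["config"]["seed"] == 9
        assert manifest["n_positive"] == int(bench.y.sum())

    def test_null_config_only_flips_signal(self):
        cfg = config(seed=1)
        null = null_config(cfg)
        assert null.signal == 0.0 and null.seed == cfg.seed

    def test_byte_level_determinism(self):
        a = make_benchmark(config(seed=13))
        b = make_benchmark(config(seed=13))
        np.testing.assert_array_equal(a.X.to_numpy(), b.X.to_numpy())
        np.testing.assert_array_equal(a.y, b.y)
        assert a.known_network.edges == b.known_network.edges


class TestFeatureSelectionBenchmark:
    def test_shapes_and_determinism(self):
        X, y, informative = simulate_feature_selection(n=50, seed=3)
        assert X.shape == (50, 55) and y.shape == (50,)
        assert informative.tolist() == [0, 1, 2, 3, 4]
        X2, y2, _ = simulate_feature_selection(n=50, seed=3)
        np.testing.assert_array_equal(X, X2)
        np.testing.assert_array_equal(y, y2)
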