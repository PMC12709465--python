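import numpy as np
import pytest
from scipy.stats import halfnorm

from trajgrn.data_io import EnsembleConfig
from trajgrn.ensemble_mapping import (
    EnsembleTopology,
    ReferenceStateSet,
    compute_cutoffs,
    deviation_metric,
    fit_log_shift,
    grn_entropy,
    histogram_overlap,
    local_density,
    map_models,
    reference_shares,
    sample_ensemble_params,
    select_reference_states,
    simulate_ensemble,
    weighted_mapping_percentage,
)
from trajgrn.trajectories import TrajectoryBundle, uniform_grid

TOGGLE = EnsembleTopology(["A", "B"], [("A", "B", -1), ("B", "A", -1)])


class TestSampling:
    def test_parameter_ranges(self):
        rng = np.random.default_rng(0)
        p = sample_ensemble_params(TOGGLE, 5000, rng)
        assert p.g.min() >= 1.0 and p.g.max() <= 100.0
        assert p.k.min() >= 0.1 and p.k.max() <= 1.0
        assert np.all(p.lam >= 0.01 - 1e-12) and np.all(p.lam <= 100.0)
        # inhibition edges: lambda = 1/f with f ~ U(1,100)
        assert p.lam.max() <= 1.0  # both edges inhibitory here
        assert set(np.unique(p.n)) <= {1.0, 2.0, 3.0, 4.0, 5.0, 6.0}

    def test_unsigned_edge_rejected(self):
        with pytest.raises(ValueError, match="sign"):
            EnsembleTopology(["A", "B"], [("A", "B", 0)])

    def test_seeded_determinism(self):
        a = simulate_ensemble(TOGGLE, 50, seed=4)
        b = simulate_ensemble(TOGGLE, 50, seed=4)
        np.testing.assert_array_equal(a, b)


class TestSimulation:
    def test_unregulated_gene_reaches_g_over_k(self):
        top = EnsembleTopology(["A"], [])
        rng = np.random.default_rng(1)
        raw = simulate_ensemble(top, 200, seed=1)
        # every profile must equal its own g/k; check distribution support
        assert raw.min() >= 1.0 and raw.max() <= 1000.0
        p = sample_ensemble_params(top, 200, np.random.default_rng(0))
        assert raw.shape == (200, 1)

    def test_toggle_is_bimodal(self):
        raw = simulate_ensemble(TOGGLE, 1500, seed=3)
        diff = np.log2(raw[:, 0] + 1) - np.log2(raw[:, 1] + 1)
        assert np.mean(diff > 2) > 0.15 and np.mean(diff < -2) > 0.15


class TestLogShift:
    def test_recovers_planted_shift(self):
        rng = np.random.default_rng(0)
        shifts = 2.0 ** np.linspace(-10, 5, 31)
        s_true = float(shifts[12])
        target_z = rng.normal(0, 1, 201)
        # construct ensemble values whose log2(u + s_true) is ~ target dist
        u = 2.0 ** (target_z * 1.7 + 3.0) - s_true
        u = np.maximum(u, 0.0)
        est = fit_log_shift(u, target_z * 1.7 + 3.0)
        assert abs(np.log2(est) - np.log2(s_true)) <= 0.5 + 1e-9

    def test_identical_distributions_full_overlap(self):
        x = np.random.default_rng(0).normal(size=500)
        assert histogram_overlap(x, x) == pytest.approx(1.0)

    def test_grid_size(self):
        cfg = EnsembleConfig()
        assert cfg.shift_grid_size == 31


class TestCutoffsAndMapping:
    def test_halfnormal_quantile_oracle(self):
        """1-gene reference at the random cloud's mean: D_r is the 5th
        percentile of |N(0,1)|."""
        refs = ReferenceStateSet(np.array([0]), np.array([[0.0]]))
        d = compute_cutoffs(refs, 1, n_random=200000, seed=1)
        expected = halfnorm.ppf(0.05)
        assert abs(d[0] - expected) < 0.01

    def test_cutoff_homogeneity(self):
        refs = ReferenceStateSet(np.array([0]), np.array([[1.0, -0.5]]))
        d1 = compute_cutoffs(refs, 2, n_random=50000, seed=2)
        refs2 = ReferenceStateSet(np.array([0]), np.array([[2.0, -1.0]]))
        d2 = compute_cutoffs(refs2, 2, n_random=50000, seed=2,
                             ensemble_sd=np.array([2.0, 2.0]))
        assert abs(d2[0] / d1[0] - 2.0) < 0.05

    def test_mapping_rules(self):
        refs = ReferenceStateSet(np.array([0, 1]),
                                 np.array([[0.0, 0.0], [4.0, 4.0]]))
        refs.cutoffs = np.array([1.0, 2.0])
        profiles = np.array([
            [0.0, 0.0],     # exactly reference 0
            [10.0, 10.0],   # outside every cutoff
            [3.2, 3.2],     # inside ref1 cutoff only
        ])
        out = map_models(profiles, refs)
        np.testing.assert_array_equal(out, [0, -1, 1])

    def test_min_ratio_tiebreak(self):
        refs = ReferenceStateSet(np.array([0, 1]),
                                 np.array([[0.0], [1.0]]))
        refs.cutoffs = np.array([1.0, 2.0])
        # profile at 0.5: ratios 0.5 vs 0.25 -> reference 1
        out = map_models(np.array([[0.5]]), refs)
        assert out[0] == 1


class TestDensityAndMetrics:
    def test_density_formula(self):
        # R=1 at v=3 -> 15/pi; construct 17 points: 16 on unit sphere
        rng = np.random.default_rng(0)
        x = rng.normal(size=(16, 3))
        x = x / np.linalg.norm(x, axis=1, keepdims=True)
        profiles = np.vstack([[0.0, 0.0, 0.0], x])
        rho = local_density(profiles, k_neighbors=15, mode="full")
        assert abs(rho[0] - 15.0 / np.pi) < 1e-9

    def test_density_1d_example(self):
        # distance to 15th neighbour = 2, v = 1 -> 15/(2 pi)
        profiles = np.r_[[0.0], np.linspace(2.0, 2.0, 15),
                         np.linspace(5, 6, 5)][:, None]
        rho = local_density(profiles, k_neighbors=15, mode="full")
        assert abs(rho[0] - 15.0 / (2 * np.pi)) < 1e-9

    def test_weighted_mapping_bounds(self):
        dens = np.ones(4)
        assert weighted_mapping_percentage(np.array([0, 1, 0, 2]), dens) == 1.0
        assert weighted_mapping_percentage(np.array([-1, -1, -1, -1]), dens) == 0.0
        assert weighted_mapping_percentage(np.array([0, -1]), np.ones(2)) == 0.5

    def test_entropy_examples(self):
        assert grn_entropy(np.array([1.0, 0, 0, 0, 0, 0])) == 0.0
        assert abs(grn_entropy(np.full(6, 1 / 6)) - np.log2(6)) < 1e-12
        assert abs(grn_entropy(np.array([0.5, 0.5, 0, 0, 0, 0])) - 1.0) < 1e-12

    def test_deviation_metric_examples(self):
        refs = ReferenceStateSet(np.array([0]), np.array([[0.0]]))
        refs.cutoffs = np.array([1.0])
        unmapped = np.full((10, 1), 2.0)     # ratio 2
        rand = np.full((10, 1), 3.0)         # ratio 3
        out = deviation_metric(unmapped, np.full(10, -1), refs, rand)
        assert abs(out["omega"] - 0.5) < 1e-12
        # unmapped cloud == random cloud -> omega = 1
        out2 = deviation_metric(rand, np.full(10, -1), refs, rand)
        assert abs(out2["omega"] - 1.0) < 1e-12

    def test_omega_missing_when_baseline_inside(self):
        refs = ReferenceStateSet(np.array([0]), np.array([[0.0]]))
        refs.cutoffs = np.array([1.0])
        out = deviation_metric(np.full((5, 1), 2.0), np.full(5, -1), refs,
                               np.full((5, 1), 0.5))
        assert np.isnan(out["omega"])


class TestReferences:
    def test_even_indices_default(self, grid201):
        bundle = TrajectoryBundle.from_arrays(
            ["A"], grid201, (0.1 + grid201)[None, :])
        refs = select_reference_states(bundle, ["A"], 6)
        np.testing.assert_array_equal(refs.indices, [0, 40, 80, 120, 160, 200])

    def test_two_references_are_endpoints(self, grid201):
        bundle = TrajectoryBundle.from_arrays(
            ["A"], grid201, (0.1 + grid201)[None, :])
        refs = select_reference_states(bundle, ["A"], 2)
        np.testing.assert_array_equal(refs.indices, [0, 200])

    def test_mapping_invariant_under_rotation(self):
        rng = np.random.default_rng(0)
        profiles = rng.normal(size=(200, 3))
        states = rng.normal(size=(4, 3))
        refs = ReferenceStateSet(np.arange(4), states)
        refs.cutoffs = np.array([1.0, 1.2, 0.8, 1.5])
        base = map_models(profiles, refs)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        refs_rot = ReferenceStateSet(np.arange(4), states @ q)
        refs_rot.cutoffs = refs.cutoffs
        rotated = map_models(profiles @ q, refs_rot)
        np.testing.assert_array_equal(base, rotated)
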