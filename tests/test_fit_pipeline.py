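import numpy as np
import pytest

from trajgrn.data_io import FitConfig, child_rng
from trajgrn.fit_pipeline import (
    GeneFitter,
    RegulatoryScenario,
    assemble_network,
    data_mse,
)
from trajgrn.ode_core import shifted_hill
from trajgrn.trajectories import uniform_grid

GRID = uniform_grid(201)


def make_problem(signs, seed=0, lam_mag=2.0):
    """A target generated exactly by the quasi-steady-state model."""
    rng = np.random.default_rng(seed)
    n = len(signs)
    regs = {}
    lam, R, hill = [], [], []
    log2y = 0.0
    for j, s in enumerate(signs):
        x = 0.1 + 0.9 * np.abs(np.sin((j + 1.3) * np.pi * GRID + rng.uniform(0, 3)))
        regs[f"r{j}"] = x
        lam_j = 2.0 ** (lam_mag if s > 0 else -lam_mag)
        R_j = rng.uniform(0.3, 0.7) * x.max()
        n_j = rng.uniform(2.5, 4.5)
        lam.append(lam_j); R.append(R_j); hill.append(n_j)
        log2y = log2y + np.log2(shifted_hill(x, lam_j, R_j, n_j))
    C = rng.uniform(-1, 1)
    target = 2.0 ** (log2y + C)
    target = target / target.max()
    truth = {"lam": lam, "R": R, "n": hill, "C": C}
    return target, regs, truth


class TestSampling:
    def test_initial_ranges(self):
        target, regs, _ = make_problem((1, -1), seed=1)
        f = GeneFitter("y", target, regs, rng=np.random.default_rng(0))
        for _ in range(50):
            p = f.sample_initial_params((1, -1))
            lam_a, lam_i = p[0], p[1]
            assert 2.0 < lam_a < 4.0
            assert 0.25 < lam_i < 0.5
            R = p[2:4]
            for j, name in enumerate(regs):
                my = regs[name].max()
                assert 0.3 * my <= R[j] <= 0.7 * my
            assert np.all((0.01 < p[4:6]) & (p[4:6] < 0.99))
            assert -2.0 < p[-1] < 2.0

    def test_seeded_draws_reproducible(self):
        target, regs, _ = make_problem((1,), seed=2)
        a = GeneFitter("y", target, regs, rng=np.random.default_rng(5))
        b = GeneFitter("y", target, regs, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a.sample_initial_params((1,)),
                                      b.sample_initial_params((1,)))


class TestCvFit:
    def test_zero_regulator_recovers_mean(self):
        rng = np.random.default_rng(0)
        target = rng.normal(0.5, 0.1, 201)
        f = GeneFitter("y", np.abs(target), {},
                       config=FitConfig(target_scale="linear"),
                       rng=np.random.default_rng(0))
        cand = f.cv_fit((), (), np.array([0.0]), 0.0)
        assert abs(cand.params[-1] - np.mean(np.abs(target))) < 1e-6
        assert cand.cv_mse < 2 * np.var(np.abs(target))

    def test_truth_init_gives_zero_residual(self):
        target, regs, truth = make_problem((1, -1), seed=3)
        f = GeneFitter("y", target, regs, rng=np.random.default_rng(0))
        init = np.r_[truth["lam"], truth["R"], truth["n"],
                     truth["C"] - np.log2(2.0 ** (np.log2(target).max()))]
        # C absorbs the max-scaling offset; start near truth
        init[-1] = truth["C"]
        Y = np.vstack(list(regs.values()))
        pred_c = np.log2(target) - (
            np.log2(shifted_hill(Y[0], truth["lam"][0], truth["R"][0], truth["n"][0])) +
            np.log2(shifted_hill(Y[1], truth["lam"][1], truth["R"][1], truth["n"][1])))
        init[-1] = pred_c.mean()
        cand = f.cv_fit(tuple(regs), (1, -1), init, 0.0)
        assert cand.cv_mse < 1e-8

    def test_random_init_recovers_lambda(self):
        target, regs, truth = make_problem((1, -1), seed=4)
        f = GeneFitter("y", target, regs, config=FitConfig(max_nfev=300),
                       rng=np.random.default_rng(1))
        best = None
        for _ in range(6):
            cand = f.cv_fit(tuple(regs), (1, -1),
                            f.sample_initial_params((1, -1)), 0.0)
            if best is None or cand.cv_mse < best.cv_mse:
                best = cand
        lam = best.unpack()["lam"]
        assert np.all(np.abs(lam / np.array(truth["lam"]) - 1.0) < 0.1)


class TestStage1:
    def test_schedule_arithmetic_one_regulator(self):
        target, regs, _ = make_problem((1,), seed=5)
        cfg = FitConfig(n_refits=10)
        f = GeneFitter("y", target, regs, config=cfg,
                       rng=np.random.default_rng(0))
        pool = f.stage1()
        # 2 patterns -> keep 1 -> 1 + 10 refits = 11 pool members
        assert len(pool) == 11

    def test_schedule_arithmetic_three_regulators(self):
        target, regs, _ = make_problem((1, -1, 1), seed=6)
        cfg = FitConfig(n_refits=10)
        f = GeneFitter("y", target, regs, config=cfg,
                       rng=np.random.default_rng(0))
        pool = f.stage1()
        # 8 patterns -> keep 4 -> 4 * (1 + 10) = 44 <= 200, all returned
        assert len(pool) == 44

    def test_best_pattern_is_truth_for_single_activator(self):
        target, regs, _ = make_problem((1,), seed=7)
        f = GeneFitter("y", target, regs,
                       config=FitConfig(n_refits=2),
                       rng=np.random.default_rng(0))
        pool = f.stage1()
        assert pool[0].signs == (1,)

    def test_too_many_regulators_rejected(self):
        target, regs, _ = make_problem((1,), seed=8)
        many = {f"x{i}": regs["r0"] for i in range(13)}
        with pytest.raises(ValueError, match="pre-prune"):
            GeneFitter("y", target, many)


class TestTuning:
    def test_grid_has_twenty_points(self):
        target, regs, _ = make_problem((1,), seed=9)
        f = GeneFitter("y", target, regs, rng=np.random.default_rng(0))
        grid = f.tuning_grid()
        assert len(grid) == 20
        lnw = np.log(grid)
        assert abs(lnw[0] + 15) < 1e-9 and abs(lnw[-1] - 2) < 1e-9
        np.testing.assert_allclose(np.diff(lnw), np.diff(lnw)[0])

    def test_monotone_curve_picks_smallest_weight(self):
        """Noiseless data: regularization only hurts, so w* = e^-15."""
        target, regs, _ = make_problem((1,), seed=10)
        f = GeneFitter("y", target, regs,
                       config=FitConfig.reduced(tuning_grid_size=8),
                       rng=np.random.default_rng(0))
        pool = f.stage1()
        curve = f.estimate_tuning_weight(pool[:2])
        assert curve.w_star <= curve.grid[1]


class TestScenarios:
    def _scenario(self, ratios):
        r = np.asarray(ratios, float)
        ref = np.ones_like(r)
        return RegulatoryScenario((), ("a",), r * ref, ref,
                                  float(np.sum(r / ref)))

    def test_reducibility_index_examples(self):
        assert self._scenario([1.0] * 10).index == 10.0
        assert self._scenario([2.0] * 10).index == 20.0
        assert self._scenario([1, 1, 1, 1, 1, 2, 2, 2, 2, 2]).index == 15.0

    def test_removable_edges(self):
        target, regs, _ = make_problem((1, -1), seed=11)
        f = GeneFitter("y", target, regs, rng=np.random.default_rng(0))
        names = tuple(regs)
        mk = lambda signs: type("C", (), {
            "regulators": names, "signs": signs,
            "params": np.r_[[3.0 if s > 0 else 0.4 for s in signs],
                            [0.5, 0.5], [2.0, 2.0], 0.0]})()
        assert f.removable_edges([mk((1, 1)), mk((1, -1))]) == [names[1]]
        assert f.removable_edges([mk((1, 1)), mk((1, 1))]) == []
        assert f.removable_edges([mk((1, 1))]) == []

    def test_select_scenario_rules(self):
        target, regs, _ = make_problem((1,), seed=12)
        f = GeneFitter("y", target, regs, rng=np.random.default_rng(0))
        mk = lambda removed, retained, I: RegulatoryScenario(
            removed, retained, np.ones(10), np.ones(10), I)
        s_all = mk((), ("a", "b", "c", "d", "e"), 10.0)
        s3 = mk(("d", "e"), ("a", "b", "c"), 10.2)
        s3b = mk(("c", "e"), ("a", "b", "d"), 10.5)
        s5 = mk((), ("a", "b", "c", "d", "e"), 10.1)
        # fewest edges below cutoff
        assert f.select_scenario([s_all, s3, s5], cutoff=11.0) is s3
        # tie on edge count -> lower index
        assert f.select_scenario([s3, s3b], cutoff=11.0) is s3
        # cutoff below everything -> empty-removal scenario
        assert f.select_scenario([s_all, s3], cutoff=5.0) is s_all

    def test_empty_removal_never_worsens(self):
        """Refitting from the reference optima cannot exceed I = n_refs."""
        target, regs, _ = make_problem((1, -1), seed=13)
        f = GeneFitter("y", target, regs, config=FitConfig.reduced(),
                       rng=np.random.default_rng(2))
        pool = f.stage1()
        scen = f.score_scenario((), pool[:3])
        assert scen.index <= 3 + 1e-6


class TestEndToEnd:
    def test_known_generator_recovered(self):
        target, regs, truth = make_problem((1, -1), seed=14)
        f = GeneFitter("y", target, regs, config=FitConfig.reduced(),
                       rng=np.random.default_rng(3))
        res = f.run()
        assert set(res.fit.regulators) == set(regs)
        fitted = dict(zip(res.fit.regulators, res.fit.signs))
        assert fitted == {"r0": 1, "r1": -1}

    def test_deterministic_given_seed(self):
        target, regs, _ = make_problem((1, -1), seed=15)
        runs = []
        for _ in range(2):
            f = GeneFitter("y", target, regs, config=FitConfig.reduced(),
                           rng=child_rng(9, "det"))
            runs.append(f.run())
        a, b = runs
        assert a.fit.regulators == b.fit.regulators
        assert a.fit.signs == b.fit.signs
        np.testing.assert_array_equal(
            np.r_[[a.fit.params[r] for r in a.fit.regulators]],
            np.r_[[b.fit.params[r] for r in b.fit.regulators]])

    def test_assembled_model_simulation_ready(self):
        target, regs, _ = make_problem((1,), seed=16)
        f = GeneFitter("y", target, regs, config=FitConfig.reduced(),
                       rng=np.random.default_rng(4))
        res = f.run()
        model = assemble_network([res.fit])
        assert model.simulation_ready
        for e in model.edges:
            assert e.lam != 1.0
        kin = model.kinetics["y"]
        assert kin.degradation == 1.0
        assert abs(np.log2(kin.production) - res.fit.params["C"]) < 1e-9
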