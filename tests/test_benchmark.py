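import numpy as np
import pytest

from trajgrn.benchmark_synthetic import (
    BenchmarkCase,
    RankedPrediction,
    add_noise,
    correlation_ranking,
    f_beta,
    generate_curve_library,
    generate_suite,
    scenario_to_ranking,
    score_prediction,
    signed_edge_confusion,
    simulate_target,
)
from trajgrn.fit_pipeline import RegulatoryScenario
from trajgrn.ode_core import shifted_hill


def brute_force_metrics(labels, scores):
    """Independent oracle: threshold sweep over all distinct scores."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    pos, neg = labels.sum(), len(labels) - labels.sum()
    thresholds = np.unique(scores)[::-1]
    tpr, fpr, prec, rec = [0.0], [0.0], [], []
    ap, prev_rec = 0.0, 0.0
    for t in thresholds:
        sel = scores >= t
        tp = int((labels[sel] == 1).sum())
        fp = int((labels[sel] == 0).sum())
        tpr.append(tp / pos)
        fpr.append(fp / neg if neg else 0.0)
        p = tp / (tp + fp)
        r = tp / pos
        ap += (r - prev_rec) * p
        prev_rec = r
    auroc = np.trapezoid(tpr, fpr)
    return float(auroc), float(ap)


class TestCurveLibrary:
    def test_size_positivity_determinism(self):
        lib = generate_curve_library(seed=5)
        assert lib.curves.shape == (10, 201)
        assert lib.curves.min() >= 0.1 - 1e-12
        lib2 = generate_curve_library(seed=5)
        np.testing.assert_array_equal(lib.curves, lib2.curves)
        assert not np.array_equal(lib.curves,
                                  generate_curve_library(seed=6).curves)


class TestTargetSimulation:
    def test_formula_matches_hand_evaluation(self):
        """One activator at its threshold everywhere, C = 0 -> y = 2.5."""
        x = np.full(201, 0.8)
        lam, R, n = 4.0, 0.8, 3.0
        log2y = np.log2(shifted_hill(x, lam, R, n))
        y = 2.0 ** log2y
        np.testing.assert_allclose(y, 2.5)

    def test_drawn_parameters_within_ranges(self):
        lib = generate_curve_library(seed=0)
        rng = np.random.default_rng(1)
        curves = {n_: lib[n_] for n_ in lib.names[:4]}
        y, signs, params = simulate_target(curves, rng)
        for name, x in curves.items():
            lam, R, n = params[name]
            assert 0.1 * x.max() <= R <= 0.9 * x.max()
            assert 2.5 <= n <= 4.5
            if signs[name] > 0:
                assert 2.0 <= lam <= 8.0
            else:
                assert 0.125 <= lam <= 0.5
        assert -2.0 <= params["C"] <= 2.0
        # y consistent with the drawn parameters
        log2y = params["C"]
        for name, x in curves.items():
            log2y = log2y + np.log2(shifted_hill(x, *params[name]))
        np.testing.assert_allclose(y, 2.0 ** log2y)


class TestNoise:
    def test_zero_noise_identity(self):
        x = np.linspace(0.5, 2, 201)
        np.testing.assert_array_equal(add_noise(x, 0.0,
                                                np.random.default_rng(0)), x)

    def test_relative_scale(self):
        rng = np.random.default_rng(0)
        x = np.full(201, 3.0)
        reps = np.array([add_noise(x, 0.1, rng) for _ in range(100)])
        rel = (reps - 3.0) / 3.0
        assert abs(rel.std() - 0.1) < 0.005

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.ones(3), -0.1, np.random.default_rng(0))


class TestSuite:
    def test_suite_composition(self):
        cases = generate_suite(seed=2)
        assert len(cases) == 81
        combos = {}
        for c in cases:
            key = (len(c.regulators), len(c.decoys))
            combos[key] = combos.get(key, 0) + 1
            assert not set(c.regulators) & set(c.decoys)
            assert 2 <= len(c.regulators) <= 7
            assert 1 <= len(c.decoys) <= 9 - len(c.regulators)
        assert all(v == 3 for v in combos.values())
        assert len(combos) == 27


class TestScoring:
    def test_perfect_ranking(self):
        truth = {"a": 1, "b": -1}
        pred = RankedPrediction(["a", "b", "c", "d"])
        m = score_prediction(pred, truth, ["a", "b", "c", "d"])
        assert m.auroc == 1.0 and m.auprc == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(3, 10))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            order = list(rng.permutation([f"c{i}" for i in range(n)]))
            truth = {f"c{i}": 1 for i in range(n) if labels[i]}
            pred = RankedPrediction(order)
            m = score_prediction(pred, truth, [f"c{i}" for i in range(n)])
            scores = [pred.scores()[f"c{i}"] for i in range(n)]
            auroc, auprc = brute_force_metrics(labels, scores)
            assert abs(m.auroc - auroc) < 1e-12
            assert abs(m.auprc - auprc) < 1e-12

    def test_random_ranking_auroc_near_half(self):
        rng = np.random.default_rng(1)
        truth = {f"c{i}": 1 for i in range(3)}
        cands = [f"c{i}" for i in range(9)]
        vals = [score_prediction(RankedPrediction(list(rng.permutation(cands))),
                                 truth, cands).auroc for _ in range(1000)]
        assert abs(np.mean(vals) - 0.5) < 0.02

    def test_log_weighting_is_rank_monotone(self):
        """AUROC from the log(A - pi + 2) confidence equals AUROC from raw
        negated ranks: the weighting is a monotone transform of rank."""
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 10))
            cands = [f"c{i}" for i in range(n)]
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            pred = RankedPrediction(list(rng.permutation(cands)))
            truth = {c: 1 for i, c in enumerate(cands) if labels[i]}
            m = score_prediction(pred, truth, cands)
            raw = roc_auc_score(labels, [-pred.ranks[c] for c in cands])
            assert abs(m.auroc - raw) < 1e-12


class TestScenarioRanking:
    def _scen(self, retained, index):
        return RegulatoryScenario((), tuple(retained), np.ones(1), np.ones(1),
                                  index)

    def test_frequency_ranking(self):
        cands = ["a", "b", "c"]
        scens = [self._scen(("a", "b", "c"), 12.0),
                 self._scen(("a", "b"), 10.5),
                 self._scen(("a",), 10.2)]
        ranking = scenario_to_ranking(scens, cands)
        assert ranking.candidates[0] == "a"
        assert ranking.candidates[1] == "b"
        assert ranking.candidates[-1] == "c"

    def test_never_retained_ranks_last(self):
        cands = ["a", "b"]
        scens = [self._scen(("a",), 10.0)]
        ranking = scenario_to_ranking(scens, cands)
        assert ranking.candidates == ["a", "b"]

    def test_best_scenario_per_size_wins(self):
        cands = ["a", "b"]
        scens = [self._scen(("a",), 10.0), self._scen(("b",), 12.0)]
        # both have 1 edge; only the lower-index one (retaining "a") counts
        ranking = scenario_to_ranking(scens, cands)
        assert ranking.candidates[0] == "a"


class TestCorrelationBaseline:
    def test_true_regulator_outranks_unrelated_decoy(self):
        grid = np.linspace(0, 1, 201)
        reg = np.sin(np.pi * grid) + 1.0
        case = BenchmarkCase(
            "t", ["r"], ["d"], target=2.0 * reg,
            curves={"r": reg, "d": np.full(201, 1.0) +
                    0.01 * np.cos(17 * grid)},
            truth_signs={"r": 1}, params={})
        ranking = correlation_ranking(case)
        assert ranking.candidates[0] == "r"


class TestFamilyAuprc:
    def test_growing_family_integration(self):
        from trajgrn.benchmark_synthetic import network_family_auprc
        lit = {("A", "B"): 1, ("B", "C"): -1, ("C", "D"): 1}
        families = [
            {("A", "B"): 1},
            {("A", "B"): 1, ("B", "C"): -1},
            {("A", "B"): 1, ("B", "C"): -1, ("C", "D"): -1},
        ]
        auprc = network_family_auprc(families, lit)
        assert 0.0 <= auprc <= 1.0
        perfect = network_family_auprc([dict(lit)], lit)
        assert perfect == 1.0


class TestSignedConfusion:
    def test_perfect_prediction(self):
        lit = {("A", "B"): 1, ("B", "C"): -1}
        out = signed_edge_confusion(dict(lit), lit)
        assert out["precision"] == out["recall"] == out["f_beta"] == 1.0

    def test_flipped_signs_no_true_positives(self):
        lit = {("A", "B"): 1}
        out = signed_edge_confusion({("A", "B"): -1}, lit)
        assert out["tp"] == 0 and out["fp"] == 1

    def test_f01_hand_computation(self):
        # 3 TP, 1 FP, 2 FN -> precision .75, recall .6
        lit = {(f"s{i}", f"t{i}"): 1 for i in range(5)}
        lit[("x", "y")] = 1
        pred = {(f"s{i}", f"t{i}"): 1 for i in range(3)}
        pred[("s3", "t3")] = -1   # sign-inconsistent -> FP
        out = signed_edge_confusion(pred, lit)
        assert out["tp"] == 3 and out["fp"] == 1 and out["fn"] == 2
        # recompute with the printed example's counts
        assert abs(f_beta(0.75, 0.6, 0.1) -
                   (1 + 0.01) * 0.75 * 0.6 / (0.01 * 0.75 + 0.6)) < 1e-12
        assert abs(f_beta(0.75, 0.6, 0.1) - 0.7481) < 1e-4

    def test_empty_literature_rejected(self):
        with pytest.raises(ValueError):
            signed_edge_confusion({("A", "B"): 1}, {})
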