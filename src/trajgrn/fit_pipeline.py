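"""Four-stage per-gene shifted-Hill model optimization and edge trimming.

For each target gene with N candidate regulators the pipeline

1. enumerates all 2^N activation/inhibition sign patterns, fits each by
   cross-validated nonlinear least squares without regularization, keeps the
   best half (or top 50 when N > 6), refits the keepers from resampled
   initial parameters, and pools the best models;
2. estimates the regularization weight w* from a tuning curve (cubic spline
   through log mean cross-validated MSE over a 20-point ln w grid spanning
   [-15, 2]) and refits the pool with the penalty w * sum (lambda - 1)^2,
   which shrinks dispensable interactions toward lambda = 1;
3. marks edges whose fitted lambda falls on both sides of 1 across the pool
   as removable, refits every subset of removable edges from the top models
   (no regularization, no cross-validation), and scores each subset by the
   reducibility index I = sum_h MSE_h / MSE_ori,h over the reference models;
   among subsets with I below a cutoff the fewest-edge one wins (ties by
   lowest I);
4. refits all candidates under the winning reduced scenario, re-estimates
   w*, refits again, and returns the minimum-MSE model within the most
   frequent sign pattern.

Assembling one fit per gene yields a signed GRNModel with unit-timescale
kinetics (k = 1, g = 2^C).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.optimize import least_squares

from .data_io import FitConfig
from .ode_core import GRNModel, GeneKinetics, RegulationEdgeParams

LOG2 = np.log(2.0)
C_BOUNDS = (-20.0, 20.0)


@dataclass
class FitCandidate:
    """One optimized parameter set for a fixed sign pattern."""

    regulators: tuple          # active regulator names, fixed order
    signs: tuple               # +1 / -1 per active regulator
    params: np.ndarray         # packed (lam..., R..., n..., C)
    cv_mse: float              # mean held-out data MSE over folds
    mse: float                 # full-data data-term MSE of ``params``
    stage: str = ""

    def lam(self) -> np.ndarray:
        n = len(self.regulators)
        return self.params[:n]

    def unpack(self) -> dict:
        n = len(self.regulators)
        p = self.params
        return {"lam": p[:n], "R": p[n:2 * n], "n": p[2 * n:3 * n], "C": p[-1]}


@dataclass
class TuningCurve:
    grid: np.ndarray           # w values (exp of the even ln w grid)
    mean_log_mse: np.ndarray
    w_star: float
    flat: bool = False


@dataclass
class RegulatoryScenario:
    removed: tuple             # removed regulator names
    retained: tuple
    mses: np.ndarray           # refit MSE_h per reference model
    ref_mses: np.ndarray       # MSE_ori,h of the reference models
    index: float               # reducibility index I
    best: FitCandidate | None = None
    fits: list = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.retained)


@dataclass
class GeneModelFit:
    gene: str
    regulators: tuple
    signs: tuple
    params: dict               # regulator -> (lam, R, n); plus "C"
    mse: float
    pattern_count: int = 0     # frequency of the winning sign pattern


@dataclass
class GeneFitResult:
    gene: str
    fit: GeneModelFit
    scenarios: list            # all scored RegulatoryScenario, for ranking
    w_star: float
    candidates: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Residuals / jacobian of the quasi-steady-state fit
# ---------------------------------------------------------------------------


def _hill_terms(params: np.ndarray, Y: np.ndarray):
    """Shifted-Hill values H (N x M) plus pieces reused by the jacobian."""
    n_reg = Y.shape[0]
    lam = params[:n_reg, None]
    R = params[n_reg:2 * n_reg, None]
    n = params[2 * n_reg:3 * n_reg, None]
    s = (Y / R) ** n
    H = lam + (1.0 - lam) / (1.0 + s)
    return lam, R, n, s, H


def _predict(params: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """sum_j log2 H_j + C along the trajectory."""
    if Y.shape[0] == 0:
        return np.full(Y.shape[1], params[-1])
    *_, H = _hill_terms(params, Y)
    return np.log2(H).sum(axis=0) + params[-1]


def _residuals(params, Y, target, w):
    m = len(target)
    r = (_predict(params, Y) - target) / np.sqrt(m)
    if w > 0 and Y.shape[0] > 0:
        r = np.r_[r, np.sqrt(w) * (params[:Y.shape[0]] - 1.0)]
    return r


def _jacobian(params, Y, target, w):
    n_reg, m = Y.shape
    n_par = 3 * n_reg + 1
    J = np.zeros((m + (n_reg if w > 0 else 0), n_par))
    scale = 1.0 / np.sqrt(m)
    if n_reg:
        lam, R, n, s, H = _hill_terms(params, Y)
        inv = 1.0 / (H * LOG2)
        frac = s / (1.0 + s)
        J[:m, :n_reg] = (frac * inv).T * scale                       # d/dlam
        dR = (1.0 - lam) * n * s / (R * (1.0 + s) ** 2)
        J[:m, n_reg:2 * n_reg] = (dR * inv).T * scale                # d/dR
        with np.errstate(divide="ignore", invalid="ignore"):
            lg = np.where(Y > 0, np.log(np.maximum(Y, 1e-300) / R), 0.0)
        dn = -(1.0 - lam) * s * lg / (1.0 + s) ** 2
        J[:m, 2 * n_reg:3 * n_reg] = (dn * inv).T * scale            # d/dn
    J[:m, -1] = scale                                                # d/dC
    if w > 0 and n_reg:
        J[m:, :n_reg] = np.sqrt(w) * np.eye(n_reg)
    return J


def data_mse(params, Y, target) -> float:
    return float(np.mean((_predict(params, Y) - target) ** 2))


# ---------------------------------------------------------------------------
# Per-gene fitter
# ---------------------------------------------------------------------------


class GeneFitter:
    """Fits one target gene against its candidate regulator trajectories.

    ``target`` and each row of ``Y`` are the max-scaled trajectory values on
    the shared M-point grid. With ``config.target_scale == "log2"`` the target
    is log2-transformed before fitting (the self-consistent convention); the
    default fits the values as they stand.
    """

    def __init__(self, gene: str, target: np.ndarray, regulators: dict,
                 config: FitConfig | None = None,
                 rng: np.random.Generator | None = None):
        self.gene = gene
        self.cfg = config or FitConfig()
        self.rng = rng or np.random.default_rng(0)
        self.reg_names = tuple(regulators)
        if len(self.reg_names) > self.cfg.max_regulators:
            raise ValueError(
                f"{gene}: {len(self.reg_names)} candidate regulators exceed "
                f"the cap of {self.cfg.max_regulators}; pre-prune the initial "
                "network")
        self.Y_full = np.vstack([regulators[r] for r in self.reg_names]) \
            if self.reg_names else np.empty((0, len(target)))
        if np.any(self.Y_full < 0):
            raise ValueError("regulator trajectories must be non-negative "
                             "(max-scale them first)")
        target = np.asarray(target, float)
        if self.cfg.target_scale == "log2":
            target = np.log2(np.maximum(target, 1e-9))
        self.target = target
        self.m = len(target)
        self.max_y = self.Y_full.max(axis=1) if self.reg_names else np.empty(0)
        self._folds = self._make_folds()

    # -- plumbing ---------------------------------------------------------

    def _make_folds(self):
        idx = np.arange(self.m)
        k = self.cfg.cv_folds
        if self.cfg.cv_interleaved:
            return [idx[idx % k == f] for f in range(k)]
        return [chunk for chunk in np.array_split(idx, k)]

    def _subproblem(self, regulators: tuple):
        sel = [self.reg_names.index(r) for r in regulators]
        return self.Y_full[sel] if sel else np.empty((0, self.m))

    def _pack_bounds(self, regulators: tuple, signs: tuple,
                     free_sign: bool = False):
        cfg = self.cfg
        my = np.array([self.Y_full[self.reg_names.index(r)].max()
                       for r in regulators]) if regulators else np.empty(0)
        if free_sign:
            lam_lo = [cfg.lambda_inh_bounds[0]] * len(signs)
            lam_hi = [cfg.lambda_act_bounds[1]] * len(signs)
        else:
            lam_lo = [cfg.lambda_act_bounds[0] if s > 0
                      else cfg.lambda_inh_bounds[0] for s in signs]
            lam_hi = [cfg.lambda_act_bounds[1] if s > 0
                      else cfg.lambda_inh_bounds[1] for s in signs]
        lo = np.r_[lam_lo, np.full(len(signs), 1e-3), np.full(len(signs), cfg.n_bounds[0]),
                   C_BOUNDS[0]]
        hi = np.r_[lam_hi, 10.0 * np.maximum(my, 1e-3), np.full(len(signs), cfg.n_bounds[1]),
                   C_BOUNDS[1]]
        return lo, hi

    def sample_initial_params(self, signs: tuple, regulators: tuple | None = None
                              ) -> np.ndarray:
        """Uniform draws: lam in (2,4) / (0.25,0.5) by sign, R in
        (0.3, 0.7) * max y_j, n in (0.01, 0.99), C in (-2, 2)."""
        regulators = regulators if regulators is not None else self.reg_names
        rng = self.rng
        lam = np.array([rng.uniform(2.0, 4.0) if s > 0 else rng.uniform(0.25, 0.5)
                        for s in signs])
        my = np.array([self.Y_full[self.reg_names.index(r)].max()
                       for r in regulators]) if regulators else np.empty(0)
        R = rng.uniform(0.3 * my, 0.7 * my) if len(my) else np.empty(0)
        n = rng.uniform(0.01, 0.99, size=len(signs))
        C = rng.uniform(-2.0, 2.0)
        return np.r_[lam, R, n, C]

    def _solve(self, Y, target, init, w, lo, hi):
        init = np.clip(init, np.asarray(lo) + 1e-12, np.asarray(hi) - 1e-12)
        res = least_squares(_residuals, init, jac=_jacobian, args=(Y, target, w),
                            bounds=(lo, hi), max_nfev=self.cfg.max_nfev,
                            method="trf", x_scale="jac")
        return res.x

    # -- single-candidate fits -------------------------------------------

    def fit_full(self, regulators: tuple, signs: tuple, init: np.ndarray,
                 w: float = 0.0, stage: str = "",
                 free_sign: bool = False) -> FitCandidate:
        """One bounded fit on all data; cv_mse set to the full-data MSE.

        ``free_sign`` lifts the per-sign lambda bounds (used in scenario
        scoring, where the topology, not the sign pattern, is under test);
        the reported signs then follow the fitted lambda.
        """
        Y = self._subproblem(regulators)
        lo, hi = self._pack_bounds(regulators, signs, free_sign)
        params = self._solve(Y, self.target, init, w, lo, hi)
        mse = data_mse(params, Y, self.target)
        if free_sign:
            signs = tuple(1 if params[i] > 1 else -1
                          for i in range(len(regulators)))
        return FitCandidate(regulators, signs, params, mse, mse, stage)

    def cv_fit(self, regulators: tuple, signs: tuple, init: np.ndarray,
               w: float = 0.0, stage: str = "") -> FitCandidate:
        """Five-fold cross-validated fit from one initialization.

        Folds follow pseudotime order (point l -> fold l mod 5 by default).
        The returned parameters come from a final fit on all data; cv_mse is
        the mean held-out data-term MSE.
        """
        Y = self._subproblem(regulators)
        lo, hi = self._pack_bounds(regulators, signs)
        test_mses = []
        for fold in self._folds:
            train = np.setdiff1d(np.arange(self.m), fold)
            try:
                p = self._solve(Y[:, train], self.target[train], init, w, lo, hi)
            except Exception:
                continue  # optimizer failure on a fold: skip and flag
            test_mses.append(data_mse(p, Y[:, fold], self.target[fold]))
        if not test_mses:
            raise RuntimeError(f"{self.gene}: every CV fold failed")
        params = self._solve(Y, self.target, init, w, lo, hi)
        return FitCandidate(regulators, signs, params,
                            float(np.mean(test_mses)),
                            data_mse(params, Y, self.target), stage)

    def _fit(self, regulators, signs, init, w, stage, cv=True):
        if cv:
            return self.cv_fit(regulators, signs, init, w, stage)
        return self.fit_full(regulators, signs, init, w, stage)

    # -- stage 1 ----------------------------------------------------------

    def _screen(self, signs: tuple) -> FitCandidate:
        """Cheap pattern-screening fit on a strided subgrid; the candidate is
        scored by its full-data MSE so ranking stays comparable."""
        cfg = self.cfg
        stride = max(1, cfg.screen_subsample)
        Y = self._subproblem(self.reg_names)
        lo, hi = self._pack_bounds(self.reg_names, signs)
        init = self.sample_initial_params(signs)
        saved = self.cfg.max_nfev
        if cfg.screen_max_nfev:
            self.cfg.max_nfev = cfg.screen_max_nfev
        try:
            params = self._solve(Y[:, ::stride], self.target[::stride], init,
                                 0.0, lo, hi)
        finally:
            self.cfg.max_nfev = saved
        mse = data_mse(params, Y, self.target)
        return FitCandidate(self.reg_names, signs, params, mse, mse, "screen")

    def stage1(self) -> list:
        """Enumerate sign patterns, fit, keep the best, refit with restarts."""
        cfg = self.cfg
        n = len(self.reg_names)
        patterns = list(product((1, -1), repeat=n))
        screening = not cfg.stage1_cv and (cfg.screen_subsample > 1 or
                                           cfg.screen_max_nfev)
        if screening:
            first = [self._screen(s) for s in patterns]
        else:
            first = [self._fit(self.reg_names, s,
                               self.sample_initial_params(s), 0.0, "stage1",
                               cv=cfg.stage1_cv)
                     for s in patterns]
        first.sort(key=lambda c: c.cv_mse)
        if screening:
            limit = (len(first) + 1) // 2 if n <= 6 else cfg.keep_top_n
            first = [self.fit_full(c.regulators, c.signs, c.params, 0.0,
                                   "stage1") for c in first[:limit]]
            first.sort(key=lambda c: c.cv_mse)
        if n <= 6:
            keep = first[:max(1, len(first) // 2)]
        else:
            keep = first[:cfg.keep_top_n]
        pool = list(keep)
        for cand in keep:
            for _ in range(cfg.n_refits):
                pool.append(self._fit(self.reg_names, cand.signs,
                                      self.sample_initial_params(cand.signs),
                                      0.0, "stage1", cv=cfg.stage1_cv))
        pool.sort(key=lambda c: c.cv_mse)
        if len(pool) < 2 * cfg.pool_size:
            return pool
        return pool[:cfg.pool_size]

    # -- stage 2 ----------------------------------------------------------

    def tuning_grid(self) -> np.ndarray:
        return np.exp(np.linspace(-15.0, 2.0, self.cfg.tuning_grid_size))

    def estimate_tuning_weight(self, top_candidates: list,
                               grid: np.ndarray | None = None) -> TuningCurve:
        """w* at the spline minimum of log mean CV MSE over the ln w grid."""
        grid = self.tuning_grid() if grid is None else np.asarray(grid, float)
        inits = top_candidates[: self.cfg.tuning_inits]
        mean_log = np.empty(len(grid))
        for i, w in enumerate(grid):
            mses = [self.cv_fit(c.regulators, c.signs, c.params, w,
                                "tuning").cv_mse for c in inits]
            mean_log[i] = np.log(max(np.mean(mses), 1e-300))
        lnw = np.log(grid)
        if np.ptp(mean_log) < 1e-12:
            return TuningCurve(grid, mean_log, float(grid[0]), flat=True)
        k = min(3, len(grid) - 1)
        spline = UnivariateSpline(lnw, mean_log, k=k)
        fine = np.linspace(lnw[0], lnw[-1], 400)
        w_star = float(np.exp(fine[int(np.argmin(spline(fine)))]))
        return TuningCurve(grid, mean_log, w_star)

    def stage2(self, pool: list, w_star: float) -> list:
        """Refit the pool with the regularization weight; re-rank by CV MSE.

        Initial lambda are resampled within the per-sign ranges (other
        parameters too, matching the stage-1 sampling scheme).
        """
        out = []
        for cand in pool:
            init = self.sample_initial_params(cand.signs, cand.regulators)
            out.append(self.cv_fit(cand.regulators, cand.signs, init, w_star,
                                   "stage2"))
        out.sort(key=lambda c: c.cv_mse)
        return out

    # -- stage 3 ----------------------------------------------------------

    def removable_edges(self, candidates: list) -> list:
        """Regulators whose fitted lambda lies on both sides of 1 across models.

        When more edges qualify than ``config.max_removable``, the most
        sign-ambiguous ones (minority-sign frequency closest to one half)
        stay removable and the rest are treated as decided.
        """
        if len(candidates) < 2:
            return []
        removable = []
        for r in self.reg_names:
            signs = [1 if c.params[c.regulators.index(r)] > 1 else -1
                     for c in candidates if r in c.regulators]
            pos = sum(1 for s in signs if s > 0)
            if 0 < pos < len(signs):
                ambiguity = min(pos, len(signs) - pos) / len(signs)
                removable.append((ambiguity, r))
        removable.sort(key=lambda t: (-t[0], t[1]))
        kept = removable[: self.cfg.max_removable]
        return [r for _, r in sorted(kept, key=lambda t:
                                     self.reg_names.index(t[1]))]

    @staticmethod
    def _restrict(cand: FitCandidate, retained: tuple) -> tuple:
        """Project a candidate's parameters onto a retained regulator subset."""
        keep = [i for i, r in enumerate(cand.regulators) if r in retained]
        u = cand.unpack()
        regs = tuple(cand.regulators[i] for i in keep)
        signs = tuple(cand.signs[i] for i in keep)
        params = np.r_[u["lam"][keep], u["R"][keep], u["n"][keep], u["C"]]
        return regs, signs, params

    def score_scenario(self, removed: tuple, ref_models: list,
                       ref_mses=None) -> RegulatoryScenario:
        """Refit the top reference models with ``removed`` edges deleted.

        No regularization and no cross-validation here; the reducibility
        index I = sum_h MSE_h / MSE_ori,h flags whether the deleted edges
        were dispensable (I stays near the number of reference models).
        ``ref_mses`` supplies polished (regularization-free) reference MSEs;
        without it the reference models' own MSEs are used.
        """
        retained = tuple(r for r in self.reg_names if r not in removed)
        mses = []
        best = None
        fits = []
        for ref in ref_models:
            regs, signs, init = self._restrict(ref, retained)
            cand = self.fit_full(regs, signs, init, 0.0, "scenario",
                                 free_sign=True)
            mses.append(cand.mse)
            fits.append(cand)
            if best is None or cand.mse < best.mse:
                best = cand
        mses_arr = np.array(mses)
        if ref_mses is None:
            ref_arr = np.maximum([ref.mse for ref in ref_models], 1e-300)
        else:
            ref_arr = np.maximum(np.asarray(ref_mses, float), 1e-300)
        index = float(np.sum(mses_arr / ref_arr))
        scen = RegulatoryScenario(tuple(removed), retained, mses_arr, ref_arr,
                                  index, best)
        scen.fits = fits
        return scen

    def enumerate_scenarios(self, removable: list, stage2_cands: list) -> list:
        """Score every subset of removable edges.

        Reference MSEs are the no-removal refits of the reference models
        (a regularization-free polish), so the empty scenario scores exactly
        the number of reference models and every other index isolates the
        effect of the deletions.
        """
        refs = stage2_cands[: self.cfg.scenario_inits]
        base = self.score_scenario((), refs)
        base_mses = np.maximum(np.minimum(base.mses, base.ref_mses), 1e-300)
        base.ref_mses = base_mses
        base.index = float(np.sum(base.mses / base_mses))
        scenarios = [base]
        # removals warm-start from the polished (regularization-free)
        # reference fits so every scenario faces the same optimizer gap
        polished = base.fits
        for k in range(1, len(removable) + 1):
            for removed in combinations(removable, k):
                scenarios.append(self.score_scenario(removed, polished,
                                                     ref_mses=base_mses))
        return scenarios

    def select_scenario(self, scenarios: list, cutoff: float | None = None
                        ) -> RegulatoryScenario:
        """Fewest retained edges among scenarios under the cutoff; ties by I.

        The index scale follows the number of reference models actually used;
        a cutoff stated for 10 references is rescaled accordingly.
        """
        cutoff = self.cfg.reducibility_cutoff if cutoff is None else cutoff
        if scenarios and len(scenarios[0].mses) != 10:
            cutoff = cutoff * len(scenarios[0].mses) / 10.0
        ok = [s for s in scenarios if s.index < cutoff]
        if not ok:
            empty = [s for s in scenarios if not s.removed]
            return empty[0] if empty else min(scenarios, key=lambda s: s.index)
        return min(ok, key=lambda s: (s.n_edges, s.index))

    # -- final stage ------------------------------------------------------

    def finalize_gene(self, scenario: RegulatoryScenario,
                      stage2_cands: list) -> GeneModelFit:
        """Refit all candidates under the reduced scenario and take the
        minimum-MSE model within the most frequent sign pattern."""
        retained = scenario.retained
        reduced = []
        for cand in stage2_cands:
            regs, signs, init = self._restrict(cand, retained)
            reduced.append(self.fit_full(regs, signs, init, 0.0, "final-init"))
        reduced.sort(key=lambda c: c.cv_mse)
        if retained:
            curve = self.estimate_tuning_weight(reduced)
            final = [self.fit_full(c.regulators, c.signs, c.params, curve.w_star,
                                   "final") for c in reduced]
        else:
            final = reduced
        groups: dict = {}
        for c in final:
            key = tuple(1 if c.params[i] > 1 else -1
                        for i in range(len(c.regulators)))
            groups.setdefault(key, []).append(c)
        best_key = max(groups, key=lambda k: len(groups[k]))
        winner = min(groups[best_key], key=lambda c: c.mse)
        u = winner.unpack()
        params = {r: (float(u["lam"][i]), float(u["R"][i]), float(u["n"][i]))
                  for i, r in enumerate(winner.regulators)}
        params["C"] = float(u["C"])
        return GeneModelFit(self.gene, winner.regulators, best_key, params,
                            winner.mse, pattern_count=len(groups[best_key]))

    # -- orchestration ----------------------------------------------------

    def run(self, cutoff: float | None = None,
            finalize: bool = True) -> GeneFitResult:
        """Full four-stage sweep. ``finalize=False`` skips the final
        refinement and reports the chosen scenario's best refit instead
        (sufficient when only the scenario ranking is needed)."""
        pool = self.stage1()
        if self.reg_names:
            curve = self.estimate_tuning_weight(pool)
            cands = self.stage2(pool, curve.w_star)
            w_star = curve.w_star
        else:
            cands, w_star = pool, 0.0
        removable = self.removable_edges(cands)
        scenarios = self.enumerate_scenarios(removable, cands)
        chosen = self.select_scenario(scenarios, cutoff)
        if finalize:
            fit = self.finalize_gene(chosen, cands)
        else:
            best = chosen.best if chosen.best is not None else cands[0]
            u = best.unpack()
            params = {r: (float(u["lam"][i]), float(u["R"][i]),
                          float(u["n"][i]))
                      for i, r in enumerate(best.regulators)}
            params["C"] = float(u["C"])
            signs = tuple(1 if u["lam"][i] > 1 else -1
                          for i in range(len(best.regulators)))
            fit = GeneModelFit(self.gene, best.regulators, signs, params,
                               best.mse)
        return GeneFitResult(self.gene, fit, scenarios, w_star, cands)


# ---------------------------------------------------------------------------
# Whole-network assembly
# ---------------------------------------------------------------------------


def fit_gene(gene: str, bundle, candidate_regulators, config=None, rng=None,
             cutoff: float | None = None) -> GeneFitResult:
    """Fit one gene from a max-scaled TrajectoryBundle."""
    target = bundle[gene].values
    regs = {r: bundle[r].values for r in candidate_regulators}
    fitter = GeneFitter(gene, target, regs, config=config, rng=rng)
    return fitter.run(cutoff)


def assemble_network(gene_fits: list, input_genes: dict | None = None) -> GRNModel:
    """Union the per-gene fits into a simulation-ready signed model.

    ``input_genes`` optionally maps pure-input node -> baseline level for
    regulators that are never themselves fitted (for example an extrinsic
    signal); they get flat kinetics g = level, k = 1.
    """
    genes, kinetics, edges = [], {}, []
    for fit in gene_fits:
        genes.append(fit.gene)
        kinetics[fit.gene] = GeneKinetics(
            fit.gene, log_ratio=fit.params["C"]).resolve_unit_timescale()
        for r in fit.regulators:
            lam, R, n = fit.params[r]
            edges.append(RegulationEdgeParams(r, fit.gene, lam, R, n))
    for e in edges:
        if e.source not in kinetics:
            level = (input_genes or {}).get(e.source, 1.0)
            genes.append(e.source)
            kinetics[e.source] = GeneKinetics(e.source, production=level,
                                              degradation=1.0)
    # deduplicate gene list, preserving order
    seen, ordered = set(), []
    for g in genes:
        if g not in seen:
            seen.add(g)
            ordered.append(g)
    return GRNModel(genes=ordered, kinetics=kinetics, edges=edges)


def fit_network(bundle, initial_grn, config: FitConfig | None = None,
                seed: int = 0, cutoff: float | None = None,
                input_genes: dict | None = None) -> tuple:
    """Fit every target of an initial GRN; returns (GRNModel, [GeneFitResult]).

    Genes that appear only as sources (no incoming candidate edges) are
    treated as inputs and left unfitted.
    """
    from .data_io import child_seed
    results = []
    targets = sorted({t for t in initial_grn.edges["target"]})
    for gene in targets:
        rng = np.random.default_rng(child_seed(seed, f"fit:{gene}"))
        regs = initial_grn.regulators_of(gene)
        results.append(fit_gene(gene, bundle, regs, config=config, rng=rng,
                                cutoff=cutoff))
    model = assemble_network([r.fit for r in results], input_genes=input_genes)
    return model, results
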