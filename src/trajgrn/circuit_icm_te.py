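"""Ground-truth three-gene circuit of the ICM-to-TE fate decision.

Oct4 (x1) maintains the inner-cell-mass (ICM) identity, Cdx2 (x2) drives
trophectoderm (TE) commitment, Esrrb (x3) closes a coherent feed-forward
loop, and the FGF signal (x4) is an extrinsic input acting on Cdx2. The
ground-truth interactions are

    Esrrb -> Oct4 (+),  Cdx2 -| Oct4,  Oct4 -| Cdx2,
    FGF  -| Cdx2,       Cdx2 -| Esrrb.

The input signal follows a half-cosine ramp from 150 down to 25 over the
first half of the simulation window (T = 1000) and stays at 25 afterwards.
FGF is wired as an inhibitor of Cdx2 so that this decreasing protocol
completes the ICM -> TE transition: falling FGF releases Cdx2, which flips
the Oct4/Cdx2 toggle.

The shipped parameter set is this package's own (tuned to the qualitative
behaviour the circuit must show): the signal window contains a contiguous
bistable interval (both ICM and TE stable, including at x4 = 150) with a
single attractor above and below it, so the forward passage is irreversible
— reversing the signal leaves the system committed to TE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ode_core import GRNModel, GeneKinetics, RegulationEdgeParams, rk4_integrate
from .trajectories import SmoothedTrajectory, TrajectoryBundle, uniform_grid

OCT4, CDX2, ESRRB, FGF = "Oct4", "Cdx2", "Esrrb", "FGF"
GENES = (OCT4, CDX2, ESRRB)
DEFAULT_T = 1000.0

#: Ground-truth signed edges (source, target, sign).
GROUND_TRUTH_EDGES = (
    (ESRRB, OCT4, +1),
    (CDX2, OCT4, -1),
    (OCT4, CDX2, -1),
    (FGF, CDX2, -1),
    (CDX2, ESRRB, -1),
)


def fgf_signal(t, T: float = DEFAULT_T):
    """Half-cosine ramp 150 -> 25 over [0, T/2], then constant 25."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > T):
        raise ValueError("time outside [0, T]")
    ramp = 150.0 - 125.0 * (1.0 - np.cos(np.pi * t_arr / (T / 2.0))) / 2.0
    out = np.where(t_arr <= T / 2.0, ramp, 25.0)
    return float(out) if np.isscalar(t) else out


@dataclass
class CircuitParams:
    """Kinetics and regulation of the shipped ground-truth circuit."""

    production: dict = field(default_factory=lambda: {OCT4: 15.0, CDX2: 80.0,
                                                      ESRRB: 40.0})
    degradation: dict = field(default_factory=lambda: {OCT4: 0.5, CDX2: 0.2,
                                                       ESRRB: 0.5})
    # (source, target) -> (lambda, R, n); thresholds and timescales are
    # deliberately heterogeneous so each gene switches at a different time
    # and with a different lag along the transition
    regulation: dict = field(default_factory=lambda: {
        (ESRRB, OCT4): (4.0, 40.0, 4.0),
        (CDX2, OCT4): (0.25, 10.0, 4.0),
        (OCT4, CDX2): (0.05, 40.0, 4.0),
        (FGF, CDX2): (0.02, 90.0, 4.0),
        (CDX2, ESRRB): (0.05, 30.0, 8.0),
    })

    def to_model(self) -> GRNModel:
        """Model over Oct4/Cdx2/Esrrb/FGF; FGF has flat unit kinetics and is
        meant to be clamped by a driver."""
        kinetics = {g: GeneKinetics(g, production=self.production[g],
                                    degradation=self.degradation[g])
                    for g in GENES}
        kinetics[FGF] = GeneKinetics(FGF, production=150.0, degradation=1.0)
        edges = [RegulationEdgeParams(src, tgt, lam, R, n)
                 for (src, tgt), (lam, R, n) in self.regulation.items()]
        return GRNModel(genes=[*GENES, FGF], kinetics=kinetics, edges=edges)


def count_stable_states(params: CircuitParams, x4: float, n_starts: int = 200,
                        seed: int = 0, tol: float = 1e-6,
                        merge_tol: float = 1e-3, t_max: float = 400.0) -> list:
    """Multi-start attractor census at a frozen signal level.

    Random positive initial states are relaxed to steady state; converged
    states are merged when closer than ``merge_tol`` in relative terms.
    """
    if n_starts < 50:
        raise ValueError("need at least 50 starts for a census")
    model = params.to_model()
    # hold the signal at x4 via its own kinetics so RK4 sub-steps see a
    # genuine fixed point rather than a post-step clamp
    model.kinetics[FGF] = GeneKinetics(FGF, production=float(x4), degradation=1.0)
    model._arrays = None
    rng = np.random.default_rng(seed)
    scale = np.array([params.production[g] / params.degradation[g]
                      for g in GENES] + [x4])
    # half uniform starts, half on/off corner patterns: basins of strongly
    # inhibited states can be narrow under purely uniform sampling
    X = rng.uniform(0.0, 1.5, size=(n_starts, 4)) * scale
    half = n_starts // 2
    mask = np.where(rng.random((half, 4)) < 0.5, 0.02, 1.0)
    X[:half] = rng.uniform(0.5, 1.5, size=(half, 4)) * scale * mask
    fgf_col = len(GENES)
    X[:, fgf_col] = x4
    step = 0.2
    t = 0.0
    free = np.array([i for i in range(4) if i != fgf_col])
    while t < t_max:
        for _ in range(50):
            k1 = model.rhs(X)
            k2 = model.rhs(X + step / 2 * k1)
            k3 = model.rhs(X + step / 2 * k2)
            k4 = model.rhs(X + step * k3)
            X = np.maximum(X + step / 6 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
            X[:, fgf_col] = x4
            t += step
        rate = np.abs(model.rhs(X)[:, free])
        if np.max(rate) < tol * max(1.0, np.max(np.abs(X))):
            break
    ok = np.max(np.abs(model.rhs(X)[:, free]), axis=1) < \
        1e-3 * max(1.0, float(np.max(np.abs(X))))
    attractors: list = []
    for state in X[ok]:
        for a in attractors:
            if np.linalg.norm(state - a) <= merge_tol * (1.0 + np.linalg.norm(a)):
                break
        else:
            attractors.append(state)
    return attractors


def icm_attractor(params: CircuitParams, x4: float = 150.0) -> np.ndarray:
    """The high-Oct4/high-Esrrb attractor at the given signal level."""
    states = count_stable_states(params, x4, n_starts=400, seed=1)
    idx = {g: i for i, g in enumerate([*GENES, FGF])}
    best = max(states, key=lambda s: s[idx[OCT4]])
    if best[idx[OCT4]] <= best[idx[CDX2]]:
        raise ValueError("no high-Oct4 attractor found at this signal level")
    return best


def te_attractor(params: CircuitParams, x4: float = 25.0) -> np.ndarray:
    states = count_stable_states(params, x4, n_starts=400, seed=2)
    idx = {g: i for i, g in enumerate([*GENES, FGF])}
    best = max(states, key=lambda s: s[idx[CDX2]])
    if best[idx[CDX2]] <= best[idx[OCT4]]:
        raise ValueError("no high-Cdx2 attractor found at this signal level")
    return best


def simulate_circuit(params: CircuitParams | None = None, T: float = DEFAULT_T,
                     step: float = 0.05, n_points: int = 201) -> dict:
    """Drive the circuit from the ICM attractor with the FGF protocol.

    Returns a dict with the recorded times and per-gene trajectories; for the
    shipped parameters the final state is the TE attractor.
    """
    params = params or CircuitParams()
    model = params.to_model()
    x0 = icm_attractor(params, fgf_signal(0.0, T))
    resid = model.rhs(np.array(x0))
    free = [i for i, g in enumerate([*GENES, FGF]) if g != FGF]
    if np.max(np.abs(resid[free])) > 1e-3:
        raise ValueError("initial state is not an attractor of the circuit")
    record = np.linspace(0.0, T, n_points)
    times, states = rk4_integrate(model, x0, (0.0, T), step,
                                  drivers={FGF: lambda t: fgf_signal(t, T)},
                                  record_times=record)
    gene_order = [*GENES, FGF]
    return {"times": times,
            "trajectories": {g: states[:, i] for i, g in enumerate(gene_order)},
            "final_state": states[-1], "params": params}


def initial_grn_variants() -> dict:
    """Candidate-regulator sets for the two reconstruction starts.

    Variant "full": every gene may be regulated by all other genes including
    FGF. Variant "minus_oct4_esrrb" drops the Oct4 -> Esrrb candidate.
    """
    full = {
        OCT4: [CDX2, ESRRB, FGF],
        CDX2: [OCT4, ESRRB, FGF],
        ESRRB: [OCT4, CDX2, FGF],
    }
    minus = {g: list(v) for g, v in full.items()}
    minus[ESRRB] = [CDX2, FGF]
    return {"full": full, "minus_oct4_esrrb": minus}


def make_reconstruction_fixture(params: CircuitParams | None = None,
                                seed: int = 0, T: float = DEFAULT_T,
                                noise: float = 0.05) -> dict:
    """Simulated trajectories plus ground truth for end-to-end reconstruction.

    Each 201-point trajectory carries multiplicative Gaussian measurement
    noise of relative scale ``noise`` (emulating the roughness of smoothed
    experimental trajectories; it also keeps the reducibility ratios of the
    downstream fit on a meaningful scale instead of ratios of near-zero
    residuals). Returns ``{"bundle": TrajectoryBundle (201-grid, incl. FGF),
    "truth": {(src, tgt): sign}, "variants": candidate-regulator dicts}``.
    """
    from .data_io import child_rng
    sim = simulate_circuit(params, T=T)
    grid = uniform_grid(len(sim["times"]))
    rng = child_rng(seed, "icmte-noise")
    trajs = {}
    for g, v in sim["trajectories"].items():
        noisy = np.maximum(v * (1.0 + noise * rng.standard_normal(v.shape)),
                           1e-6) if noise > 0 else v
        trajs[g] = SmoothedTrajectory(g, grid, noisy)
    bundle = TrajectoryBundle(grid, trajs)
    truth = {(s, t): sg for s, t, sg in GROUND_TRUTH_EDGES}
    return {"bundle": bundle, "truth": truth,
            "variants": initial_grn_variants(), "sim": sim}


def reconstruct(variant: str = "minus_oct4_esrrb", config=None, seed: int = 0,
                params: CircuitParams | None = None,
                fixture: dict | None = None) -> dict:
    """Run the fit pipeline on the simulated circuit trajectories.

    Returns the fitted edge-sign dict, the ground truth, and per-gene fit
    results.
    """
    from .data_io import child_rng
    from .fit_pipeline import GeneFitter
    from .trajectories import max_scale

    fixture = fixture or make_reconstruction_fixture(params, seed=seed)
    bundle = fixture["bundle"].transform(max_scale)
    candidates = fixture["variants"][variant]
    fitted_edges: dict = {}
    results = {}
    for gene, regs in candidates.items():
        fitter = GeneFitter(gene, bundle[gene].values,
                            {r: bundle[r].values for r in regs},
                            config=config,
                            rng=child_rng(seed, f"icmte:{variant}:{gene}"))
        res = fitter.run()
        results[gene] = res
        for i, r in enumerate(res.fit.regulators):
            fitted_edges[(r, gene)] = res.fit.signs[i]
    return {"edges": fitted_edges, "truth": fixture["truth"],
            "results": results}
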