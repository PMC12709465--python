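"""Random-parameter ensemble simulation and reference-state mapping.

Given only a signed GRN topology, an ensemble of ODE models with randomly
drawn kinetic parameters (10,000 by default) is integrated to steady state,
giving a cloud of expression profiles that summarizes the states the
topology can robustly realize. Each gene's simulated distribution is
log-shifted (log2(u + shift), shift chosen on a grid to maximize histogram
overlap with the observed trajectory distribution) and standardized; each
profile is then mapped to the nearest of n_r = 6 reference states taken
evenly along the smoothed trajectories, provided its distance falls under
the reference's cutoff (the 5th percentile of random-profile distances).

Summary metrics: the density-weighted mapping percentage p_tot (profiles
weighted by inverse local density rho_a = 15 / (pi * R_a^v), with R_a the
distance to the 15th nearest neighbour in either the full gene space or the
first three principal components), the entropy H of the per-reference shares,
and the deviation metric omega = (d_u - 1)/(d_theta - 1) comparing unmapped
profiles with the random baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .data_io import EnsembleConfig, child_rng
from .trajectories import TrajectoryBundle


@dataclass
class EnsembleTopology:
    """A signed topology: genes plus (source, target, sign) edges."""

    genes: list
    edges: list                 # (source, target, +1/-1)

    def __post_init__(self):
        for s, t, sign in self.edges:
            if sign not in (1, -1):
                raise ValueError(f"edge {s}->{t} lacks a sign")
            if s not in self.genes or t not in self.genes:
                raise ValueError(f"edge {s}->{t} references unknown gene")

    @classmethod
    def from_model(cls, model) -> "EnsembleTopology":
        return cls(list(model.genes),
                   [(e.source, e.target, e.sign) for e in model.edges])


@dataclass
class EnsembleParams:
    """Per-model kinetic parameters drawn for a whole ensemble batch."""

    g: np.ndarray               # (B, G) production
    k: np.ndarray               # (B, G) degradation
    lam: np.ndarray             # (B, E) fold change (already signed)
    R: np.ndarray               # (B, E) Hill thresholds
    n: np.ndarray               # (B, E) Hill coefficients (integers 1..6)


def sample_ensemble_params(topology: EnsembleTopology, n_models: int,
                           rng: np.random.Generator) -> EnsembleParams:
    """Canonical random-circuit ranges: g ~ U(1,100), k ~ U(0.1,1),
    fold change f ~ U(1,100) with lambda = f (activation) or 1/f
    (inhibition), integer n ~ {1..6}, and R ~ U(0.02, 1.98) times the
    source's unregulated level g_src/k_src of the same draw."""
    G, E = len(topology.genes), len(topology.edges)
    gidx = {g: i for i, g in enumerate(topology.genes)}
    g = rng.uniform(1.0, 100.0, size=(n_models, G))
    k = rng.uniform(0.1, 1.0, size=(n_models, G))
    f = rng.uniform(1.0, 100.0, size=(n_models, E))
    signs = np.array([sign for *_, sign in topology.edges])
    lam = np.where(signs > 0, f, 1.0 / f)
    src = np.array([gidx[s] for s, *_ in topology.edges], dtype=int)
    base = g[:, src] / k[:, src] if E else np.empty((n_models, 0))
    R = rng.uniform(0.02, 1.98, size=(n_models, E)) * base
    n = rng.integers(1, 7, size=(n_models, E)).astype(float)
    return EnsembleParams(g, k, lam, R, n)


def sample_ensemble_model(topology: EnsembleTopology, seed: int = 0):
    """One random model from the ensemble distribution, as a GRNModel."""
    from .ode_core import GRNModel, GeneKinetics, RegulationEdgeParams
    rng = np.random.default_rng(seed)
    p = sample_ensemble_params(topology, 1, rng)
    kin = {g: GeneKinetics(g, production=float(p.g[0, i]),
                           degradation=float(p.k[0, i]))
           for i, g in enumerate(topology.genes)}
    edges = [RegulationEdgeParams(s, t, float(p.lam[0, j]), float(p.R[0, j]),
                                  float(p.n[0, j]))
             for j, (s, t, _) in enumerate(topology.edges)]
    return GRNModel(genes=list(topology.genes), kinetics=kin, edges=edges)


def _batched_rhs(X: np.ndarray, topology: EnsembleTopology,
                 params: EnsembleParams, gidx: dict) -> np.ndarray:
    prod = params.g.copy()
    for j, (s, t, _) in enumerate(topology.edges):
        y = X[:, gidx[s]]
        sfrac = (y / params.R[:, j]) ** params.n[:, j]
        H = params.lam[:, j] + (1.0 - params.lam[:, j]) / (1.0 + sfrac)
        prod[:, gidx[t]] *= H
    return prod - params.k * X


def _batched_steady_state(topology: EnsembleTopology, params: EnsembleParams,
                          x0: np.ndarray, t_max: float = 200.0,
                          step: float = 0.05, rel_tol: float = 1e-4):
    """Fixed-step RK4 for the whole batch until relative stationarity."""
    gidx = {g: i for i, g in enumerate(topology.genes)}
    X = x0.copy()
    t = 0.0
    check_every = int(round(2.0 / step))
    converged = np.zeros(X.shape[0], dtype=bool)
    i = 0
    while t < t_max:
        k1 = _batched_rhs(X, topology, params, gidx)
        k2 = _batched_rhs(X + step / 2 * k1, topology, params, gidx)
        k3 = _batched_rhs(X + step / 2 * k2, topology, params, gidx)
        k4 = _batched_rhs(X + step * k3, topology, params, gidx)
        X = np.maximum(X + step / 6 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
        t += step
        i += 1
        if i % check_every == 0:
            rate = np.abs(_batched_rhs(X, topology, params, gidx))
            scale = np.maximum(params.k * X, 1.0)
            converged = np.max(rate / scale, axis=1) < rel_tol
            if converged.all():
                break
    return X, converged


@dataclass
class EnsembleProfiles:
    genes: list
    raw: np.ndarray             # (n_models, G) steady states, >= 0
    shifts: np.ndarray          # per-gene log shift constant
    normalized: np.ndarray      # per-gene mean 0, sd 1
    norm_mean: np.ndarray = None
    norm_sd: np.ndarray = None


def simulate_ensemble(topology: EnsembleTopology, n_models: int = 10000,
                      seed: int = 0, config: EnsembleConfig | None = None,
                      max_fail_rate: float = 0.2) -> np.ndarray:
    """Steady-state profiles (n_models x G) of the random-parameter ensemble.

    Non-converged draws are resampled; a failure rate above 20% raises with
    a suggestion to increase the integration horizon.
    """
    if n_models < 1:
        raise ValueError("need at least one model")
    rng = child_rng(seed, "ensemble")
    rows = []
    attempts = 0
    failures = 0
    remaining = n_models
    while remaining > 0:
        batch = remaining
        params = sample_ensemble_params(topology, batch, rng)
        x0 = rng.uniform(0.0, 1.5, size=params.g.shape) * (params.g / params.k)
        X, ok = _batched_steady_state(topology, params, x0)
        attempts += batch
        failures += int((~ok).sum())
        rows.append(X[ok])
        remaining -= int(ok.sum())
        if attempts >= 3 * n_models and failures / attempts > max_fail_rate:
            raise RuntimeError(
                "ensemble convergence failure rate above 20%; increase t_max")
    return np.vstack(rows)[:n_models]


# ---------------------------------------------------------------------------
# Log-shift normalization
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    return (x - np.mean(x)) / sd if sd > 0 else x - np.mean(x)


def histogram_overlap(a: np.ndarray, b: np.ndarray, bins: int = 50) -> float:
    """Histogram intersection of two samples over their pooled range."""
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi <= lo:
        return 1.0
    ha, _ = np.histogram(a, bins=bins, range=(lo, hi), density=False)
    hb, _ = np.histogram(b, bins=bins, range=(lo, hi), density=False)
    return float(np.minimum(ha / len(a), hb / len(b)).sum())


def fit_log_shift(ensemble_column: np.ndarray, target_values: np.ndarray,
                  grid_size: int = 31, bins: int = 50) -> float:
    """Shift constant maximizing the overlap of log2(u + shift) with the
    trajectory distribution (both standardized). Grid: log2(shift) even in
    [-10, 5]."""
    shifts = 2.0 ** np.linspace(-10.0, 5.0, grid_size)
    target_z = _standardize(np.asarray(target_values, float))
    if np.ptp(ensemble_column) == 0:
        return float(shifts[0])
    best_shift, best_overlap = float(shifts[0]), -1.0
    for s in shifts:
        z = _standardize(np.log2(ensemble_column + s))
        ov = histogram_overlap(z, target_z, bins)
        if ov > best_overlap:
            best_overlap, best_shift = ov, float(s)
    return best_shift


def normalize_profiles(raw: np.ndarray, genes: list,
                       bundle: TrajectoryBundle,
                       config: EnsembleConfig | None = None) -> EnsembleProfiles:
    cfg = config or EnsembleConfig()
    shifts = np.empty(len(genes))
    logged = np.empty_like(raw)
    for i, g in enumerate(genes):
        shifts[i] = fit_log_shift(raw[:, i], bundle[g].values,
                                  cfg.shift_grid_size, cfg.overlap_bins)
        logged[:, i] = np.log2(raw[:, i] + shifts[i])
    mean = logged.mean(axis=0)
    sd = np.where(logged.std(axis=0) > 0, logged.std(axis=0), 1.0)
    return EnsembleProfiles(genes, raw, shifts, (logged - mean) / sd,
                            norm_mean=mean, norm_sd=sd)


# ---------------------------------------------------------------------------
# Reference states, mapping, metrics
# ---------------------------------------------------------------------------


@dataclass
class ReferenceStateSet:
    indices: np.ndarray         # grid indices, ordered by pseudotime
    states: np.ndarray          # (n_r, G) standardized reference vectors
    cutoffs: np.ndarray = None  # D_r per reference


def select_reference_states(bundle: TrajectoryBundle, genes: list,
                            n_r: int = 6) -> ReferenceStateSet:
    """n_r evenly spaced grid points (endpoints included); vectors are the
    per-gene standardized trajectory values at those points."""
    if n_r < 2:
        raise ValueError("need at least two reference states")
    M = len(bundle.grid)
    indices = np.round(np.linspace(0, M - 1, n_r)).astype(int)
    mat = np.vstack([_standardize(bundle[g].values) for g in genes])
    return ReferenceStateSet(indices, mat[:, indices].T)


def compute_cutoffs(references: ReferenceStateSet, n_genes: int,
                    n_random: int = 10000, seed: int = 0,
                    percentile: float = 5.0,
                    ensemble_mean=None, ensemble_sd=None) -> np.ndarray:
    """D_r = 5th percentile of random-profile distances to reference r.

    Random profiles are per-gene normal with the ensemble's normalized mean
    and sd (0 and 1 after standardization unless overridden)."""
    rng = child_rng(seed, "cutoffs")
    mean = np.zeros(n_genes) if ensemble_mean is None else ensemble_mean
    sd = np.ones(n_genes) if ensemble_sd is None else ensemble_sd
    random_profiles = rng.normal(mean, sd, size=(n_random, n_genes))
    d = np.linalg.norm(random_profiles[:, None, :] -
                       references.states[None, :, :], axis=2)
    return np.percentile(d, percentile, axis=0)


def map_models(profiles: np.ndarray, references: ReferenceStateSet) -> np.ndarray:
    """Assignment per model: reference index, or -1 when unmapped.

    A profile maps to reference r when its distance is within D_r; multiple
    qualifying references resolve by the minimum D/D_r ratio."""
    d = np.linalg.norm(profiles[:, None, :] - references.states[None, :, :],
                       axis=2)
    ratio = d / references.cutoffs[None, :]
    best = np.argmin(ratio, axis=1)
    assigned = np.where(ratio[np.arange(len(profiles)), best] <= 1.0, best, -1)
    return assigned


def local_density(profiles: np.ndarray, k_neighbors: int = 15,
                  mode: str = "low", constant: float = 15.0) -> np.ndarray:
    """rho_a = constant / (pi * R_a^v), R_a = distance to the k-th neighbour.

    ``mode="low"`` computes distances within the first three principal
    components (v = 3); ``mode="full"`` uses all genes (v = n_genes).
    """
    if len(profiles) <= k_neighbors:
        raise ValueError("need more profiles than neighbours")
    if mode == "low":
        v = min(3, profiles.shape[1])
        space = PCA(n_components=v).fit_transform(profiles) \
            if profiles.shape[1] > v else profiles
    else:
        v = profiles.shape[1]
        space = profiles
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(space)
    dist, _ = nn.kneighbors(space)
    R = np.maximum(dist[:, -1], 1e-12)
    return constant / (np.pi * R ** v)


def weighted_mapping_percentage(assignments: np.ndarray,
                                densities: np.ndarray) -> float:
    """p_tot = sum of inverse densities over mapped models, normalized."""
    inv = 1.0 / densities
    total = inv.sum()
    return float(inv[assignments >= 0].sum() / total) if total > 0 else 0.0


def reference_shares(assignments: np.ndarray, densities: np.ndarray,
                     n_r: int, mapped_only: bool = True) -> np.ndarray:
    inv = 1.0 / densities
    denom = inv[assignments >= 0].sum() if mapped_only else inv.sum()
    if denom == 0:
        return np.zeros(n_r)
    return np.array([inv[assignments == r].sum() / denom for r in range(n_r)])


def grn_entropy(shares: np.ndarray) -> float:
    """Shannon entropy (bits) of per-reference shares; 0 log 0 := 0."""
    p = np.asarray(shares, float)
    if p.sum() <= 0:
        return float("nan")
    p = p / p.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def deviation_metric(profiles: np.ndarray, assignments: np.ndarray,
                     references: ReferenceStateSet,
                     random_profiles: np.ndarray) -> dict:
    """d_u over unmapped models, d_theta over the random baseline, and
    omega = (d_u - 1)/(d_theta - 1); omega is NaN when d_theta <= 1."""
    def _avg_norm_dist(mat):
        if len(mat) == 0:
            return np.nan
        d = np.linalg.norm(mat[:, None, :] - references.states[None, :, :],
                           axis=2)
        return float(np.mean(np.min(d / references.cutoffs[None, :], axis=1)))

    d_u = _avg_norm_dist(profiles[assignments < 0])
    d_theta = _avg_norm_dist(random_profiles)
    omega = (d_u - 1.0) / (d_theta - 1.0) \
        if np.isfinite(d_u) and np.isfinite(d_theta) and d_theta > 1 else np.nan
    return {"d_u": d_u, "d_theta": d_theta, "omega": omega,
            "n_unmapped": int((assignments < 0).sum())}


@dataclass
class MappingResult:
    genes: list
    assignments: np.ndarray
    p_tot_low: float
    p_tot_full: float
    shares: np.ndarray
    entropy: float
    deviation: dict
    profiles: EnsembleProfiles = None
    references: ReferenceStateSet = None


def map_ensemble(topology: EnsembleTopology, bundle: TrajectoryBundle,
                 config: EnsembleConfig | None = None,
                 seed: int = 0) -> MappingResult:
    """Full pipeline: simulate, normalize, map, and score one topology."""
    cfg = config or EnsembleConfig()
    genes = [g for g in topology.genes if g in bundle]
    raw = simulate_ensemble(topology, cfg.n_models, seed, cfg)
    keep = [topology.genes.index(g) for g in genes]
    profiles = normalize_profiles(raw[:, keep], genes, bundle, cfg)
    refs = select_reference_states(bundle, genes, cfg.n_references)
    refs.cutoffs = compute_cutoffs(refs, len(genes), cfg.n_random, seed,
                                   cfg.cutoff_percentile)
    assignments = map_models(profiles.normalized, refs)
    rho_low = local_density(profiles.normalized, cfg.k_neighbors, "low",
                            cfg.density_constant)
    rho_full = local_density(profiles.normalized, cfg.k_neighbors, "full",
                             cfg.density_constant)
    p_low = weighted_mapping_percentage(assignments, rho_low)
    p_full = weighted_mapping_percentage(assignments, rho_full)
    shares = reference_shares(assignments, rho_low, cfg.n_references,
                              cfg.entropy_mapped_only)
    rng = child_rng(seed, "deviation")
    random_profiles = rng.normal(size=(cfg.n_random, len(genes)))
    dev = deviation_metric(profiles.normalized, assignments, refs,
                           random_profiles)
    return MappingResult(genes, assignments, p_low, p_full, shares,
                         grn_entropy(shares), dev, profiles, refs)
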