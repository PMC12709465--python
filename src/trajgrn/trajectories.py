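"""Smoothed per-gene expression trajectories along pseudotime.

Expression is log-normalized, fitted gene-by-gene with a cubic regression
spline (4 interior knots by default) against pseudotime, and evaluated on a
shared uniform grid of M = 201 points spanning [0, 1] inclusive. Standardized
trajectories (mean 0, sd 1) feed clustering and reporting; max-scaled
trajectories (max exactly 1, hence non-negative) feed the ODE fitting, whose
Hill inputs must be positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline, CubicSpline

from .data_io import ExpressionDataset, ValidationError

DEFAULT_M = 201


def uniform_grid(m: int = DEFAULT_M) -> np.ndarray:
    """M evenly spaced pseudotime points on [0, 1], both endpoints included."""
    if m < 5:
        raise ValueError("grid must have at least 5 points")
    return np.linspace(0.0, 1.0, m)


def log_normalize(values: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """log2(CPM/100 + 1) library-size normalization of a gene x cell table.

    A stand-in for variance-stabilizing normalization; pre-normalized input
    may bypass this entirely.
    """
    values = np.asarray(values, dtype=float)
    totals = values.sum(axis=0)
    totals = np.where(totals > 0, totals, 1.0)
    cpm_over_100 = values / totals * scale
    return np.log2(cpm_over_100 + 1.0)


@dataclass
class SmoothedTrajectory:
    """One gene's smoothed expression on a uniform pseudotime grid."""

    gene: str
    grid: np.ndarray
    values: np.ndarray
    scale_record: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValidationError("grid/values length mismatch")
        if len(self.grid) < 5:
            raise ValidationError("trajectory needs at least 5 grid points")
        steps = np.diff(self.grid)
        if not np.all(steps > 0) or not np.allclose(steps, steps[0], rtol=1e-8):
            raise ValidationError("grid must be strictly increasing and uniform")

    @property
    def sd(self) -> float:
        return float(np.std(self.values))

    def copy_with(self, values, **scale_updates) -> "SmoothedTrajectory":
        rec = dict(self.scale_record)
        rec.update(scale_updates)
        return SmoothedTrajectory(self.gene, self.grid.copy(),
                                  np.asarray(values, float), rec)


def _spline_design(x: np.ndarray, n_knots: int) -> tuple:
    """Cubic B-spline design matrix with interior knots at pseudotime quantiles."""
    k = 3
    interior = np.quantile(x, np.linspace(0, 1, n_knots + 2)[1:-1])
    lo, hi = float(np.min(x)), float(np.max(x))
    t = np.r_[[lo] * (k + 1), interior, [hi] * (k + 1)]
    design = BSpline.design_matrix(x, t, k, extrapolate=True).toarray()
    return design, t, k


def smooth_trajectory(values, pseudotime, gene: str = "", n_knots: int = 4,
                      m: int = DEFAULT_M, min_cells: int = 20) -> SmoothedTrajectory:
    """Least-squares cubic spline fit of expression against pseudotime.

    The smoother is linear in the data. All-constant input yields the constant
    trajectory with ``sd`` recorded as 0 so callers can exclude it.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(pseudotime, dtype=float)
    if y.shape != x.shape:
        raise ValidationError("expression/pseudotime length mismatch")
    if len(y) < min_cells:
        raise ValidationError(f"need at least {min_cells} cells, got {len(y)}")
    if np.any(x < 0) or np.any(x > 1):
        raise ValidationError("pseudotime must lie in [0, 1]")
    grid = uniform_grid(m)
    if np.ptp(y) == 0:
        return SmoothedTrajectory(gene, grid, np.full(m, y[0]),
                                  {"constant": True, "sd": 0.0})
    design, t, k = _spline_design(x, n_knots)
    coefs, *_ = np.linalg.lstsq(design, y, rcond=None)
    spline = BSpline(t, coefs, k, extrapolate=True)
    return SmoothedTrajectory(gene, grid, spline(grid), {"sd": float(np.std(y))})


def resample(traj: SmoothedTrajectory, m: int = DEFAULT_M) -> SmoothedTrajectory:
    """Re-evaluate a trajectory on an M-point uniform grid (cubic interpolation)."""
    if m < 5:
        raise ValidationError("M must be at least 5")
    grid = uniform_grid(m)
    if len(grid) == len(traj.grid) and np.allclose(grid, traj.grid):
        return SmoothedTrajectory(traj.gene, grid, traj.values.copy(),
                                  dict(traj.scale_record))
    interp = CubicSpline(traj.grid, traj.values)
    return SmoothedTrajectory(traj.gene, grid, interp(grid),
                              dict(traj.scale_record))


def standardize(traj: SmoothedTrajectory) -> SmoothedTrajectory:
    """Zero-mean, unit-sd (population) trajectory; scale stored for inversion."""
    mu, sd = float(np.mean(traj.values)), float(np.std(traj.values))
    if sd == 0:
        raise ValidationError(
            f"trajectory {traj.gene!r} is constant; exclude it from analysis")
    return traj.copy_with((traj.values - mu) / sd, mean=mu, sd=sd)


def max_scale(traj: SmoothedTrajectory, floor: float = 1e-6) -> SmoothedTrajectory:
    """Scale a trajectory so its maximum is exactly 1 (fitting-side convention).

    Negative values (possible after standardization) are first shifted so the
    minimum maps to a small positive floor, keeping Hill inputs positive.
    """
    vals = traj.values.astype(float)
    shift = 0.0
    if vals.min() < floor:
        shift = floor - vals.min()
        vals = vals + shift
    mx = vals.max()
    if mx <= 0:
        raise ValidationError("non-positive maximum after shift")
    out = traj.copy_with(vals / mx, shift=shift, max=float(mx))
    return out


@dataclass
class TrajectoryBundle:
    """Smoothed trajectories of many genes sharing one uniform grid."""

    grid: np.ndarray
    trajectories: dict          # gene -> SmoothedTrajectory

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        for g, tr in self.trajectories.items():
            if not np.allclose(tr.grid, self.grid):
                raise ValidationError(f"trajectory {g!r} is on a different grid")

    @property
    def genes(self) -> list:
        return list(self.trajectories)

    def __getitem__(self, gene: str) -> SmoothedTrajectory:
        return self.trajectories[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.trajectories

    def values_matrix(self, genes=None) -> np.ndarray:
        genes = genes if genes is not None else self.genes
        return np.vstack([self.trajectories[g].values for g in genes])

    def transform(self, fn) -> "TrajectoryBundle":
        return TrajectoryBundle(self.grid,
                                {g: fn(tr) for g, tr in self.trajectories.items()})

    def subset(self, genes) -> "TrajectoryBundle":
        return TrajectoryBundle(self.grid, {g: self.trajectories[g] for g in genes})

    def to_tsv(self, path) -> None:
        import pandas as pd
        df = pd.DataFrame({"grid": self.grid})
        for g in self.genes:
            df[g] = self.trajectories[g].values
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TrajectoryBundle":
        import pandas as pd
        df = pd.read_csv(path, sep="\t")
        grid = df["grid"].to_numpy()
        trajs = {g: SmoothedTrajectory(g, grid, df[g].to_numpy())
                 for g in df.columns if g != "grid"}
        return cls(grid, trajs)

    @classmethod
    def from_arrays(cls, genes, grid, matrix) -> "TrajectoryBundle":
        matrix = np.asarray(matrix, float)
        return cls(grid, {g: SmoothedTrajectory(g, grid, matrix[i])
                          for i, g in enumerate(genes)})


def smooth_dataset(dataset: ExpressionDataset, n_knots: int = 4, m: int = DEFAULT_M,
                   normalize: bool = True, min_cells: int = 20) -> TrajectoryBundle:
    """Log-normalize (optional) and smooth every gene of a dataset."""
    values = log_normalize(dataset.values) if normalize else dataset.values
    grid = uniform_grid(m)
    trajs = {}
    for i, gene in enumerate(dataset.genes):
        trajs[gene] = smooth_trajectory(values[i], dataset.pseudotime, gene=gene,
                                        n_knots=n_knots, m=m, min_cells=min_cells)
    return TrajectoryBundle(grid, trajs)


def pc1_pseudotime(values: np.ndarray) -> np.ndarray:
    """Rank cells along the first principal component (pseudotime stand-in).

    A convenience for datasets lacking a pseudotime; a crude substitute for a
    dedicated trajectory-inference method.
    """
    from sklearn.decomposition import PCA
    z = values.T - values.T.mean(axis=0)
    pc1 = PCA(n_components=1).fit_transform(z)[:, 0]
    order = np.argsort(np.argsort(pc1))
    return order / max(len(order) - 1, 1)
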