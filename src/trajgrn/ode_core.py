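"""Shifted-Hill regulatory ODE model.

The expression x_i of gene i obeys

    dx_i/dt = g_i * prod_j H(x_j; lambda_ij, R_ij, n_ij) - k_i * x_i,

with the shifted Hill function H(y) = lambda + (1 - lambda) / (1 + (y/R)^n):
H(0) = 1 and H(inf) = lambda, so lambda > 1 activates and lambda < 1
inhibits. Under a quasi-steady-state assumption the log fixed point is

    log2 x_i = sum_j log2 H(y_j) + C,       C = log2(g_i / k_i),

which is what the fitting pipeline regresses along trajectories. Fitting
identifies only C, not the timescale; simulation-ready models therefore
resolve k_i = 1 and g_i = 2^C (a unit relaxation timescale), so driving
protocols must be slow relative to 1.

Integration is fixed-step classical RK4, with optional driver overrides
clamping chosen genes to prescribed time courses at every sub-step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

LOG2 = np.log(2.0)


class IntegrationError(RuntimeError):
    pass


def shifted_hill(y, lam: float, R: float, n: float):
    """lambda + (1 - lambda)/(1 + (y/R)^n); lies between 1 and lambda."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("Hill input must be non-negative")
    s = (y / R) ** n
    return lam + (1.0 - lam) / (1.0 + s)


@dataclass
class RegulationEdgeParams:
    source: str
    target: str
    lam: float                 # maximal fold change, > 0, != 1 when retained
    threshold: float           # Hill threshold R > 0
    hill: float                # Hill coefficient n > 0

    @property
    def sign(self) -> int:
        return 1 if self.lam > 1 else -1

    def hill_value(self, y):
        return shifted_hill(y, self.lam, self.threshold, self.hill)


@dataclass
class GeneKinetics:
    gene: str
    production: float | None = None     # g_i
    degradation: float | None = None    # k_i
    log_ratio: float | None = None      # C = log2(g_i / k_i)

    def __post_init__(self):
        if (self.production is not None and self.degradation is not None
                and self.production > 0):
            c = np.log2(self.production / self.degradation)
            if self.log_ratio is None:
                self.log_ratio = float(c)
            elif abs(self.log_ratio - c) > 1e-9:
                raise ValueError(
                    f"{self.gene}: C={self.log_ratio} inconsistent with g/k")

    @property
    def resolved(self) -> bool:
        return self.production is not None and self.degradation is not None

    def resolve_unit_timescale(self) -> "GeneKinetics":
        """Fix k = 1 and g = 2^C (fitting determines only their ratio)."""
        if self.log_ratio is None:
            raise ValueError(f"{self.gene}: no C to resolve kinetics from")
        return GeneKinetics(self.gene, production=float(2.0 ** self.log_ratio),
                            degradation=1.0, log_ratio=self.log_ratio)


@dataclass
class GRNModel:
    """A signed, parameterized regulatory network ready for simulation."""

    genes: list
    kinetics: dict             # gene -> GeneKinetics
    edges: list = field(default_factory=list)   # RegulationEdgeParams

    def __post_init__(self):
        gene_set = set(self.genes)
        for e in self.edges:
            if e.source not in gene_set or e.target not in gene_set:
                raise ValueError(f"edge {e.source}->{e.target} references "
                                 "a gene outside the model")
        self._index = {g: i for i, g in enumerate(self.genes)}
        self._incoming = {g: [e for e in self.edges if e.target == g]
                          for g in self.genes}
        self._arrays = None

    @property
    def simulation_ready(self) -> bool:
        return all(self.kinetics[g].resolved for g in self.genes)

    def regulators_of(self, gene: str) -> list:
        return [e.source for e in self._incoming[gene]]

    def edge(self, source: str, target: str) -> RegulationEdgeParams:
        for e in self._incoming[target]:
            if e.source == source:
                return e
        raise KeyError((source, target))

    def _prepare_arrays(self):
        if self._arrays is not None:
            return self._arrays
        for g in self.genes:
            if not self.kinetics[g].resolved:
                raise ValueError(f"{g}: unresolved kinetics; cannot simulate")
        g_arr = np.array([self.kinetics[g].production for g in self.genes])
        k_arr = np.array([self.kinetics[g].degradation for g in self.genes])
        src = np.array([self._index[e.source] for e in self.edges], dtype=int)
        tgt = np.array([self._index[e.target] for e in self.edges], dtype=int)
        lam = np.array([e.lam for e in self.edges])
        R = np.array([e.threshold for e in self.edges])
        n = np.array([e.hill for e in self.edges])
        self._arrays = (g_arr, k_arr, src, tgt, lam, R, n)
        return self._arrays

    def rhs(self, x: np.ndarray) -> np.ndarray:
        """dx/dt at state x; x may be a batch of states (..., n_genes)."""
        g_arr, k_arr, src, tgt, lam, R, n = self._prepare_arrays()
        x = np.asarray(x, dtype=float)
        prod = np.broadcast_to(g_arr, x.shape).copy()
        if len(src):
            y = np.maximum(x[..., src], 0.0)
            H = lam + (1.0 - lam) / (1.0 + (y / R) ** n)
            if x.ndim == 1:
                np.multiply.at(prod, tgt, H)
            else:
                for j, t in enumerate(tgt):
                    prod[..., t] *= H[..., j]
        return prod - k_arr * x

    def qss_log_prediction(self, gene: str, regulator_values: dict) -> float:
        """log2 of the frozen-regulator fixed point of gene's ODE."""
        kin = self.kinetics[gene]
        total = kin.log_ratio if kin.log_ratio is not None else \
            np.log2(kin.production / kin.degradation)
        for e in self._incoming[gene]:
            total += np.log2(e.hill_value(regulator_values[e.source]))
        return float(total)

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "kinetics": {g: {"g": self.kinetics[g].production,
                             "k": self.kinetics[g].degradation,
                             "C": self.kinetics[g].log_ratio}
                         for g in self.genes},
            "edges": [{"source": e.source, "target": e.target, "lambda": e.lam,
                       "R": e.threshold, "n": e.hill} for e in self.edges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GRNModel":
        kin = {g: GeneKinetics(g, production=v.get("g"), degradation=v.get("k"),
                               log_ratio=v.get("C"))
               for g, v in d["kinetics"].items()}
        edges = [RegulationEdgeParams(e["source"], e["target"], e["lambda"],
                                      e["R"], e["n"]) for e in d["edges"]]
        return cls(genes=list(d["genes"]), kinetics=kin, edges=edges)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path) -> "GRNModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def qss_log_prediction(model: GRNModel, gene: str, regulator_values: dict) -> float:
    return model.qss_log_prediction(gene, regulator_values)


def objective(prediction: np.ndarray, target: np.ndarray, lambdas, w: float) -> float:
    """Mean squared prediction error plus w * sum (lambda - 1)^2."""
    prediction = np.asarray(prediction, float)
    target = np.asarray(target, float)
    if prediction.shape != target.shape:
        raise ValueError("prediction/target length mismatch")
    if w < 0:
        raise ValueError("regularization weight must be non-negative")
    data = float(np.mean((prediction - target) ** 2))
    reg = float(w * np.sum((np.asarray(lambdas, float) - 1.0) ** 2))
    return data + reg


def rk4_integrate(model: GRNModel, x0, t_span, step: float,
                  drivers: dict | None = None, record_times=None):
    """Classical fixed-step RK4 over ``t_span``.

    ``drivers`` maps gene -> f(t) clamped at every RK4 sub-step (and in the
    recorded output). Returns ``(times, states)`` with states of shape
    (len(times), n_genes); ``record_times`` defaults to every step.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    t0, t1 = float(t_span[0]), float(t_span[1])
    x = np.array(x0, dtype=float)
    idx = {g: model._index[g] for g in (drivers or {})}

    def clamp(xv, t):
        for g, fn in (drivers or {}).items():
            xv[idx[g]] = fn(t)
        return xv

    def f(t, xv):
        return model.rhs(clamp(xv.copy(), t))

    n_steps = int(round((t1 - t0) / step))
    times_out = [t0]
    x = clamp(x, t0)
    states = [x.copy()]
    t = t0
    for _ in range(n_steps):
        k1 = f(t, x)
        k2 = f(t + step / 2, x + step / 2 * k1)
        k3 = f(t + step / 2, x + step / 2 * k2)
        k4 = f(t + step, x + step * k3)
        x = x + step / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += step
        x = clamp(x, t)
        x = np.maximum(x, 0.0)     # production>=0, linear decay: floor solver noise
        if not np.all(np.isfinite(x)):
            raise IntegrationError(f"non-finite state at t={t:.6g}")
        times_out.append(t)
        states.append(x.copy())
    times_arr = np.array(times_out)
    states_arr = np.array(states)
    if record_times is not None:
        record_times = np.asarray(record_times, float)
        out = np.empty((len(record_times), states_arr.shape[1]))
        for j in range(states_arr.shape[1]):
            out[:, j] = np.interp(record_times, times_arr, states_arr[:, j])
        gene_list = list(model.genes)
        for g, fn in (drivers or {}).items():
            out[:, gene_list.index(g)] = [fn(t) for t in record_times]
        return record_times, out
    return times_arr, states_arr


def find_steady_state(model: GRNModel, x0, tol: float = 1e-6,
                      t_max: float = 1000.0, step: float = 0.05,
                      drivers: dict | None = None):
    """Integrate until max|dx/dt| < tol or t_max; returns (state, converged)."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    x = np.array(x0, dtype=float)
    if drivers:
        for g, fn in drivers.items():
            x[model._index[g]] = fn(0.0)
    t = 0.0
    chunk = min(5.0, t_max)
    if np.max(np.abs(model.rhs(x))) < tol:
        return x, True
    while t < t_max:
        span = min(chunk, t_max - t)
        _, states = rk4_integrate(model, x, (t, t + span), step, drivers=drivers)
        x = states[-1]
        t += span
        if np.max(np.abs(model.rhs(x))) < tol:
            return x, True
    return x, False
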