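"""Driving simulations of a fitted GRN model and hysteresis diagnostics.

A fitted model is driven by clamping 1-3 TFs to their observed (max-scaled)
trajectories, mapped linearly from pseudotime [0, 1] onto a simulation
window [0, S] (S = 100 by default, slow relative to the unit relaxation
timescale). The forward run starts from the relaxed steady state at the
trajectories' initial values; the backward run starts from the forward run's
final state and clamps drivers to the time-reversed trajectories. Two mean
squared deviations summarize each driver set:

* ``msd_data``    — forward non-driver trajectories vs the observed ones,
  each gene min-max rescaled to [0, 1] independently;
* ``msd_hysteresis`` — forward vs time-reversed backward trajectories,
  rescaled jointly per gene so coinciding paths give exactly 0.

Scanning all driver combinations reproduces the single/pair MSD matrices and
the data-vs-hysteresis scatter used to shortlist driver TFs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .data_io import DrivingConfig
from .ode_core import GRNModel, find_steady_state, rk4_integrate
from .trajectories import TrajectoryBundle


@dataclass
class DrivingReport:
    drivers: tuple
    times: np.ndarray           # output grid on [0, S]
    forward: dict               # gene -> simulated forward trajectory
    backward: dict              # gene -> simulated backward trajectory
    msd_data: float
    msd_hysteresis: float
    initial_converged: bool = True


def _minmax(x: np.ndarray) -> np.ndarray:
    span = np.ptp(x)
    if span == 0:
        return np.zeros_like(x)
    return (x - x.min()) / span


def _joint_minmax(a: np.ndarray, b: np.ndarray) -> tuple:
    lo = min(a.min(), b.min())
    span = max(a.max(), b.max()) - lo
    if span == 0:
        return np.zeros_like(a), np.zeros_like(b)
    return (a - lo) / span, (b - lo) / span


def _driver_fn(values: np.ndarray, S: float, reverse: bool = False):
    grid = np.linspace(0.0, S, len(values))
    vals = values[::-1] if reverse else values

    def fn(t):
        return float(np.interp(t, grid, vals))

    return fn


def run_driving(model: GRNModel, drivers, bundle: TrajectoryBundle,
                config: DrivingConfig | None = None) -> DrivingReport:
    """Forward/backward clamped simulation for one driver set."""
    cfg = config or DrivingConfig()
    drivers = tuple(drivers)
    if not 1 <= len(drivers) <= 3:
        raise ValueError("driver sets must contain 1-3 genes")
    for d in drivers:
        if d not in model.genes:
            raise ValueError(f"driver {d!r} not in the model")
    S = cfg.total_time
    step = S / cfg.n_steps
    genes = list(model.genes)
    observed = {g: bundle[g].values for g in genes if g in bundle}
    m = len(next(iter(observed.values())))
    record = np.linspace(0.0, S, m)

    fwd_fns = {d: _driver_fn(observed[d], S) for d in drivers}
    x0 = np.array([observed.get(g, np.zeros(1))[0] for g in genes])
    x_init, converged = find_steady_state(model, x0, t_max=200.0, step=step,
                                          drivers={d: (lambda t, f=fwd_fns[d]:
                                                       f(0.0)) for d in drivers})
    _, fwd = rk4_integrate(model, x_init, (0.0, S), step, drivers=fwd_fns,
                           record_times=record)
    bwd_fns = {d: _driver_fn(observed[d], S, reverse=True) for d in drivers}
    _, bwd = rk4_integrate(model, fwd[-1], (0.0, S), step, drivers=bwd_fns,
                           record_times=record)

    non_drivers = [g for g in genes if g not in drivers and g in observed]
    msd_data_terms, msd_hyst_terms = [], []
    fwd_dict, bwd_dict = {}, {}
    for i, g in enumerate(genes):
        fwd_dict[g] = fwd[:, i]
        bwd_dict[g] = bwd[:, i]
    for g in non_drivers:
        i = genes.index(g)
        sim_f = _minmax(fwd[:, i])
        data = _minmax(observed[g])
        msd_data_terms.append(np.mean((sim_f - data) ** 2))
        f_scaled, b_scaled = _joint_minmax(fwd[:, i], bwd[::-1, i])
        msd_hyst_terms.append(np.mean((f_scaled - b_scaled) ** 2))
    msd_data = float(np.mean(msd_data_terms)) if msd_data_terms else 0.0
    msd_hyst = float(np.mean(msd_hyst_terms)) if msd_hyst_terms else 0.0
    return DrivingReport(drivers, record, fwd_dict, bwd_dict, msd_data,
                         msd_hyst, initial_converged=converged)


def scan_driver_combinations(model: GRNModel, bundle: TrajectoryBundle,
                             config: DrivingConfig | None = None) -> tuple:
    """DrivingReport per driver combination plus the two MSD matrices.

    Singles populate the diagonals, pairs the (symmetric) off-diagonals.
    Returns ``(reports, msd_data_matrix, msd_hysteresis_matrix)`` with
    matrices as DataFrames indexed by gene.
    """
    cfg = config or DrivingConfig()
    genes = [g for g in model.genes if g in bundle]
    reports = {}
    for g in genes:
        reports[(g,)] = run_driving(model, (g,), bundle, cfg)
    if cfg.max_drivers >= 2:
        for pair in combinations(genes, 2):
            reports[pair] = run_driving(model, pair, bundle, cfg)
    if cfg.max_drivers >= 3:
        for trio in combinations(genes, 3):
            reports[trio] = run_driving(model, trio, bundle, cfg)
    data_m = pd.DataFrame(np.nan, index=genes, columns=genes)
    hyst_m = pd.DataFrame(np.nan, index=genes, columns=genes)
    for combo, rep in reports.items():
        if len(combo) == 1:
            data_m.loc[combo[0], combo[0]] = rep.msd_data
            hyst_m.loc[combo[0], combo[0]] = rep.msd_hysteresis
        elif len(combo) == 2:
            a, b = combo
            data_m.loc[a, b] = data_m.loc[b, a] = rep.msd_data
            hyst_m.loc[a, b] = hyst_m.loc[b, a] = rep.msd_hysteresis
    return reports, data_m, hyst_m
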