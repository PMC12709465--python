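"""Trajectory-shape clustering by turning-point sign patterns.

A smoothed, standardized trajectory is partitioned at its turning points
(strict sign changes of the first finite difference, with plateaus absorbed
into the preceding trend). Segments whose amplitude (max - min) falls below a
threshold are merged into their neighbours by removing the delimiting turning
points, iterating to a fixed point. The gene's cluster label is the
alternating sign string of the surviving segments; only six labels are
possible ("+", "-", "+-", "-+", "+-+", "-+-"). Genes whose trajectories keep
more than two turning points, or prune to nothing, are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ClusterConfig
from .trajectories import SmoothedTrajectory, TrajectoryBundle, standardize

VALID_LABELS = ("+", "-", "+-", "-+", "+-+", "-+-")


@dataclass
class TurningPointProfile:
    gene: str
    turning_indices: list
    segment_signs: list        # "+" / "-" per segment, alternating
    label: str                 # sign string, or "EXCLUDED(<reason>)"

    @property
    def excluded(self) -> bool:
        return self.label.startswith("EXCLUDED")


def filter_low_variance(values: np.ndarray, genes, sd_threshold: float = 0.25):
    """Retain genes whose per-gene sd on processed data reaches the threshold."""
    sds = np.std(np.asarray(values, float), axis=1)
    return [g for g, sd in zip(genes, sds) if sd >= sd_threshold]


def _segment_signs(values: np.ndarray, boundaries: list) -> list:
    """Net trend of each segment delimited by the boundary indices."""
    signs = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        signs.append("+" if values[b] >= values[a] else "-")
    return signs


def find_turning_points(traj_or_values) -> list:
    """Grid indices of strict local extrema of the trajectory sequence.

    Zero first differences (plateaus) inherit the preceding trend, so a
    plateau inside a monotone stretch is not a turning point.
    """
    values = getattr(traj_or_values, "values", traj_or_values)
    values = np.asarray(values, float)
    d = np.diff(values)
    signs = np.sign(d)
    # absorb plateaus into the preceding trend
    for i in range(len(signs)):
        if signs[i] == 0:
            signs[i] = signs[i - 1] if i > 0 else 0
    # leading plateau: inherit the first non-zero trend
    nz = np.nonzero(signs)[0]
    if len(nz) == 0:
        return []
    signs[: nz[0]] = signs[nz[0]]
    turning = [i for i in range(1, len(values) - 1) if signs[i] != signs[i - 1]]
    return turning


def prune_turning_points(traj_or_values, indices, amp_threshold: float = 0.2) -> list:
    """Drop turning points delimiting segments of amplitude below threshold.

    A sub-threshold first or last segment loses its single delimiting turning
    point; an interior one loses both (its neighbours then merge, sharing one
    trend). Pruning repeats until every segment clears the threshold or no
    turning point remains. The smallest offending segment is resolved first.
    """
    values = getattr(traj_or_values, "values", traj_or_values)
    values = np.asarray(values, float)
    indices = sorted(indices)
    while indices:
        bounds = [0, *indices, len(values) - 1]
        amps = [np.ptp(values[a:b + 1]) for a, b in zip(bounds[:-1], bounds[1:])]
        worst = int(np.argmin(amps))
        if amps[worst] >= amp_threshold:
            break
        if worst == 0:                       # first segment
            drop = {indices[0]}
        elif worst == len(amps) - 1:         # last segment
            drop = {indices[-1]}
        else:                                # interior segment: both ends
            drop = {indices[worst - 1], indices[worst]}
        indices = [i for i in indices if i not in drop]
        # merging may leave adjacent segments with equal trend; re-derive
        # turning points among the survivors so signs stay alternating
        bounds = [0, *indices, len(values) - 1]
        signs = _segment_signs(values, bounds)
        keep = [idx for k, idx in enumerate(indices) if signs[k] != signs[k + 1]]
        indices = keep
    return indices


def classify(traj: SmoothedTrajectory, amp_threshold: float = 0.2,
             max_turning_points: int = 2) -> TurningPointProfile:
    """Assign the trajectory's shape label from its pruned turning points."""
    values = traj.values
    turning = prune_turning_points(values, find_turning_points(values),
                                   amp_threshold)
    if len(turning) > max_turning_points:
        return TurningPointProfile(traj.gene, turning, [],
                                   "EXCLUDED(too_many_turns)")
    bounds = [0, *turning, len(values) - 1]
    if np.ptp(values) == 0:
        return TurningPointProfile(traj.gene, [], [], "EXCLUDED(flat)")
    signs = _segment_signs(values, bounds)
    label = "".join(signs)
    if label not in VALID_LABELS:
        # non-alternating residue can only arise from pathological plateaus
        return TurningPointProfile(traj.gene, turning, signs,
                                   f"EXCLUDED(pattern:{label})")
    return TurningPointProfile(traj.gene, turning, signs, label)


def cluster_genes(bundle: TrajectoryBundle, processed_values: np.ndarray = None,
                  genes=None, config: ClusterConfig | None = None) -> pd.DataFrame:
    """Variance-filter, standardize, and classify every gene of a bundle.

    ``processed_values`` (gene x cell, aligned with ``genes``) carries the
    pre-smoothing processed data used for the sd filter; when omitted, the
    filter falls back to the smoothed trajectory sd.
    """
    cfg = config or ClusterConfig()
    all_genes = bundle.genes
    if processed_values is not None:
        genes = genes if genes is not None else all_genes
        retained = set(filter_low_variance(processed_values, genes,
                                           cfg.sd_threshold))
    else:
        retained = {g for g in all_genes
                    if bundle[g].sd >= cfg.sd_threshold}
    rows = []
    for g in all_genes:
        if g not in retained:
            rows.append((g, "EXCLUDED(low_variance)", ""))
            continue
        traj = bundle[g]
        if np.std(traj.values) == 0:
            rows.append((g, "EXCLUDED(flat)", ""))
            continue
        prof = classify(standardize(traj), cfg.amp_threshold,
                        cfg.max_turning_points)
        rows.append((g, prof.label, ",".join(map(str, prof.turning_indices))))
    return pd.DataFrame(rows, columns=["gene", "label", "turning_indices"])


def clusters_from_table(table: pd.DataFrame) -> dict:
    """Group retained genes by label: {label: set of genes}."""
    out: dict = {}
    for row in table.itertuples():
        if row.label in VALID_LABELS:
            out.setdefault(row.label, set()).add(row.gene)
    return out
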