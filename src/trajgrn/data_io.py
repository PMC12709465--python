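"""Input/output, run configuration, seeding, and synthetic fixture generation.

On-disk formats
---------------
* dense expression CSV/TSV: genes as rows, cells as columns, optional
  ``pseudotime`` row (otherwise a companion one-column file);
* MatrixMarket triplets (``.mtx``) with ``genes.tsv`` / ``barcodes.tsv``
  companions;
* GMT gene-set collections (TF -> target sets);
* TSV edge tables with header ``source  target  provenance  nes  sign``;
* SIF networks (``source  activates|inhibits|unknown  target``);
* JSON model reports and YAML run configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

logger = logging.getLogger("trajgrn")

SIF_TOKENS = {1: "activates", -1: "inhibits", 0: "unknown"}
SIF_SIGNS = {v: k for k, v in SIF_TOKENS.items()}


class ValidationError(ValueError):
    """Raised when an on-disk input violates a dataset contract."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryConfig:
    n_knots: int = 4          # interior spline knots
    grid_size: int = 201      # M evenly spaced pseudotime points (endpoints included)
    min_cells: int = 20


@dataclass
class ClusterConfig:
    sd_threshold: float = 0.25     # low-variance gene filter, on processed data
    amp_threshold: float = 0.2     # turning-point segment amplitude prune
    max_turning_points: int = 2    # beyond this the gene is excluded


@dataclass
class EnrichConfig:
    q_cutoff: float = 0.1          # BH-adjusted Fisher p for core-TF selection
    dedup_p: float = 1e-20         # target-set overlap p below which TFs are redundant
    nes_threshold: float = 1.0     # motif edges kept when NES exceeds this


@dataclass
class FitConfig:
    """Knobs of the four-stage per-gene optimization.

    The ``reduced`` preset trades restarts for speed while keeping every
    stage of the procedure; it is the configuration used by the package's
    own benchmark harness.
    """

    cv_folds: int = 5
    cv_interleaved: bool = True      # fold = point index mod 5 (pseudotime order)
    target_scale: str = "log2"       # "log2": fit the log2 QSS prediction to
    #   log2 of the max-scaled values (self-consistent; the generating model
    #   is then a member of the fitted family); "linear": to the values as
    #   they stand

    n_refits: int = 10               # stage-1 restarts per kept candidate
    pool_size: int = 100             # candidates carried into stage 2
    keep_top_n: int = 50             # stage-1 keep when N_i > 6 (else best 50%)
    stage1_cv: bool = True           # rank initial pattern fits by CV (vs all-data fit)
    tuning_grid_size: int = 20       # ln w grid points over [-15, 2]
    tuning_inits: int = 4            # top models used for the tuning curve
    scenario_inits: int = 10         # reference models refit per scenario
    reducibility_cutoff: float = 11.0
    max_regulators: int = 12         # hard cap on candidate regulators
    max_removable: int = 12          # cap on the removable-edge set size
    #   (when exceeded, the most sign-ambiguous edges are kept removable)
    max_nfev: int = 100              # optimizer budget per fit
    screen_subsample: int = 1        # grid stride for the stage-1 pattern
    #   screen (1 = use every point); kept candidates are refit on all points
    screen_max_nfev: int = 0         # optimizer budget for the screen (0 =
    #   same as max_nfev)
    lambda_act_bounds: tuple = (1.0 + 1e-3, 100.0)
    lambda_inh_bounds: tuple = (1e-2, 1.0 - 1e-3)
    n_bounds: tuple = (1e-3, 10.0)

    @classmethod
    def reduced(cls, **overrides) -> "FitConfig":
        base = dict(n_refits=0, pool_size=30, keep_top_n=30, stage1_cv=False,
                    tuning_grid_size=10, tuning_inits=2, scenario_inits=3,
                    max_nfev=40)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def benchmark(cls, **overrides) -> "FitConfig":
        """Cheapest schedule that still runs every stage; used for the
        many-case benchmark sweeps."""
        base = dict(n_refits=0, pool_size=20, keep_top_n=20, stage1_cv=False,
                    tuning_grid_size=6, tuning_inits=2, scenario_inits=2,
                    max_removable=6, max_nfev=25, screen_subsample=3,
                    screen_max_nfev=12)
        base.update(overrides)
        return cls(**base)


@dataclass
class DrivingConfig:
    total_time: float = 100.0    # simulation window S onto which pseudotime maps
    n_steps: int = 2000          # RK4 steps over the window
    max_drivers: int = 2


@dataclass
class EnsembleConfig:
    n_models: int = 10000
    n_references: int = 6
    k_neighbors: int = 15
    density_constant: float = 15.0   # numerator of the local-density formula
    n_random: int = 10000            # random profiles for distance cutoffs
    cutoff_percentile: float = 5.0
    shift_grid_size: int = 31        # log2 shift grid over [-10, 5]
    overlap_bins: int = 50
    entropy_mapped_only: bool = True


@dataclass
class BenchmarkConfig:
    n_curves: int = 10
    noise_levels: tuple = (0.0, 0.05, 0.1, 0.2)
    replicates: int = 3


@dataclass
class FixtureConfig:
    n_genes: int = 60
    n_cells: int = 200
    n_tfs: int = 6
    noise: float = 0.05
    base_expression: float = 100.0


@dataclass
class RunConfig:
    """All tunables of the pipeline, with paper-default values."""

    seed: int = 0
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    driving: DrivingConfig = field(default_factory=DrivingConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    fixture: FixtureConfig = field(default_factory=FixtureConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        def _clean(obj):
            if isinstance(obj, tuple):
                return [_clean(v) for v in obj]
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            return obj
        Path(path).write_text(yaml.safe_dump(_clean(self.to_dict()), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        kwargs: dict = {"seed": raw.get("seed", 0)}
        for fld in dataclasses.fields(cls):
            if fld.name == "seed":
                continue
            sub_cls = fld.default_factory  # type: ignore[union-attr]
            sub_raw = dict(raw.get(fld.name, {}))
            for sf in dataclasses.fields(sub_cls):
                if sf.name in sub_raw and isinstance(sf.default, tuple):
                    sub_raw[sf.name] = tuple(sub_raw[sf.name])
            kwargs[fld.name] = sub_cls(**sub_raw)
        return cls(**kwargs)


def child_seed(seed: int, label: str) -> int:
    """Derive a stable per-module child seed from the global seed.

    Keeps every module independently reproducible from one RunConfig seed.
    """
    return (int(seed) * 1_000_003 + zlib.crc32(label.encode())) % (2**31 - 1)


def child_rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, label))


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """A gene x cell expression table with per-cell pseudotime."""

    genes: list
    cells: list
    values: np.ndarray          # shape (n_genes, n_cells), non-negative
    pseudotime: np.ndarray      # shape (n_cells,), rescaled to [0, 1]
    stage_labels: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene identifiers")
        if np.any(self.values < 0):
            raise ValidationError("values: negative expression entries")
        if self.pseudotime.shape != (len(self.cells),):
            raise ValidationError("pseudotime length does not match cells")
        if not np.all(np.isfinite(self.pseudotime)):
            raise ValidationError("pseudotime: non-finite entries")
        lo, hi = self.pseudotime.min(), self.pseudotime.max()
        if hi > lo:
            self.pseudotime = (self.pseudotime - lo) / (hi - lo)
        else:
            raise ValidationError("pseudotime: all cells share one value")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(gene)]


@dataclass
class GeneSetCollection:
    """TF -> target gene sets over a background universe."""

    sets: dict                 # TF id -> set of target gene ids
    background: set

    def __post_init__(self):
        self.sets = {tf: set(t) for tf, t in self.sets.items()}
        self.background = set(self.background)
        for tf, targets in self.sets.items():
            if not targets:
                raise ValidationError(f"gene set for {tf} is empty")

    def restricted(self) -> "GeneSetCollection":
        """Restrict every target set to the background; drop emptied sets."""
        sets = {tf: t & self.background for tf, t in self.sets.items()}
        return GeneSetCollection({tf: t for tf, t in sets.items() if t},
                                 self.background)


EDGE_COLUMNS = ["source", "target", "provenance", "nes", "sign"]


def make_edge_table(rows: Sequence[tuple]) -> pd.DataFrame:
    """Build a validated edge table from (source, target, provenance[, nes[, sign]])."""
    recs = []
    for row in rows:
        src, tgt, prov = row[0], row[1], row[2]
        nes = row[3] if len(row) > 3 else np.nan
        sign = row[4] if len(row) > 4 else np.nan
        recs.append((src, tgt, prov, nes, sign))
    df = pd.DataFrame(recs, columns=EDGE_COLUMNS)
    if df.duplicated(subset=["source", "target", "provenance"]).any():
        raise ValidationError("duplicated (source, target, provenance) rows")
    return df


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_expression(path, fmt: str | None = None, pseudotime_path=None,
                    genes_path=None, cells_path=None) -> ExpressionDataset:
    """Read an expression matrix (genes x cells) plus pseudotime.

    ``fmt`` is inferred from the suffix when omitted ("csv"/"tsv"/"mtx").
    For dense tables a row labelled ``pseudotime`` may carry the pseudotime;
    otherwise ``pseudotime_path`` names a one-column file aligned with cells.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt in ("csv", "tsv", "txt"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        pt = None
        if "pseudotime" in df.index:
            pt = df.loc["pseudotime"].to_numpy(dtype=float)
            df = df.drop(index="pseudotime")
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    elif fmt == "mtx":
        mat = scipy.io.mmread(path)
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat,
                            dtype=float)
        genes_path = genes_path or path.with_name("genes.tsv")
        cells_path = cells_path or path.with_name("barcodes.tsv")
        genes = [ln.split("\t")[0].strip() for ln in
                 Path(genes_path).read_text().splitlines() if ln.strip()]
        cells = [ln.split("\t")[0].strip() for ln in
                 Path(cells_path).read_text().splitlines() if ln.strip()]
        pt = None
    else:
        raise ValidationError(f"unsupported expression format: {fmt}")
    if pt is None:
        if pseudotime_path is None:
            raise ValidationError("pseudotime: not embedded and no file given")
        pt = _read_pseudotime(pseudotime_path, cells)
    return ExpressionDataset(genes=genes, cells=cells, values=values, pseudotime=pt)


def _read_pseudotime(path, cells) -> np.ndarray:
    rows = [line.replace(",", "\t").split() for line in
            Path(path).read_text().replace("\t", " ").splitlines() if line.strip()]
    if all(len(r) == 2 for r in rows):
        mapping = {r[0]: float(r[1]) for r in rows}
        try:
            return np.array([mapping[c] for c in cells])
        except KeyError as exc:
            raise ValidationError(f"pseudotime: missing cell {exc}") from exc
    try:
        vals = np.array([float(r[-1]) for r in rows])
    except ValueError as exc:
        raise ValidationError(f"pseudotime: unparsable file ({exc})") from exc
    if len(vals) != len(cells):
        raise ValidationError("pseudotime: length does not match cells")
    return vals


def write_expression(dataset: ExpressionDataset, path, fmt: str = "csv") -> None:
    path = Path(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.DataFrame(dataset.values, index=dataset.genes, columns=dataset.cells)
        df.loc["pseudotime"] = dataset.pseudotime
        df.to_csv(path, sep=sep)
    elif fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(dataset.values))
        path.with_name("genes.tsv").write_text("\n".join(dataset.genes) + "\n")
        path.with_name("barcodes.tsv").write_text("\n".join(dataset.cells) + "\n")
        np.savetxt(path.with_name("pseudotime.tsv"), dataset.pseudotime)
    else:
        raise ValidationError(f"unsupported expression format: {fmt}")


def read_gmt(path) -> GeneSetCollection:
    sets: dict = {}
    universe: set = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        name, targets = parts[0], [g for g in parts[2:] if g]
        sets[name] = set(targets)
        universe |= sets[name]
    return GeneSetCollection(sets=sets, background=universe)


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = ["\t".join([tf, "na", *sorted(targets)])
             for tf, targets in collection.sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"edge table missing columns: {missing}")
    return df[EDGE_COLUMNS]


def write_edge_table(df: pd.DataFrame, path) -> None:
    df[EDGE_COLUMNS].to_csv(path, sep="\t", index=False)


def write_sif(edges, path) -> None:
    """Write (source, sign, target) triples; sign in {+1, -1, 0/None}."""
    lines = []
    for src, tgt, sign in edges:
        token = SIF_TOKENS[int(sign) if sign not in (None, 0) and not
                           (isinstance(sign, float) and np.isnan(sign)) else 0]
        lines.append(f"{src}\t{token}\t{tgt}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sif(path) -> list:
    edges = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        src, token, tgt = line.split("\t")
        edges.append((src, tgt, SIF_SIGNS[token]))
    return edges


def write_grn(model_or_edges, path, fmt: str = "sif") -> None:
    """Write a fitted model (JSON) or an edge list (SIF / TSV).

    ``model_or_edges`` is a GRNModel for fmt="json", otherwise an iterable of
    (source, target, sign) triples or an edge-table DataFrame.
    """
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(model_or_edges.to_dict(), indent=1))
    elif fmt == "sif":
        if isinstance(model_or_edges, pd.DataFrame):
            triples = [(r.source, r.target, None if pd.isna(r.sign) else int(r.sign))
                       for r in model_or_edges.itertuples()]
        elif hasattr(model_or_edges, "edges"):
            triples = [(e.source, e.target, e.sign) for e in model_or_edges.edges]
        else:
            triples = [(s, t, sg) for s, t, sg in model_or_edges]
        write_sif(triples, path)
    elif fmt == "tsv":
        write_edge_table(model_or_edges, path)
    else:
        raise ValidationError(f"unsupported GRN format: {fmt}")


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

#: The six admissible trajectory shape classes: sign string of the slope
#: segments between turning points.
SHAPE_CLASSES = ("+", "-", "+-", "-+", "+-+", "-+-")


def shape_function(label: str):
    """Smooth canonical trajectory for a shape class, amplitude ~1 on [0, 1]."""
    if label == "+":
        return lambda t: t
    if label == "-":
        return lambda t: 1.0 - t
    if label == "+-":
        return lambda t: np.sin(np.pi * t)
    if label == "-+":
        return lambda t: 1.0 - np.sin(np.pi * t)
    if label == "+-+":
        return lambda t: 0.5 + 0.5 * np.sin(2 * np.pi * (t - 0.0)) * np.cos(np.pi * t / 4)
    if label == "-+-":
        return lambda t: 0.5 - 0.5 * np.sin(2 * np.pi * t) * np.cos(np.pi * t / 4)
    raise ValueError(f"unknown shape class {label!r}")


@dataclass
class FixtureTruth:
    """Ground truth recorded alongside a synthetic dataset."""

    tf_shapes: dict            # TF id -> shape label
    tf_targets: dict           # TF id -> list of target gene ids
    gene_shapes: dict          # every gene id -> shape label


def generate_fixture_dataset(config: FixtureConfig | None = None,
                             seed: int = 0) -> tuple:
    """Simulate a gene x cell dataset with known trajectory shapes.

    Each TF is assigned one of the six shape classes; its target group shares
    the shape. Expression is ``base * (0.25 + shape(pt))`` with multiplicative
    Gaussian noise. Returns ``(ExpressionDataset, FixtureTruth)``.
    """
    cfg = config or FixtureConfig()
    if cfg.n_genes <= 0 or cfg.n_cells <= 0 or cfg.n_tfs <= 0:
        raise ValidationError("fixture dimensions must be positive")
    rng = np.random.default_rng(seed)
    pt = np.sort(rng.uniform(0, 1, cfg.n_cells))
    pt[0], pt[-1] = 0.0, 1.0
    tfs = [f"TF{i+1}" for i in range(cfg.n_tfs)]
    others = [f"G{i+1}" for i in range(cfg.n_genes - cfg.n_tfs)]
    genes = tfs + others
    tf_shapes = {tf: SHAPE_CLASSES[i % len(SHAPE_CLASSES)] for i, tf in enumerate(tfs)}
    # partition non-TF genes into target groups, one per TF
    groups = np.array_split(np.array(others), cfg.n_tfs)
    tf_targets = {tf: list(grp) for tf, grp in zip(tfs, groups)}
    gene_shapes = dict(tf_shapes)
    for tf, grp in tf_targets.items():
        for g in grp:
            gene_shapes[g] = tf_shapes[tf]
    values = np.empty((len(genes), cfg.n_cells))
    for i, g in enumerate(genes):
        mean = cfg.base_expression * (0.25 + shape_function(gene_shapes[g])(pt))
        noise = 1.0 + cfg.noise * rng.standard_normal(cfg.n_cells)
        values[i] = np.maximum(mean * noise, 0.0)
    ds = ExpressionDataset(genes=genes, cells=[f"cell{j}" for j in range(cfg.n_cells)],
                           values=values, pseudotime=pt)
    return ds, FixtureTruth(tf_shapes=tf_shapes, tf_targets=tf_targets,
                            gene_shapes=gene_shapes)


def fixture_gene_sets(truth: FixtureTruth, extra_background=()) -> GeneSetCollection:
    """TF target-set collection implied by a fixture's ground truth."""
    background = set(truth.gene_shapes) | set(extra_background)
    return GeneSetCollection(sets={tf: set(t) for tf, t in truth.tf_targets.items()},
                             background=background)
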