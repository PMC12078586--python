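"""Binary GGO (bGGO) wrapper feature selection.

The continuous optimizer searches [0, 1]^D; before every fitness
evaluation an agent's position is pushed through a steep sigmoid
transfer function and thresholded into a 0/1 inclusion mask.  A mask is
scored by the wrapper fitness

    F = alpha * Err + (1 - alpha) * |s| / |S|

where ``Err`` is the leave-out error of a single-nearest-neighbour
classifier restricted to the selected columns, ``|s|`` the number of
selected features and ``|S|`` the total feature count.  Smaller is
better: the fitness trades classification error against subset size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import train_test_split

from .ggo import GGOConfig, OptimizationResult, run_ggo

__all__ = [
    "BinaryMask",
    "FitnessSpec",
    "FeatureTable",
    "SelectionResult",
    "SelectionRunStats",
    "sigmoid_transfer",
    "binarize",
    "subset_fitness",
    "nn_error",
    "prepare_split",
    "select_features",
    "exhaustive_select",
    "aggregate_runs",
    "run_selection_repeats",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class BinaryMask:
    """A 0/1 inclusion vector over feature columns."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("mask bits must be 0 or 1")

    @property
    def selected_count(self) -> int:
        return int(self.bits.sum())

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def __len__(self) -> int:
        return len(self.bits)


@dataclass
class FitnessSpec:
    """Weights of the wrapper fitness; ``beta = 1 - alpha`` exactly."""

    alpha: float = 0.99

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def beta(self) -> float:
        return 1.0 - self.alpha


@dataclass
class FeatureTable:
    """Numeric sample-by-feature matrix with class labels."""

    values: np.ndarray
    labels: np.ndarray
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must match the number of rows")
        if np.isnan(self.values).any():
            raise ValueError("feature table contains missing values")
        if not self.column_names:
            self.column_names = [f"f{i}" for i in range(self.values.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_csv(cls, path, label_column: str = "label") -> "FeatureTable":
        frame = pd.read_csv(path)
        labels = frame.pop(label_column).to_numpy()
        return cls(frame.to_numpy(dtype=float), labels, list(frame.columns))

    def to_csv(self, path, label_column: str = "label") -> None:
        frame = pd.DataFrame(self.values, columns=self.column_names)
        frame[label_column] = self.labels
        frame.to_csv(path, index=False)


@dataclass
class SelectionResult:
    """Best mask found by one selection run."""

    best_mask: BinaryMask
    best_fitness: float
    error_at_best: float
    fitness_trace: np.ndarray
    seed_used: int
    evaluations: int = 0


@dataclass
class SelectionRunStats:
    """Repeated-run summary: average error, average relative subset
    size, and best / worst / mean / sample-SD of the run fitnesses."""

    avg_error: float
    avg_select_size: float
    best_fitness: float
    worst_fitness: float
    mean_fitness: float
    sd_fitness: float
    M: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Avg. Error", self.avg_error),
            ("Avg. Select-Size", self.avg_select_size),
            ("Avg. Fitness", self.mean_fitness),
            ("Best Fitness", self.best_fitness),
            ("Worst Fitness", self.worst_fitness),
            ("Standard deviation-Fitness", self.sd_fitness),
        ]
        return pd.DataFrame(rows, columns=["Metric", "Value"])


# ---------------------------------------------------------------------------
# Transfer function and fitness
# ---------------------------------------------------------------------------

def sigmoid_transfer(m):
    """Steep logistic ``1 / (1 + exp(-10 * (m - 0.5)))``, centred at 0.5."""
    m = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp(-10.0 * (m - 0.5)))
    return float(out) if out.ndim == 0 else out


def binarize(position: np.ndarray) -> BinaryMask:
    """Threshold a continuous position into bits: 1 iff the sigmoid is
    >= 0.5, i.e. iff the component is >= 0.5 (inclusive)."""
    position = np.asarray(position, dtype=float)
    return BinaryMask((sigmoid_transfer(position) >= 0.5).astype(np.int8))


def subset_fitness(mask: BinaryMask, err: float, spec: FitnessSpec) -> float:
    """Wrapper fitness ``alpha*err + (1 - alpha)*|s|/|S|`` (minimize)."""
    if not 0.0 <= err <= 1.0:
        raise ValueError("error rate must lie in [0, 1]")
    return spec.alpha * err + spec.beta * mask.selected_count / len(mask)


def nn_error(mask: BinaryMask, train: FeatureTable, eval: FeatureTable) -> float:
    """Misclassification fraction of the single-nearest-neighbour rule
    on the evaluation rows, with Euclidean distance restricted to the
    selected columns."""
    if train.n_samples == 0:
        raise ValueError("training table is empty")
    if mask.selected_count == 0:
        raise ValueError("mask selects no features")
    cols = mask.selected_indices
    dist = cdist(eval.values[:, cols], train.values[:, cols])
    nearest = np.argmin(dist, axis=1)
    return float(np.mean(train.labels[nearest] != eval.labels))


# ---------------------------------------------------------------------------
# Train/validation split used inside the wrapper
# ---------------------------------------------------------------------------

def prepare_split(
    table: FeatureTable,
    seed: int,
    validation_fraction: float = 0.2,
    standardize: bool = True,
) -> tuple[FeatureTable, FeatureTable]:
    """Seeded stratified split of a feature table into the wrapper's
    training and validation parts, with optional z-scoring by the
    training statistics (constant columns are left unscaled)."""
    if len(np.unique(table.labels)) < 2:
        raise ValueError("feature selection needs at least two classes")
    idx_train, idx_val = train_test_split(
        np.arange(table.n_samples),
        test_size=validation_fraction,
        random_state=seed % (2**31),
        stratify=table.labels,
    )
    x_train = table.values[idx_train]
    x_val = table.values[idx_val]
    if standardize:
        mu = x_train.mean(axis=0)
        sd = x_train.std(axis=0, ddof=0)
        sd[sd == 0.0] = 1.0
        x_train = (x_train - mu) / sd
        x_val = (x_val - mu) / sd
    train = FeatureTable(x_train, table.labels[idx_train], list(table.column_names))
    val = FeatureTable(x_val, table.labels[idx_val], list(table.column_names))
    return train, val


def _mask_objective(train: FeatureTable, val: FeatureTable, spec: FitnessSpec):
    """Build the memoized continuous objective over [0,1]^D.

    An all-zero mask receives the worst possible error (fitness
    ``alpha * 1``) so the search stays total.  Returns the objective and
    the cache mapping mask bytes -> (fitness, error).
    """
    cache: dict[bytes, tuple[float, float]] = {}

    def fitness_of_mask(mask: BinaryMask) -> tuple[float, float]:
        key = mask.bits.tobytes()
        if key not in cache:
            if mask.selected_count == 0:
                cache[key] = (spec.alpha * 1.0, 1.0)
            else:
                err = nn_error(mask, train, val)
                cache[key] = (subset_fitness(mask, err, spec), err)
        return cache[key]

    def objective(position: np.ndarray) -> float:
        return fitness_of_mask(binarize(position))[0]

    return objective, fitness_of_mask, cache


def select_features(
    table: FeatureTable,
    spec: FitnessSpec,
    cfg: GGOConfig,
    split: tuple[FeatureTable, FeatureTable] | None = None,
    standardize: bool = True,
) -> SelectionResult:
    """Run bGGO over the feature columns of ``table``.

    The continuous search space is [0, 1] per feature; every agent is
    binarized before each fitness evaluation.  ``split`` may supply an
    explicit (train, validation) pair; otherwise a stratified 80/20
    split seeded by ``cfg.seed`` is created.
    """
    if table.n_features < 1:
        raise ValueError("table has no feature columns")
    if split is None:
        split = prepare_split(table, cfg.seed, standardize=standardize)
    train, val = split

    import dataclasses as _dc
    cfg = _dc.replace(cfg, bounds=tuple((0.0, 1.0) for _ in range(table.n_features)))

    objective, fitness_of_mask, _ = _mask_objective(train, val, spec)
    result = run_ggo(objective, cfg)
    best_mask = binarize(result.best_position)
    best_fitness, error_at_best = fitness_of_mask(best_mask)
    return SelectionResult(
        best_mask=best_mask,
        best_fitness=best_fitness,
        error_at_best=error_at_best,
        fitness_trace=result.fitness_trace,
        seed_used=cfg.seed,
        evaluations=result.evaluations,
    )


def exhaustive_select(
    split: tuple[FeatureTable, FeatureTable], spec: FitnessSpec
) -> SelectionResult:
    """Brute-force enumeration of all non-empty masks (small D only);
    the global minimum of the wrapper fitness on the given split."""
    train, val = split
    D = train.n_features
    if D > 20:
        raise ValueError("exhaustive enumeration is limited to D <= 20")
    best: tuple[float, float, BinaryMask] | None = None
    for code in range(1, 2**D):
        bits = np.array([(code >> d) & 1 for d in range(D)], dtype=np.int8)
        mask = BinaryMask(bits)
        err = nn_error(mask, train, val)
        fit = subset_fitness(mask, err, spec)
        if best is None or fit < best[0]:
            best = (fit, err, mask)
    assert best is not None
    fit, err, mask = best
    return SelectionResult(
        best_mask=mask,
        best_fitness=fit,
        error_at_best=err,
        fitness_trace=np.array([fit]),
        seed_used=-1,
        evaluations=2**D - 1,
    )


# ---------------------------------------------------------------------------
# Multi-run statistics
# ---------------------------------------------------------------------------

def aggregate_runs(results: Sequence[SelectionResult], D: int) -> SelectionRunStats:
    """Summary statistics over M repeated selection runs (sample SD
    with M - 1 denominator)."""
    M = len(results)
    if M < 2:
        raise ValueError("need at least 2 runs: the sample SD denominator is M - 1")
    fitnesses = np.array([r.best_fitness for r in results])
    return SelectionRunStats(
        avg_error=float(np.mean([r.error_at_best for r in results])),
        avg_select_size=float(np.mean([r.best_mask.selected_count / D for r in results])),
        best_fitness=float(fitnesses.min()),
        worst_fitness=float(fitnesses.max()),
        mean_fitness=float(fitnesses.mean()),
        sd_fitness=float(fitnesses.std(ddof=1)),
        M=M,
    )


def run_selection_repeats(
    table: FeatureTable,
    spec: FitnessSpec,
    cfg: GGOConfig,
    repeats: int = 10,
) -> tuple[list[SelectionResult], SelectionRunStats]:
    """Repeat selection with seeds ``cfg.seed + k`` and aggregate."""
    import dataclasses as _dc
    results = [
        select_features(table, spec, _dc.replace(cfg, seed=cfg.seed + k))
        for k in range(repeats)
    ]
    return results, aggregate_runs(results, table.n_features)
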