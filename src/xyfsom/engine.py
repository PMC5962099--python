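"""Supervised self-organizing map (xyf-SOM) training and prediction.

Each map node carries a concatenated codebook: an X part in standardized
catch-rate space and a Y part in class-indicator space. During training the
winning node for a presented trip is the argmin of the combined distance

    D(o, u) = alpha_xy * Dx(o, u) + (1 - alpha_xy) * Dy(o, u)

where Dx is squared Euclidean distance in X space, Dy is the Tanimoto
(binarized-disagreement) distance in Y space, and both are rescaled so that
their maximum over the current node set is 1. The winner and all nodes
within the current neighborhood radius are pulled toward the presented
object by the current learning rate; both the learning rate and the radius
shrink over the preset number of passes through the data. At prediction
time only the X layer is compared, and the predicted class is the argmax of
the winner's Y codebook.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import GridSpec
from .logbook import (
    ClassEncoding,
    TripTable,
    destandardize_columns,
    encode_classes,
    labels_for_table,
    standardize_columns,
)

__all__ = [
    "CodebookSet",
    "TrainingParams",
    "TrainedMap",
    "tanimoto_distance",
    "combined_distance",
    "init_codebooks",
    "find_winner",
    "update_codebooks",
    "train_som",
    "fit",
    "predict",
    "confusion_matrix",
    "bootstrap_prediction_ci",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class CodebookSet:
    """Per-node X-layer and Y-layer codebook (weight) matrices.

    Node ordering is shared between layers: row ``i`` of both matrices
    belongs to grid node ``i``.
    """

    x_weights: np.ndarray  # (n_nodes, n_species), standardized units
    y_weights: np.ndarray  # (n_nodes, n_classes), each entry in [0, 1]

    def __post_init__(self) -> None:
        self.x_weights = np.asarray(self.x_weights, dtype=float)
        self.y_weights = np.asarray(self.y_weights, dtype=float)
        if self.x_weights.ndim != 2 or self.y_weights.ndim != 2:
            raise ValueError("codebook matrices must be 2-D")
        if self.x_weights.shape[0] != self.y_weights.shape[0]:
            raise ValueError(
                f"x and y layers disagree on node count: "
                f"{self.x_weights.shape[0]} vs {self.y_weights.shape[0]}"
            )
        if np.any(self.y_weights < -1e-12) or np.any(self.y_weights > 1 + 1e-12):
            raise ValueError("y_weights entries must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.x_weights.shape[0]

    def copy(self) -> "CodebookSet":
        return CodebookSet(self.x_weights.copy(), self.y_weights.copy())


@dataclass(frozen=True)
class TrainingParams:
    """Knobs of the training schedule.

    ``rlen`` counts full passes through the data; the learning rate decays
    linearly from ``lr_start`` to ``lr_end`` over all presentations.
    ``alpha_xy`` is the X-vs-Y weight of the combined distance (0.5 means
    equal weight; 1 ignores the class layer). ``radius_start`` defaults to
    the 2/3 quantile of inter-node grid distances when left as None.
    """

    rlen: int = 1000
    lr_start: float = 0.05
    lr_end: float = 0.01
    alpha_xy: float = 0.5
    radius_start: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rlen < 1:
            raise ValueError("rlen must be >= 1")
        if not (self.lr_start >= self.lr_end > 0):
            raise ValueError("need lr_start >= lr_end > 0")
        if not (0.0 <= self.alpha_xy <= 1.0):
            raise ValueError("alpha_xy must lie in [0, 1]")
        if self.radius_start is not None and self.radius_start < 0:
            raise ValueError("radius_start must be >= 0")


@dataclass
class TrainedMap:
    """Everything downstream analyses need: codebooks, grid, scaling, labels."""

    grid: GridSpec
    codebooks: CodebookSet
    column_means: np.ndarray
    column_sds: np.ndarray
    species_names: tuple[str, ...]
    class_labels: tuple[str, ...]
    factors: tuple[str, ...]
    params: TrainingParams
    quantization_error: float

    def __post_init__(self) -> None:
        self.column_means = np.asarray(self.column_means, dtype=float)
        self.column_sds = np.asarray(self.column_sds, dtype=float)
        k = len(self.species_names)
        if self.column_means.shape != (k,) or self.column_sds.shape != (k,):
            raise ValueError("column scaling vectors must have length = species count")
        if self.quantization_error < 0:
            raise ValueError("quantization_error must be >= 0")

    def x_weights_kg(self) -> np.ndarray:
        """X-layer codebooks de-standardized back to kg/trip units."""
        return destandardize_columns(
            self.codebooks.x_weights, self.column_means, self.column_sds
        )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def tanimoto_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of positions whose values, binarized at 0.5, disagree.

    Well defined for continuous codebook Y rows and reduces to plain
    agreement/disagreement for one-hot class vectors.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a > 0.5) != (b > 0.5)))


def _tanimoto_to_nodes(y_nodes: np.ndarray, y_obj: np.ndarray) -> np.ndarray:
    """Vectorized Tanimoto distance of one object to every node's Y row."""
    return ((y_nodes > 0.5) != (y_obj > 0.5)).mean(axis=1)


def combined_distance(dx: float, dy: float, alpha_xy: float) -> float:
    """Weighted sum of the (already max-rescaled) X and Y distances."""
    if not (0.0 <= alpha_xy <= 1.0):
        raise ValueError("alpha_xy must lie in [0, 1]")
    return alpha_xy * dx + (1.0 - alpha_xy) * dy


def _combined_to_nodes(
    codebooks: CodebookSet, x_obj: np.ndarray, y_obj: np.ndarray | None, alpha_xy: float
) -> np.ndarray:
    """Combined distance of one object to every node (vectorized).

    X distances are squared Euclidean; each layer is rescaled by its maximum
    over the node set (a zero maximum leaves that layer at zero). With
    ``y_obj`` None (prediction mode) only the X layer is used.
    """
    diff = codebooks.x_weights - x_obj
    dx = np.einsum("ij,ij->i", diff, diff)
    mx = dx.max()
    if mx > 0:
        dx = dx / mx
    if y_obj is None:
        return dx
    dy = _tanimoto_to_nodes(codebooks.y_weights, y_obj)
    my = dy.max()
    if my > 0:
        dy = dy / my
    return alpha_xy * dx + (1.0 - alpha_xy) * dy


def find_winner(
    x_obj: np.ndarray,
    y_obj: np.ndarray | None,
    codebooks: CodebookSet,
    alpha_xy: float,
) -> int:
    """Index of the best-matching node; ties go to the lowest node index."""
    x_obj = np.asarray(x_obj, dtype=float)
    if x_obj.shape != (codebooks.x_weights.shape[1],):
        raise ValueError(
            f"object has {x_obj.shape} features, codebooks expect "
            f"({codebooks.x_weights.shape[1]},)"
        )
    if y_obj is not None:
        y_obj = np.asarray(y_obj, dtype=float)
        if y_obj.shape != (codebooks.y_weights.shape[1],):
            raise ValueError(
                f"class vector has shape {y_obj.shape}, codebooks expect "
                f"({codebooks.y_weights.shape[1]},)"
            )
    if not (0.0 <= alpha_xy <= 1.0):
        raise ValueError("alpha_xy must lie in [0, 1]")
    return int(np.argmin(_combined_to_nodes(codebooks, x_obj, y_obj, alpha_xy)))


# ---------------------------------------------------------------------------
# Initialization and updates
# ---------------------------------------------------------------------------

def init_codebooks(
    X: np.ndarray, Y: np.ndarray, grid: GridSpec, seed: int | np.random.Generator
) -> CodebookSet:
    """Prototype pattern: assign randomly chosen training rows to the nodes.

    Sampling is without replacement when there are at least as many training
    rows as nodes, with replacement otherwise.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.size == 0:
        raise ValueError("empty training matrix")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = X.shape[0]
    idx = rng.choice(n, size=grid.n_nodes, replace=n < grid.n_nodes)
    return CodebookSet(X[idx].copy(), Y[idx].copy())


def update_codebooks(
    codebooks: CodebookSet,
    winner: int,
    x_obj: np.ndarray,
    y_obj: np.ndarray,
    lr: float,
    radius: float,
    node_distances: np.ndarray,
    neighborhood: str = "bubble",
) -> None:
    """Pull the winner and its grid neighborhood toward the object, in place.

    Bubble kernel: every node within ``radius`` grid units of the winner
    moves by ``lr * (obj - w)``. Gaussian kernel: all nodes move, damped by
    ``exp(-d^2 / (2 r^2))``. Updates are convex combinations, so Y-layer
    entries stay inside [0, 1].
    """
    if not (0.0 < lr <= 1.0):
        raise ValueError("learning rate must lie in (0, 1]")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    d = node_distances[winner]
    if neighborhood == "bubble":
        mask = d <= radius
        codebooks.x_weights[mask] += lr * (x_obj - codebooks.x_weights[mask])
        codebooks.y_weights[mask] += lr * (y_obj - codebooks.y_weights[mask])
    elif neighborhood == "gaussian":
        r = max(radius, 1e-12)
        h = (lr * np.exp(-(d**2) / (2.0 * r**2)))[:, None]
        codebooks.x_weights += h * (x_obj - codebooks.x_weights)
        codebooks.y_weights += h * (y_obj - codebooks.y_weights)
    else:  # pragma: no cover - guarded by GridSpec
        raise ValueError(f"unknown neighborhood {neighborhood!r}")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _schedules(
    params: TrainingParams, grid: GridSpec, n_objects: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-presentation learning rates and neighborhood radii.

    The learning rate interpolates linearly from ``lr_start`` to ``lr_end``
    over all presentations. The radius interpolates from ``radius_start``
    down to 1 over the first 2/3 of presentations, then stays at 0
    (winner-only updates) for the remainder.
    """
    total = params.rlen * n_objects
    t = np.arange(total)
    denom = max(total - 1, 1)
    lrs = params.lr_start + (params.lr_end - params.lr_start) * t / denom
    r0 = params.radius_start if params.radius_start is not None else grid.default_radius()
    shrink = (2 * total) // 3
    radii = np.zeros(total)
    if shrink > 0:
        s = np.arange(shrink) / max(shrink - 1, 1)
        radii[:shrink] = r0 + (1.0 - r0) * s
    return lrs, radii


def train_som(
    X: np.ndarray, Y: np.ndarray, grid: GridSpec, params: TrainingParams
) -> tuple[CodebookSet, float]:
    """Train the supervised map; returns (codebooks, quantization error).

    ``X`` must already be standardized and ``Y`` one-hot. Objects are
    presented one at a time in a freshly shuffled order each pass, using the
    seeded generator, so training is bit-reproducible for a fixed seed. The
    quantization error is the mean X-layer Euclidean distance of each
    training object to its final winning node (winner search in training
    mode, i.e. including the class layer).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching row counts")
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(Y)):
        raise ValueError("NaN or infinite values in training inputs")
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty training matrix")

    rng = np.random.default_rng(params.seed)
    codebooks = init_codebooks(X, Y, grid, rng)
    node_d = grid.node_distances()
    lrs, radii = _schedules(params, grid, n)
    alpha = params.alpha_xy
    kernel = grid.neighborhood

    step = 0
    for _ in range(params.rlen):
        order = rng.permutation(n)
        for i in order:
            w = int(np.argmin(_combined_to_nodes(codebooks, X[i], Y[i], alpha)))
            update_codebooks(
                codebooks, w, X[i], Y[i], lrs[step], radii[step], node_d, kernel
            )
            step += 1

    qe = quantization_error(codebooks, X, Y, alpha)
    return codebooks, qe


def quantization_error(
    codebooks: CodebookSet, X: np.ndarray, Y: np.ndarray | None, alpha_xy: float
) -> float:
    """Mean X-layer Euclidean distance of objects to their winning nodes."""
    total = 0.0
    for i in range(X.shape[0]):
        y = Y[i] if Y is not None else None
        w = int(np.argmin(_combined_to_nodes(codebooks, X[i], y, alpha_xy)))
        total += float(np.linalg.norm(X[i] - codebooks.x_weights[w]))
    return total / X.shape[0]


def fit(
    table: TripTable,
    grid: GridSpec,
    params: TrainingParams = TrainingParams(),
    factors: Sequence[str] = ("gear", "season", "year"),
) -> TrainedMap:
    """Standardize, encode classes, train, and package a :class:`TrainedMap`."""
    Z, means, sds = standardize_columns(table)
    enc = encode_classes(table, factors)
    codebooks, qe = train_som(Z, enc.indicator, grid, params)
    return TrainedMap(
        grid=grid,
        codebooks=codebooks,
        column_means=means,
        column_sds=sds,
        species_names=table.species_names,
        class_labels=enc.class_labels,
        factors=enc.factors,
        params=params,
        quantization_error=qe,
    )


# ---------------------------------------------------------------------------
# Prediction and evaluation
# ---------------------------------------------------------------------------

def _align_species(map_: TrainedMap, table: TripTable) -> np.ndarray:
    """Catch matrix of ``table`` reordered to the map's species columns."""
    if table.species_names == map_.species_names:
        return table.catch
    missing = sorted(set(map_.species_names) - set(table.species_names))
    extra = sorted(set(table.species_names) - set(map_.species_names))
    if missing or extra:
        raise ValueError(
            f"species columns do not match the trained map: missing {missing}, extra {extra}"
        )
    order = [table.species_names.index(s) for s in map_.species_names]
    return table.catch[:, order]


def predict(map_: TrainedMap, table: TripTable) -> np.ndarray:
    """Predicted class label per trip.

    New trips are standardized with the stored column means/SDs, matched to
    their winning node by X-layer distance only, and assigned the argmax
    class of that node's Y codebook (ties to the lowest class index).
    """
    catch = _align_species(map_, table)
    Z = (catch - map_.column_means) / map_.column_sds
    labels = np.empty(table.n_trips, dtype=object)
    xw = map_.codebooks.x_weights
    yw = map_.codebooks.y_weights
    for i in range(table.n_trips):
        diff = xw - Z[i]
        w = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
        labels[i] = map_.class_labels[int(np.argmax(yw[w]))]
    return labels


def winner_distances(map_: TrainedMap, table: TripTable) -> np.ndarray:
    """X-layer Euclidean distance of each trip to its winning node."""
    catch = _align_species(map_, table)
    Z = (catch - map_.column_means) / map_.column_sds
    xw = map_.codebooks.x_weights
    out = np.empty(table.n_trips)
    for i in range(table.n_trips):
        diff = xw - Z[i]
        d2 = np.einsum("ij,ij->i", diff, diff)
        out[i] = np.sqrt(d2.min())
    return out


def true_labels(map_: TrainedMap, table: TripTable) -> np.ndarray:
    """Observed class label per trip under the map's factor set."""
    return labels_for_table(table, map_.factors, map_.class_labels)


def confusion_matrix(
    true: Sequence[str], predicted: Sequence[str], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Row-percentage confusion matrix: cell (i, j) is the percent of
    class-i objects predicted as class j; each row sums to 100."""
    true = np.asarray(true, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if len(true) == 0:
        raise ValueError("empty label sequences")
    if len(true) != len(predicted):
        raise ValueError("label sequences differ in length")
    if labels is None:
        labels = sorted(set(true) | set(predicted))
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)))
    for t, p in zip(true, predicted):
        counts[index[t], index[p]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        pct = 100.0 * counts / row_sums
    out = pd.DataFrame(pct, index=labels, columns=labels)
    return out.loc[row_sums[:, 0] > 0]  # drop classes never observed as true


@dataclass
class BootstrapCI:
    """Per-class bootstrap summary of correct-classification percentages."""

    table: pd.DataFrame  # index: class labels + "overall"; columns: mean/lower/upper/missing
    level: float
    n_boot: int
    replicates: pd.DataFrame | None = None


def bootstrap_prediction_ci(
    map_: TrainedMap,
    table: TripTable,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    keep_replicates: bool = False,
) -> BootstrapCI:
    """Bootstrap the hold-out set to get per-class prediction-power CIs.

    The hold-out trips are resampled with replacement ``n_boot`` times; each
    replicate records the percent correctly classified per class (and
    overall). Returned are the replicate mean and the percentile interval at
    ``level``. Classes absent from the hold-out set are reported as missing,
    not as zero; classes absent from an individual replicate simply do not
    contribute to that replicate's summary.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    truth = true_labels(map_, table)
    pred = predict(map_, table)
    correct = (truth == pred).astype(float)
    classes = list(map_.class_labels)
    class_idx = {c: i for i, c in enumerate(classes)}
    truth_codes = np.array([class_idx[t] for t in truth])

    rng = np.random.default_rng(seed)
    n = table.n_trips
    per_class = np.full((n_boot, len(classes)), np.nan)
    overall = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        c = correct[idx]
        g = truth_codes[idx]
        overall[b] = 100.0 * c.mean()
        for k in np.unique(g):
            per_class[b, k] = 100.0 * c[g == k].mean()

    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = {}
    present = set(truth_codes.tolist())
    for k, lab in enumerate(classes):
        if k not in present:
            rows[lab] = (np.nan, np.nan, np.nan, True)
            continue
        vals = per_class[:, k]
        rows[lab] = (
            float(np.nanmean(vals)),
            float(np.nanpercentile(vals, 100 * lo_q)),
            float(np.nanpercentile(vals, 100 * hi_q)),
            False,
        )
    rows["overall"] = (
        float(overall.mean()),
        float(np.percentile(overall, 100 * lo_q)),
        float(np.percentile(overall, 100 * hi_q)),
        False,
    )
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean", "lower", "upper", "missing"]
    )
    reps = None
    if keep_replicates:
        reps = pd.DataFrame(per_class, columns=classes)
        reps["overall"] = overall
    return BootstrapCI(table=out, level=level, n_boot=n_boot, replicates=reps)
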