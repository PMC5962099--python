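"""Grid-size selection for the supervised map.

Map capacity scales with node count: prediction power rises and mean
object-to-prototype distance falls, both approximately as power laws of the
number of nodes. This module provides the 5*sqrt(n) starting heuristic,
near-square shape proposals, a hold-out size scan, and log-log power-law
fits of both curves; the selected shape is the one with maximum hold-out
prediction percentage (ties to fewer nodes).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import TrainingParams, fit, predict, true_labels, winner_distances
from .grid import GridSpec
from .logbook import TripTable, encode_classes

logger = logging.getLogger(__name__)


def heuristic_node_count(n_samples: int) -> int:
    """Starting node count c = 5 * sqrt(n), rounded half away from zero."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return int(math.floor(5.0 * math.sqrt(n_samples) + 0.5))


def _best_factor_pair(m: int) -> tuple[int, int]:
    """Factor pair (rows, cols), rows <= cols, minimizing cols - rows."""
    r = int(math.isqrt(m))
    while m % r != 0:
        r -= 1
    return r, m // r


def propose_grid_shapes(n_nodes_targets: Sequence[int]) -> list[tuple[int, int]]:
    """Near-square (rows, cols) for each target node count.

    A shape qualifies as near-square when cols <= 2 * rows; awkward targets
    (primes and skinny composites) are rounded up to the nearest node count
    admitting such a pair, so e.g. 7 becomes (2, 4).
    """
    shapes = []
    for target in n_nodes_targets:
        if target < 1:
            raise ValueError("node-count targets must be >= 1")
        m = target
        while True:
            r, c = _best_factor_pair(m)
            if c <= 2 * r:
                shapes.append((r, c))
                break
            m += 1
    return shapes


@dataclass
class PowerLawFit:
    """y = a * x^b fitted by OLS on (log10 x, log10 y)."""

    a: float
    b: float
    r_squared: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(x, dtype=float) ** self.b


def fit_power_law(x: Sequence[float], y: Sequence[float]) -> PowerLawFit:
    """Fit y = a*x^b by ordinary least squares on the log10 scale.

    Degenerate constant-y inputs give b = 0 and r_squared reported as 0
    (with a warning), since the fraction of explained variance is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("power-law fit needs at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive x and y")
    lx, ly = np.log10(x), np.log10(y)
    if np.allclose(ly, ly[0]):
        warnings.warn("constant y: power-law exponent set to 0, r^2 undefined (reported as 0)")
        return PowerLawFit(a=float(y[0]), b=0.0, r_squared=0.0)
    res = stats.linregress(lx, ly)
    return PowerLawFit(
        a=float(10.0**res.intercept), b=float(res.slope), r_squared=float(res.rvalue**2)
    )


@dataclass
class SizeScanResult:
    """Outcome of a map-size scan.

    ``records`` columns: n_rows, n_cols, n_nodes, prediction_percent,
    mean_object_distance. ``selected`` attains the maximum recorded
    prediction percentage.
    """

    records: pd.DataFrame
    prediction_fit: PowerLawFit
    distance_fit: PowerLawFit
    selected: tuple[int, int]
    train_index: np.ndarray
    test_index: np.ndarray


def stratified_split(
    table: TripTable,
    factors: Sequence[str],
    train_frac: float = 2.0 / 3.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Single stratified random hold-out split by class label.

    Within each class, a seeded shuffle sends the first ``ceil(frac * n)``
    trips to the training set; singleton classes go entirely to training.
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie in (0, 1)")
    enc = encode_classes(table, factors)
    labels = enc.indicator.argmax(axis=1)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for k in range(enc.n_classes):
        members = np.flatnonzero(labels == k)
        members = members[rng.permutation(len(members))]
        n_train = int(math.ceil(train_frac * len(members)))
        if n_train == len(members) and len(members) > 1:
            n_train = len(members) - 1  # keep at least one hold-out trip per class
        train_idx.extend(members[:n_train])
        test_idx.extend(members[n_train:])
    if not test_idx:
        raise ValueError("hold-out set is empty; use more trips or a smaller train_frac")
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def default_size_targets(n_samples: int, n_points: int = 10) -> list[int]:
    """Geometric sequence of node counts from 4 up to 4x the 5*sqrt(n) rule."""
    top = max(8, 4 * heuristic_node_count(n_samples))
    seq = np.unique(np.geomspace(4, top, n_points).round().astype(int))
    return [int(v) for v in seq]


def scan_sizes(
    table: TripTable,
    shapes: Sequence[tuple[int, int]],
    params: TrainingParams = TrainingParams(),
    seed: int = 0,
    factors: Sequence[str] = ("gear", "season", "year"),
    train_frac: float = 2.0 / 3.0,
    distance: str = "quantization",
) -> SizeScanResult:
    """Train one map per shape on a shared split and score the hold-out set.

    Every shape sees the identical stratified train/hold-out split (shared
    seed), is trained with ``params`` (seed offset by the shape index so
    maps are independent draws), and is scored by overall hold-out
    prediction percentage plus either mean object-to-winner X distance
    (``distance="quantization"``) or the fraction of hold-out objects whose
    two best nodes are not grid-adjacent (``distance="topographic"``).
    """
    if len(shapes) < 2:
        raise ValueError("scan needs at least 2 shapes")
    if distance not in ("quantization", "topographic"):
        raise ValueError("distance must be 'quantization' or 'topographic'")
    train_idx, test_idx = stratified_split(table, factors, train_frac, seed)
    train_tab = table.subset(train_idx)
    test_tab = table.subset(test_idx)

    rows = []
    for s, (n_rows, n_cols) in enumerate(shapes):
        grid = GridSpec(n_rows, n_cols)
        if grid.n_nodes > train_tab.n_trips:
            logger.info(
                "shape %dx%d has more nodes (%d) than training trips (%d); "
                "initialization samples with replacement",
                n_rows, n_cols, grid.n_nodes, train_tab.n_trips,
            )
        p = TrainingParams(
            rlen=params.rlen,
            lr_start=params.lr_start,
            lr_end=params.lr_end,
            alpha_xy=params.alpha_xy,
            radius_start=params.radius_start,
            seed=params.seed + s,
        )
        m = fit(train_tab, grid, p, factors)
        truth = true_labels(m, test_tab)
        pred = predict(m, test_tab)
        pct = 100.0 * float(np.mean(truth == pred))
        if distance == "quantization":
            dist = float(winner_distances(m, test_tab).mean())
        else:
            dist = _topographic_error(m, test_tab)
        rows.append((n_rows, n_cols, grid.n_nodes, pct, dist))

    records = pd.DataFrame(
        rows, columns=["n_rows", "n_cols", "n_nodes", "prediction_percent", "mean_object_distance"]
    )

    prediction_fit = _safe_power_law(records["n_nodes"], records["prediction_percent"])
    distance_fit = _safe_power_law(records["n_nodes"], records["mean_object_distance"])

    best = records.sort_values(
        ["prediction_percent", "n_nodes"], ascending=[False, True], kind="stable"
    ).iloc[0]
    selected = (int(best["n_rows"]), int(best["n_cols"]))
    return SizeScanResult(
        records=records,
        prediction_fit=prediction_fit,
        distance_fit=distance_fit,
        selected=selected,
        train_index=train_idx,
        test_index=test_idx,
    )


def _safe_power_law(x: pd.Series, y: pd.Series) -> PowerLawFit:
    """Power-law fit dropping non-positive points (logged), if any.

    A two-point scan determines the power law exactly; the fit is then the
    interpolant (r^2 reported as 1).
    """
    keep = (x > 0) & (y > 0)
    if keep.sum() < len(x):
        logger.warning("dropping %d non-positive point(s) from power-law fit", len(x) - keep.sum())
    xv, yv = x[keep].to_numpy(dtype=float), y[keep].to_numpy(dtype=float)
    if len(xv) == 2 and xv[0] != xv[1]:
        b = (np.log10(yv[1]) - np.log10(yv[0])) / (np.log10(xv[1]) - np.log10(xv[0]))
        a = yv[0] / xv[0] ** b
        return PowerLawFit(a=float(a), b=float(b), r_squared=1.0)
    return fit_power_law(xv, yv)


def _topographic_error(m, test_tab) -> float:
    """Fraction of objects whose two nearest nodes are not grid-adjacent
    (adjacency includes diagonals: grid distance <= sqrt(2))."""
    from .engine import _align_species  # local import to avoid cycle at module load

    catch = _align_species(m, test_tab)
    Z = (catch - m.column_means) / m.column_sds
    xw = m.codebooks.x_weights
    node_d = m.grid.node_distances()
    bad = 0
    for i in range(test_tab.n_trips):
        diff = xw - Z[i]
        d2 = np.einsum("ij,ij->i", diff, diff)
        order = np.argsort(d2, kind="stable")
        if node_d[order[0], order[1]] > math.sqrt(2) + 1e-9:
            bad += 1
    return bad / test_tab.n_trips
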