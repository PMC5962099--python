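"""Downstream fleet analyses on trained-map codebook weights.

Following the workflow this package implements, catch-rate statistics are
computed on the map's node weights (each node is a prototype fishing trip),
not on raw trips: nodes are grouped by the argmax class of their Y codebook,
the X codebooks are de-standardized back to kg/trip, and groups are then
summarized, tested (Kruskal-Wallis with Bonferroni-corrected rank-sum post
hocs) and visualized as shared-bandwidth density shapes (beanplot-style).
A ``source="trips"`` escape hatch computes the same statistics on raw trip
rows for comparison. Species affinities are explored by Ward clustering of
the species columns of the X codebooks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .bandwidth import sheather_jones_bandwidth
from .engine import TrainedMap
from .logbook import TripTable

__all__ = [
    "GroupedWeights",
    "assign_node_groups",
    "SpeciesDendrogram",
    "cluster_species",
    "group_catch_stats",
    "GroupTestResult",
    "kruskal_wallis",
    "DensityCurve",
    "shared_bandwidth_density",
]


@dataclass
class GroupedWeights:
    """Node-level weights in kg/trip with one class label per node."""

    labels: np.ndarray  # (n_nodes,) class label strings
    weights_kg: pd.DataFrame  # nodes x species, kg/trip
    factors: tuple[str, ...]

    def factor_frame(self) -> pd.DataFrame:
        """Per-node factor columns split out of the combined labels."""
        parts = [lab.split("|") for lab in self.labels]
        return pd.DataFrame(parts, columns=list(self.factors))


def assign_node_groups(map_: TrainedMap) -> GroupedWeights:
    """Label each node by the argmax of its Y codebook row (ties to the
    lowest class index) and de-standardize its X codebook to kg/trip."""
    yw = map_.codebooks.y_weights
    if yw.size == 0:
        raise ValueError("untrained map: empty codebooks")
    idx = yw.argmax(axis=1)
    labels = np.array([map_.class_labels[i] for i in idx], dtype=object)
    weights = pd.DataFrame(map_.x_weights_kg(), columns=list(map_.species_names))
    return GroupedWeights(labels=labels, weights_kg=weights, factors=map_.factors)


@dataclass
class SpeciesDendrogram:
    """Ward-linkage dendrogram over species.

    ``linkage`` is a scipy linkage matrix; merge heights are non-decreasing
    (Ward linkage is monotone). ``merge_table`` lists one row per merge.
    """

    linkage: np.ndarray
    labels: tuple[str, ...]

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["left", "right", "height", "n_members"]
        ).astype({"left": int, "right": int, "n_members": int})

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.left), walk(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return walk(tree) + ";"


def cluster_species(map_: TrainedMap) -> SpeciesDendrogram:
    """Agglomerative Ward clustering of species by their per-node weights.

    Each species is represented by its column of the X-layer codebooks (its
    profile over map nodes, in standardized units); Euclidean distance with
    Ward's minimum-variance linkage.
    """
    xw = map_.codebooks.x_weights
    if xw.shape[1] < 2:
        raise ValueError("nothing to cluster: need at least 2 species")
    Z = hierarchy.linkage(xw.T, method="ward")
    return SpeciesDendrogram(linkage=Z, labels=tuple(map_.species_names))


def _grouped_values(
    grouped: GroupedWeights | TripTable,
    species: str | None,
    group_by: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long frame with columns (group, value) for the requested quantity."""
    if isinstance(grouped, GroupedWeights):
        df = grouped.weights_kg
        factor_cols = grouped.factor_frame()
        factors = list(grouped.factors)
    else:  # raw trips
        df = pd.DataFrame(grouped.catch, columns=list(grouped.species_names))
        factor_cols = pd.DataFrame(
            {"gear": grouped.gear, "season": grouped.season, "year": grouped.year.astype(str)}
        )
        factors = ["gear", "season", "year"]
    if species is None or species == "total":
        values = df.sum(axis=1)
    else:
        if species not in df.columns:
            raise KeyError(f"unknown species {species!r}")
        values = df[species]
    keys = list(group_by) if group_by is not None else factors
    bad = [k for k in keys if k not in factor_cols.columns]
    if bad:
        raise ValueError(f"unknown grouping factor(s) {bad}")
    group = factor_cols[keys].astype(str).agg("|".join, axis=1)
    return pd.DataFrame({"group": group.to_numpy(), "value": values.to_numpy()})


def group_catch_stats(
    grouped: GroupedWeights | TripTable,
    species: str | None = None,
    group_by: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean +/- sample SD of catch rate (kg/trip) per group.

    ``species=None`` (or ``"total"``) sums over species per node before
    averaging. Pass a :class:`TripTable` to compute the same statistics on
    raw trips instead of node weights. Single-member groups report SD 0
    with ``sd_defined=False``.
    """
    long = _grouped_values(grouped, species, group_by)
    rows = []
    for g, sub in long.groupby("group", sort=True):
        v = sub["value"].to_numpy()
        sd_def = len(v) > 1
        rows.append(
            {
                "group": g,
                "n": len(v),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if sd_def else 0.0,
                "sd_defined": sd_def,
            }
        )
    return pd.DataFrame(rows).set_index("group")


@dataclass
class GroupTestResult:
    """Kruskal-Wallis H and p plus Bonferroni-adjusted pairwise p-values."""

    H: float
    p: float
    pairwise: pd.DataFrame
    group_names: tuple[str, ...]


def kruskal_wallis(
    groups: Sequence[Sequence[float]], names: Sequence[str] | None = None
) -> GroupTestResult:
    """Kruskal-Wallis rank test with Bonferroni-corrected post hoc pairs.

    H uses the midrank tie correction; p comes from the chi-square
    distribution with (number of groups - 1) degrees of freedom. Post hoc
    comparisons are two-sided Wilcoxon rank-sum tests per pair, with raw
    p-values multiplied by the number of pairs and capped at 1. All-equal
    data across every group yields H = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group needs at least 1 value")
    if names is None:
        names = tuple(f"group{i}" for i in range(len(arrays)))
    names = tuple(names)

    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*arrays)
        H, p = float(H), float(p)

    k = len(arrays)
    n_comp = k * (k - 1) // 2
    pw = pd.DataFrame(np.full((k, k), np.nan), index=names, columns=names)
    for i, j in combinations(range(k), 2):
        both = np.concatenate([arrays[i], arrays[j]])
        if np.all(both == both[0]):
            raw = 1.0
        else:
            raw = float(stats.ranksums(arrays[i], arrays[j]).pvalue)
        adj = min(1.0, raw * n_comp)
        pw.iloc[i, j] = pw.iloc[j, i] = adj
    return GroupTestResult(H=H, p=p, pairwise=pw, group_names=names)


@dataclass
class DensityCurve:
    """Gaussian-kernel density of one group on a shared grid/bandwidth."""

    group: str
    grid_points: np.ndarray
    density: np.ndarray
    bandwidth: float


def shared_bandwidth_density(
    groups: Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
    gridsize: int = 256,
) -> list[DensityCurve]:
    """Beanplot-style densities: one Sheather-Jones bandwidth for all groups.

    The bandwidth is computed once on the pooled values (Silverman fallback
    when the SJ root cannot be bracketed, logged), then each group's
    Gaussian-kernel density is evaluated on a common grid spanning the
    pooled range +/- 3 bandwidths, so group shapes are directly comparable.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if names is None:
        names = tuple(f"group{i}" for i in range(len(arrays)))
    pooled = np.concatenate(arrays) if arrays else np.array([])
    if len(pooled) < 3:
        raise ValueError("need at least 3 pooled values")
    if np.all(pooled == pooled[0]):
        raise ValueError("zero-variance pooled data")
    h = sheather_jones_bandwidth(pooled)
    grid = np.linspace(pooled.min() - 3 * h, pooled.max() + 3 * h, gridsize)
    curves = []
    for name, arr in zip(names, arrays):
        if len(arr) == 0:
            continue
        z = (grid[:, None] - arr[None, :]) / h
        dens = np.exp(-0.5 * z * z).sum(axis=1) / (len(arr) * h * np.sqrt(2 * np.pi))
        curves.append(DensityCurve(group=str(name), grid_points=grid, density=dens, bandwidth=h))
    return curves
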