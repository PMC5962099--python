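"""Rectangular SOM grid geometry.

Nodes live on an ``n_rows x n_cols`` rectangular lattice; node ``i`` sits at
integer coordinates ``(i // n_cols, i % n_cols)`` (row-major order) and
inter-node distance is plain Euclidean distance on those coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

TOPOLOGIES = ("rectangular",)
NEIGHBORHOODS = ("bubble", "gaussian")


@dataclass(frozen=True)
class GridSpec:
    """Shape and neighborhood kernel of a SOM lattice."""

    n_rows: int
    n_cols: int
    topology: str = "rectangular"
    neighborhood: str = "bubble"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(f"grid must be at least 1x1, got {self.n_rows}x{self.n_cols}")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}; choose from {TOPOLOGIES}")
        if self.neighborhood not in NEIGHBORHOODS:
            raise ValueError(
                f"unknown neighborhood {self.neighborhood!r}; choose from {NEIGHBORHOODS}"
            )

    @property
    def n_nodes(self) -> int:
        return self.n_rows * self.n_cols

    def coordinates(self) -> np.ndarray:
        """(n_nodes, 2) array of (row, col) integer coordinates, row-major."""
        rows, cols = np.divmod(np.arange(self.n_nodes), self.n_cols)
        return np.column_stack([rows, cols]).astype(float)

    def node_distances(self) -> np.ndarray:
        """(n_nodes, n_nodes) Euclidean distances between node coordinates."""
        coords = self.coordinates()
        if self.n_nodes == 1:
            return np.zeros((1, 1))
        return squareform(pdist(coords))

    def default_radius(self) -> float:
        """Starting neighborhood radius: 2/3 quantile of inter-node distances."""
        if self.n_nodes == 1:
            return 0.0
        return float(np.quantile(pdist(self.coordinates()), 2.0 / 3.0))
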