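"""Hexagonal spot lattices and spatial weights.

Visium-style slides arrange capture spots on an offset hexagonal lattice:
a spot exists at array position ``(row, col)`` only when ``row + col`` is
even ("doubled-width" hex coordinates).  Each interior spot has six
lattice neighbors at offsets ``(0, ±2)`` and ``(±1, ±1)``.

:class:`SpotGrid` is the spatial support of every downstream analysis;
:func:`build_weights` turns it into the row-standardized spatial weights
matrix that the local Moran statistic consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

POSITIONS_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]

# lattice-distance-1 offsets on the doubled-width hex grid
HEX_OFFSETS = ((0, 2), (0, -2), (1, 1), (1, -1), (-1, 1), (-1, -1))


class LatticeError(ValueError):
    """Invalid lattice geometry or weights construction."""


@dataclass
class SpotGrid:
    """Spot barcodes with lattice coordinates and tissue flags.

    Parameters
    ----------
    positions
        One row per spot with the standard tissue-positions columns
        (``barcode, in_tissue, array_row, array_col,
        pxl_row_in_fullres, pxl_col_in_fullres``).  ``array_row +
        array_col`` must be even for every spot (Visium dialect) and
        barcodes must be unique.
    """

    positions: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in POSITIONS_COLUMNS if c not in self.positions.columns]
        if missing:
            raise LatticeError(f"positions table missing columns: {missing}")
        if self.positions["barcode"].duplicated().any():
            dupes = self.positions["barcode"][self.positions["barcode"].duplicated()]
            raise LatticeError(f"duplicate barcodes: {sorted(set(dupes))[:5]}")
        parity = (self.positions["array_row"] + self.positions["array_col"]) % 2
        if (parity != 0).any():
            bad = self.positions.loc[parity != 0, "barcode"].iloc[0]
            raise LatticeError(
                f"spot {bad!r} violates the offset-lattice parity rule "
                "(array_row + array_col must be even)"
            )
        self.positions = self.positions.reset_index(drop=True)

    @property
    def n_spots(self) -> int:
        return len(self.positions)

    @property
    def barcodes(self) -> pd.Series:
        return self.positions["barcode"]

    def in_tissue(self) -> "SpotGrid":
        """Restrict to spots with ``in_tissue == 1``."""
        return SpotGrid(self.positions[self.positions["in_tissue"] == 1].copy())

    def hex_distance_from(self, center: tuple[int, int]) -> np.ndarray:
        """Lattice (hex) distance of every spot from ``center``."""
        r = self.positions["array_row"].to_numpy()
        c = self.positions["array_col"].to_numpy()
        return hex_distance(r, c, center[0], center[1])

    def contains(self, row: int, col: int) -> bool:
        r = self.positions["array_row"].to_numpy()
        c = self.positions["array_col"].to_numpy()
        return bool(np.any((r == row) & (c == col)))


def hex_distance(r1, c1, r2, c2) -> np.ndarray:
    """Hex lattice distance between doubled-width coordinates.

    For doubled-width coordinates the distance is
    ``dy + max(0, (dx - dy) / 2)`` with ``dy = |r1-r2|``, ``dx = |c1-c2|``;
    adjacent spots (the six ``HEX_OFFSETS``) are at distance 1.
    """
    dy = np.abs(np.asarray(r1) - r2)
    dx = np.abs(np.asarray(c1) - c2)
    return dy + np.maximum(0, (dx - dy) // 2)


def make_hex_grid(n_rows: int, n_cols: int, spacing: float = 100.0) -> SpotGrid:
    """Build a fully in-tissue offset hex lattice of synthetic spots.

    A spot is placed at every ``(r, c)`` with ``0 <= r < n_rows``,
    ``0 <= c < n_cols`` and ``r + c`` even, so the grid holds
    ``ceil(n_rows * n_cols / 2)`` spots.  Pixel coordinates place
    lattice-adjacent spots exactly ``spacing`` apart.
    """
    if n_rows < 1 or n_cols < 1:
        raise LatticeError(f"grid dimensions must be >= 1, got ({n_rows}, {n_cols})")
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    keep = (rows + cols) % 2 == 0
    r, c = rows[keep], cols[keep]
    positions = pd.DataFrame(
        {
            "barcode": [f"SYN-{ri:03d}x{ci:03d}" for ri, ci in zip(r, c)],
            "in_tissue": 1,
            "array_row": r,
            "array_col": c,
            # equilateral embedding: row pitch sqrt(3)/2, col pitch 1/2
            "pxl_row_in_fullres": r * spacing * np.sqrt(3.0) / 2.0,
            "pxl_col_in_fullres": c * spacing / 2.0,
        }
    )
    return SpotGrid(positions)


@dataclass
class SpatialWeights:
    """Neighbor lists and edge weights over the in-tissue spots of a grid.

    ``neighbors[i]`` / ``weights[i]`` give the neighbor indices and edge
    weights of spot ``i`` (positional index into ``barcodes``).  Islands
    (degree-0 spots) carry empty lists and are excluded from inference.
    """

    neighbors: list[np.ndarray]
    weights: list[np.ndarray]
    barcodes: pd.Series
    row_standardized: bool = True
    scheme: str = "hex_adjacency"
    islands: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])

    def non_island_mask(self) -> np.ndarray:
        mask = np.ones(self.n, dtype=bool)
        mask[self.islands] = False
        return mask

    def to_sparse(self) -> sparse.csr_matrix:
        rows = np.repeat(np.arange(self.n), self.cardinalities)
        cols = np.concatenate(self.neighbors) if self.n else np.array([], dtype=int)
        vals = np.concatenate(self.weights) if self.n else np.array([])
        return sparse.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def lag(self, values: np.ndarray) -> np.ndarray:
        """Spatial lag ``(W v)_i``; NaN on islands."""
        out = self.to_sparse() @ np.asarray(values, dtype=float)
        out[self.islands] = np.nan
        return out


def build_weights(
    grid: SpotGrid,
    scheme: str = "hex_adjacency",
    k: int = 6,
    row_standardize: bool = True,
) -> SpatialWeights:
    """Construct spatial weights over the in-tissue spots of ``grid``.

    ``hex_adjacency`` links spots at lattice distance 1 (≤ 6 neighbors);
    ``knn`` links each spot to its ``k`` nearest pixel-coordinate
    neighbors and then symmetrizes the adjacency (union of directed
    edges).  Weights are binary, then row-standardized to ``1/degree``
    by default.  Degree-0 spots are flagged as islands; a grid where
    every spot is an island is rejected.
    """
    tissue = grid.in_tissue()
    pos = tissue.positions
    n = len(pos)
    if n < 2:
        raise LatticeError(f"need >= 2 in-tissue spots to build weights, got {n}")

    if scheme == "hex_adjacency":
        coord_to_idx = {
            (r, c): i
            for i, (r, c) in enumerate(zip(pos["array_row"], pos["array_col"]))
        }
        neighbors = []
        for r, c in zip(pos["array_row"], pos["array_col"]):
            nb = [
                coord_to_idx[(r + dr, c + dc)]
                for dr, dc in HEX_OFFSETS
                if (r + dr, c + dc) in coord_to_idx
            ]
            neighbors.append(np.array(sorted(nb), dtype=int))
    elif scheme == "knn":
        from sklearn.neighbors import NearestNeighbors

        xy = pos[["pxl_row_in_fullres", "pxl_col_in_fullres"]].to_numpy(dtype=float)
        k_eff = min(k, n - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(xy)
        _, idx = nn.kneighbors(xy)
        adj: list[set[int]] = [set() for _ in range(n)]
        for i in range(n):
            for j in idx[i, 1:]:  # drop self
                adj[i].add(int(j))
                adj[int(j)].add(i)  # symmetrize
        neighbors = [np.array(sorted(s), dtype=int) for s in adj]
    else:
        raise LatticeError(f"unknown weights scheme {scheme!r}")

    islands = np.array([i for i, nb in enumerate(neighbors) if len(nb) == 0], dtype=int)
    if len(islands) == n:
        raise LatticeError("every spot is an island; no spatial structure to analyze")
    if len(islands):
        warnings.warn(
            f"{len(islands)} island spot(s) excluded from spatial inference",
            stacklevel=2,
        )

    weights = []
    for nb in neighbors:
        if len(nb) == 0:
            weights.append(np.array([]))
        elif row_standardize:
            weights.append(np.full(len(nb), 1.0 / len(nb)))
        else:
            weights.append(np.ones(len(nb)))
    return SpatialWeights(
        neighbors=neighbors,
        weights=weights,
        barcodes=tissue.barcodes.reset_index(drop=True),
        row_standardized=row_standardize,
        scheme=scheme,
        islands=islands,
    )
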