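"""Spatial thinning of occurrences and buffered background areas.

Thinning keeps at most one record per species per grid cell (chosen uniformly
at random within the cell), removing the density bias of heterogeneous survey
effort. Backgrounds are the cells whose centers lie within a planar buffer
distance of at least one occurrence of a population group; they define the
environmental availability against which niche occupancy is measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .synthetic_landscape import ClimateStack, GridGeometry, OccurrenceTable

__all__ = ["BackgroundMask", "thin_occurrences", "build_background"]


@dataclass(frozen=True)
class BackgroundMask:
    """Boolean background grid for one population group at one buffer radius."""

    group: str
    buffer_km: float
    cells: np.ndarray  # bool, (nrows, ncols)

    def __post_init__(self) -> None:
        if self.group not in ("core", "disjunct", "species"):
            raise ValueError(f"unknown group {self.group!r}")

    @property
    def n_cells(self) -> int:
        return int(self.cells.sum())

    def union(self, other: "BackgroundMask") -> "BackgroundMask":
        if self.cells.shape != other.cells.shape:
            raise ValueError("background grids have different shapes")
        return BackgroundMask("species", self.buffer_km, self.cells | other.cells)


def thin_occurrences(occ: OccurrenceTable, cell_km: float, seed: int = 0,
                     geometry: GridGeometry | None = None) -> OccurrenceTable:
    """Retain randomly one occurrence per species per ``cell_km`` grid cell.

    The thinning lattice is anchored at the raster origin when ``geometry`` is
    given (so thinning and modelling share a lattice), else at (0, 0).
    Idempotent; never increases the record count; deterministic given seed.
    """
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    df = occ.df
    if df.empty:
        return occ
    rng = np.random.default_rng(seed)
    x0 = geometry.xll if geometry is not None else 0.0
    y0 = geometry.yll if geometry is not None else 0.0
    ci = np.floor((df["x"].to_numpy(float) - x0) / cell_km).astype(int)
    ri = np.floor((df["y"].to_numpy(float) - y0) / cell_km).astype(int)
    key = df.assign(_ci=ci, _ri=ri)
    # one uniformly random representative per species x cell
    keep = (key.sample(frac=1.0, random_state=rng.integers(2**31))
               .drop_duplicates(subset=["species", "_ci", "_ri"])
               .index)
    out = df.loc[sorted(keep)].reset_index(drop=True)
    return OccurrenceTable(out)


def build_background(occ_group: OccurrenceTable, stack: ClimateStack,
                     buffer_km: float, group: str | None = None) -> BackgroundMask:
    """Cells whose centers lie within ``buffer_km`` of any group occurrence.

    Distance is planar center-to-point; nodata cells are never included.
    """
    if buffer_km <= 0:
        raise ValueError("buffer_km must be positive")
    if len(occ_group) == 0:
        raise ValueError("background is undefined for an empty occurrence group")
    x, y = occ_group.xy()
    X, Y = stack.geometry.cell_centers()
    tree = cKDTree(np.column_stack([x, y]))
    d, _ = tree.query(np.column_stack([X.ravel(), Y.ravel()]), k=1)
    cells = (d.reshape(stack.shape) <= buffer_km) & ~stack.nodata_mask
    groups = set(occ_group.df["group"].unique())
    label = group or (groups.pop() if len(groups) == 1 else "species")
    return BackgroundMask(label, buffer_km, cells)
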