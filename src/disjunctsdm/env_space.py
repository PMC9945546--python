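"""Harmonized environmental space and gridded occurrence-density surfaces.

To compare niches across climate scenarios on a common footing, all scenarios'
cell values are pooled, standardized, and decomposed by a single PCA; the first
two axes define the environmental space, and every scenario is scored with the
same loadings (the "harmonized" projection that addresses model
transferability). Niches are then quantified as normalized occupancy surfaces
on an R x R grid in that space: a Gaussian kernel density of occurrences,
corrected for the density of available environments in the group's background,
after the gridded-environmental-space framework of Broennimann and colleagues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .synthetic_landscape import ClimateStack, ScenarioSet

__all__ = [
    "EnvProjection",
    "EnvGrid",
    "NicheDensity",
    "pooled_pca",
    "occurrence_density",
    "occupancy_from_densities",
    "silverman_bandwidth",
]

#: background-support cutoff as a fraction of the background density maximum
SUPPORT_EPS = 1e-12


class DegenerateLayersError(ValueError):
    """Pooled climate matrix is rank-deficient; names the offending layers."""


@dataclass(frozen=True)
class EnvProjection:
    """A single standardized PCA applied to every scenario.

    ``loadings`` has orthonormal columns (layers x 2); ``explained_var`` holds
    the full spectrum (non-increasing, sums to 1); ``scores`` maps each
    scenario id to a (2, nrows, ncols) grid of PC1/PC2 values, NaN on nodata.
    """

    loadings: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    explained_var: np.ndarray
    scores: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        g = self.loadings.T @ self.loadings
        if not np.allclose(g, np.eye(self.loadings.shape[1]), atol=1e-8):
            raise ValueError("loadings columns must be orthonormal")
        if np.any(np.diff(self.explained_var) > 1e-12):
            raise ValueError("explained_var must be non-increasing")

    def project_points(self, env: np.ndarray) -> np.ndarray:
        """Project raw environmental rows (n, k) to PC scores (n, 2)."""
        return ((env - self.center) / self.scale) @ self.loadings

    def scores_at_cells(self, scenario_id: str, rows: np.ndarray,
                        cols: np.ndarray) -> np.ndarray:
        """(n, 2) PC scores of grid cells in one scenario."""
        s = self.scores[scenario_id]
        return s[:, rows, cols].T

    def background_scores(self, scenario_id: str, cells: np.ndarray) -> np.ndarray:
        """(m, 2) PC scores of the True cells of a boolean grid."""
        s = self.scores[scenario_id]
        return s[:, cells].T


def pooled_pca(scenarios: ScenarioSet | Sequence[ClimateStack]) -> EnvProjection:
    """Standardized PCA on the row-stacked non-masked cells of all scenarios.

    Centering, scaling and the eigen-decomposition are computed once on the
    pooled matrix; each scenario is then scored with the shared loadings and
    the first two components are retained. Component signs are fixed so the
    largest-magnitude loading of each axis is positive (reproducibility).
    """
    stacks = scenarios.all_stacks() if isinstance(scenarios, ScenarioSet) else list(scenarios)
    names = stacks[0].layer_names
    if len(names) < 2:
        raise ValueError("need at least 2 layers")
    pooled = np.vstack([s.env_table() for s in stacks])
    if pooled.shape[0] < 3:
        raise ValueError("need at least 3 non-masked cells")

    center = pooled.mean(axis=0)
    scale = pooled.std(axis=0)
    dead = [names[i] for i in np.flatnonzero(scale == 0)]
    if dead:
        raise DegenerateLayersError(f"constant layer(s): {dead}")
    z = (pooled - center) / scale

    corr = (z.T @ z) / z.shape[0]
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    if evals[1] < 1e-10 * evals[0]:
        # find which layers are redundant to make the error actionable
        c = np.corrcoef(z, rowvar=False)
        pairs = [(names[i], names[j]) for i in range(len(names))
                 for j in range(i + 1, len(names)) if abs(c[i, j]) > 0.9999]
        raise DegenerateLayersError(
            f"pooled climate matrix has rank < 2; near-duplicate layers: {pairs}")

    loadings = evecs[:, :2].copy()
    for j in range(2):  # deterministic sign convention
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] = -loadings[:, j]

    scores: dict[str, np.ndarray] = {}
    for s in stacks:
        zs = (s.data - center[:, None, None]) / scale[:, None, None]
        sc = np.tensordot(loadings.T, np.nan_to_num(zs), axes=1)
        scores[s.scenario_id] = np.where(s.nodata_mask, np.nan, sc)
    return EnvProjection(loadings, center, scale, evals / evals.sum(), scores)


@dataclass(frozen=True)
class EnvGrid:
    """R x R discretization of the 2-D environmental space."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    R: int = 100

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError("grid bounds must be strictly ordered")
        if self.R < 10:
            raise ValueError("R must be >= 10")

    @classmethod
    def from_scores(cls, scores: Sequence[np.ndarray], R: int = 100,
                    margin: float = 0.05) -> "EnvGrid":
        """Bounds covering all pooled (n, 2) score sets, with a relative margin."""
        pts = np.vstack([np.asarray(s) for s in scores])
        (xmin, ymin), (xmax, ymax) = pts.min(axis=0), pts.max(axis=0)
        mx = margin * (xmax - xmin or 1.0)
        my = margin * (ymax - ymin or 1.0)
        return cls(xmin - mx, xmax + mx, ymin - my, ymax + my, R)

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates along each axis (length R each)."""
        gx = self.xmin + (np.arange(self.R) + 0.5) * (self.xmax - self.xmin) / self.R
        gy = self.ymin + (np.arange(self.R) + 0.5) * (self.ymax - self.ymin) / self.R
        return gx, gy


@dataclass(frozen=True)
class NicheDensity:
    """Normalized occupancy surface of one group on an EnvGrid.

    ``z`` is nonnegative, sums to 1, and is zero outside the group's
    available-environment support.
    """

    grid: EnvGrid
    z: np.ndarray  # (R, R), axis 0 = PC1 axis, axis 1 = PC2 axis
    group: str
    bandwidth: tuple[float, float]

    def __post_init__(self) -> None:
        if self.z.shape != (self.grid.R, self.grid.R):
            raise ValueError("z shape does not match grid")
        if not np.isclose(self.z.sum(), 1.0, atol=1e-9):
            raise ValueError("occupancy must sum to 1")
        if np.any(self.z < 0):
            raise ValueError("occupancy must be nonnegative")

    def centroid(self) -> np.ndarray:
        """z-weighted centroid in PC coordinates, shape (2,)."""
        gx, gy = self.grid.axes()
        return np.array([np.sum(self.z.sum(axis=1) * gx),
                         np.sum(self.z.sum(axis=0) * gy)])


def silverman_bandwidth(points: np.ndarray) -> tuple[float, float]:
    """Per-axis Silverman rule-of-thumb bandwidths for (n, 2) points."""
    pts = np.asarray(points, float)
    n = len(pts)
    out = []
    for j in range(2):
        sd = pts[:, j].std(ddof=1) if n > 1 else 1.0
        iqr = np.subtract(*np.percentile(pts[:, j], [75, 25]))
        spread = min(sd, iqr / 1.349) if iqr > 0 else sd
        out.append(0.9 * (spread or 1.0) * n ** (-0.2))
    return tuple(out)


def occupancy_from_densities(occ_d: np.ndarray, bg_d: np.ndarray,
                             correction: bool = True) -> np.ndarray:
    """Normalized occupancy surface from occurrence and background densities."""
    support = bg_d > SUPPORT_EPS * bg_d.max()
    if correction:
        z = np.where(support, occ_d / np.where(support, bg_d, 1.0), 0.0)
    else:
        z = np.where(support, occ_d, 0.0)
    total = z.sum()
    if total <= 0:
        raise ValueError("all occurrences fall outside the grid bounds / support")
    return z / total


def _grid_kde(points: np.ndarray, grid: EnvGrid,
              bandwidth: tuple[float, float]) -> np.ndarray:
    """Separable Gaussian KDE evaluated on the grid cell centers, (R, R)."""
    gx, gy = grid.axes()
    hx, hy = bandwidth
    ux = (gx[:, None] - points[None, :, 0]) / hx
    uy = (gy[:, None] - points[None, :, 1]) / hy
    kx = np.exp(-0.5 * ux * ux) / (hx * np.sqrt(2 * np.pi))
    ky = np.exp(-0.5 * uy * uy) / (hy * np.sqrt(2 * np.pi))
    return (kx @ ky.T) / len(points)


def occurrence_density(
    points: np.ndarray,
    background: np.ndarray,
    grid: EnvGrid | None = None,
    bandwidth: tuple[float, float] | str = "auto",
    *,
    group: str = "",
    correction: bool = True,
    min_points: int = 5,
) -> NicheDensity:
    """Gridded niche occupancy of a group in environmental space.

    Parameters
    ----------
    points : (n, 2) PC scores of the group's occurrences (n >= 5).
    background : (m, 2) PC scores of the group's available environment.
    grid : EnvGrid, default built from the background scores.
    bandwidth : per-axis kernel widths, or ``"auto"`` for Silverman's rule
        computed on the background scores (scale-aware and reproducible).
    correction : if True (default), occupancy is the ratio of occurrence
        density to background density wherever the background density exceeds
        a tiny support threshold, and 0 elsewhere -- the environment-
        availability correction. If False, the raw occurrence density
        (restricted to the background support) is used.

    The result is normalized to sum to 1.
    """
    points = np.atleast_2d(np.asarray(points, float))
    background = np.atleast_2d(np.asarray(background, float))
    if len(points) < min_points:
        raise ValueError(f"need at least {min_points} occurrence points")
    if len(background) == 0:
        raise ValueError("background must be non-empty")
    if grid is None:
        grid = EnvGrid.from_scores([background])
    h = silverman_bandwidth(background) if bandwidth == "auto" else tuple(bandwidth)

    occ_d = _grid_kde(points, grid, h)
    bg_d = _grid_kde(background, grid, h)
    z = occupancy_from_densities(occ_d, bg_d, correction)
    return NicheDensity(grid, z, group, h)
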