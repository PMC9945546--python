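"""Synthetic climate landscapes and virtual species with disjunct population groups.

This module generates the raw material for desk-scale niche-modelling studies:
multi-layer climate raster stacks with controlled spatial autocorrelation and
inter-layer correlation, perturbed "future" stacks emulating GCM x RCP
projections, and virtual species whose true climatic niche is known exactly.
A virtual species occupies two geographically disjoint regions -- a larger
"core" group and a smaller "disjunct" group -- mirroring the sampling regime
of alpine plants whose outlying populations sit tens to hundreds of km from
the main range.

All generators are pure functions of their seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "GridGeometry",
    "ClimateStack",
    "ScenarioSet",
    "VirtualTruth",
    "OccurrenceTable",
    "GROUP_LABELS",
    "generate_climate_stack",
    "generate_future_stack",
    "generate_scenario_set",
    "make_virtual_species",
    "sample_occurrences",
    "future_halving_true_range",
]

GROUP_LABELS = ("core", "disjunct")

#: layer-unit templates cycled over when the caller does not supply means/sds
#: (annual temperature degC, annual precipitation mm, seasonality, ...)
_DEFAULT_MEANS = (8.0, 1500.0, 60.0, 18.0, 300.0, 6.5)
_DEFAULT_SDS = (4.0, 400.0, 25.0, 5.0, 120.0, 2.0)


class CapacityError(ValueError):
    """Requested more samples than a region can supply."""


@dataclass(frozen=True)
class GridGeometry:
    """Regular planar grid in km, ESRI ASCII-grid convention (row 0 = top)."""

    nrows: int
    ncols: int
    cellsize_km: float = 1.0
    xll: float = 0.0
    yll: float = 0.0

    def __post_init__(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0 or self.cellsize_km <= 0:
            raise ValueError("grid shape and cell size must be positive")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of cell-center coordinates, shape (nrows, ncols)."""
        cs = self.cellsize_km
        x = self.xll + (np.arange(self.ncols) + 0.5) * cs
        y = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * cs
        return np.meshgrid(x, y)

    def point_to_rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map planar coordinates to (row, col) indices; raises if off-grid."""
        col = np.floor((np.asarray(x) - self.xll) / self.cellsize_km).astype(int)
        row = self.nrows - 1 - np.floor((np.asarray(y) - self.yll) / self.cellsize_km).astype(int)
        if np.any((row < 0) | (row >= self.nrows) | (col < 0) | (col >= self.ncols)):
            raise ValueError("point outside the raster extent")
        return row, col


@dataclass(frozen=True)
class ClimateStack:
    """Named co-registered raster layers for one climate scenario.

    Attributes
    ----------
    scenario_id : str
        e.g. ``"current"`` or ``"GCM1_rcp85"``.
    layer_names : tuple of str
        Unique, ordered layer names.
    data : ndarray, shape (n_layers, nrows, ncols)
        Layer values in layer units; finite on every non-masked cell.
    geometry : GridGeometry
    nodata_mask : ndarray of bool, shape (nrows, ncols)
        True where no data.
    """

    scenario_id: str
    layer_names: tuple[str, ...]
    data: np.ndarray
    geometry: GridGeometry
    nodata_mask: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.layer_names)) != len(self.layer_names):
            raise ValueError("layer names must be unique")
        k, nr, nc = self.data.shape
        if k != len(self.layer_names):
            raise ValueError("layer count does not match layer_names")
        if (nr, nc) != (self.geometry.nrows, self.geometry.ncols):
            raise ValueError("data shape does not match grid geometry")
        if self.nodata_mask.shape != (nr, nc):
            raise ValueError("nodata_mask shape does not match grid")
        valid = ~self.nodata_mask
        if not np.all(np.isfinite(self.data[:, valid])):
            raise ValueError("non-masked cells must be finite")

    @property
    def n_layers(self) -> int:
        return len(self.layer_names)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def layer(self, name: str) -> np.ndarray:
        try:
            return self.data[self.layer_names.index(name)]
        except ValueError:
            raise KeyError(f"no layer named {name!r}") from None

    def env_at_cells(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Environmental values at cells, shape (n_points, n_layers)."""
        return self.data[:, rows, cols].T

    def env_table(self) -> np.ndarray:
        """All non-masked cells as a (n_cells, n_layers) matrix."""
        valid = ~self.nodata_mask
        return self.data[:, valid].T

    def same_grid_as(self, other: "ClimateStack") -> bool:
        return (
            self.geometry == other.geometry
            and self.layer_names == other.layer_names
            and np.array_equal(self.nodata_mask, other.nodata_mask)
        )


@dataclass(frozen=True)
class ScenarioSet:
    """A current climate stack plus future stacks keyed by (gcm_id, rcp_id)."""

    current: ClimateStack
    futures: Mapping[tuple[str, str], ClimateStack] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, stack in self.futures.items():
            if not self.current.same_grid_as(stack):
                raise ValueError(f"future {key} is not co-registered with current")

    @property
    def rcp_ids(self) -> tuple[str, ...]:
        return tuple(sorted({rcp for (_, rcp) in self.futures}))

    def futures_for_rcp(self, rcp_id: str) -> dict[tuple[str, str], ClimateStack]:
        return {k: v for k, v in self.futures.items() if k[1] == rcp_id}

    def all_stacks(self) -> list[ClimateStack]:
        return [self.current, *self.futures.values()]


@dataclass(frozen=True)
class VirtualTruth:
    """Known-truth niche of a virtual species.

    Suitability of a cell is the product of per-layer Gaussian terms
    ``exp(-0.5 ((v - optimum) / breadth)^2)``, hence in [0, 1]. ``true_threshold``
    (absolute suitability) defines the species' true range; ``region_masks``
    delimit the core and disjunct sampling regions, separated by a stated gap.
    """

    optimum: np.ndarray
    breadth: np.ndarray
    true_threshold: float
    region_masks: Mapping[str, np.ndarray]
    gap_km: float = 30.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.breadth) <= 0):
            raise ValueError("niche breadths must be positive")
        core = self.region_masks["core"]
        disj = self.region_masks["disjunct"]
        if np.any(core & disj):
            raise ValueError("core and disjunct regions must be disjoint")

    def suitability(self, stack: ClimateStack) -> np.ndarray:
        """True suitability grid in [0, 1]; NaN on nodata cells."""
        opt = np.asarray(self.optimum, float)[:, None, None]
        brd = np.asarray(self.breadth, float)[:, None, None]
        z = (stack.data - opt) / brd
        suit = np.exp(-0.5 * np.sum(z * z, axis=0))
        suit = np.where(stack.nodata_mask, np.nan, suit)
        return suit

    def true_range(self, stack: ClimateStack) -> np.ndarray:
        """Boolean grid of the true range (suitability >= true_threshold)."""
        suit = self.suitability(stack)
        return np.where(np.isnan(suit), False, suit >= self.true_threshold)


@dataclass(frozen=True)
class OccurrenceTable:
    """Point occurrence records with species and population-group labels.

    Thin wrapper over a DataFrame with columns ``species, group, x, y``;
    group labels are restricted to ``{"core", "disjunct"}``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"species", "group", "x", "y"} - set(self.df.columns)
        if missing:
            raise ValueError(f"occurrence table missing columns: {sorted(missing)}")
        bad = set(self.df["group"].unique()) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, group: str) -> "OccurrenceTable":
        if group == "species":
            return self
        return OccurrenceTable(self.df[self.df["group"] == group].reset_index(drop=True))

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        return self.df["x"].to_numpy(float), self.df["y"].to_numpy(float)

    def rowcols(self, geometry: GridGeometry) -> tuple[np.ndarray, np.ndarray]:
        return geometry.point_to_rowcol(*self.xy())


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _kernel_l2(sigma: float) -> float:
    """Theoretical sd of 2-D Gaussian-smoothed unit white noise.

    For a separable kernel the 2-D L2 norm is the square of the 1-D norm,
    i.e. sqrt(sum k_ij^2) = sum_i w_i^2 with w the normalized 1-D weights
    (scipy's truncation radius of 4 sigma).
    """
    if sigma <= 0:
        return 1.0
    r = max(int(4.0 * sigma + 0.5), 1)
    w = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
    w /= w.sum()
    return float(np.sum(w**2))


def _smooth_unit_field(rng: np.random.Generator, shape: tuple[int, int],
                       sigma_cells: float) -> np.ndarray:
    """Gaussian-filtered, demeaned white noise with unit asymptotic variance.

    The field is divided by the theoretical standard deviation of smoothed
    white noise (the kernel's L2 norm), so its variance is ~1 when the
    autocorrelation range is small relative to the grid and collapses toward 0
    in the over-smoothed limit (near-constant layers).
    """
    noise = rng.standard_normal(shape)
    f = gaussian_filter(noise - noise.mean(), sigma=sigma_cells, mode="reflect")
    return f / _kernel_l2(sigma_cells)


def generate_climate_stack(
    n_layers: int,
    shape: tuple[int, int] = (200, 200),
    autocorr_range: float = 20.0,
    cross_corr: float = 0.3,
    seed: int = 0,
    *,
    cellsize_km: float = 1.0,
    layer_means: Sequence[float] | None = None,
    layer_sds: Sequence[float] | None = None,
    scenario_id: str = "current",
    nodata_mask: np.ndarray | None = None,
) -> ClimateStack:
    """Generate a stack of correlated, spatially autocorrelated climate layers.

    Each layer is a Gaussian random field obtained by smoothing white noise
    with a Gaussian kernel of standard deviation ``autocorr_range / 2`` cells
    (so the field's autocorrelation falls to 1/e at roughly ``autocorr_range``
    km), normalized to unit asymptotic variance, mixed to the target uniform
    cross-correlation ``cross_corr`` by a Cholesky factor, and rescaled to
    layer units. When the autocorrelation range far exceeds the grid, layers
    become near-constant (variance well below the white-noise variance).

    Parameters
    ----------
    n_layers : int
        Number of climate layers (>= 2), stand-ins for bioclimatic variables.
    shape : (nrows, ncols)
    autocorr_range : float
        Spatial autocorrelation scale in km (> 0).
    cross_corr : float
        Target pairwise correlation between layers, in
        ``(-1/(n_layers-1), 1]`` so the correlation matrix is valid.
    seed : int
        Deterministic: identical arguments give bit-identical stacks.
    """
    if n_layers < 2:
        raise ValueError("n_layers must be >= 2")
    nr, nc = shape
    if nr <= 0 or nc <= 0:
        raise ValueError("shape must be positive")
    if autocorr_range <= 0:
        raise ValueError("autocorr_range must be positive")
    lo = -1.0 / (n_layers - 1)
    if not (lo < cross_corr <= 1.0):
        raise ValueError(f"cross_corr must lie in ({lo:.3f}, 1] for {n_layers} layers")

    rng = np.random.default_rng(seed)
    sigma = (autocorr_range / cellsize_km) / 2.0
    fields = np.stack([_smooth_unit_field(rng, (nr, nc), sigma) for _ in range(n_layers)])

    # impose uniform cross-correlation via Cholesky of (1-rho) I + rho J
    corr = np.full((n_layers, n_layers), cross_corr)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    mixed = np.tensordot(chol, fields, axes=1)

    means = np.array([(_DEFAULT_MEANS[i % len(_DEFAULT_MEANS)] if layer_means is None
                       else layer_means[i]) for i in range(n_layers)], float)
    sds = np.array([(_DEFAULT_SDS[i % len(_DEFAULT_SDS)] if layer_sds is None
                     else layer_sds[i]) for i in range(n_layers)], float)
    data = means[:, None, None] + sds[:, None, None] * mixed

    mask = np.zeros((nr, nc), bool) if nodata_mask is None else np.asarray(nodata_mask, bool)
    data = np.where(mask, np.nan, data)
    names = tuple(f"bio{i + 1}" for i in range(n_layers))
    return ClimateStack(scenario_id, names, data, GridGeometry(nr, nc, cellsize_km), mask)


def generate_collinear_stack(
    n_layers: int,
    shape: tuple[int, int] = (200, 200),
    autocorr_range: float = 20.0,
    n_factors: int = 2,
    noise_sd: float = 0.02,
    seed: int = 0,
    *,
    cellsize_km: float = 1.0,
    layer_means: Sequence[float] | None = None,
    layer_sds: Sequence[float] | None = None,
    scenario_id: str = "current",
    nodata_mask: np.ndarray | None = None,
) -> ClimateStack:
    """Generate a low-rank stack: layers as mixtures of few latent fields.

    Real bioclimatic variables are strongly collinear - a handful of latent
    climate gradients explain most of their variance, which is why two
    principal components usually suffice downstream. This generator makes
    that structure explicit: ``n_factors`` independent smooth fields are
    mixed by a random loading matrix into ``n_layers`` observed layers, plus
    white noise of relative amplitude ``noise_sd``. With small ``noise_sd``
    any function of the layers is (nearly) a function of the latent fields,
    so a rank-``n_factors`` ordination can represent it without
    misspecification - the regime needed for known-truth recovery
    experiments.

    Deterministic given seed.
    """
    if n_layers < 2:
        raise ValueError("n_layers must be >= 2")
    if not (1 <= n_factors <= n_layers):
        raise ValueError("n_factors must be in [1, n_layers]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    nr, nc = shape
    if nr <= 0 or nc <= 0:
        raise ValueError("shape must be positive")

    rng = np.random.default_rng(seed)
    sigma = (autocorr_range / cellsize_km) / 2.0
    factors = np.stack([_smooth_unit_field(rng, (nr, nc), sigma)
                        for _ in range(n_factors)])
    loadings = rng.normal(size=(n_layers, n_factors))
    mixed = np.tensordot(loadings, factors, axes=1)
    if noise_sd > 0:
        mixed = mixed + noise_sd * np.stack(
            [rng.standard_normal((nr, nc)) for _ in range(n_layers)])

    raw_sd = mixed.std(axis=(1, 2), keepdims=True)
    raw_sd = np.where(raw_sd > 0, raw_sd, 1.0)
    means = np.array([(_DEFAULT_MEANS[i % len(_DEFAULT_MEANS)] if layer_means is None
                       else layer_means[i]) for i in range(n_layers)], float)
    sds = np.array([(_DEFAULT_SDS[i % len(_DEFAULT_SDS)] if layer_sds is None
                     else layer_sds[i]) for i in range(n_layers)], float)
    data = means[:, None, None] + sds[:, None, None] * mixed / raw_sd

    mask = np.zeros((nr, nc), bool) if nodata_mask is None else np.asarray(nodata_mask, bool)
    data = np.where(mask, np.nan, data)
    names = tuple(f"bio{i + 1}" for i in range(n_layers))
    return ClimateStack(scenario_id, names, data, GridGeometry(nr, nc, cellsize_km), mask)


def generate_future_stack(
    current: ClimateStack,
    offsets: Mapping[str, float] | None = None,
    factors: Mapping[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    gcm_id: str = "GCM1",
    rcp_id: str = "rcp26",
    noise_autocorr_range: float = 20.0,
) -> ClimateStack:
    """Perturb a current stack into a future scenario.

    ``future = factor * current + offset + smooth noise`` per layer, with the
    nodata mask preserved. Offsets/factors are given per layer name and default
    to 0 / 1; ``noise_sd`` (layer units, applied to every layer) stands in for
    the spread between GCMs and is a smooth random field with that asymptotic
    standard deviation.
    """
    offsets = dict(offsets or {})
    factors = dict(factors or {})
    unknown = (set(offsets) | set(factors)) - set(current.layer_names)
    if unknown:
        raise KeyError(f"unknown layer name(s): {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    sigma = (noise_autocorr_range / current.geometry.cellsize_km) / 2.0
    data = current.data.copy()
    for i, name in enumerate(current.layer_names):
        layer = factors.get(name, 1.0) * data[i] + offsets.get(name, 0.0)
        if noise_sd > 0:
            layer = layer + noise_sd * _smooth_unit_field(rng, current.shape, sigma)
        data[i] = layer
    data = np.where(current.nodata_mask, np.nan, data)
    return replace(current, scenario_id=f"{gcm_id}_{rcp_id}", data=data)


def generate_scenario_set(
    current: ClimateStack,
    rcp_offsets: Mapping[str, Mapping[str, float]] | None = None,
    gcm_ids: Sequence[str] = ("GCM1", "GCM2", "GCM3", "GCM4"),
    noise_sd: float = 0.3,
    seed: int = 0,
) -> ScenarioSet:
    """Build a full GCM x RCP scenario set around a current stack.

    Each RCP has a shared per-layer offset (default: a moderate +1.5 and an
    extreme +4.0 warming applied to the first, temperature-like, layer); GCMs
    within an RCP differ only by independent smooth noise of sd ``noise_sd``,
    emulating inter-model spread.
    """
    if rcp_offsets is None:
        first = current.layer_names[0]
        rcp_offsets = {"rcp26": {first: 1.5}, "rcp85": {first: 4.0}}
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(rcp_offsets) * len(gcm_ids)))
    futures: dict[tuple[str, str], ClimateStack] = {}
    for rcp_id, offs in rcp_offsets.items():
        for gcm_id in gcm_ids:
            child_seed = int(next(children).generate_state(1)[0] % (2**31))
            futures[(gcm_id, rcp_id)] = generate_future_stack(
                current, offsets=offs, noise_sd=noise_sd, seed=child_seed,
                gcm_id=gcm_id, rcp_id=rcp_id)
    return ScenarioSet(current, futures)


def _default_region_masks(stack: ClimateStack, gap_km: float) -> dict[str, np.ndarray]:
    """Left (larger, core) and right (smaller, disjunct) bands split by a gap."""
    nr, nc = stack.shape
    cs = stack.geometry.cellsize_km
    gap_cells = int(np.ceil(gap_km / cs))
    core_end = int(0.55 * nc)
    disj_start = core_end + gap_cells
    if disj_start >= nc:
        raise ValueError("grid too narrow for the requested disjunction gap")
    cols = np.arange(nc)
    core = np.broadcast_to(cols < core_end, (nr, nc)) & ~stack.nodata_mask
    disj = np.broadcast_to(cols >= disj_start, (nr, nc)) & ~stack.nodata_mask
    return {"core": core.copy(), "disjunct": disj.copy()}


def make_virtual_species(
    stack: ClimateStack,
    *,
    optimum_quantile: float = 0.2,
    breadth_scale: float = 0.5,
    threshold_fraction: float = 0.5,
    gap_km: float = 30.0,
    region_masks: Mapping[str, np.ndarray] | None = None,
    optimum_region: str | None = None,
    snap_optimum: bool = False,
) -> VirtualTruth:
    """Construct a virtual species truth on a landscape.

    The niche optimum defaults to the ``optimum_quantile`` quantile of each
    layer over the landscape (a low quantile gives a cold-margin species, the
    regime of high-mountain plants); breadth is ``breadth_scale`` times each
    layer's spatial standard deviation. The true range is defined by an
    absolute suitability cutoff at ``threshold_fraction`` of the maximum
    suitability realized on the landscape. If ``optimum_region`` names one of
    the region masks, the quantiles are taken over that region's cells only,
    which guarantees the species' climate actually occurs there (useful to
    ensure the smaller disjunct band supports a population). With
    ``snap_optimum`` the quantile vector is replaced by the climate of the
    nearest actual cell (standardized Euclidean distance), so the optimum is a
    realizable climate rather than an independent per-layer construct.
    """
    masks_for_optimum = (dict(region_masks) if region_masks is not None
                         else _default_region_masks(stack, gap_km))
    if optimum_region is not None:
        if optimum_region not in masks_for_optimum:
            raise ValueError(f"unknown region {optimum_region!r}")
        sel = masks_for_optimum[optimum_region] & ~stack.nodata_mask
        env = stack.data[:, sel].T
    else:
        env = stack.env_table()
    optimum = np.quantile(env, optimum_quantile, axis=0)
    breadth = breadth_scale * stack.env_table().std(axis=0)
    if snap_optimum:
        scale = np.where(breadth > 0, breadth, 1.0)
        dist2 = (((env - optimum) / scale) ** 2).sum(axis=1)
        optimum = env[int(np.argmin(dist2))].copy()
    masks = masks_for_optimum
    truth = VirtualTruth(optimum, breadth, np.nan, masks, gap_km=gap_km)
    smax = np.nanmax(truth.suitability(stack))
    return replace(truth, true_threshold=float(threshold_fraction * smax))


def sample_occurrences(
    truth: VirtualTruth,
    stack: ClimateStack,
    n_core: int,
    n_disjunct: int,
    seed: int = 0,
    species: str = "virtualis",
    method: str = "suitability",
) -> OccurrenceTable:
    """Sample occurrence points from the virtual species.

    With ``method="suitability"`` (default), cells within each region mask are
    drawn without replacement with probability proportional to continuous true
    suitability. With ``method="threshold"``, cells are drawn uniformly from
    the thresholded true range (suitability >= true_threshold) within each
    region, which makes the species' realized distribution coincide with its
    potential range. Points are placed at cell centers. Deterministic given
    seed.
    """
    if method not in ("suitability", "threshold"):
        raise ValueError(f"unknown sampling method {method!r}")
    rng = np.random.default_rng(seed)
    suit = truth.suitability(stack)
    X, Y = stack.geometry.cell_centers()
    rows = []
    for group, n in (("core", n_core), ("disjunct", n_disjunct)):
        if n == 0:
            continue
        mask = truth.region_masks[group] & ~stack.nodata_mask
        if method == "threshold":
            sel = mask & (np.nan_to_num(suit) >= truth.true_threshold)
        else:
            sel = mask & (np.nan_to_num(suit) > 0)
        idx = np.flatnonzero(sel.ravel())
        if n > idx.size:
            raise CapacityError(
                f"requested {n} {group} occurrences but only {idx.size} cells "
                f"with positive suitability are available in that region")
        if method == "threshold":
            chosen = rng.choice(idx, size=n, replace=False)
        else:
            p = suit.ravel()[idx]
            chosen = rng.choice(idx, size=n, replace=False, p=p / p.sum())
        rows.append(pd.DataFrame({
            "species": species, "group": group,
            "x": X.ravel()[chosen], "y": Y.ravel()[chosen]}))
    if not rows:
        df = pd.DataFrame(columns=["species", "group", "x", "y"])
    else:
        df = pd.concat(rows, ignore_index=True)
    return OccurrenceTable(df)


def future_halving_true_range(
    stack: ClimateStack,
    truth: VirtualTruth,
    *,
    layer: str | None = None,
    direction: dict[str, float] | None = None,
    target_fraction: float = 0.5,
    gcm_id: str = "GCM1",
    rcp_id: str = "rcp85",
    tol: float = 0.005,
    max_offset: float | None = None,
) -> tuple[ClimateStack, float]:
    """Construct a deterministic future stack shrinking the true range.

    Bisects a scale factor on an additive shift ``direction`` (per-layer
    offsets; default: a unit shift of the first layer, or of ``layer`` if
    given) so that the number of true-suitable cells under the future climate
    is ``target_fraction`` of the current count. Returns the future stack and
    the achieved fraction. Used as a known-truth oracle for range-change
    tests: a fraction of 0.5 corresponds to a true range change of -50 %.
    Passing a ``direction`` spanning all layers mimics a coherent climate
    shift in which correlated variables move together, as they do across GCM
    projections.
    """
    if direction is None:
        direction = {layer or stack.layer_names[0]: 1.0}
    unknown = set(direction) - set(stack.layer_names)
    if unknown:
        raise ValueError(f"direction names unknown layers: {sorted(unknown)}")
    cpr = int(truth.true_range(stack).sum())
    if cpr == 0:
        raise ValueError("true current range is empty; cannot target a fraction of it")

    def future(scale: float) -> ClimateStack:
        offsets = {name: scale * v for name, v in direction.items()}
        return generate_future_stack(stack, offsets=offsets, noise_sd=0.0,
                                     gcm_id=gcm_id, rcp_id=rcp_id)

    def frac(scale: float) -> float:
        return truth.true_range(future(scale)).sum() / cpr

    # choose the scale sign that shrinks the range, then bracket by doubling
    sign = 1.0 if frac(1e-6) <= frac(-1e-6) else -1.0
    env = stack.env_table()
    norm = float(np.linalg.norm([
        v * env[:, stack.layer_names.index(name)].std()
        for name, v in direction.items()]))
    hi = sign * (max_offset or norm / max(
        np.linalg.norm(list(direction.values())), 1e-12))
    for _ in range(60):
        if frac(hi) <= target_fraction:
            break
        hi *= 1.5
    else:
        raise RuntimeError("could not bracket the target range fraction")
    lo = 0.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        f = frac(mid)
        if abs(f - target_fraction) <= tol:
            lo = hi = mid
            break
        if f > target_fraction:
            lo = mid
        else:
            hi = mid
    scale = 0.5 * (lo + hi)
    fut = future(scale)
    return fut, float(truth.true_range(fut).sum() / cpr)
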