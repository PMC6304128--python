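"""Territory-level habitat features: moving windows, terrain, zonal means.

A territory is summarized by the mean of each habitat layer over the
circular buffer approximating the average home-range size (1000 km² by
default), plus the count of other wolf pairs within 40 km as a density
proxy, and the dispersal-distance category used to stratify the models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .landscape import LANDCOVER_BANDS, SCALAR_BANDS, LandscapeStack, PairRegistry

logger = logging.getLogger(__name__)

DEFAULT_TERRITORY_AREA_KM2 = 1000.0
WOLF_DENSITY_RADIUS_M = 40_000.0
SHORT_MAX_M = 40_000.0
LONG_MIN_M = 200_000.0

#: Column order of the per-territory feature table.
FEATURE_COLUMNS: tuple[str, ...] = (
    "pct_forest",
    "pct_mire",
    "pct_mountain",
    "pct_water",
    "pct_agricultural",
    "pct_human_dominated",
    "altitude",
    "slope",
    "roughness",
    "human_density",
    "main_road_density",
    "secondary_road_density",
    "human_accessibility",
    "bear_index",
    "moose_harvest_density",
    "wolf_pair_density",
)


@dataclass(frozen=True)
class TerritoryFeatures:
    """Feature vector of one (natal / available / established) territory."""

    center: tuple[float, float]
    year: int
    values: Mapping[str, float]
    coverage: float = 1.0

    def __post_init__(self) -> None:
        pct = [v for k, v in self.values.items() if k.startswith("pct_")]
        if pct and abs(sum(pct) - 100.0) > 1e-6:
            raise ValueError("land-cover percentages must sum to 100")


def territory_radius(area_km2: float) -> float:
    """Radius (m) of the circle with the given area: r = sqrt(A / pi)."""
    if area_km2 <= 0:
        raise ValueError("area_km2 must be positive")
    return float(np.sqrt(area_km2 * 1e6 / np.pi))


def dispersal_category(distance_m: float) -> str:
    """Distance class: short < 40 km, medium 40–200 km, long > 200 km."""
    if distance_m < 0:
        raise ValueError("distance_m must be >= 0")
    if distance_m < SHORT_MAX_M:
        return "short"
    if distance_m <= LONG_MIN_M:
        return "medium"
    return "long"


def landcover_percentage_layers(
    class_grid: np.ndarray,
    window: int = 3,
    classes: Sequence[str] = LANDCOVER_BANDS,
) -> dict[str, np.ndarray]:
    """Moving-window percentage of each vegetation class.

    The window shrinks at grid edges: the denominator is the count of
    in-grid window cells, so per-cell class percentages always close to
    100.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    grid = np.asarray(class_grid)
    known = set(classes)
    present = set(np.unique(grid).tolist())
    unknown = present - known
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(map(str, unknown))}")
    kernel = np.ones((window, window))
    denom = ndimage.correlate(np.ones(grid.shape), kernel, mode="constant", cval=0.0)
    out = {}
    for cls in classes:
        ind = (grid == cls).astype(float)
        num = ndimage.correlate(ind, kernel, mode="constant", cval=0.0)
        out[f"pct_{cls}"] = 100.0 * num / denom
    return out


def terrain_layers(
    dem_grid: np.ndarray, resolution_m: float, roughness_window: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Slope (degrees) and roughness (m) from a DEM.

    Slope is the arctangent of the central-difference gradient magnitude.
    Roughness is max minus min elevation over the moving neighborhood
    (default 3x3: a cell and its 8 neighbors); edge neighborhoods shrink
    to in-grid cells.
    """
    dem = np.asarray(dem_grid, float)
    if dem.ndim != 2 or min(dem.shape) < 2:
        raise ValueError("DEM must be a 2-D grid with at least 2 cells per axis")
    if not np.all(np.isfinite(dem)):
        raise ValueError("DEM must be finite")
    if resolution_m <= 0:
        raise ValueError("resolution_m must be positive")
    gy, gx = np.gradient(dem, resolution_m)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    # 'nearest' padding only replicates in-grid values, so the max/min over
    # the padded window equal those over the shrunken in-grid window.
    mx = ndimage.maximum_filter(dem, roughness_window, mode="nearest")
    mn = ndimage.minimum_filter(dem, roughness_window, mode="nearest")
    return slope, mx - mn


def landcover_class_grid(landscape: LandscapeStack) -> np.ndarray:
    """Dominant vegetation class per cell (argmax of the fraction bands)."""
    stack = np.stack([landscape.bands[b] for b in LANDCOVER_BANDS])
    idx = stack.argmax(axis=0)
    return np.asarray(LANDCOVER_BANDS, dtype=object)[idx]


def derive_layers(
    landscape: LandscapeStack, window: int = 3, roughness_window: int = 3
) -> dict[str, np.ndarray]:
    """All per-cell layers entering territory extraction, keyed by feature name.

    Layers are derived from whichever bands the stack carries: land-cover
    percentage layers need the six fraction bands jointly; slope and
    roughness need ``altitude``; scalar bands pass through unchanged.
    """
    layers: dict[str, np.ndarray] = {}
    if all(b in landscape.bands for b in LANDCOVER_BANDS):
        layers.update(
            landcover_percentage_layers(landcover_class_grid(landscape), window=window)
        )
    if "altitude" in landscape.bands:
        slope, rough = terrain_layers(
            landscape.bands["altitude"], landscape.resolution, roughness_window
        )
        layers["slope"] = slope
        layers["roughness"] = rough
    for name in SCALAR_BANDS:
        if name in landscape.bands:
            layers[name] = landscape.bands[name]
    return layers


class TerritoryFeatureExtractor:
    """Zonal-mean extractor with precomputed layers and disc offsets.

    Precomputing the circular-buffer cell offsets once makes repeated
    extraction over hundreds of territories cheap.
    """

    def __init__(
        self,
        landscape: LandscapeStack,
        registry: PairRegistry,
        radius_m: float | None = None,
        window: int = 3,
        roughness_window: int = 3,
    ) -> None:
        self.landscape = landscape
        self.registry = registry
        self.radius_m = (
            territory_radius(DEFAULT_TERRITORY_AREA_KM2) if radius_m is None else radius_m
        )
        self.layers = derive_layers(landscape, window, roughness_window)
        res = landscape.resolution
        r_cells = int(np.ceil(self.radius_m / res)) + 1
        dr, dc = np.mgrid[-r_cells : r_cells + 1, -r_cells : r_cells + 1]
        self._offsets = np.column_stack([dr.ravel(), dc.ravel()])
        self._offset_xy = (self._offsets + 0.0) * res  # displacement of cell centers

    def __call__(self, center, year, exclude_centers=()) -> TerritoryFeatures:
        return extract_territory_features(
            center,
            year,
            self.landscape,
            self.registry,
            self.radius_m,
            layers=self.layers,
            exclude_centers=exclude_centers,
            _offsets=self._offsets,
        )


def extract_territory_features(
    center: tuple[float, float],
    year: int,
    landscape: LandscapeStack,
    registry: PairRegistry,
    radius_m: float | None = None,
    layers: Mapping[str, np.ndarray] | None = None,
    exclude_centers: Iterable[tuple[float, float]] = (),
    _offsets: np.ndarray | None = None,
) -> TerritoryFeatures:
    """Mean of every habitat layer over the territory circle at ``center``.

    A layer value is the mean over cells whose centers fall inside the
    circle of ``radius_m`` (default: the 1000 km² territory radius).
    ``wolf_pair_density`` is the count of same-year registry centers
    within 40 km, excluding ``exclude_centers`` (the focal disperser's
    own natal/established territories).  A circle entirely off the grid
    is an error; partial overlap is allowed and the in-grid coverage
    fraction is logged and stored.
    """
    if radius_m is None:
        radius_m = territory_radius(DEFAULT_TERRITORY_AREA_KM2)
    if layers is None:
        layers = derive_layers(landscape)
    res = landscape.resolution
    nrow, ncol = landscape.shape
    cx, cy = center
    # nearest cell whose center anchors the disc
    ccol = int(np.floor((cx - landscape.origin[0]) / res))
    crow = int(np.floor((cy - landscape.origin[1]) / res))
    if _offsets is None:
        r_cells = int(np.ceil(radius_m / res)) + 1
        dr, dc = np.mgrid[-r_cells : r_cells + 1, -r_cells : r_cells + 1]
        _offsets = np.column_stack([dr.ravel(), dc.ravel()])
    rows = crow + _offsets[:, 0]
    cols = ccol + _offsets[:, 1]
    xc = landscape.origin[0] + (cols + 0.5) * res
    yc = landscape.origin[1] + (rows + 0.5) * res
    in_circle = (xc - cx) ** 2 + (yc - cy) ** 2 <= radius_m**2
    in_grid = (rows >= 0) & (rows < nrow) & (cols >= 0) & (cols < ncol)
    use = in_circle & in_grid
    n_circle = int(in_circle.sum())
    n_use = int(use.sum())
    if n_use == 0:
        raise ValueError("territory circle lies entirely outside the raster")
    coverage = n_use / n_circle
    if coverage < 1.0:
        logger.info(
            "territory at (%.0f, %.0f): %.1f%% raster coverage", cx, cy, 100 * coverage
        )
    rsel, csel = rows[use], cols[use]
    values = {name: float(grid[rsel, csel].mean()) for name, grid in layers.items()}

    others = registry.centers_for_year(year, exclude=exclude_centers)
    if len(others):
        d = np.hypot(others[:, 0] - cx, others[:, 1] - cy)
        values["wolf_pair_density"] = int((d <= WOLF_DENSITY_RADIUS_M).sum())
    else:
        values["wolf_pair_density"] = 0
    return TerritoryFeatures((float(cx), float(cy)), int(year), values, coverage)
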