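"""Planar raster stacks, study-area polygons and territory bookkeeping.

All coordinates are planar meters, x increasing east and y increasing
north.  Grids are addressed by ``(row, col)`` with row 0 at the *bottom*
of the map and values anchored at cell centers, so the cell ``(r, c)``
center sits at ``origin + ((c + 0.5) * res, (r + 0.5) * res)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely.geometry as sgeom
from shapely.geometry import Polygon

#: Land-cover fraction bands; per cell they form a composition summing to 1.
LANDCOVER_BANDS: tuple[str, ...] = (
    "forest",
    "mire",
    "mountain",
    "water",
    "agricultural",
    "human_dominated",
)

#: Continuous covariate bands (units in the docstrings of the generator).
SCALAR_BANDS: tuple[str, ...] = (
    "altitude",
    "human_density",
    "main_road_density",
    "secondary_road_density",
    "human_accessibility",
    "bear_index",
    "moose_harvest_density",
)

ALL_BANDS: tuple[str, ...] = LANDCOVER_BANDS + SCALAR_BANDS

#: Bands constrained to be non-negative (densities, index values).
NONNEGATIVE_BANDS: tuple[str, ...] = (
    "human_density",
    "main_road_density",
    "secondary_road_density",
    "human_accessibility",
    "bear_index",
    "moose_harvest_density",
)


@dataclass(frozen=True)
class LandscapeStack:
    """Multi-band habitat raster sharing one grid geometry.

    Parameters
    ----------
    bands
        Mapping band name -> 2-D float array of shape ``(nrow, ncol)``.
    resolution
        Cell edge length in meters.
    origin
        ``(x, y)`` of the grid's lower-left corner in meters.
    """

    bands: Mapping[str, np.ndarray]
    resolution: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) != 1:
            raise ValueError("all bands must share one grid shape")
        shape = shapes.pop()
        if len(shape) != 2 or min(shape) < 1:
            raise ValueError(f"bands must be non-empty 2-D grids, got {shape}")
        unknown = set(self.bands) - set(ALL_BANDS)
        if unknown:
            raise ValueError(f"unknown band names: {sorted(unknown)}")
        cover = [b for b in LANDCOVER_BANDS if b in self.bands]
        if cover:
            if set(cover) != set(LANDCOVER_BANDS):
                raise ValueError("land-cover bands must be present jointly")
            total = sum(self.bands[b] for b in LANDCOVER_BANDS)
            if not np.allclose(total, 1.0, atol=1e-9):
                raise ValueError("land-cover fractions must sum to 1 per cell")
        if "bear_index" in self.bands:
            bi = self.bands["bear_index"]
            if bi.min() < -1e-12 or bi.max() > 1 + 1e-12:
                raise ValueError("bear_index must lie in [0, 1]")
        for name in NONNEGATIVE_BANDS:
            if name in self.bands and self.bands[name].min() < -1e-12:
                raise ValueError(f"band {name!r} must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    @property
    def extent_m(self) -> tuple[float, float]:
        """(width, height) of the grid in meters."""
        nrow, ncol = self.shape
        return ncol * self.resolution, nrow * self.resolution

    def bounds_polygon(self, inset_m: float = 0.0) -> Polygon:
        """Rectangle covering the grid, optionally inset on all sides."""
        x0, y0 = self.origin
        w, h = self.extent_m
        return sgeom.box(x0 + inset_m, y0 + inset_m, x0 + w - inset_m, y0 + h - inset_m)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col); out-of-grid points clip to the edge."""
        nrow, ncol = self.shape
        col = np.clip(((np.asarray(x) - self.origin[0]) / self.resolution).astype(int), 0, ncol - 1)
        row = np.clip(((np.asarray(y) - self.origin[1]) / self.resolution).astype(int), 0, nrow - 1)
        return row, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x (per column) and y (per row) cell-center coordinates."""
        nrow, ncol = self.shape
        x = self.origin[0] + (np.arange(ncol) + 0.5) * self.resolution
        y = self.origin[1] + (np.arange(nrow) + 0.5) * self.resolution
        return x, y

    def value_at(self, band: str, x, y):
        row, col = self.index_of(x, y)
        return self.bands[band][row, col]


@dataclass(frozen=True)
class StudyArea:
    """Simple closed polygon delimiting where territories may exist."""

    polygon: Polygon

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError("study area must be a valid polygon with positive area")

    def contains(self, x, y) -> np.ndarray | bool:
        pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
        from shapely import contains_xy

        out = contains_xy(self.polygon, pts[:, 0], pts[:, 1])
        return bool(out[0]) if np.isscalar(x) else out

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Rejection-sample ``n`` points uniformly inside the polygon."""
        minx, miny, maxx, maxy = self.polygon.bounds
        out = np.empty((0, 2))
        while len(out) < n:
            m = max(4 * (n - len(out)), 16)
            x = rng.uniform(minx, maxx, m)
            y = rng.uniform(miny, maxy, m)
            keep = self.contains(x, y)
            out = np.vstack([out, np.column_stack([x, y])[keep]])
        return out[:n]


@dataclass
class PairRegistry:
    """Yearly register of existing pair-territory centers."""

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["year", "x", "y"])
    )

    def __post_init__(self) -> None:
        missing = {"year", "x", "y"} - set(self.entries.columns)
        if missing:
            raise ValueError(f"registry table missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, year: int, x: float, y: float) -> None:
        self.entries.loc[len(self.entries)] = [int(year), float(x), float(y)]

    def centers_for_year(
        self,
        year: int,
        exclude: Iterable[tuple[float, float]] = (),
        atol: float = 1.0,
    ) -> np.ndarray:
        """Centers registered in ``year``, minus any ``exclude`` centers.

        ``exclude`` removes the focal disperser's own natal/established
        territories; matching is within ``atol`` meters.
        """
        sub = self.entries[self.entries["year"] == year]
        pts = sub[["x", "y"]].to_numpy(float)
        for ex, ey in exclude:
            if len(pts) == 0:
                break
            d = np.hypot(pts[:, 0] - ex, pts[:, 1] - ey)
            pts = pts[d > atol]
        return pts


@dataclass(frozen=True)
class Disperser:
    """One successful disperser: the unit of the matched analysis."""

    id: str
    sex: str
    natal_center: tuple[float, float]
    established_center: tuple[float, float]
    year: int

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")

    @property
    def dispersal_distance(self) -> float:
        """Euclidean natal-to-established distance, meters."""
        (x0, y0), (x1, y1) = self.natal_center, self.established_center
        return float(np.hypot(x1 - x0, y1 - y0))


@dataclass(frozen=True)
class Trajectory:
    """Ordered planar track; the raw material of movement profiles."""

    points: np.ndarray
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("a trajectory needs >= 3 (x, y) points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("trajectory coordinates must be finite")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# Plain-text / TIFF serialization


def write_landscape_tiff(stack: LandscapeStack, path) -> None:
    """Write a multi-band TIFF; grid metadata travels in ImageDescription."""
    import tifffile

    names = list(stack.bands)
    data = np.stack([stack.bands[n] for n in names]).astype(np.float64)
    meta = {
        "bands": names,
        "resolution_m": stack.resolution,
        "origin": list(stack.origin),
        "row0": "bottom",
    }
    tifffile.imwrite(path, data, description=json.dumps(meta))


def read_landscape_tiff(path) -> LandscapeStack:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = json.loads(tf.pages[0].description)
    bands = {n: data[i].astype(float) for i, n in enumerate(meta["bands"])}
    return LandscapeStack(bands, meta["resolution_m"], tuple(meta["origin"]))


def write_study_area_geojson(area: StudyArea, path) -> None:
    gj = {
        "type": "Feature",
        "properties": {"units": "m"},
        "geometry": sgeom.mapping(area.polygon),
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


def read_study_area_geojson(path) -> StudyArea:
    with open(path) as fh:
        gj = json.load(fh)
    geom = gj["geometry"] if gj.get("type") == "Feature" else gj
    return StudyArea(sgeom.shape(geom))


def dispersers_to_frame(dispersers: Sequence[Disperser]) -> pd.DataFrame:
    rows = [
        {
            "id": d.id,
            "sex": d.sex,
            "natal_x": d.natal_center[0],
            "natal_y": d.natal_center[1],
            "established_x": d.established_center[0],
            "established_y": d.established_center[1],
            "year": d.year,
            "dispersal_distance_m": d.dispersal_distance,
        }
        for d in dispersers
    ]
    return pd.DataFrame(rows)


def dispersers_from_frame(df: pd.DataFrame) -> list[Disperser]:
    return [
        Disperser(
            id=str(r["id"]),
            sex=str(r["sex"]),
            natal_center=(float(r["natal_x"]), float(r["natal_y"])),
            established_center=(float(r["established_x"]), float(r["established_y"])),
            year=int(r["year"]),
        )
        for _, r in df.iterrows()
    ]


def trajectories_to_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    frames = []
    for i, tr in enumerate(trajectories):
        t = tr.timestamps if tr.timestamps is not None else np.arange(len(tr))
        frames.append(
            pd.DataFrame(
                {"id": i, "t": t, "x": tr.points[:, 0], "y": tr.points[:, 1]}
            )
        )
    return pd.concat(frames, ignore_index=True)
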