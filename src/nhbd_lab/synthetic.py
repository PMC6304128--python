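"""Synthetic landscapes, reference trajectories and disperser populations.

The generator emulates every input a field study of natal habitat-biased
dispersal (NHBD) would draw from monitoring and GIS data: spatially
autocorrelated habitat rasters, GPS-like dispersal trajectories, and a
population of dispersers whose settlement preference for natal-like
habitat is a tunable ground truth (``nhbd_strength``).
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
from scipy import ndimage

from .landscape import (
    ALL_BANDS,
    LANDCOVER_BANDS,
    SCALAR_BANDS,
    Disperser,
    LandscapeStack,
    PairRegistry,
    StudyArea,
    Trajectory,
)

logger = logging.getLogger(__name__)

#: Default marginal parameters per band, loosely emulating a boreal
#: forest-dominated landscape (means in each band's natural units).
#: Land-cover entries give the target mean share and the spread of the
#: underlying log-ratio field; scalar entries give mean and sd.
DEFAULT_BAND_PARAMS: dict[str, dict[str, float]] = {
    "forest": {"share": 0.60, "sd": 1.0},
    "mire": {"share": 0.10, "sd": 1.0},
    "mountain": {"share": 0.10, "sd": 1.0},
    "water": {"share": 0.08, "sd": 1.0},
    "agricultural": {"share": 0.07, "sd": 1.0},
    "human_dominated": {"share": 0.05, "sd": 1.0},
    "altitude": {"mean": 400.0, "sd": 150.0},
    "human_density": {"mean": 5.0, "sd": 4.0},
    "main_road_density": {"mean": 0.19, "sd": 0.08},
    "secondary_road_density": {"mean": 0.87, "sd": 0.3},
    "human_accessibility": {"mean": 10.0, "sd": 5.0},
    "bear_index": {"mean": 0.3, "sd": 0.15},
    "moose_harvest_density": {"mean": 0.3, "sd": 0.12},
}

# Practical variogram range: smoothed-noise correlation exp(-d^2/(4 sigma^2))
# drops to 0.05 (95% of the sill) at d = 2 sigma sqrt(ln 20).
_RANGE_TO_SIGMA = 1.0 / (2.0 * np.sqrt(np.log(20.0)))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _autocorrelated_field(
    shape: tuple[int, int], sigma_cells: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary unit-variance Gaussian field via smoothed white noise."""
    z = rng.standard_normal(shape)
    if sigma_cells > 0:
        z = ndimage.gaussian_filter(z, sigma_cells, mode="wrap")
        z /= z.std()
        z -= z.mean()
    return z


def generate_landscape(
    resolution_m: float,
    extent_cells: tuple[int, int],
    autocorr_range_m: float = 0.0,
    band_params: Mapping[str, Mapping[str, float]] | None = None,
    seed=None,
) -> LandscapeStack:
    """Generate a multi-band habitat raster with known autocorrelation.

    Each band is a stationary, spatially autocorrelated field (white noise
    smoothed with a Gaussian kernel) rescaled to its configured marginal
    mean/sd.  ``autocorr_range_m`` is the practical variogram range: the
    lag at which the semivariogram reaches ~95% of its sill (0 gives white
    noise).  The six land-cover bands come from independent fields pushed
    through a softmax so per-cell fractions close to 1.

    Bounded bands (densities, bear index) are clipped to their support;
    keep sd well below mean if clipping must stay rare.
    """
    nrow, ncol = extent_cells
    if nrow <= 0 or ncol <= 0:
        raise ValueError("extent_cells must be positive")
    if resolution_m <= 0:
        raise ValueError("resolution_m must be positive")
    if autocorr_range_m < 0:
        raise ValueError("autocorr_range_m must be >= 0")
    params = {k: dict(v) for k, v in DEFAULT_BAND_PARAMS.items()}
    if band_params:
        unknown = set(band_params) - set(ALL_BANDS)
        if unknown:
            raise ValueError(f"unknown band names: {sorted(unknown)}")
        for name, p in band_params.items():
            params[name].update(p)

    rng = _rng(seed)
    sigma = autocorr_range_m * _RANGE_TO_SIGMA / resolution_m
    bands: dict[str, np.ndarray] = {}

    # Compositional land cover: softmax over six log-ratio fields whose
    # offsets are the log target shares.
    logits = np.empty((len(LANDCOVER_BANDS), nrow, ncol))
    for i, name in enumerate(LANDCOVER_BANDS):
        p = params[name]
        field = _autocorrelated_field((nrow, ncol), sigma, rng) if p["sd"] > 0 else 0.0
        logits[i] = np.log(p["share"]) + p["sd"] * field
    logits -= logits.max(axis=0)
    expl = np.exp(logits)
    expl /= expl.sum(axis=0)
    for i, name in enumerate(LANDCOVER_BANDS):
        bands[name] = expl[i]

    for name in SCALAR_BANDS:
        p = params[name]
        if p["sd"] == 0:
            bands[name] = np.full((nrow, ncol), p["mean"])
            continue
        field = _autocorrelated_field((nrow, ncol), sigma, rng)
        values = p["mean"] + p["sd"] * field
        if name == "bear_index":
            values = np.clip(values, 0.0, 1.0)
        elif name != "altitude":
            values = np.clip(values, 0.0, None)
        bands[name] = values

    return LandscapeStack(bands, resolution_m, (0.0, 0.0))


def _draw_lengths(step_params: Mapping[str, float], n: int, rng) -> np.ndarray:
    dist = step_params.get("distribution", "lognormal")
    if dist == "lognormal":
        return rng.lognormal(np.log(step_params["median"]), step_params["sigma"], n)
    if dist == "fixed":
        return np.full(n, float(step_params["length"]))
    if dist == "exponential":
        return rng.exponential(step_params["mean"], n)
    raise ValueError(f"unknown step-length distribution {dist!r}")


def generate_reference_trajectories(
    n_trajectories: int = 13,
    step_params: Mapping[str, float] | None = None,
    turn_concentration: float = 2.0,
    n_steps: int = 200,
    seed=None,
) -> list[Trajectory]:
    """Simulate GPS-like dispersal tracks with CRW structure.

    Step lengths are i.i.d. from ``step_params`` (default log-normal,
    median 2 km, log-sd 0.75 — a coarse stand-in for sub-daily wolf GPS
    steps); turning angles are von Mises around 0 with the given
    concentration (``inf`` gives a straight path).  The default pool size
    of 13 matches one reference trajectory per collared disperser.
    """
    if n_trajectories < 1:
        raise ValueError("n_trajectories must be >= 1")
    if n_steps < 3:
        raise ValueError("n_steps must be >= 3 (no turning angle otherwise)")
    step_params = step_params or {"distribution": "lognormal", "median": 2000.0, "sigma": 0.75}
    rng = _rng(seed)
    out = []
    for _ in range(n_trajectories):
        lengths = _draw_lengths(step_params, n_steps, rng)
        if np.isinf(turn_concentration):
            turns = np.zeros(n_steps - 1)
        else:
            turns = rng.vonmises(0.0, turn_concentration, n_steps - 1)
        headings = rng.uniform(-np.pi, np.pi) + np.concatenate([[0.0], np.cumsum(turns)])
        steps = lengths[:, None] * np.column_stack([np.cos(headings), np.sin(headings)])
        pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        out.append(Trajectory(pts, timestamps=np.arange(n_steps + 1, dtype=float)))
    return out


DEFAULT_SEX_COUNTS = {"M": 140, "F": 131}
DEFAULT_DISPERSAL_KERNEL = {"distribution": "lognormal", "median": 50_000.0, "sigma": 1.0}


def _standardized_territory_features(
    landscape: LandscapeStack, radius_m: float
) -> np.ndarray:
    """Per-cell standardized *territory-scale* habitat features.

    Each band is replaced by its mean over the disc of ``radius_m``
    centered on the cell (edge discs shrink to in-grid cells), then
    standardized over the landscape.  Settlement preference thus compares
    habitat at the scale a territory actually occupies rather than at a
    single cell.
    """
    from scipy.signal import fftconvolve

    r = int(np.ceil(radius_m / landscape.resolution))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disc = ((xx**2 + yy**2) * landscape.resolution**2 <= radius_m**2).astype(float)
    denom = fftconvolve(np.ones(landscape.shape), disc, mode="same")
    layers = []
    for name in ALL_BANDS:
        sm = fftconvolve(landscape.bands[name], disc, mode="same") / denom
        sd = sm.std()
        if sd > 0:
            layers.append((sm - sm.mean()) / sd)
    return np.stack(layers, axis=-1)


def simulate_wolf_population(
    landscape: LandscapeStack,
    study_area: StudyArea,
    n_dispersers: int | None = None,
    sex_counts: Mapping[str, int] | None = None,
    dispersal_kernel: Mapping[str, float] | None = None,
    nhbd_strength: float = 0.0,
    n_candidate_sites: int = 20,
    seed=None,
    years: tuple[int, int] = (1998, 2012),
    max_retries: int = 20,
    settlement_radius_m: float | None = None,
) -> tuple[list[Disperser], PairRegistry]:
    """Simulate dispersers with a tunable natal-habitat settlement bias.

    Each disperser starts from a uniform natal center, draws a target
    dispersal distance from ``dispersal_kernel`` (default log-normal,
    median 50 km, log-sd 1 — populating the short/medium/long distance
    categories) and a uniform direction, then chooses among
    ``n_candidate_sites`` admissible candidate sites scattered around the
    target displacement with probability proportional to
    ``exp(nhbd_strength * similarity(natal, site))``.  Similarity is the
    negative Euclidean distance between standardized territory-scale
    habitat features — per-band disc means of radius
    ``settlement_radius_m`` (default: the 1000 km² territory radius), the
    scale a territory actually occupies — divided by ``sqrt(n_bands)``
    so one unit is roughly one per-band standard deviation.
    ``nhbd_strength = 0`` gives settlement indifferent to the natal
    habitat.

    Returns the dispersers and a registry holding every settled territory
    under its establishment year.
    """
    if not np.isfinite(nhbd_strength):
        raise ValueError("nhbd_strength must be finite")
    if n_candidate_sites < 1:
        raise ValueError("n_candidate_sites must be >= 1")
    sex_counts = dict(sex_counts or DEFAULT_SEX_COUNTS)
    if n_dispersers is None:
        n_dispersers = sum(sex_counts.values())
    elif n_dispersers != sum(sex_counts.values()):
        # honor the explicit total; split proportionally to the requested mix
        total = sum(sex_counts.values())
        m = int(round(n_dispersers * sex_counts.get("M", 0) / total)) if total else n_dispersers // 2
        sex_counts = {"M": m, "F": n_dispersers - m}
    kernel = dict(dispersal_kernel or DEFAULT_DISPERSAL_KERNEL)
    rng = _rng(seed)

    registry = PairRegistry()
    dispersers: list[Disperser] = []
    if n_dispersers == 0:
        return dispersers, registry

    if settlement_radius_m is None:
        from .features import DEFAULT_TERRITORY_AREA_KM2, territory_radius

        settlement_radius_m = territory_radius(DEFAULT_TERRITORY_AREA_KM2)
    feats = _standardized_territory_features(landscape, settlement_radius_m)
    nfeat = feats.shape[-1]

    sexes = np.array(["M"] * sex_counts.get("M", 0) + ["F"] * sex_counts.get("F", 0))
    rng.shuffle(sexes)
    natal = study_area.sample_uniform(len(sexes), rng)
    entries = []

    for i, sex in enumerate(sexes):
        nx, ny = natal[i]
        nrow, ncol = landscape.index_of(nx, ny)
        z_natal = feats[nrow, ncol]
        site = None
        for _ in range(max_retries):
            dist = _draw_lengths(kernel, 1, rng)[0]
            theta = rng.uniform(-np.pi, np.pi)
            # candidates sit on the arc at exactly the drawn distance, with
            # angular scatter of the order of a territory diameter so that
            # alternatives genuinely differ in territory-scale habitat; the
            # settled distance therefore follows the kernel by construction
            sd_theta = min(np.pi, max(0.5, 1.5 * settlement_radius_m / dist))
            angles = theta + rng.normal(0.0, sd_theta, 4 * n_candidate_sites)
            cand = np.column_stack(
                [nx + dist * np.cos(angles), ny + dist * np.sin(angles)]
            )
            cand = cand[study_area.contains(cand[:, 0], cand[:, 1])]
            if len(cand) >= n_candidate_sites:
                cand = cand[:n_candidate_sites]
                crow, ccol = landscape.index_of(cand[:, 0], cand[:, 1])
                z = feats[crow, ccol]
                sim = -np.linalg.norm(z - z_natal, axis=1) / np.sqrt(nfeat)
                w = np.exp(nhbd_strength * sim - (nhbd_strength * sim).max())
                site = cand[rng.choice(len(cand), p=w / w.sum())]
                break
        if site is None:
            logger.warning("disperser %d: no admissible candidate site; dropped", i)
            continue
        year = int(rng.integers(years[0], years[1] + 1))
        d = Disperser(
            id=f"W{i:04d}",
            sex=str(sex),
            natal_center=(float(nx), float(ny)),
            established_center=(float(site[0]), float(site[1])),
            year=year,
        )
        dispersers.append(d)
        entries.append((year, float(site[0]), float(site[1])))

    import pandas as pd

    registry = PairRegistry(pd.DataFrame(entries, columns=["year", "x", "y"]))
    return dispersers, registry
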