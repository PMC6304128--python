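"""End-to-end experiment driver: simulate -> extract -> availability ->
similarity -> fit, plus the availability-size sensitivity sweep.

Stages communicate through documented CSV/TIFF artifacts when an output
directory is given, so each stage is independently runnable and
replaceable; in-memory use composes the same stage functions directly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import availability as avail
from . import clogit, similarity, synthetic
from .features import FEATURE_COLUMNS, TerritoryFeatureExtractor, dispersal_category
from .landscape import (
    Disperser,
    LandscapeStack,
    PairRegistry,
    StudyArea,
    Trajectory,
    dispersers_to_frame,
    trajectories_to_frame,
    write_landscape_tiff,
    write_study_area_geojson,
)

logger = logging.getLogger(__name__)

DEFAULT_BUFFER_RADII_M = (25_000.0, 50_000.0, 100_000.0, 200_000.0, 300_000.0)


@dataclass
class ExperimentConfig:
    """All knobs of one experiment; serialized alongside every output."""

    seed: int = 1
    # landscape
    resolution_m: float = 500.0
    extent_cells: tuple[int, int] = (200, 200)
    autocorr_range_m: float = 10_000.0
    band_params: Mapping | None = None
    # reference trajectories
    n_profiles: int = 13
    step_params: Mapping | None = None
    turn_concentration: float = 2.0
    n_steps: int = 200
    # population
    n_dispersers: int = 200
    dispersal_kernel: Mapping | None = None
    nhbd_strength: float = 0.0
    n_candidate_sites: int = 20
    years: tuple[int, int] = (1998, 2012)
    # availability
    availability_method: str = "crw"
    buffer_radius_m: float = 100_000.0
    buffer_radii_m: tuple[float, ...] = DEFAULT_BUFFER_RADII_M
    exclusion_radius_m: float | None = None
    # similarity
    cluster_methods: tuple[str, ...] = ("kmeans", "pam", "hierarchical")
    k_values: tuple[int, ...] = similarity.K_SWEEP
    include_distance_metric: bool = True
    n_components: int = similarity.N_COMPONENTS_DEFAULT
    # model
    screen_threshold: float = 0.6
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.availability_method not in ("crw", "buffer"):
            raise ValueError("availability_method must be 'crw' or 'buffer'")
        bad = set(self.cluster_methods) - set(similarity.CLUSTER_METHODS)
        if bad:
            raise ValueError(f"unknown cluster methods: {sorted(bad)}")
        if any(k < 2 for k in self.k_values):
            raise ValueError("k values must be >= 2")
        if self.n_dispersers < 0:
            raise ValueError("n_dispersers must be >= 0")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.md5(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("extent_cells", "years", "buffer_radii_m", "cluster_methods", "k_values"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class World:
    """Everything the generator produced for one experiment."""

    landscape: LandscapeStack
    study_area: StudyArea
    trajectories: list[Trajectory]
    profiles: list[avail.MovementProfile]
    dispersers: list[Disperser]
    registry: PairRegistry


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def cluster_seed(config: ExperimentConfig) -> int:
    """Deterministic clustering seed derived from the master seed."""
    state = np.random.SeedSequence(config.seed).spawn(5)[4].generate_state(1)[0]
    return int(state % (2**31 - 1))


def simulate_world(config: ExperimentConfig) -> World:
    """Stage 1: landscape, study area, reference tracks, population."""
    rng_land, rng_traj, rng_pop = _child_rngs(config.seed, 3)
    landscape = synthetic.generate_landscape(
        config.resolution_m,
        config.extent_cells,
        config.autocorr_range_m,
        config.band_params,
        seed=rng_land,
    )
    study_area = StudyArea(landscape.bounds_polygon())
    trajectories = synthetic.generate_reference_trajectories(
        config.n_profiles,
        config.step_params,
        config.turn_concentration,
        config.n_steps,
        seed=rng_traj,
    )
    profiles = [avail.fit_movement_profile(t) for t in trajectories]
    dispersers, registry = synthetic.simulate_wolf_population(
        landscape,
        study_area,
        n_dispersers=config.n_dispersers,
        dispersal_kernel=config.dispersal_kernel,
        nhbd_strength=config.nhbd_strength,
        n_candidate_sites=config.n_candidate_sites,
        seed=rng_pop,
        years=config.years,
    )
    return World(landscape, study_area, trajectories, profiles, dispersers, registry)


def build_availability(
    config: ExperimentConfig,
    world: World,
    method: str | None = None,
    radius_m: float | None = None,
) -> dict[str, avail.AvailabilitySet]:
    """Stage 2: the 11 matched available territories per disperser.

    Dispersers for whom no admissible set can be built are skipped with a
    logged reason and drop out of the matched analysis.
    """
    method = method or config.availability_method
    radius_m = radius_m if radius_m is not None else config.buffer_radius_m
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    sets: dict[str, avail.AvailabilitySet] = {}
    for d in world.dispersers:
        try:
            if method == "crw":
                sets[d.id] = avail.crw_availability_set(
                    d, world.profiles, world.study_area, world.registry,
                    seed=rng, exclusion_radius_m=config.exclusion_radius_m,
                )
            else:
                sets[d.id] = avail.buffer_availability_set(
                    d, radius_m, world.study_area, world.registry,
                    seed=rng, exclusion_radius_m=config.exclusion_radius_m,
                )
        except avail.AvailabilityError as err:
            logger.info("availability failed: %s", err)
    return sets


def extract_records(
    config: ExperimentConfig,
    world: World,
    sets: Mapping[str, avail.AvailabilitySet],
) -> pd.DataFrame:
    """Stage 3: the long-format territory feature table.

    One row per (disperser, record): natal (point_index -1), established
    (0) and the 11 available territories (1..11), each with the Table-1
    style habitat features, the disperser's sex, establishment year and
    distance category.
    """
    extractor = TerritoryFeatureExtractor(
        world.landscape, world.registry, radius_m=config.exclusion_radius_m
    )
    rows = []
    for d in world.dispersers:
        if d.id not in sets:
            continue
        focal = (d.natal_center, d.established_center)
        recs = [("natal", -1, d.natal_center, "none", np.nan)]
        recs.append(("established", 0, d.established_center, "none", np.nan))
        for j, p in enumerate(sets[d.id].points, start=1):
            recs.append(("available", j, p.center, p.method, p.source))
        for role, idx, center, method, source in recs:
            tf = extractor(center, d.year, exclude_centers=focal)
            row = {
                "disperser_id": d.id,
                "role": role,
                "point_index": idx,
                "sex": d.sex,
                "year": d.year,
                "x": center[0],
                "y": center[1],
                "method": method,
                "source": source,
                "dispersal_distance_m": d.dispersal_distance,
                "distance_category": dispersal_category(d.dispersal_distance),
            }
            row.update({k: tf.values[k] for k in FEATURE_COLUMNS})
            rows.append(row)
    return pd.DataFrame(rows)


def fit_grid(
    config: ExperimentConfig,
    records: pd.DataFrame,
    availability_label: str,
) -> pd.DataFrame:
    """Stages 4-5: similarity definitions x model suites -> tidy grid.

    For every clustering method and cluster count the full model suite is
    fitted (per sex x distance category, plus pooled with interactions);
    the continuous natal-distance similarity metric is one extra variant,
    its coefficients reported x100 for readability.
    """
    matrix = similarity.build_feature_matrix(records, variables=list(FEATURE_COLUMNS))
    scores = similarity.pca_scores(matrix, config.n_components)
    screened = clogit.correlation_screen(
        records[list(FEATURE_COLUMNS)], config.screen_threshold
    )
    # model covariates: the declared model-variable set (keep-priority
    # list) that survived the screen — the compositional land-cover
    # percentages outside it would alias the design
    retained = [c for c in screened if c in clogit.DEFAULT_KEEP_PRIORITY]
    base = records[records["role"].isin(["established", "available"])].copy()
    base["outcome"] = (base["role"] == "established").astype(int)
    base["stratum"] = base["disperser_id"]
    mask = records["role"].isin(["established", "available"]).to_numpy()

    out = []
    cseed = cluster_seed(config)
    for method in config.cluster_methods:
        for k in config.k_values:
            model = similarity.cluster_territories(scores, method, k, seed=cseed)
            cov = similarity.nhbd_covariates(model, matrix, scores)
            df = base.copy()
            df["nhbd"] = cov["nhbd_indicator"].to_numpy()[mask]
            suite = clogit.fit_model_suite(
                df, ["nhbd"] + retained, alpha=config.alpha
            )
            suite.insert(0, "k", k)
            suite.insert(0, "similarity_method", method)
            out.append(suite)
    if config.include_distance_metric:
        cov_dist = similarity.nhbd_covariates(
            similarity.cluster_territories(scores, "kmeans", similarity.K_DEFAULT, cseed),
            matrix,
            scores,
        )
        df = base.copy()
        df["nhbd"] = cov_dist["natal_distance"].to_numpy()[mask]
        suite = clogit.fit_model_suite(df, ["nhbd"] + retained, alpha=config.alpha)
        # report the continuous-metric coefficient x100 for readability
        sel = suite["variable"].astype(str).str.startswith("nhbd")
        for col in ("beta", "se", "ci_lo", "ci_hi"):
            suite.loc[sel, col] = suite.loc[sel, col] * 100.0
        suite.loc[sel, "variable"] = suite.loc[sel, "variable"].str.replace(
            "nhbd", "natal_distance_x100", regex=False
        )
        suite.insert(0, "k", np.nan)
        suite.insert(0, "similarity_method", "dist")
        out.append(suite)
    grid = pd.concat(out, ignore_index=True)
    grid.insert(0, "availability", availability_label)
    parts = grid["group"].str.split("/", n=1, expand=True)
    if parts.shape[1] == 1:
        parts[1] = None
    grid["sex"] = parts[0].where(parts[1].notna(), None)
    grid["distance_category"] = parts[1]
    return grid


def _write_csv(df: pd.DataFrame, path: Path, config: ExperimentConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.hash()} seed={config.seed}\n")
        # %.17g round-trips float64 exactly, keeping staged reruns bit-equal
        df.to_csv(fh, index=False, float_format="%.17g")


def _dump_world(config: ExperimentConfig, world: World, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    write_landscape_tiff(world.landscape, out / "landscape.tif")
    write_study_area_geojson(world.study_area, out / "study_area.geojson")
    _write_csv(trajectories_to_frame(world.trajectories), out / "trajectories.csv", config)
    _write_csv(dispersers_to_frame(world.dispersers), out / "dispersers.csv", config)
    _write_csv(world.registry.entries, out / "registry.csv", config)


def availability_to_frame(sets: Mapping[str, avail.AvailabilitySet]) -> pd.DataFrame:
    rows = [
        {
            "disperser_id": did,
            "point_index": j,
            "x": p.center[0],
            "y": p.center[1],
            "method": p.method,
            "source": p.source,
        }
        for did, s in sets.items()
        for j, p in enumerate(s.points, start=1)
    ]
    return pd.DataFrame(rows)


def run_nhbd_analysis(config: ExperimentConfig, out_dir=None) -> pd.DataFrame:
    """Run the full experiment; deterministic under ``config.seed``.

    Returns the tidy coefficient grid (one row per availability x
    similarity-method x k x group x variable).  With ``out_dir`` every
    intermediate table is written, each CSV carrying the config hash and
    seed in a header comment.
    """
    out = Path(out_dir) if out_dir is not None else None
    stage = "simulate"
    try:
        world = simulate_world(config)
        if out:
            _dump_world(config, world, out)
        stage = "availability"
        sets = build_availability(config, world)
        if out:
            _write_csv(availability_to_frame(sets), out / "availability.csv", config)
        stage = "extract"
        records = extract_records(config, world, sets)
        if out:
            _write_csv(records, out / "territory_features.csv", config)
        stage = "similarity/fit"
        label = (
            "crw"
            if config.availability_method == "crw"
            else f"buffer_{int(config.buffer_radius_m)}"
        )
        grid = fit_grid(config, records, label)
        if out:
            _write_csv(grid, out / "result_grid.csv", config)
        return grid
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err


def buffer_sensitivity_sweep(
    config: ExperimentConfig,
    radii_m: Sequence[float] | None = None,
    out_dir=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Refit the NHBD models across buffer sizes on one simulated world.

    Returns ``(grid, trend)``: the per-radius coefficient grid and, per
    sex x distance-category x similarity definition, the Spearman rank
    correlation of the NHBD coefficient with buffer radius — the
    monotone-trend statistic for "larger availability, stronger NHBD".
    """
    radii = tuple(radii_m if radii_m is not None else config.buffer_radii_m)
    if len(radii) < 3:
        raise ValueError("the buffer sweep needs >= 3 radii (trend undefined)")
    world = simulate_world(config)
    out = Path(out_dir) if out_dir is not None else None
    if out:
        _dump_world(config, world, out)
    grids = []
    for r in radii:
        sets = build_availability(config, world, method="buffer", radius_m=r)
        records = extract_records(config, world, sets)
        grid = fit_grid(config, records, f"buffer_{int(r)}")
        grid.insert(0, "radius_m", float(r))
        grids.append(grid)
    grid = pd.concat(grids, ignore_index=True)

    nhbd = grid[grid["variable"] == "nhbd"]
    trows = []
    for (group, method, k), sub in nhbd.groupby(
        ["group", "similarity_method", "k"], dropna=False
    ):
        conv = sub[sub["converged"]]
        if len(conv) < 3:
            rho = np.nan
        else:
            rho = stats.spearmanr(conv["radius_m"], conv["beta"]).statistic
        trows.append(
            {
                "group": group,
                "similarity_method": method,
                "k": k,
                "n_radii": len(conv),
                "spearman_rho": rho,
            }
        )
    trend = pd.DataFrame(
        trows, columns=["group", "similarity_method", "k", "n_radii", "spearman_rho"]
    )
    if out:
        _write_csv(grid, out / "buffer_sweep_grid.csv", config)
        _write_csv(trend, out / "buffer_sweep_trend.csv", config)
    return grid, trend
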