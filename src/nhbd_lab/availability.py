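"""Matched availability: 11 available territories per disperser.

Two definitions are supported, mirroring the two classic ways of framing
"what was available" to a dispersing animal:

* **CRW** — correlated random walks resampled from reference movement
  profiles and endpoint-conditioned to run from the natal to the
  established center; one random vertex per walk, 11 walks from 11
  distinct profiles.
* **Buffer** — uniform points in the buffer of the straight natal to
  established line, with the buffer radius swept as a sensitivity axis.

Points must be admissible: inside the study area and at least one
territory radius away from every same-year existing pair territory and
from the focal disperser's own natal and established territories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from shapely.geometry import LineString

from .features import DEFAULT_TERRITORY_AREA_KM2, territory_radius
from .landscape import Disperser, PairRegistry, StudyArea, Trajectory

logger = logging.getLogger(__name__)

N_AVAILABLE = 11


class AvailabilityError(RuntimeError):
    """Raised when no admissible availability set can be constructed."""


class NoAdmissibleVertex(AvailabilityError):
    """A conditioned walk offered no admissible interior vertex."""


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    w = np.mod(np.asarray(a, float) + np.pi, 2 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


@dataclass(frozen=True)
class MovementProfile:
    """Empirical step-length / turning-angle samples of one reference track."""

    step_lengths: np.ndarray
    turning_angles: np.ndarray

    def __post_init__(self) -> None:
        sl = np.asarray(self.step_lengths, float)
        ta = np.asarray(self.turning_angles, float)
        if len(sl) < 2:
            raise ValueError("a movement profile needs >= 2 steps")
        if np.any(sl <= 0):
            raise ValueError("step lengths must be positive")
        if np.any((ta <= -np.pi) | (ta > np.pi)):
            raise ValueError("turning angles must lie in (-pi, pi]")
        object.__setattr__(self, "step_lengths", sl)
        object.__setattr__(self, "turning_angles", ta)

    @property
    def n_steps(self) -> int:
        return len(self.step_lengths)


@dataclass(frozen=True)
class AvailabilityPoint:
    """One available-territory center and the record of how it was drawn."""

    center: tuple[float, float]
    method: str  # 'crw' or 'buffer'
    source: int | float  # generating profile index, or buffer radius (m)


@dataclass(frozen=True)
class AvailabilitySet:
    """The 1:11 matched availability of one disperser."""

    disperser_id: str
    points: tuple[AvailabilityPoint, ...]

    def __post_init__(self) -> None:
        if len(self.points) != N_AVAILABLE:
            raise ValueError(f"an availability set must hold exactly {N_AVAILABLE} points")
        crw_sources = [p.source for p in self.points if p.method == "crw"]
        if crw_sources and len(set(crw_sources)) != len(crw_sources):
            raise ValueError("CRW points must come from distinct generating walks")


def fit_movement_profile(trajectory: Trajectory) -> MovementProfile:
    """Step lengths and signed heading changes of a trajectory.

    Zero-length steps (duplicate consecutive fixes) are dropped with a
    warning before angles are computed.
    """
    pts = trajectory.points
    keep = np.ones(len(pts), bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0
    if not keep.all():
        logger.warning("dropping %d duplicate consecutive points", (~keep).sum())
        pts = pts[keep]
    if len(pts) < 3:
        raise ValueError("too few distinct points for a movement profile")
    steps = np.diff(pts, axis=0)
    lengths = np.linalg.norm(steps, axis=1)
    headings = np.arctan2(steps[:, 1], steps[:, 0])
    turns = _wrap_angle(np.diff(headings))
    return MovementProfile(lengths, turns)


def _free_crw(
    profile: MovementProfile, n_steps: int, rng: np.random.Generator
) -> np.ndarray:
    lengths = rng.choice(profile.step_lengths, n_steps, replace=True)
    turns = rng.choice(profile.turning_angles, n_steps - 1, replace=True)
    headings = rng.uniform(-np.pi, np.pi) + np.concatenate([[0.0], np.cumsum(turns)])
    steps = lengths[:, None] * np.column_stack([np.cos(headings), np.sin(headings)])
    return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])


def simulate_conditioned_crw(
    profile: MovementProfile,
    start: tuple[float, float],
    end: tuple[float, float],
    n_steps: int | None = None,
    seed=None,
    max_retries: int = 10,
) -> Trajectory:
    """A CRW resampled from ``profile`` and pinned to run start -> end.

    A free walk (steps and turning angles resampled with replacement) is
    rigidly translated, rotated and uniformly scaled so its endpoints hit
    ``start`` and ``end``.  The similarity transform preserves the whole
    turning-angle sequence, so the walk keeps the profile's movement
    signature.
    """
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    if np.allclose(start, end):
        raise ValueError("start and end must differ")
    if n_steps is None:
        n_steps = profile.n_steps
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    span = np.linalg.norm(end - start)
    for _ in range(max_retries):
        pts = _free_crw(profile, n_steps, rng)
        chord = np.linalg.norm(pts[-1] - pts[0])
        if chord > 1e-9 * max(span, 1.0):
            break
    else:
        raise AvailabilityError("degenerate free walk: endpoints coincide repeatedly")
    z = pts[:, 0] + 1j * pts[:, 1]
    a = ((end[0] - start[0]) + 1j * (end[1] - start[1])) / (z[-1] - z[0])
    w = (start[0] + 1j * start[1]) + a * (z - z[0])
    return Trajectory(np.column_stack([w.real, w.imag]))


def is_admissible(
    point: tuple[float, float],
    study_area: StudyArea,
    registry: PairRegistry,
    year: int,
    exclusion_radius_m: float | None = None,
    focal_centers: Sequence[tuple[float, float]] = (),
) -> bool:
    """Could a territory be placed at ``point``?

    True iff the point is inside the study area and at least
    ``exclusion_radius_m`` (default: one territory radius, ~17.8 km) away
    from every same-year registry center and from each of the focal
    disperser's own centers (``focal_centers``); the focal centers'
    registry entries themselves are ignored.
    """
    mask = admissible_mask(
        np.asarray([point], float), study_area, registry, year, exclusion_radius_m, focal_centers
    )
    return bool(mask[0])


def admissible_mask(
    points: np.ndarray,
    study_area: StudyArea,
    registry: PairRegistry,
    year: int,
    exclusion_radius_m: float | None = None,
    focal_centers: Sequence[tuple[float, float]] = (),
) -> np.ndarray:
    """Vectorized admissibility over an ``(n, 2)`` array of points."""
    if exclusion_radius_m is None:
        exclusion_radius_m = territory_radius(DEFAULT_TERRITORY_AREA_KM2)
    pts = np.asarray(points, float)
    ok = np.asarray(study_area.contains(pts[:, 0], pts[:, 1]))
    others = registry.centers_for_year(year, exclude=focal_centers)
    centers = list(map(tuple, others)) + [tuple(c) for c in focal_centers]
    for cx, cy in centers:
        ok &= np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) >= exclusion_radius_m
    return ok


def sample_point_on_crw(
    trajectory: Trajectory,
    admissibility: Callable[[np.ndarray], np.ndarray],
    seed=None,
    source: int = -1,
    mode: str = "vertex",
) -> AvailabilityPoint:
    """One random admissible point on a conditioned walk.

    ``mode='vertex'`` (default) draws uniformly among admissible interior
    vertices (endpoints — the natal and established centers — excluded).
    ``mode='arc'`` draws uniformly by arc length instead.  Raises
    :class:`NoAdmissibleVertex` when the walk offers nothing admissible.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "vertex":
        interior = trajectory.points[1:-1]
        ok = np.asarray(admissibility(interior), bool)
        if not ok.any():
            raise NoAdmissibleVertex("no admissible interior vertex on this walk")
        idx = rng.choice(np.flatnonzero(ok))
        xy = interior[idx]
        return AvailabilityPoint((float(xy[0]), float(xy[1])), "crw", source)
    if mode == "arc":
        pts = trajectory.points
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        for _ in range(200):
            s = rng.uniform(0.0, cum[-1])
            i = int(np.searchsorted(cum, s, side="right") - 1)
            i = min(i, len(seg) - 1)
            frac = (s - cum[i]) / seg[i] if seg[i] > 0 else 0.0
            xy = pts[i] + frac * (pts[i + 1] - pts[i])
            if np.asarray(admissibility(xy[None, :]), bool)[0]:
                return AvailabilityPoint((float(xy[0]), float(xy[1])), "crw", source)
        raise NoAdmissibleVertex("no admissible arc-length point after 200 draws")
    raise ValueError(f"unknown sampling mode {mode!r}")


def crw_availability_set(
    disperser: Disperser,
    profiles: Sequence[MovementProfile],
    study_area: StudyArea,
    registry: PairRegistry,
    seed=None,
    exclusion_radius_m: float | None = None,
    n_steps: int | None = None,
    max_crw_retries: int = 20,
    mode: str = "vertex",
) -> AvailabilitySet:
    """11 available points from 11 distinct conditioned CRWs.

    Profiles are chosen uniformly without replacement from the pool
    (default pool: the 13 reference wolves).  A walk with no admissible
    vertex is resimulated up to ``max_crw_retries`` times, then its
    profile is swapped for an unused one; an exhausted pool fails the
    disperser.
    """
    if len(profiles) < N_AVAILABLE:
        raise ValueError(f"need >= {N_AVAILABLE} movement profiles")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = list(rng.permutation(len(profiles)))
    chosen, backups = order[:N_AVAILABLE], order[N_AVAILABLE:]
    focal = (disperser.natal_center, disperser.established_center)

    def admissibility(pts: np.ndarray) -> np.ndarray:
        return admissible_mask(
            pts, study_area, registry, disperser.year, exclusion_radius_m, focal
        )

    points: list[AvailabilityPoint] = []
    for prof_idx in list(chosen):
        idx = prof_idx
        while True:
            point = None
            for _ in range(max_crw_retries):
                walk = simulate_conditioned_crw(
                    profiles[idx],
                    disperser.natal_center,
                    disperser.established_center,
                    n_steps=n_steps,
                    seed=rng,
                )
                try:
                    point = sample_point_on_crw(walk, admissibility, rng, source=idx, mode=mode)
                    break
                except NoAdmissibleVertex:
                    continue
            if point is not None:
                points.append(point)
                break
            if not backups:
                raise AvailabilityError(
                    f"disperser {disperser.id}: CRW profile pool exhausted "
                    f"without an admissible point"
                )
            idx = backups.pop(0)
            logger.info(
                "disperser %s: profile %d exhausted, substituting profile %d",
                disperser.id,
                prof_idx,
                idx,
            )
    return AvailabilitySet(disperser.id, tuple(points))


def buffer_availability_set(
    disperser: Disperser,
    radius_m: float,
    study_area: StudyArea,
    registry: PairRegistry,
    seed=None,
    exclusion_radius_m: float | None = None,
    min_acceptance: float = 1e-4,
    batch: int = 512,
) -> AvailabilitySet:
    """11 points uniform in the buffered natal-established line.

    Points are rejection-sampled from the intersection of the straight
    natal-to-established segment's buffer (``radius_m``) with the study
    area, and must additionally be admissible.  Failure is raised when
    the empirical acceptance rate falls below ``min_acceptance``.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    line = LineString([disperser.natal_center, disperser.established_center])
    region = line.buffer(radius_m).intersection(study_area.polygon)
    if region.is_empty or region.area <= 0:
        raise AvailabilityError(f"disperser {disperser.id}: empty availability region")
    focal = (disperser.natal_center, disperser.established_center)
    minx, miny, maxx, maxy = region.bounds
    points: list[AvailabilityPoint] = []
    tried = 0
    from shapely import contains_xy

    while len(points) < N_AVAILABLE:
        x = rng.uniform(minx, maxx, batch)
        y = rng.uniform(miny, maxy, batch)
        tried += batch
        ok = contains_xy(region, x, y)
        pts = np.column_stack([x, y])[ok]
        if len(pts):
            ok2 = admissible_mask(
                pts, study_area, registry, disperser.year, exclusion_radius_m, focal
            )
            for xy in pts[ok2]:
                points.append(AvailabilityPoint((float(xy[0]), float(xy[1])), "buffer", radius_m))
                if len(points) == N_AVAILABLE:
                    break
        if tried >= batch * 20 and (len(points) / tried) < min_acceptance:
            raise AvailabilityError(
                f"disperser {disperser.id}: acceptance {len(points)}/{tried} "
                f"below floor {min_acceptance}"
            )
    return AvailabilitySet(disperser.id, tuple(points))
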