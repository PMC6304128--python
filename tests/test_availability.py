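import numpy as np
import pytest
from scipy import stats
import shapely.geometry as sgeom

from nhbd_lab import availability as av
from nhbd_lab.landscape import Disperser, PairRegistry, StudyArea, Trajectory

import pandas as pd


class TestMovementProfile:
    def test_collinear_equal_steps(self):
        pts = np.column_stack([np.arange(5) * 100.0, np.zeros(5)])
        prof = av.fit_movement_profile(Trajectory(pts))
        np.testing.assert_allclose(prof.step_lengths, 100.0)
        np.testing.assert_allclose(prof.turning_angles, 0.0, atol=1e-12)

    def test_unit_square_turns(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], float)
        prof = av.fit_movement_profile(Trajectory(pts))
        np.testing.assert_allclose(prof.turning_angles, np.pi / 2, atol=1e-12)
        assert prof.n_steps == 4

    def test_three_point_counting(self):
        prof = av.fit_movement_profile(Trajectory(np.array([[0, 0], [1, 0], [1, 2.0]])))
        assert prof.n_steps == 2 and len(prof.turning_angles) == 1

    def test_duplicate_points_dropped(self):
        pts = np.array([[0, 0], [1, 0], [1, 0], [2, 0], [3, 0.0]])
        prof = av.fit_movement_profile(Trajectory(pts))
        assert prof.n_steps == 3  # zero-length step removed


class TestConditionedCRW:
    start, end = (10_000.0, 5_000.0), (60_000.0, 42_000.0)

    def test_endpoints_pinned(self, profiles):
        for seed in range(10):
            walk = av.simulate_conditioned_crw(profiles[0], self.start, self.end, seed=seed)
            np.testing.assert_allclose(walk.points[0], self.start, atol=1e-6)
            np.testing.assert_allclose(walk.points[-1], self.end, atol=1e-6)

    def test_turning_angles_preserved(self, profiles):
        # reconstruct the free walk with the same resampling stream, then
        # compare its turning-angle sequence with the conditioned walk's
        rng = np.random.default_rng(42)
        free = av._free_crw(profiles[1], profiles[1].n_steps, rng)
        rng = np.random.default_rng(42)
        walk = av.simulate_conditioned_crw(
            profiles[1], self.start, self.end, seed=rng
        )
        a_free = av.fit_movement_profile(Trajectory(free)).turning_angles
        a_cond = av.fit_movement_profile(walk).turning_angles
        np.testing.assert_allclose(a_free, a_cond, atol=1e-9)

    def test_reconditioning_is_identity(self, profiles):
        # a walk already pinned to (start, end) maps onto itself
        walk = av.simulate_conditioned_crw(profiles[2], self.start, self.end, seed=3)
        z = walk.points[:, 0] + 1j * walk.points[:, 1]
        a = (complex(*self.end) - complex(*self.start)) / (z[-1] - z[0])
        w = complex(*self.start) + a * (z - z[0])
        np.testing.assert_allclose(np.column_stack([w.real, w.imag]), walk.points, atol=1e-9)

    def test_step_ratios_from_profile(self, profiles):
        # uniform scaling preserves step-length ratios, so every ratio of
        # conditioned steps must occur among profile step-length ratios
        walk = av.simulate_conditioned_crw(profiles[0], self.start, self.end, seed=1)
        steps = np.linalg.norm(np.diff(walk.points, axis=0), axis=1)
        ratios = steps / steps[0]
        prof_ratios = profiles[0].step_lengths / profiles[0].step_lengths[:, None]
        for r in ratios[:20]:
            assert np.any(np.isclose(prof_ratios, r, rtol=1e-9))

    def test_coincident_endpoints_rejected(self, profiles):
        with pytest.raises(ValueError):
            av.simulate_conditioned_crw(profiles[0], (0, 0), (0, 0), seed=1)


class TestAdmissibility:
    def test_outside_polygon(self, square_area, empty_registry):
        assert not av.is_admissible((-5.0, 10.0), square_area, empty_registry, 2005)

    def test_empty_registry_interior(self, square_area, empty_registry):
        assert av.is_admissible((100_000.0, 100_000.0), square_area, empty_registry, 2005)

    def test_exclusion_distance(self, square_area, registry_2005):
        # default exclusion radius ~17.8 km around the pair at (50, 50) km
        assert not av.is_admissible((60_000.0, 50_000.0), square_area, registry_2005, 2005)
        assert av.is_admissible((70_000.0, 50_000.0), square_area, registry_2005, 2005)

    def test_custom_radius(self, square_area, registry_2005):
        p = (60_000.0, 50_000.0)  # 10 km from the (50,50) km pair
        assert not av.is_admissible(p, square_area, registry_2005, 2005, 15_000.0)
        assert av.is_admissible(p, square_area, registry_2005, 2005, 9_000.0)

    def test_focal_centers_blocked(self, square_area, empty_registry):
        p = (100_000.0, 100_000.0)
        assert not av.is_admissible(
            p, square_area, empty_registry, 2005, focal_centers=[(105_000.0, 100_000.0)]
        )


class TestSamplePoint:
    def walk(self):
        pts = np.column_stack([np.linspace(0, 20_000, 22), np.zeros(22)])
        return Trajectory(pts)

    def test_single_admissible_vertex(self):
        target = self.walk().points[7]

        def adm(p):
            return np.all(np.isclose(p, target), axis=1)

        for seed in range(5):
            out = av.sample_point_on_crw(self.walk(), adm, seed=seed)
            np.testing.assert_allclose(out.center, target)

    def test_uniform_over_admissible_vertices(self):
        walk = self.walk()
        rng = np.random.default_rng(0)
        counts = np.zeros(20)
        for _ in range(10_000):
            p = av.sample_point_on_crw(walk, lambda q: np.ones(len(q), bool), rng)
            counts[int(round(p.center[0] / (20_000 / 21))) - 1] += 1
        chi = stats.chisquare(counts)
        assert chi.pvalue > 0.01

    def test_exhaustion_signalled(self):
        with pytest.raises(av.NoAdmissibleVertex):
            av.sample_point_on_crw(self.walk(), lambda q: np.zeros(len(q), bool), 0)

    def test_endpoints_never_sampled(self):
        walk = self.walk()
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = av.sample_point_on_crw(walk, lambda q: np.ones(len(q), bool), rng)
            assert 0.0 < p.center[0] < 20_000.0


@pytest.fixture
def disperser():
    return Disperser("w1", "F", (60_000.0, 60_000.0), (120_000.0, 110_000.0), 2005)


class TestCrwAvailability:
    def test_eleven_points_distinct_walks(self, disperser, profiles, square_area, empty_registry):
        s = av.crw_availability_set(disperser, profiles, square_area, empty_registry, seed=1)
        assert len(s.points) == 11
        assert len({p.source for p in s.points}) == 11
        for p in s.points:
            assert square_area.contains(*p.center)

    def test_pool_of_eleven_all_used(self, disperser, profiles, square_area, empty_registry):
        s = av.crw_availability_set(
            disperser, profiles[:11], square_area, empty_registry, seed=2
        )
        assert {p.source for p in s.points} == set(range(11))

    def test_determinism(self, disperser, profiles, square_area, empty_registry):
        s1 = av.crw_availability_set(disperser, profiles, square_area, empty_registry, seed=3)
        s2 = av.crw_availability_set(disperser, profiles, square_area, empty_registry, seed=3)
        assert [p.center for p in s1.points] == [p.center for p in s2.points]

    def test_small_pool_rejected(self, disperser, profiles, square_area, empty_registry):
        with pytest.raises(ValueError):
            av.crw_availability_set(disperser, profiles[:5], square_area, empty_registry, 1)

    def test_points_respect_focal_keepout(self, disperser, profiles, square_area, empty_registry):
        s = av.crw_availability_set(disperser, profiles, square_area, empty_registry, seed=4)
        for p in s.points:
            for focal in (disperser.natal_center, disperser.established_center):
                assert np.hypot(p.center[0] - focal[0], p.center[1] - focal[1]) >= 17_841.0

    def test_farther_dispersal_farther_available_points(self, profiles, square_area, empty_registry, rng):
        # availability tracks the dispersal route: the mean distance of
        # available points from the natal center grows with the natal-to-
        # established distance
        chords, means = [], []
        for i in range(40):
            d = float(rng.uniform(45_000, 160_000))
            theta = float(rng.uniform(0, 2 * np.pi))
            natal = np.array([100_000.0, 100_000.0])
            est = natal + d * np.array([np.cos(theta), np.sin(theta)])
            if not square_area.contains(*est):
                continue
            disp = Disperser(f"w{i}", "M", tuple(natal), tuple(est), 2005)
            s = av.crw_availability_set(disp, profiles, square_area, empty_registry, seed=rng)
            dist = [np.hypot(p.center[0] - natal[0], p.center[1] - natal[1]) for p in s.points]
            chords.append(d)
            means.append(np.mean(dist))
        rho = stats.spearmanr(chords, means).statistic
        assert rho > 0


class TestBufferAvailability:
    def test_points_within_buffer_and_area(self, disperser, profiles, square_area, empty_registry):
        radius = 30_000.0
        seg = sgeom.LineString([disperser.natal_center, disperser.established_center])
        rng = np.random.default_rng(0)
        for _ in range(40):
            s = av.buffer_availability_set(
                disperser, radius, square_area, empty_registry, seed=rng
            )
            for p in s.points:
                assert seg.distance(sgeom.Point(p.center)) <= radius + 1e-6
                assert square_area.contains(*p.center)

    def test_sweep_endpoint_radii_supported(self, disperser, square_area, empty_registry):
        for radius in (25_000.0, 300_000.0):
            s = av.buffer_availability_set(
                disperser, radius, square_area, empty_registry, seed=1
            )
            assert len(s.points) == 11

    def test_uniform_when_buffer_covers_area(self, disperser, square_area, empty_registry):
        # radius far beyond the study area: sampling reduces to uniform
        rng = np.random.default_rng(2)
        pts = []
        for _ in range(120):
            s = av.buffer_availability_set(
                disperser, 10_000_000.0, square_area, empty_registry, seed=rng,
                exclusion_radius_m=0.0,
            )
            pts.extend(p.center for p in s.points)
        pts = np.asarray(pts)
        counts, _, _ = np.histogram2d(
            pts[:, 0], pts[:, 1], bins=4, range=[[0, 200_000], [0, 200_000]]
        )
        chi = stats.chisquare(counts.ravel())
        assert chi.pvalue > 0.01

    def test_nonpositive_radius_rejected(self, disperser, square_area, empty_registry):
        with pytest.raises(ValueError):
            av.buffer_availability_set(disperser, 0.0, square_area, empty_registry, 1)
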