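"""Morphometry tests: closed-form geometry oracles and brute-force counts."""

import numpy as np
import pytest

from neuroquant.errors import FilamentTopologyError, ValidationError
from neuroquant.morphometry import (
    FilamentModel,
    PunctaSet,
    count_puncta_near_filament,
    distance_to_filament_surface,
    neurite_mean_length,
    synapse_density,
    viability_percent,
)
from neuroquant.synthetic import SceneSpec, generate_scene


def straight_filament(length=10.0, radius=0.5):
    return FilamentModel(
        node_ids=np.array([1, 2]),
        xyz=np.array([[0.0, 0.0, 0.0], [length, 0.0, 0.0]]),
        radius=np.array([radius, radius]),
        parent=np.array([-1, 1]),
    )


def brute_force_distance(point, filament):
    """Per-segment scalar-loop oracle for the capsule surface distance."""
    p0, p1, r0, r1 = filament.segments()
    best = np.inf
    for a, b, ra, rb in zip(p0, p1, r0, r1):
        ab = b - a
        denom = float(ab @ ab)
        t = float((point - a) @ ab) / denom if denom > 0 else 0.0
        t = min(max(t, 0.0), 1.0)
        close = a + t * ab
        d = float(np.linalg.norm(point - close)) - (ra + t * (rb - ra))
        best = min(best, max(d, 0.0))
    return best


class TestSurfaceDistance:
    def test_perpendicular_case(self):
        fil = straight_filament()
        assert distance_to_filament_surface(np.array([5.0, 0.0, 3.0]), fil) == \
            pytest.approx(2.5)

    def test_on_skeleton_clamps_to_zero(self):
        fil = straight_filament()
        assert distance_to_filament_surface(np.array([5.0, 0.0, 0.0]), fil) == 0.0

    def test_endpoint_cap(self):
        fil = straight_filament()
        assert distance_to_filament_surface(np.array([-2.0, 0.0, 0.0]), fil) == \
            pytest.approx(1.5)

    def test_tapered_radius_interpolation(self):
        fil = FilamentModel(node_ids=np.array([1, 2]),
                            xyz=np.array([[0.0, 0, 0], [10.0, 0, 0]]),
                            radius=np.array([1.0, 0.0]),
                            parent=np.array([-1, 1]))
        # at x = 5 the local radius is 0.5
        assert distance_to_filament_surface(np.array([5.0, 0.0, 2.0]), fil) == \
            pytest.approx(1.5)

    def test_rigid_invariance(self, rng):
        fil, pts, _ = generate_scene(SceneSpec(seed=4, n_inside=15, n_outside=15))
        d0 = distance_to_filament_surface(pts.xyz, fil)
        # random rotation via QR; det +1
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        shift = np.array([12.0, -7.0, 3.0])
        d1 = distance_to_filament_surface(
            pts.transformed(q, shift).xyz, fil.transformed(q, shift))
        np.testing.assert_allclose(d1, d0, atol=1e-9)

    def test_brute_force_oracle_random_scenes(self):
        for seed in range(5):
            fil, pts, _ = generate_scene(SceneSpec(seed=seed, n_inside=20, n_outside=20))
            fast = distance_to_filament_surface(pts.xyz, fil)
            slow = np.array([brute_force_distance(p, fil) for p in pts.xyz])
            np.testing.assert_allclose(fast, slow, atol=1e-12)


class TestCounting:
    def test_threshold_inclusive_boundary(self):
        fil = straight_filament()
        exactly = PunctaSet(np.array([[5.0, 0.0, 3.0]]))        # surface distance 2.5
        just_out = PunctaSet(np.array([[5.0, 0.0, 3.01]]))      # 2.51
        assert count_puncta_near_filament(exactly, fil) == 1
        assert count_puncta_near_filament(just_out, fil) == 0

    def test_monotone_in_threshold(self):
        fil, pts, _ = generate_scene(SceneSpec(seed=8, n_inside=25, n_outside=25))
        counts = [count_puncta_near_filament(pts, fil, th)
                  for th in [0.5, 1.0, 2.0, 2.5, 3.5, 6.0]]
        assert counts == sorted(counts)

    def test_construction_count_exact(self):
        fil, pts, truth = generate_scene(SceneSpec(seed=1))
        assert count_puncta_near_filament(pts, fil) == truth.n_inside == 30

    def test_fast_equals_brute_force_count(self):
        for seed in [2, 3]:
            fil, pts, _ = generate_scene(SceneSpec(seed=seed, n_inside=100, n_outside=100))
            fast = count_puncta_near_filament(pts, fil)
            slow = sum(brute_force_distance(p, fil) <= 2.5 for p in pts.xyz)
            assert fast == slow


class TestDensity:
    def test_arithmetic(self):
        # 12 puncta in 400 um^3 is 3 per 100 um^3; use a filament whose
        # frustum volume is exactly 400: cylinder r with pi r^2 L = 400
        length = 50.0
        radius = np.sqrt(400.0 / (np.pi * length))
        fil = straight_filament(length=length, radius=radius)
        assert fil.volume_um3 == pytest.approx(400.0, rel=1e-12)
        res = synapse_density(12, fil)
        assert res.density_per_100um3 == pytest.approx(3.0, rel=1e-12)
        assert res.density_per_100um == pytest.approx(100 * 12 / length, rel=1e-12)

    def test_cylinder_volume(self):
        fil = straight_filament(length=10.0, radius=0.5)
        assert fil.volume_um3 == pytest.approx(np.pi * 0.25 * 10.0, rel=1e-12)

    def test_zero_included(self):
        res = synapse_density(0, straight_filament())
        assert res.density_per_100um3 == 0.0

    def test_shell_density_recovery(self):
        """Puncta placed uniformly in the 2.5 um shell come back at the
        constructed density within 10% for n >= 200."""
        spec = SceneSpec(seed=11, n_inside=250, n_outside=50, n_nodes=12)
        fil, pts, truth = generate_scene(spec)
        counted = count_puncta_near_filament(pts, fil, truth.threshold_um)
        assert abs(counted - truth.n_inside) / truth.n_inside < 0.10


class TestLengthsAndViability:
    def test_mean_of_lengths(self):
        fils = [straight_filament(length) for length in (100.0, 200.0, 300.0)]
        assert neurite_mean_length(fils) == pytest.approx(200.0)
        assert neurite_mean_length(fils[:1]) == pytest.approx(100.0)

    def test_polyline_length(self):
        fil = FilamentModel(node_ids=np.array([1, 2, 3]),
                            xyz=np.array([[0.0, 0, 0], [3.0, 4.0, 0], [3.0, 4.0, 12.0]]),
                            radius=np.array([0.5, 0.5, 0.5]),
                            parent=np.array([-1, 1, 2]))
        assert fil.total_length_um == pytest.approx(17.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            neurite_mean_length([])

    @pytest.mark.parametrize("live,dead,expected", [
        (60, 40, 60.0), (0, 10, 0.0), (67, 33, 67.0)])
    def test_viability(self, live, dead, expected):
        assert viability_percent(live, dead).percent_viable == pytest.approx(expected)

    def test_viability_degenerate(self):
        with pytest.raises(ValidationError):
            viability_percent(0, 0)


class TestFilamentValidation:
    def test_dangling_parent(self):
        with pytest.raises(FilamentTopologyError):
            FilamentModel(node_ids=np.array([1, 2]),
                          xyz=np.zeros((2, 3)), radius=np.zeros(2),
                          parent=np.array([-1, 99]))

    def test_negative_radius(self):
        with pytest.raises(ValidationError):
            FilamentModel(node_ids=np.array([1, 2]),
                          xyz=np.zeros((2, 3)), radius=np.array([0.5, -0.1]),
                          parent=np.array([-1, 1]))

    def test_cycle_detected(self):
        with pytest.raises(FilamentTopologyError):
            FilamentModel(node_ids=np.array([1, 2]),
                          xyz=np.zeros((2, 3)), radius=np.zeros(2),
                          parent=np.array([2, 1]))
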