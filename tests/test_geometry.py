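"""Geometric kernels: vertices, containment, distance, overlap volume."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcfperc.geometry import (
    FibrilDomain,
    Platelet,
    inclination_deg,
    inside_tolerance_cylinder,
    min_distance,
    overlap_volume,
    platelet_vertices,
    platelet_volume,
)

from conftest import make_cube, rot_about
from oracles import (
    oracle_min_distance,
    oracle_overlap_volume,
    random_platelet,
    random_rotation,
)


class TestVerticesAndVolume:
    def test_unit_cube_corners(self):
        verts = platelet_vertices(make_cube())
        expected = {
            (sx * 0.5, sy * 0.5, sz * 0.5)
            for sx in (-1, 1)
            for sy in (-1, 1)
            for sz in (-1, 1)
        }
        assert {tuple(np.round(v, 12)) for v in verts} == expected

    def test_rotation_about_l_exchanges_width_thickness_offsets(self):
        p = Platelet(0, np.zeros(3), [1.0, 0.25, 3.0], rot_about("L", 90))
        verts = platelet_vertices(p)
        # after a 90 deg spin the W extent comes from the thickness axis
        assert np.ptp(verts[:, 0]) == pytest.approx(0.5, abs=1e-12)
        assert np.ptp(verts[:, 1]) == pytest.approx(2.0, abs=1e-12)

    def test_vertices_at_half_dims_norm_from_centroid(self, rng):
        p = random_platelet(rng)
        verts = platelet_vertices(p)
        d = np.linalg.norm(verts - p.centroid, axis=1)
        assert np.allclose(d, np.linalg.norm(p.half_dims), atol=1e-9)

    @pytest.mark.parametrize(
        "half_dims, expected",
        [((1, 1, 1), 8.0), ((45, 1.75, 55), 34650.0)],
    )
    def test_volume(self, half_dims, expected):
        p = Platelet(0, np.zeros(3), np.array(half_dims, float))
        assert platelet_volume(p) == pytest.approx(expected, rel=1e-12)

    def test_volume_rotation_invariant(self, rng):
        h = np.array([2.0, 0.5, 7.0])
        v0 = platelet_volume(Platelet(0, np.zeros(3), h))
        v1 = platelet_volume(Platelet(0, np.zeros(3), h, random_rotation(rng)))
        assert v0 == v1


class TestToleranceCylinder:
    def test_small_cube_at_center(self, domain50):
        assert inside_tolerance_cylinder(
            make_cube(center=(0, 0, 500)), domain50
        )

    def test_vertex_beyond_tolerance_radius(self, domain50):
        # vertex at radial distance 1.06 * R
        c = 1.06 * 25.0 - 0.5
        p = Platelet(0, [c, 0, 500], [0.5, 1e-3, 0.5])
        assert not inside_tolerance_cylinder(p, domain50)

    def test_vertex_exactly_on_tolerance_boundary_closed(self, domain50):
        c = 1.05 * 25.0 - 0.5
        p = Platelet(0, [c, 0, 500], [0.5, 1e-3, 0.5])
        assert inside_tolerance_cylinder(p, domain50)

    def test_longitudinal_slack_is_centered(self, domain50):
        p = Platelet(0, [0, 0, -20], [0.5, 0.5, 4.9])
        assert inside_tolerance_cylinder(p, domain50)
        p2 = Platelet(0, [0, 0, -21], [0.5, 0.5, 5.0])
        assert not inside_tolerance_cylinder(p2, domain50)


class TestMinDistance:
    def test_coincident_platelets(self):
        a, b = make_cube(0), make_cube(1)
        assert min_distance(a, b) == 0.0

    def test_face_to_face_gap(self):
        assert min_distance(
            make_cube(0), make_cube(1, center=(3, 0, 0))
        ) == pytest.approx(2.0, abs=1e-9)

    def test_rotated_cube_against_sampling_oracle(self):
        a = make_cube(0)
        b = make_cube(1, center=(3, 0, 0), R=rot_about("L", 45))
        d = min_distance(a, b)
        # edge of the rotated cube faces the flat face of the first
        assert d == pytest.approx(2.5 - np.sqrt(2) / 2, abs=1e-9)
        assert abs(d - oracle_min_distance(a, b)) < 1e-3

    def test_symmetry_and_oracle_on_random_pairs(self, rng):
        for _ in range(25):
            a = random_platelet(rng, 0)
            b = random_platelet(rng, 1)
            d = min_distance(a, b)
            assert d == pytest.approx(min_distance(b, a), abs=1e-9)
            if d > 0:
                assert abs(d - oracle_min_distance(a, b)) < 1e-3

    def test_axis_aligned_matches_interval_arithmetic(self, rng):
        for _ in range(50):
            ha, hb = rng.uniform(0.2, 2.0, 3), rng.uniform(0.2, 2.0, 3)
            ca, cb = rng.uniform(-3, 3, 3), rng.uniform(-3, 3, 3)
            a = Platelet(0, ca, ha)
            b = Platelet(1, cb, hb)
            gaps = np.maximum(np.abs(cb - ca) - (ha + hb), 0.0)
            assert min_distance(a, b) == pytest.approx(
                np.linalg.norm(gaps), abs=1e-9
            )


class TestOverlapVolume:
    def test_identical_unit_cubes(self):
        assert overlap_volume(make_cube(0), make_cube(1)) == pytest.approx(1.0)

    def test_half_offset_slab(self):
        assert overlap_volume(
            make_cube(0), make_cube(1, center=(0.5, 0, 0))
        ) == pytest.approx(0.5, abs=1e-12)

    def test_rotated_pair_against_monte_carlo(self, rng):
        a = make_cube(0)
        b = make_cube(1, center=(0.8, 0.1, 0.0), R=rot_about("L", 30))
        v = overlap_volume(a, b)
        est, se = oracle_overlap_volume(a, b, rng, n=2_000_000)
        assert abs(v - est) < max(0.01 * v, 4 * se)

    def test_axis_aligned_matches_interval_arithmetic(self, rng):
        for _ in range(50):
            ha, hb = rng.uniform(0.2, 2.0, 3), rng.uniform(0.2, 2.0, 3)
            ca, cb = rng.uniform(-1.5, 1.5, 3), rng.uniform(-1.5, 1.5, 3)
            ov = np.maximum(
                np.minimum(ca + ha, cb + hb) - np.maximum(ca - ha, cb - hb),
                0.0,
            )
            assert overlap_volume(
                Platelet(0, ca, ha), Platelet(1, cb, hb)
            ) == pytest.approx(np.prod(ov), abs=1e-9)

    def test_bounded_by_smaller_volume_and_symmetric(self, rng):
        for _ in range(100):
            a = random_platelet(rng, 0, center_scale=1.0)
            b = random_platelet(rng, 1, center_scale=1.0)
            v = overlap_volume(a, b)
            assert v == pytest.approx(overlap_volume(b, a), abs=1e-9)
            assert v <= min(platelet_volume(a), platelet_volume(b)) + 1e-9

    def test_zero_iff_positive_distance(self, rng):
        for _ in range(100):
            a = random_platelet(rng, 0, center_scale=1.5)
            b = random_platelet(rng, 1, center_scale=1.5)
            d = min_distance(a, b)
            v = overlap_volume(a, b)
            if d > 1e-9:
                assert v == 0.0
            if v > 1e-9:
                assert d == 0.0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    shift=st.lists(
        st.floats(-50, 50, allow_nan=False), min_size=3, max_size=3
    ),
    seed=st.integers(0, 2**16),
)
def test_rigid_motion_invariance(shift, seed):
    """Applying one rigid motion to both platelets changes neither the
    minimum distance nor the overlap volume."""
    rng = np.random.default_rng(seed)
    a = random_platelet(rng, 0, center_scale=1.2)
    b = random_platelet(rng, 1, center_scale=1.2)
    Q = random_rotation(rng)
    t = np.asarray(shift)
    am = Platelet(0, Q @ a.centroid + t, a.half_dims, Q @ a.orientation)
    bm = Platelet(1, Q @ b.centroid + t, b.half_dims, Q @ b.orientation)
    assert min_distance(am, bm) == pytest.approx(
        min_distance(a, b), abs=1e-6
    )
    assert overlap_volume(am, bm) == pytest.approx(
        overlap_volume(a, b), abs=1e-6
    )


class TestInclination:
    def test_identity_is_aligned(self):
        assert inclination_deg(make_cube()) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "axis, deg, expected", [("W", 20, 20), ("T", 90, 90), ("T", 20, 20)]
    )
    def test_rotations(self, axis, deg, expected):
        p = make_cube(R=rot_about(axis, deg))
        assert inclination_deg(p) == pytest.approx(expected, abs=1e-9)

    def test_spin_about_l_does_not_incline(self):
        p = make_cube(R=rot_about("L", 45))
        assert inclination_deg(p) == pytest.approx(0.0, abs=1e-9)


class TestPlateletValidation:
    def test_rejects_nonpositive_dims(self):
        with pytest.raises(ValueError):
            Platelet(0, np.zeros(3), [1.0, -1.0, 1.0])

    def test_rejects_non_orthonormal_orientation(self):
        with pytest.raises(ValueError):
            Platelet(0, np.zeros(3), [1, 1, 1], np.eye(3) * 1.01)

    def test_rejects_reflection(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            Platelet(0, np.zeros(3), [1, 1, 1], R)
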