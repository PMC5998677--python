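"""Angulation conventions, pose bookkeeping and homogeneous transforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation as ScipyRotation

from avp.geometry import (
    AffineTransform9,
    Angulation,
    GimbalLockError,
    HomogeneousTransform,
    RigidTransform,
    VoxelSpec,
    angulation_from_rotation,
    canonical_angle,
    delta_pose,
    rotation_from_angulation,
    voxel_corners,
)

TABLE_POSES = {
    "template": ((32.0, 25.0, 22.5), (7.0, 20.0, 15.0)),
    "extreme_a": ((23.0, 20.0, 35.0), (16.9, 5.8, 25.3)),
    "extreme_b": ((50.0, -1.4, 27.0), (15.9, 3.3, -1.7)),
    "extreme_c": ((19.0, 13.0, 32.0), (15.8, 1.7, 27.4)),
}


def spec_for(name, dims=(15.0, 20.0, 15.0)):
    center, angles = TABLE_POSES[name]
    return VoxelSpec("demo", name, dims, center, Angulation(*angles))


class TestRotationFromAngulation:
    def test_zero_angles_give_identity(self):
        assert np.allclose(rotation_from_angulation(Angulation(0, 0, 0)),
                           np.eye(3))

    def test_quarter_turn_about_x_maps_y_to_z(self):
        r = rotation_from_angulation(Angulation(90, 0, 0))
        assert np.allclose(r @ [0, 1, 0], [0, 0, 1], atol=1e-12)

    @pytest.mark.parametrize("angles", [a for _, a in TABLE_POSES.values()])
    def test_round_trip_on_study_poses(self, angles):
        r = rotation_from_angulation(Angulation(*angles))
        back = angulation_from_rotation(r)
        assert np.allclose(back.as_tuple(), angles, atol=1e-6)

    def test_matches_scipy_intrinsic_zyx(self):
        """Independent oracle: R = Rz(rot) Ry(t_c) Rx(t_s)."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            ts, tc, rz = rng.uniform(-179, 179, 3)
            ours = rotation_from_angulation(Angulation(ts, tc, rz))
            ref = ScipyRotation.from_euler(
                "ZYX", [rz, tc, ts], degrees=True
            ).as_matrix()
            assert np.allclose(ours, ref, atol=1e-12)

    def test_always_proper_rotation(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            r = rotation_from_angulation(Angulation(*rng.uniform(-180, 180, 3)))
            assert np.allclose(r.T @ r, np.eye(3), atol=1e-12)
            assert np.isclose(np.linalg.det(r), 1.0)

    def test_non_finite_angle_rejected(self):
        with pytest.raises(ValueError):
            rotation_from_angulation(Angulation(np.nan, 0, 0))


class TestAngulationFromRotation:
    def test_identity_decomposes_to_zero(self):
        assert angulation_from_rotation(np.eye(3)).as_tuple() == (0, 0, 0)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError):
            angulation_from_rotation(np.eye(3) * 1.1)

    def test_gimbal_lock_is_an_explicit_error(self):
        r = rotation_from_angulation(Angulation(10, 90, 5))
        with pytest.raises(GimbalLockError):
            angulation_from_rotation(r)

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(
        ts=st.floats(-179.9, 180.0),
        tc=st.floats(-88.9, 88.9),
        rz=st.floats(-179.9, 180.0),
    )
    def test_round_trip_away_from_gimbal_lock(self, ts, tc, rz):
        a = Angulation(ts, tc, rz)
        back = angulation_from_rotation(rotation_from_angulation(a))
        assert np.allclose(back.as_tuple(), a.as_tuple(), atol=1e-6)
        m = rotation_from_angulation(back)
        assert np.allclose(m, rotation_from_angulation(a), atol=1e-9)


class TestCanonicalization:
    @pytest.mark.parametrize(
        "raw,expected",
        [(190.0, -170.0), (-190.0, 170.0), (180.0, 180.0), (-180.0, 180.0),
         (360.0, 0.0), (15.0, 15.0)],
    )
    def test_canonical_range(self, raw, expected):
        assert canonical_angle(raw) == pytest.approx(expected)

    def test_angulation_canonicalizes_on_construction(self):
        assert Angulation(270, -180, 540).as_tuple() == (-90.0, 180.0, 180.0)


class TestDeltaPose:
    @pytest.mark.parametrize(
        "other,dt,dr",
        [
            ("extreme_a", (-9.0, -5.0, 12.5), (9.9, -14.2, 10.3)),
            ("extreme_b", (18.0, -26.4, 4.5), (8.9, -16.7, -16.7)),
            ("extreme_c", (-13.0, -12.0, 9.5), (8.8, -18.3, 12.4)),
        ],
    )
    def test_template_to_extreme_bookkeeping(self, other, dt, dr):
        got_dt, got_dr = delta_pose(spec_for("template"), spec_for(other))
        assert np.allclose(got_dt, dt, atol=1e-12)
        assert np.allclose(got_dr, dr, atol=1e-12)

    def test_self_difference_is_zero(self):
        dt, dr = delta_pose(spec_for("template"), spec_for("template"))
        assert np.all(dt == 0) and np.all(dr == 0)

    def test_antisymmetric(self):
        a, b = spec_for("template"), spec_for("extreme_b")
        dt_ab, dr_ab = delta_pose(a, b)
        dt_ba, dr_ba = delta_pose(b, a)
        assert np.allclose(dt_ab, -dt_ba) and np.allclose(dr_ab, -dr_ba)

    def test_mismatched_frames_rejected(self):
        a = spec_for("template")
        b = VoxelSpec("demo", "x", a.dims, a.center, a.angulation,
                      orientation="RAS")
        with pytest.raises(ValueError):
            delta_pose(a, b)


class TestVoxelCorners:
    def test_axis_aligned_cube(self):
        spec = VoxelSpec("s", "d", (2, 2, 2), (0, 0, 0), Angulation(0, 0, 0))
        corners = voxel_corners(spec)
        expected = {(sx, sy, sz) for sx in (-1, 1) for sy in (-1, 1)
                    for sz in (-1, 1)}
        assert {tuple(np.round(c, 12)) for c in corners} == expected

    def test_centroid_is_center_under_rotation(self):
        spec = spec_for("extreme_a")
        assert np.allclose(voxel_corners(spec).mean(axis=0), spec.center,
                           atol=1e-12)

    def test_edges_recover_dims_under_rotation(self):
        spec = spec_for("template")
        corners = voxel_corners(spec)
        # corner k has sign pattern of bits of k; edges flip exactly one axis
        lengths = {0: [], 1: [], 2: []}
        for i in range(8):
            for axis, bit in enumerate((4, 2, 1)):
                j = i ^ bit
                if j > i:
                    lengths[axis].append(np.linalg.norm(corners[i] - corners[j]))
        for axis, dim in enumerate(spec.dims):
            assert np.allclose(lengths[axis], dim, atol=1e-9)
            assert len(lengths[axis]) == 4


class TestVoxelSpecValidation:
    def test_nominal_volume(self, dlpfc_spec):
        assert dlpfc_spec.nominal_volume == pytest.approx(4500.0)

    @pytest.mark.parametrize("dims", [(0, 1, 1), (-2, 5, 5)])
    def test_nonpositive_dims_rejected(self, dims):
        with pytest.raises(ValueError):
            VoxelSpec("s", "d", dims, (0, 0, 0), Angulation(0, 0, 0))

    @pytest.mark.parametrize("label", ["LAX", "LLS", "AB", "XYZ", "LAA"])
    def test_bad_orientation_labels_rejected(self, label):
        with pytest.raises(ValueError):
            VoxelSpec("s", "d", (1, 1, 1), (0, 0, 0), Angulation(0, 0, 0),
                      orientation=label)

    @pytest.mark.parametrize("label", ["LAS", "RAS", "PIL", "SLA"])
    def test_valid_orientation_labels_accepted(self, label):
        spec = VoxelSpec("s", "d", (1, 1, 1), (0, 0, 0), Angulation(0, 0, 0),
                         orientation=label)
        assert spec.orientation == label


class TestTransforms:
    def rand_rigid(self, rng):
        return RigidTransform.from_parts(
            rotation_from_angulation(rng.uniform(-90, 90, 3)),
            rng.uniform(-20, 20, 3),
        )

    def test_rigid_requires_proper_rotation(self):
        m = np.eye(4)
        m[:3, :3] = np.diag([1, 1, -1])
        with pytest.raises(ValueError):
            RigidTransform(m)
        m[:3, :3] = np.eye(3) * 1.01
        with pytest.raises(ValueError):
            RigidTransform(m)

    def test_composition_associative_and_inverse(self):
        rng = np.random.default_rng(2)
        a, b, c = (self.rand_rigid(rng) for _ in range(3))
        left = (a @ b) @ c
        right = a @ (b @ c)
        assert np.allclose(left.matrix, right.matrix, atol=1e-9)
        ident = a @ a.inverse()
        assert np.allclose(ident.matrix, np.eye(4), atol=1e-9)

    def test_rigid_apply_preserves_distances(self):
        rng = np.random.default_rng(3)
        t = self.rand_rigid(rng)
        p = rng.uniform(-50, 50, (10, 3))
        d0 = np.linalg.norm(p[None] - p[:, None], axis=-1)
        q = t.apply(p)
        d1 = np.linalg.norm(q[None] - q[:, None], axis=-1)
        assert np.allclose(d0, d1, atol=1e-9)

    def test_affine9_decomposition(self):
        r = rotation_from_angulation((10, -20, 30))
        t = AffineTransform9.from_parts(r, (1.1, 0.9, 1.05), (1, 2, 3),
                                        center=(5, -5, 0))
        assert np.allclose(t.rotation, r, atol=1e-9)
        assert np.allclose(t.scales, (1.1, 0.9, 1.05), atol=1e-9)

    def test_affine9_rejects_shear(self):
        m = np.eye(4)
        m[0, 1] = 0.2
        with pytest.raises(ValueError):
            AffineTransform9(m)

    def test_affine9_scaling_about_center_fixes_center(self):
        t = AffineTransform9.from_parts(None, (1.1, 1.1, 1.1), (0, 0, 0),
                                        center=(10, 20, 30))
        assert np.allclose(t.apply(np.array([10.0, 20, 30])), [10, 20, 30])
        assert np.allclose(t.apply(np.array([20.0, 20, 30])), [21, 20, 30])
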