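"""Rigid+scale alignment, the kernel-flow deformation, and curve transport."""

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from endocompare.curves import CurveSet, LabeledCurve
from endocompare.registration import (DeformationModel, align_rigid_scale,
                                      register_diffeo, transport_curves,
                                      transport_points, varifold_distance)


class TestAlignRigidScale:
    def test_self_alignment_is_identity(self, ellipsoid_mesh):
        tf = align_rigid_scale(ellipsoid_mesh, ellipsoid_mesh)
        assert tf.scale == pytest.approx(1.0, abs=1e-6)
        assert np.linalg.norm(tf.translation) < 1e-4
        assert tf.rotation_angle_deg() < 0.01

    def test_recovers_scale_and_rotation(self, ellipsoid_mesh):
        R = Rotation.from_euler("z", 10, degrees=True).as_matrix()
        m = np.eye(4)
        m[:3, :3] = 1.2 * R
        m[:3, 3] = [4.0, -2.0, 3.0]
        target = ellipsoid_mesh.copy()
        target.apply_transform(m)
        tf = align_rigid_scale(ellipsoid_mesh, target)
        assert tf.scale == pytest.approx(1.2, abs=0.01)
        err = tf.rotation @ R.T
        ang = np.degrees(np.linalg.norm(Rotation.from_matrix(err).as_rotvec()))
        assert ang < 0.5

    def test_mean_distance_not_worse_than_init(self, ellipsoid_mesh, rng):
        # monotone acceptance: final mean closest-point (surface) distance
        # never exceeds the centroid-alignment initialization
        from endocompare.geometry import SurfaceDistanceQuery
        target = ellipsoid_mesh.copy()
        target.apply_translation([5.0, 3.0, -2.0])
        target.vertices += rng.normal(0, 0.3, target.vertices.shape)
        tf = align_rigid_scale(ellipsoid_mesh, target)
        q = SurfaceDistanceQuery(np.asarray(target.vertices), np.asarray(target.faces))
        src = np.asarray(ellipsoid_mesh.vertices)
        d_init = q.query(src + (np.asarray(target.vertices).mean(0) - src.mean(0)))[1].mean()
        d_final = q.query(tf.apply(src))[1].mean()
        assert d_final <= d_init + 1e-9

    def test_degenerate_source_rejected(self):
        flat = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]],
            faces=[[0, 1, 2], [1, 3, 2]], process=False)
        with pytest.raises(ValueError, match="degenerate"):
            align_rigid_scale(flat, flat)


class TestDeformationModel:
    def test_zero_momenta_is_identity(self, rng):
        m = DeformationModel(control_points=rng.normal(size=(7, 3)),
                             momenta=np.zeros((7, 3)), kernel_width=10.0)
        pts = rng.normal(size=(30, 3))
        np.testing.assert_allclose(transport_points(m, pts), pts, atol=1e-12)

    def test_save_load_round_trip(self, tmp_path, rng):
        m = DeformationModel(control_points=rng.normal(size=(5, 3)),
                             momenta=rng.normal(size=(5, 3)) * 0.1,
                             kernel_width=12.0, n_timesteps=8)
        m.save(tmp_path / "m.json")
        back = DeformationModel.load(tmp_path / "m.json")
        pts = rng.normal(size=(10, 3)) * 5
        np.testing.assert_allclose(transport_points(back, pts),
                                   transport_points(m, pts), atol=1e-12)

    def test_invariants(self, rng):
        with pytest.raises(ValueError):
            DeformationModel(np.zeros((3, 3)), np.zeros((4, 3)), 10.0)
        with pytest.raises(ValueError):
            DeformationModel(np.zeros((3, 3)), np.zeros((3, 3)), -1.0)


@pytest.fixture(scope="module")
def translated_sphere_result():
    s = trimesh.creation.icosphere(subdivisions=3, radius=20.0)
    t = s.copy()
    t.apply_translation([5.0, 0, 0])
    res = register_diffeo(s, t, kernel_width=15.0, data_kernel_width=5.0,
                          n_control_points=500, max_iters=30)
    return s, t, res


class TestRegisterDiffeo:
    def test_self_registration_keeps_zero_momenta(self):
        s = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
        res = register_diffeo(s, s, n_control_points=100, max_iters=10)
        assert np.abs(res.model.momenta).max() == 0.0
        assert res.final_data_term <= 1e-8 * max(res.initial_data_term, 1.0)

    def test_translated_sphere_data_term_reduction(self, translated_sphere_result):
        _, _, res = translated_sphere_result
        assert res.final_data_term <= 0.10 * res.initial_data_term

    def test_energy_trace_non_increasing(self, translated_sphere_result):
        _, _, res = translated_sphere_result
        tr = np.asarray(res.energy_trace)
        assert np.all(np.diff(tr) <= 1e-9)

    def test_no_face_inversions(self, translated_sphere_result):
        s, _, res = translated_sphere_result
        dots = np.einsum("ij,ij->i", s.face_normals, res.deformed_source.face_normals)
        assert np.all(dots > 0)

    def test_transport_reproduces_deformed_source(self, translated_sphere_result):
        s, _, res = translated_sphere_result
        moved = transport_points(res.model, np.asarray(s.vertices, float))
        err = np.abs(moved - np.asarray(res.deformed_source.vertices)).max()
        assert err < 1e-6

    def test_transported_curves_stay_near_deformed_surface(self, translated_sphere_result):
        s, _, res = translated_sphere_result
        v = np.asarray(s.vertices)
        curve = LabeledCurve(points=v[:8], label="central", side="left", strength=0.5)
        out = transport_curves(res.model, CurveSet(curves=[curve], source="brain-hull"))
        assert out[0].label == "central" and out[0].side == "left"
        from endocompare.geometry import closest_point_on_surface
        _, d = closest_point_on_surface(out[0].points, res.deformed_source.vertices,
                                        res.deformed_source.faces)
        assert d.max() <= 2.0 * 5.0  # within 2 x data kernel width

    def test_cycle_consistency(self):
        # forward then backward registration returns points near the start
        s = trimesh.creation.icosphere(subdivisions=2, radius=15.0)
        t = trimesh.creation.icosphere(subdivisions=2, radius=15.0)
        t.apply_translation([3.0, 0, 0])
        fwd = register_diffeo(s, t, kernel_width=12.0, data_kernel_width=4.0,
                              n_control_points=200, max_iters=20)
        bwd = register_diffeo(fwd.deformed_source, s, kernel_width=12.0,
                              data_kernel_width=4.0, n_control_points=200, max_iters=20)
        back = transport_points(bwd.model,
                                np.asarray(fwd.deformed_source.vertices, float))
        err = np.linalg.norm(back - np.asarray(s.vertices), axis=1).mean()
        assert err < 1.0  # documented tolerance on this fixture

    def test_invalid_kernels_rejected(self):
        s = trimesh.creation.icosphere(subdivisions=1, radius=5.0)
        with pytest.raises(ValueError):
            register_diffeo(s, s, kernel_width=-1.0)


class TestVarifold:
    def test_zero_for_identical_surfaces(self):
        s = trimesh.creation.icosphere(subdivisions=2, radius=8.0)
        assert varifold_distance(s, s, sigma=4.0) == pytest.approx(0.0, abs=1e-6)

    def test_orientation_insensitive(self):
        s = trimesh.creation.icosphere(subdivisions=2, radius=8.0)
        flipped = s.copy()
        flipped.invert()
        t = trimesh.creation.icosphere(subdivisions=2, radius=9.0)
        assert varifold_distance(s, t, 4.0) == pytest.approx(
            varifold_distance(flipped, t, 4.0), rel=1e-9)

    def test_grows_with_separation(self):
        s = trimesh.creation.icosphere(subdivisions=2, radius=8.0)
        prev = 0.0
        for shift in (1.0, 2.0, 4.0):
            t = s.copy()
            t.apply_translation([shift, 0, 0])
            d = varifold_distance(s, t, 4.0)
            assert d > prev
            prev = d
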