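"""Landmark alignment, rigid ICP, non-rigid template fitting."""

import numpy as np
import pytest
from scipy.optimize import minimize

import homoshape as hs
from homoshape.geometry import SurfaceQuery
from homoshape.registration import (
    ConvergenceError,
    FitParams,
    landmark_embedding,
    similarity_from_correspondences,
)
from homoshape.synthetic import deform_points


def _random_similarity(rng, max_angle_deg=180.0, scale=None):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    s = scale if scale is not None else rng.uniform(0.5, 2.0)
    return hs.SimilarityTransform(R, rng.normal(size=3) * 20, s)


class TestLandmarkSimilarity:
    def test_identity_on_equal_sets(self, base_shape):
        _, lms = base_shape
        t = hs.landmark_similarity_align(lms, lms)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0, atol=1e-9)
        assert t.scale == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_recovery_of_random_transform(self, base_shape, seed):
        _, lms = base_shape
        t_true = _random_similarity(np.random.default_rng(seed))
        target = lms.with_points(t_true.apply(lms.points))
        t_est = hs.landmark_similarity_align(lms, target)
        np.testing.assert_allclose(t_est.rotation, t_true.rotation, atol=1e-9)
        np.testing.assert_allclose(t_est.translation, t_true.translation, atol=1e-9)
        assert t_est.scale == pytest.approx(t_true.scale, abs=1e-9)

    def test_noisy_residual_matches_numeric_minimizer(self, base_shape):
        """Closed form equals brute-force numeric minimization of the
        summed squared landmark distance over (axis-angle, t, s)."""
        _, lms = base_shape
        rng = np.random.default_rng(5)
        src = lms.points[:12]
        t_true = _random_similarity(rng, scale=1.2)
        tgt = t_true.apply(src) + rng.normal(scale=2.0, size=(12, 3))
        t_est = similarity_from_correspondences(src, tgt)
        res_closed = np.sum((t_est.apply(src) - tgt) ** 2)

        def objective(p):
            phi = p[:3]
            ang = np.linalg.norm(phi)
            if ang < 1e-12:
                R = np.eye(3)
            else:
                k = phi / ang
                K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
                R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
            return np.sum((np.exp(p[6]) * src @ R.T + p[3:6] - tgt) ** 2)

        x0 = np.concatenate([np.zeros(3), tgt.mean(0) - src.mean(0), [0.0]])
        best = min(
            minimize(objective, x0, method="Nelder-Mead",
                     options={"maxiter": 20000, "xatol": 1e-12, "fatol": 1e-12}).fun
            for _ in range(1)
        )
        assert res_closed <= best + 1e-6

    def test_too_few_or_collinear_landmarks_rejected(self):
        from homoshape.mesh import LandmarkSet

        a = LandmarkSet(["p", "q"], [[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            hs.landmark_similarity_align(a, a)
        line = LandmarkSet(["p", "q", "r"], [[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError):
            hs.landmark_similarity_align(line, line)


class TestIcpRigid:
    def test_identical_meshes_identity(self, base_shape):
        mesh, _ = base_shape
        t = hs.icp_rigid(mesh, mesh, init=hs.SimilarityTransform.identity())
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.translation, 0, atol=1e-9)

    def test_recovers_rigid_perturbation(self, base_shape):
        """8 degrees about a random axis plus 5 mm must be recovered to
        within 0.1 degree / 0.1 mm."""
        mesh, _ = base_shape
        rng = np.random.default_rng(12)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = np.deg2rad(8.0)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        t_true = hs.SimilarityTransform(R, [3.0, -2.0, 2.5], 1.0)
        fixed = hs.apply_transform(mesh, t_true)
        t_est = hs.icp_rigid(mesh, fixed, init=hs.SimilarityTransform.identity())
        dR = t_est.rotation @ t_true.rotation.T
        angle_err = np.degrees(np.arccos(np.clip((np.trace(dR) - 1) / 2, -1, 1)))
        assert angle_err < 0.1
        assert np.linalg.norm(t_est.translation - t_true.translation) < 0.1

    def test_residual_non_increasing(self, base_shape):
        mesh, _ = base_shape
        rng = np.random.default_rng(1)
        t = _random_similarity(rng, scale=1.0)
        fixed = hs.apply_transform(mesh, hs.SimilarityTransform(t.rotation * 0 + np.eye(3), [4, 4, 4], 1.0))
        query = SurfaceQuery(fixed)
        residuals = []
        cur = hs.SimilarityTransform.identity()
        for _ in range(8):
            residuals.append(query.distances(cur.apply(mesh.vertices)).mean())
            from homoshape.registration import _rigid_at_scale

            closest, _, _ = query.closest(cur.apply(mesh.vertices))
            cur = _rigid_at_scale(mesh.vertices, closest, 1.0)
        assert all(b <= a + 1e-9 for a, b in zip(residuals, residuals[1:]))


class TestNonrigidFit:
    def test_fixed_point_on_own_surface(self, app_template):
        tpl = app_template
        hm = hs.nonrigid_fit(tpl, tpl.mesh, tpl.landmarks)
        assert hm.residual_mean < 1e-3 * tpl.mesh.bbox_diagonal
        drift = np.linalg.norm(hm.vertices - tpl.mesh.vertices, axis=1)
        assert drift.mean() < 0.005 * tpl.mesh.bbox_diagonal

    def test_known_smooth_deformation_recovered(self, app_template):
        """Residual < 1% of diagonal and landmark error < 2% of diagonal
        on a known deformation of the template itself."""
        tpl = app_template
        from homoshape.template import app_transform

        inv_pts = tpl.mesh.vertices  # already the deformation domain
        scores = np.array([2.5, -2.0, 1.5])
        # deform in the original (pre-APP) coordinates
        t = app_transform(tpl.landmarks)  # identity here, kept for clarity
        target = hs.TriMesh(
            t.apply(deform_points(t.inverse().apply(tpl.mesh.vertices), scores)),
            tpl.mesh.faces, "warped")
        target_lms = tpl.landmarks.with_points(
            t.apply(deform_points(t.inverse().apply(tpl.landmarks.points), scores)))
        hm = hs.nonrigid_fit(tpl, target, target_lms)
        diag = target.bbox_diagonal
        assert hm.residual_mean < 0.01 * diag
        B = landmark_embedding(tpl.mesh, tpl.landmarks.points)
        lm_err = np.linalg.norm(B @ hm.vertices - target_lms.points, axis=1)
        assert lm_err.max() < 0.02 * diag

    def test_topology_shared_with_template(self, app_template, quiet_config):
        mesh, lms, _ = hs.sample_specimen(quiet_config, [1, 0, 0],
                                          np.random.default_rng(2))
        m, l, _ = hs.place_in_app(mesh, lms)
        hm = hs.nonrigid_fit(app_template, m, l, source_id="s1", group=1)
        assert hm.n_vertices == app_template.mesh.n_vertices
        assert hm.faces is app_template.mesh.faces
        assert hm.group == 1

    def test_equivariance_under_rigid_target_motion(self, app_template, quiet_config):
        mesh, lms, _ = hs.sample_specimen(quiet_config, [1, -1, 0],
                                          np.random.default_rng(6))
        m, l, _ = hs.place_in_app(mesh, lms)
        hm1 = hs.nonrigid_fit(app_template, m, l)
        rng = np.random.default_rng(3)
        t = _random_similarity(rng, scale=1.0)
        hm2 = hs.nonrigid_fit(
            app_template, hs.apply_transform(m, t), l.with_points(t.apply(l.points))
        )
        np.testing.assert_allclose(
            hm2.vertices, t.apply(hm1.vertices),
            atol=1e-6 * m.bbox_diagonal * 10,
        )

    def test_lower_smoothness_floor_does_not_raise_residual(self, app_template,
                                                            quiet_config):
        mesh, lms, _ = hs.sample_specimen(quiet_config, [2, 0, 0],
                                          np.random.default_rng(9))
        m, l, _ = hs.place_in_app(mesh, lms)
        res = []
        for floor in (10.0, 1.0, 0.01):
            p = FitParams(smoothness_schedule=(100.0, 10.0, max(floor, 1.0), floor))
            res.append(hs.nonrigid_fit(app_template, m, l, params=p).residual_mean)
        assert res[2] <= res[0] + 1e-9

    def test_all_zero_weights_rejected(self, app_template):
        p = FitParams(smoothness_schedule=(0.0,), landmark_weight=0.0, data_weight=0.0)
        with pytest.raises(ValueError):
            hs.nonrigid_fit(app_template, app_template.mesh, app_template.landmarks,
                            params=p)

    def test_decreasing_schedule_enforced(self):
        with pytest.raises(ValueError):
            FitParams(smoothness_schedule=(1.0, 10.0))


class TestFitResidual:
    def test_on_surface_model_zero(self, app_template):
        hm = hs.HomologousModel(app_template.mesh.vertices, app_template.mesh.faces)
        mean, sd = hs.fit_residual(hm, app_template.mesh)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_constant_offset_above_plane(self):
        plane = hs.TriMesh(
            [[-50, -50, 0], [50, -50, 0], [50, 50, 0], [-50, 50, 0]],
            [[0, 1, 2], [0, 2, 3]],
        )
        grid = np.stack(np.meshgrid(np.linspace(-20, 20, 5),
                                    np.linspace(-20, 20, 5)), -1).reshape(-1, 2)
        verts = np.column_stack([grid, np.full(len(grid), 3.5)])
        hm = hs.HomologousModel(verts, plane.faces)
        mean, sd = hs.fit_residual(hm, plane)
        assert mean == pytest.approx(3.5, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_matches_per_vertex_oracle(self, base_shape):
        mesh, _ = base_shape
        rng = np.random.default_rng(2)
        verts = mesh.vertices[:200] + rng.normal(scale=1.5, size=(200, 3))
        hm = hs.HomologousModel(verts, mesh.faces)
        mean, sd = hs.fit_residual(hm, mesh)
        d = np.array([hs.point_to_surface_distance(p, mesh) for p in verts])
        assert mean == pytest.approx(d.mean(), abs=1e-10)
        assert sd == pytest.approx(d.std(ddof=1), abs=1e-10)
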