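import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from conftest import random_rigid
from vbb import (AmbiguityWarning, DefectSpec, DegeneracyError, FemurParams,
                 LandmarkSet, MeshQuery, PointCloud, RegistrationConfig,
                 RigidTransform, apply_defect, apply_transform, generate_femur,
                 icp_register, landmark_align, principal_axes_init,
                 sample_point_cloud, transform_landmarks)


def random_landmarks(rng):
    return LandmarkSet.from_array(rng.uniform(-40, 40, (6, 3)))


class TestLandmarkAlign:
    def test_identity_on_equal_sets(self):
        lm = random_landmarks(np.random.default_rng(0))
        t = landmark_align(lm, lm)
        assert np.abs(t.rotation - np.eye(3)).max() < 1e-12
        assert np.abs(t.translation).max() < 1e-12

    def test_exact_recovery_of_known_transform(self):
        lm = random_landmarks(np.random.default_rng(1))
        rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        truth = RigidTransform(rz, [5.0, 0.0, 0.0])
        t = landmark_align(lm, transform_landmarks(lm, truth))
        assert np.abs(t.rotation - truth.rotation).max() < 1e-12
        assert np.abs(t.translation - truth.translation).max() < 1e-12

    def test_noisy_recovery_statistics(self):
        # Monte-Carlo with sigma = 0.2 mm noise on the anatomical landmark
        # configuration (frozen 100-trial oracle run: rotation p95 = 0.46 deg,
        # max = 0.56 deg; translation p95 = 0.24 mm, max = 0.33 mm)
        _, lm = generate_femur(FemurParams(resolution_mm=3.0))
        rng = np.random.default_rng(7)
        rot_errs, tr_errs = [], []
        for _ in range(100):
            truth = random_rigid(rng)
            noisy = transform_landmarks(lm, truth).as_array() + rng.normal(0, 0.2, (6, 3))
            t = landmark_align(lm, LandmarkSet.from_array(noisy))
            err = t.compose(truth.inverse())
            rot_errs.append(err.rotation_angle_deg())
            tr_errs.append(float(np.linalg.norm(t.translation - truth.translation)))
        assert np.percentile(rot_errs, 95) < 0.5
        assert np.percentile(tr_errs, 95) < 0.3
        assert max(rot_errs) < 0.7
        assert max(tr_errs) < 0.4

    def test_collinear_landmarks_degenerate(self):
        pts = np.outer(np.arange(6.0), [1.0, 0.0, 0.0])
        lm = LandmarkSet.from_array(pts)
        with pytest.raises(DegeneracyError):
            landmark_align(lm, lm)

    def test_matches_numerical_minimizer_oracle(self):
        # brute-force minimization of the pair objective over (rotvec, t)
        rng = np.random.default_rng(3)
        for _ in range(5):
            src = rng.uniform(-30, 30, (6, 3))
            tgt = rng.uniform(-30, 30, (6, 3))
            t = landmark_align(LandmarkSet.from_array(src), LandmarkSet.from_array(tgt))

            def objective(x):
                R = Rotation.from_rotvec(x[:3]).as_matrix()
                return ((src @ R.T + x[3:] - tgt) ** 2).sum()

            x0 = np.concatenate([Rotation.from_matrix(t.rotation).as_rotvec(),
                                 t.translation])
            res = minimize(objective, x0 + rng.normal(0, 0.05, 6), method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
            assert objective(x0) <= res.fun + 1e-6


class TestICP:
    def test_points_on_surface_converge_immediately(self, femur_coarse):
        mesh, _ = femur_coarse
        cloud = sample_point_cloud(mesh, 2000, seed=0)
        res = icp_register(cloud, mesh, config=RegistrationConfig(seed=0))
        assert res.converged
        assert res.final_mean_distance_mm < 1e-6

    def test_known_transform_recovery_with_landmark_init(self, femur_default):
        mesh, lm = femur_default
        rng = np.random.default_rng(5)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        truth = RigidTransform(Rotation.from_rotvec(np.radians(8) * axis).as_matrix(),
                               6.0 * axis)
        src = apply_transform(mesh, truth)
        cloud = sample_point_cloud(src, 4000, seed=0)
        init = landmark_align(transform_landmarks(lm, truth), lm)
        res = icp_register(cloud, mesh, init=init, config=RegistrationConfig(seed=0))
        err = res.transform.compose(truth)  # should be identity
        assert err.rotation_angle_deg() < 0.1
        assert np.linalg.norm(err.translation) < 0.1

    def test_known_transform_recovery_from_identity_init(self, femur_default):
        mesh, _ = femur_default
        axis = np.array([0.0, 0.0, 1.0])
        truth = RigidTransform(Rotation.from_rotvec(np.radians(8) * axis).as_matrix(),
                               [4.0, -3.0, 2.0])
        cloud = sample_point_cloud(apply_transform(mesh, truth), 3000, seed=1)
        res = icp_register(cloud, mesh, config=RegistrationConfig(seed=1))
        err = res.transform.compose(truth)
        assert err.rotation_angle_deg() < 0.1
        assert np.linalg.norm(err.translation) < 0.1

    def test_trimming_absorbs_defect(self, femur_default):
        mesh, lm = femur_default
        defected = apply_defect(mesh, DefectSpec(center_mm=tuple(lm["ME"]),
                                                 radius_mm=25.0, seed=2))
        truth = random_rigid(np.random.default_rng(9))
        cloud = sample_point_cloud(apply_transform(defected, truth), 4000, seed=2)
        init = landmark_align(transform_landmarks(lm, truth), lm)
        res = icp_register(cloud, mesh, init=init,
                           config=RegistrationConfig(trim_fraction=0.2, seed=2))
        assert res.final_mean_distance_mm < 0.2
        err = res.transform.compose(truth)
        assert err.rotation_angle_deg() < 0.1

    def test_trimmed_mean_is_monotone_nonincreasing(self, femur_coarse):
        mesh, _ = femur_coarse
        truth = RigidTransform(Rotation.from_euler("y", 10, degrees=True).as_matrix(),
                               [5.0, 5.0, 0.0])
        cloud = sample_point_cloud(apply_transform(mesh, truth), 2000, seed=3)
        res = icp_register(cloud, mesh, config=RegistrationConfig(seed=3))
        h = res.mean_history
        assert all(h[i + 1] <= h[i] + 1e-12 for i in range(len(h) - 1))

    def test_result_is_always_proper_rotation(self, femur_coarse):
        mesh, _ = femur_coarse
        rng = np.random.default_rng(13)
        cloud = sample_point_cloud(mesh, 500, seed=4)
        for _ in range(3):
            res = icp_register(apply_transform(cloud, random_rigid(rng)), mesh,
                               config=RegistrationConfig(max_iterations=5, seed=0))
            assert np.isclose(np.linalg.det(res.transform.rotation), 1.0)


class TestPrincipalAxesInit:
    def test_identity_for_aligned_box(self):
        import trimesh

        from vbb import SurfaceMesh

        tm = trimesh.creation.box((20, 40, 90))
        box = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
        cloud = sample_point_cloud(box, 2000, seed=0)
        t = principal_axes_init(cloud, box, seed=0)
        d, _, _ = MeshQuery(box).query(t.apply(cloud.points))
        assert d.mean() < 1e-6

    def test_rotated_femur_realigned_and_beats_flipped_candidates(self, femur_coarse):
        mesh, _ = femur_coarse
        truth = RigidTransform(Rotation.from_euler("z", 30, degrees=True).as_matrix(),
                               [5.0, 2.0, 1.0])
        cloud = sample_point_cloud(apply_transform(mesh, truth), 2000, seed=0)
        query = MeshQuery(mesh)
        t = principal_axes_init(cloud, query, seed=0)
        chosen, _, _ = query.query(t.apply(cloud.points))
        assert chosen.mean() < 3.0  # coarse but inside the ICP basin
        # the three rejected axis-sign candidates differ by 180-degree flips
        # about the target's principal axes through its centroid
        tgt_pts = sample_point_cloud(mesh, 2000, seed=1).points
        centroid = tgt_pts.mean(axis=0)
        _, axes = np.linalg.eigh(np.cov((tgt_pts - centroid).T))
        for axis in axes.T:
            R = Rotation.from_rotvec(np.pi * axis).as_matrix()
            flip = RigidTransform(R, centroid - R @ centroid)
            worse, _, _ = query.query(flip.compose(t).apply(cloud.points))
            assert chosen.mean() < worse.mean()

    def test_sphere_raises_ambiguity_warning(self, sphere20):
        cloud = sample_point_cloud(sphere20, 500, seed=0)
        with pytest.warns(AmbiguityWarning):
            t = principal_axes_init(cloud, sphere20, seed=0)
        assert np.array_equal(t.rotation, np.eye(3))


class TestRegistrationConfig:
    @pytest.mark.parametrize("kwargs", [
        {"trim_fraction": 0.5}, {"trim_fraction": -0.1},
        {"max_iterations": 0}, {"convergence_tol_mm": 0.0},
        {"init_mode": "magic"},
    ])
    def test_invalid_config_rejected(self, kwargs):
        from vbb import ParameterError

        with pytest.raises(ParameterError):
            RegistrationConfig(**kwargs)
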