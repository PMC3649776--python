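import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from conftest import random_rigid
from oracles import surface_distance_oracle
from vbb import (ABCMeasurement, BankRecord, ColorMapSpec, DistanceField,
                 FemurParams, MeshQuery, ParameterError, PointCloud,
                 PreconditionError, SurfaceMesh, ValidationError, apply_transform,
                 colorimetric_export, compute_abc, generate_femur, match_score,
                 rank_candidates, read_mesh, sample_point_cloud, surface_distances,
                 write_landmarks, write_mesh)


class TestSurfaceDistances:
    def test_parallel_planes_distance_one(self):
        plane = SurfaceMesh([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]],
                            [[0, 1, 2], [0, 2, 3]])
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(1, 9, (200, 2)), np.ones(200)])
        field = surface_distances(PointCloud(pts), plane)
        assert np.abs(field.distances_mm - 1.0).max() < 1e-12

    def test_cloud_on_surface_has_zero_distance(self, femur_coarse):
        mesh, _ = femur_coarse
        cloud = sample_point_cloud(mesh, 1000, seed=0)
        field = surface_distances(cloud, mesh)
        assert field.distances_mm.max() < 1e-9

    def test_matches_exhaustive_brute_force(self, femur_coarse):
        rng = np.random.default_rng(1)
        mesh, _ = femur_coarse
        # random sub-mesh to keep the O(K*M) oracle cheap
        faces = mesh.faces[rng.choice(mesh.n_faces, 300, replace=False)]
        used = np.unique(faces)
        remap = np.zeros(mesh.n_vertices, dtype=np.int64)
        remap[used] = np.arange(len(used))
        sub = SurfaceMesh(mesh.vertices[used], remap[faces])
        pts = rng.uniform(-60, 120, (400, 3))
        field = surface_distances(PointCloud(pts), sub)
        oracle = surface_distance_oracle(pts, sub.triangles)
        assert np.abs(field.distances_mm - oracle).max() < 1e-9

    def test_rigid_invariance(self, unit_cube):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-2, 2, (100, 3))
        d0 = surface_distances(PointCloud(pts), unit_cube).distances_mm
        t = random_rigid(rng)
        moved_mesh = apply_transform(unit_cube, t)
        d1 = surface_distances(PointCloud(t.apply(pts)), moved_mesh).distances_mm
        assert np.abs(d0 - d1).max() < 1e-9

    def test_empty_cloud_rejected(self, unit_cube):
        with pytest.raises((PreconditionError, ValidationError)):
            surface_distances(PointCloud(np.zeros((0, 3))), unit_cube)


class TestMatchScore:
    def test_constant_field(self):
        s = match_score(DistanceField([1.0, 1.0, 1.0, 1.0]))
        assert (s.mean_mm, s.rms_mm, s.max_mm) == (1.0, 1.0, 1.0)

    def test_zero_two_field(self):
        s = match_score(DistanceField([0.0, 2.0]))
        assert s.mean_mm == 1.0
        assert s.rms_mm == pytest.approx(np.sqrt(2.0))
        assert s.max_mm == 2.0

    def test_percentile_linear_interpolation(self):
        s = match_score(DistanceField(np.arange(101.0)))
        assert s.p95_mm == pytest.approx(95.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(hnp.arrays(np.float64, st.integers(1, 50),
                      elements=st.floats(0, 1e3, allow_nan=False)))
    def test_summary_ordering_invariants(self, d):
        s = match_score(DistanceField(d))
        assert s.mean_mm <= s.rms_mm + 1e-12
        assert s.rms_mm <= s.max_mm + 1e-12
        assert s.p95_mm <= s.max_mm + 1e-12
        assert s.n_points == len(d)

    def test_empty_field_rejected(self):
        with pytest.raises(PreconditionError):
            DistanceField(np.zeros(0))


class TestColorimetricExport:
    def test_all_at_lower_bound_get_colormap_zero(self, tmp_path, unit_cube):
        spec = ColorMapSpec(0.0, 5.0, "viridis")
        field = DistanceField(np.zeros(unit_cube.n_vertices))
        path = tmp_path / "c.ply"
        colorimetric_export(unit_cube, field, spec, path)
        back = read_mesh(path)
        expected = spec.colors(np.zeros(1))[0]
        assert (back.vertex_colors == expected).all()

    def test_above_upper_clamps_to_colormap_one(self):
        spec = ColorMapSpec(0.0, 5.0)
        assert (spec.colors(np.array([99.0])) == spec.colors(np.array([5.0]))).all()

    def test_written_ply_colors_roundtrip(self, tmp_path, unit_cube):
        rng = np.random.default_rng(0)
        field = DistanceField(rng.uniform(0, 8, unit_cube.n_vertices))
        spec = ColorMapSpec()
        path = tmp_path / "d.ply"
        colorimetric_export(unit_cube, field, spec, path)
        assert np.array_equal(read_mesh(path).vertex_colors,
                              spec.colors(field.distances_mm))
        assert (tmp_path / "d.ply.legend.json").exists()

    def test_mismatched_lengths_rejected(self, unit_cube):
        with pytest.raises(ValidationError):
            colorimetric_export(unit_cube, DistanceField([1.0]), ColorMapSpec(),
                                "/tmp/never.ply")

    def test_invalid_scale_rejected(self):
        with pytest.raises(ParameterError):
            ColorMapSpec(5.0, 5.0)


@pytest.fixture(scope="module")
def host_and_bank(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("bank")
    host_p = FemurParams(a_mm=80, b_mm=60, c_mm=62, resolution_mm=2.5, seed=1)
    host_mesh, host_lm = generate_femur(host_p)
    records = []
    for donor_id, scale in [("exact_copy", 1.0), ("scaled_up", 1.1)]:
        mesh = SurfaceMesh(host_mesh.vertices * scale, host_mesh.faces)
        from vbb import LandmarkSet

        lm = LandmarkSet.from_array(host_lm.as_array() * scale)
        write_mesh(mesh, tmp / f"{donor_id}.stl")
        write_landmarks(lm, tmp / f"{donor_id}.landmarks.json")
        records.append(BankRecord(donor_id, "right", "distal_femur",
                                  compute_abc(lm), str(tmp / f"{donor_id}.stl"),
                                  str(tmp / f"{donor_id}.landmarks.json")))
    return host_mesh, host_lm, records


class TestRankCandidates:
    def test_exact_copy_ranked_first(self, host_and_bank):
        host_mesh, host_lm, records = host_and_bank
        from vbb import RegistrationConfig

        matches = rank_candidates(host_mesh, host_lm, records,
                                  config=RegistrationConfig(max_iterations=20,
                                                            convergence_tol_mm=1e-3),
                                  score_points=1000, seed=0)
        assert matches[0].donor_id == "exact_copy"
        assert matches[0].score.mean_mm < 1e-6
        assert matches[1].score.mean_mm > matches[0].score.mean_mm

    def test_single_candidate_report(self, host_and_bank):
        host_mesh, host_lm, records = host_and_bank
        from vbb import RegistrationConfig

        matches = rank_candidates(host_mesh, host_lm, [records[0]],
                                  config=RegistrationConfig(max_iterations=10,
                                                            convergence_tol_mm=1e-3),
                                  score_points=500, seed=0)
        assert len(matches) == 1
        assert matches[0].score.n_points == 500

    def test_unreadable_candidate_skipped_with_warning(self, host_and_bank):
        host_mesh, host_lm, records = host_and_bank
        from vbb import RegistrationConfig

        bad = BankRecord("ghost", "right", "distal_femur",
                         ABCMeasurement(80, 60, 62), "/nonexistent/ghost.stl", None)
        with pytest.warns(UserWarning, match="ghost"):
            matches = rank_candidates(host_mesh, host_lm, [records[0], bad],
                                      config=RegistrationConfig(max_iterations=5,
                                                                convergence_tol_mm=1e-3),
                                      score_points=500, seed=0)
        assert [m.donor_id for m in matches] == ["exact_copy"]

    def test_final_order_follows_surface_mean_not_abc(self, tmp_path):
        # Donor "thin" matches the host ABC exactly but its condyles are
        # squashed along z (ABC is blind to z); donor "grown" is uniformly
        # +1.5 mm in ABC but otherwise host-shaped. Surface matching must
        # prefer "grown" even though screening prefers "thin".
        host_p = FemurParams(a_mm=80, b_mm=60, c_mm=62, resolution_mm=2.5, seed=2)
        host_mesh, host_lm = generate_femur(host_p)
        from vbb import LandmarkSet, RegistrationConfig

        squash = np.array([1.0, 1.0, 0.6])
        thin = SurfaceMesh(host_mesh.vertices * squash, host_mesh.faces)
        thin_lm = LandmarkSet.from_array(host_lm.as_array() * squash)
        grown_mesh, grown_lm = generate_femur(
            FemurParams(a_mm=81.5, b_mm=61.5, c_mm=63.5, resolution_mm=2.5, seed=2))
        records = []
        for donor_id, mesh, lm in [("thin", thin, thin_lm),
                                   ("grown", grown_mesh, grown_lm)]:
            write_mesh(mesh, tmp_path / f"{donor_id}.stl")
            write_landmarks(lm, tmp_path / f"{donor_id}.landmarks.json")
            records.append(BankRecord(donor_id, "right", "distal_femur",
                                      compute_abc(lm),
                                      str(tmp_path / f"{donor_id}.stl"),
                                      str(tmp_path / f"{donor_id}.landmarks.json")))
        host_abc = compute_abc(host_lm).as_array()
        abc_dist = {r.donor_id: np.linalg.norm(r.abc.as_array() - host_abc)
                    for r in records}
        assert abc_dist["thin"] < abc_dist["grown"]  # screening would pick thin
        matches = rank_candidates(host_mesh, host_lm, records,
                                  config=RegistrationConfig(max_iterations=25,
                                                            convergence_tol_mm=1e-3),
                                  score_points=1500, seed=0)
        assert matches[0].donor_id == "grown"

    def test_self_match_is_global_minimum(self, host_and_bank):
        host_mesh, host_lm, records = host_and_bank
        from vbb import RegistrationConfig

        matches = rank_candidates(host_mesh, host_lm, records,
                                  config=RegistrationConfig(max_iterations=15,
                                                            convergence_tol_mm=1e-3),
                                  score_points=800, seed=1)
        self_score = next(m for m in matches if m.donor_id == "exact_copy")
        for m in matches:
            assert self_score.score.mean_mm <= m.score.mean_mm + 1e-12
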