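import numpy as np
import pytest

from craniomorph import (
    CohortSpec,
    RegistrationParams,
    build_cohort,
    generate_cohort,
    nonrigid_register,
    rigid_initialize,
)
from craniomorph.exceptions import DegenerateGeometryError, ManifestError
from craniomorph.geometry import (
    SimilarityTransform,
    bounding_box_diagonal,
    median_edge_length,
)
from craniomorph.meshio import LandmarkSet, read_manifest
from craniomorph.simulate import template_landmarks, write_cohort


def _rot_z(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


class TestRigidInitialize:
    def test_identity_on_identical_landmarks(self, template_small):
        lms, _ = template_landmarks(template_small)
        xf = rigid_initialize(lms, lms)
        np.testing.assert_allclose(xf.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(xf.translation, 0.0, atol=1e-10)
        assert xf.scale == pytest.approx(1.0, abs=1e-10)

    def test_recovers_constructed_similarity(self, template_small):
        lms, _ = template_landmarks(template_small)
        rot = _rot_z(np.pi / 2)
        target = LandmarkSet(
            list(lms.names), 2.0 * lms.coordinates @ rot.T + np.array([1.0, -2.0, 3.0])
        )
        xf = rigid_initialize(lms, target)
        np.testing.assert_allclose(xf.rotation, rot, atol=1e-8)
        assert xf.scale == pytest.approx(2.0, abs=1e-8)
        np.testing.assert_allclose(xf.apply(lms.coordinates), target.coordinates,
                                   atol=1e-8)

    def test_collinear_landmarks_rejected(self):
        line = LandmarkSet(["a", "b", "c"],
                           np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]]))
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            rigid_initialize(line, line)

    def test_name_mismatch_rejected(self):
        a = LandmarkSet(["a", "b", "c"], np.eye(3))
        b = LandmarkSet(["a", "b", "d"], np.eye(3))
        with pytest.raises(Exception, match="mismatch"):
            rigid_initialize(a, b)


class TestNonrigidRegister:
    def test_identity_target_near_zero_residual(self, template_small):
        result = nonrigid_register(template_small, template_small)
        diag = bounding_box_diagonal(np.asarray(template_small.vertices))
        assert result.residuals[-1] < 1e-6 * diag

    def test_infinite_sigma_limit_is_global_translation(self, template_small):
        # one iteration with a huge kernel: the update must be spatially constant
        shifted = template_small.copy()
        shifted.vertices = np.asarray(shifted.vertices) + np.array([0.3, 0.0, 0.0])
        params = RegistrationParams(iterations=1, sigma_start=1e6, sigma_end=1e6,
                                    step=1.0)
        result = nonrigid_register(template_small, shifted, params=params)
        update = result.mapped_vertices - np.asarray(template_small.vertices)
        spread = update.std(axis=0).max()
        assert spread < 1e-8 * np.abs(update).max()

    def test_rigid_equivariance(self, template_small):
        spec = CohortSpec(n_per_group=1, noise_sd=0.0, seed=2)
        cohort = generate_cohort(template_small, spec)
        target = cohort.meshes[0]
        params = RegistrationParams(iterations=15)
        base = nonrigid_register(template_small, target, params=params)

        rot = _rot_z(0.7)
        xf = SimilarityTransform(1.0, rot, np.array([0.5, -0.2, 0.1]))
        moved = target.copy()
        moved.vertices = xf.apply(np.asarray(target.vertices))
        out = nonrigid_register(template_small, moved, init=xf, params=params)
        np.testing.assert_allclose(
            out.mapped_vertices, xf.apply(base.mapped_vertices), rtol=0, atol=1e-6
        )

    def test_residuals_mostly_nonincreasing(self, template_small):
        spec = CohortSpec(n_per_group=2, decorrespond=True, noise_sd=0.0, seed=8)
        cohort = generate_cohort(template_small, spec)
        drops = 0
        total = 0
        for target in cohort.meshes:
            res = nonrigid_register(template_small, target).residuals
            diffs = np.diff(res)
            drops += int(np.count_nonzero(diffs <= 1e-12))
            total += len(diffs)
        assert drops / total >= 0.95

    def test_correspondence_recovery_on_decorresponded_target(self, template_small):
        spec = CohortSpec(n_per_group=1, decorrespond=True,
                          apply_similarity_transforms=True, noise_sd=0.0, seed=13)
        cohort = generate_cohort(template_small, spec)
        tmpl_lms, _ = template_landmarks(template_small)
        init = rigid_initialize(tmpl_lms, cohort.landmarks[0])
        result = nonrigid_register(template_small, cohort.meshes[0], init=init)
        truth = cohort.ground_truth.true_coordinates[0]
        err = np.linalg.norm(result.mapped_vertices - truth, axis=1).mean()
        target = cohort.meshes[0]
        assert err < median_edge_length(target.vertices, target.faces)

    def test_empty_target_rejected(self, template_small):
        from craniomorph.geometry import as_mesh

        empty = as_mesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(DegenerateGeometryError):
            nonrigid_register(template_small, empty)


class TestBuildCohort:
    def test_cohort_matches_ground_truth_when_corresponded(self, template_small,
                                                           tmp_path):
        spec = CohortSpec(n_per_group=2, noise_sd=0.005, litter_count=2, seed=3)
        cohort = generate_cohort(template_small, spec)
        manifest_path = write_cohort(cohort, tmp_path)
        manifest = read_manifest(manifest_path, genotype_levels=["WT", "HET"])
        tmpl_lms, _ = template_landmarks(template_small)
        out = build_cohort(manifest, template_small, tmpl_lms,
                           base_dir=manifest_path.parent)
        assert len(out) == len(cohort)
        assert out.specimen_ids == cohort.specimen_ids
        truth = cohort.ground_truth.true_coordinates
        err = np.linalg.norm(out.coordinates - truth, axis=2).mean()
        tol = median_edge_length(template_small.vertices, template_small.faces)
        assert err < tol

    def test_missing_mesh_names_specimen(self, template_small, tmp_path):
        spec = CohortSpec(n_per_group=1, litter_count=1, seed=3)
        cohort = generate_cohort(template_small, spec)
        manifest_path = write_cohort(cohort, tmp_path)
        manifest = read_manifest(manifest_path)
        (tmp_path / "S001.obj").unlink()
        tmpl_lms, _ = template_landmarks(template_small)
        with pytest.raises(ManifestError, match="S001"):
            build_cohort(manifest, template_small, tmpl_lms, base_dir=tmp_path)

    def test_single_specimen_manifest(self, template_small, tmp_path):
        spec = CohortSpec(n_per_group=(1, 0), litter_count=1, seed=4)
        cohort = generate_cohort(template_small, spec)
        manifest_path = write_cohort(cohort, tmp_path)
        manifest = read_manifest(manifest_path)
        tmpl_lms, _ = template_landmarks(template_small)
        out = build_cohort(manifest, template_small, tmpl_lms, base_dir=tmp_path)
        assert len(out) == 1
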