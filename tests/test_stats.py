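import numpy as np
import pandas as pd
import pytest

from craniomorph import CohortSpec, generate_cohort
from craniomorph.exceptions import CollinearityError, InvalidParameterError
from craniomorph.geometry import vertex_normals
from craniomorph.gpa import AlignedCohort
from craniomorph.stats import (
    CovariateTable,
    build_covariates,
    fit_pca,
    normal_displacement,
    normalize_scores,
    partial_effect,
    permutation_test,
    per_vertex_effects,
)

from conftest import analyze_cohort


def _aligned_from_scores(rng, n=20, v=30, variances=(8.0, 2.0, 0.5)):
    """Build an aligned-like cohort with known PC structure."""
    axes = np.linalg.qr(rng.normal(size=(3 * v, len(variances))))[0].T
    scores = rng.normal(size=(n, len(variances))) * np.sqrt(variances)
    scores -= scores.mean(axis=0)
    x = scores @ axes
    shapes = x.reshape(n, v, 3)
    return AlignedCohort(
        shapes=shapes,
        centroid_sizes=np.ones(n),
        mean_shape=np.zeros((v, 3)),
    )


class TestFitPca:
    def test_retention_by_cumulative_fraction(self, rng):
        # fractions ~ (0.80, 0.18, 0.02): threshold 0.96 keeps 2 components
        aligned = _aligned_from_scores(rng, n=200, variances=(80.0, 18.0, 2.0))
        model, scores = fit_pca(aligned, threshold=0.96)
        frac = model.variances / model.variances.sum()
        assert np.cumsum(frac)[1] >= 0.96 > np.cumsum(frac)[0]
        assert model.retained_m == 2
        assert scores.shape[1] == 2

    def test_threshold_one_keeps_all_nonzero(self, rng):
        aligned = _aligned_from_scores(rng, n=15, variances=(4.0, 1.0, 0.25))
        model, _ = fit_pca(aligned, threshold=1.0)
        assert model.retained_m == len(model.variances) == 3

    def test_equal_variances_require_all(self, rng):
        # 10 equal-variance directions: 9/10 < 0.96, so all 10 retained
        aligned = _aligned_from_scores(rng, n=2000, v=40, variances=(1.0,) * 10)
        model, _ = fit_pca(aligned, threshold=0.96)
        assert model.retained_m == 10

    def test_components_orthonormal_variances_sorted(self, rng):
        aligned = _aligned_from_scores(rng, n=25, variances=(5.0, 2.0, 1.0))
        model, _ = fit_pca(aligned, 0.96)
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)
        assert np.all(np.diff(model.variances) <= 1e-12)

    def test_bad_threshold_rejected(self, rng):
        aligned = _aligned_from_scores(rng)
        with pytest.raises(InvalidParameterError):
            fit_pca(aligned, threshold=1.5)


class TestNormalizeScores:
    def test_unit_variance_columns(self, rng):
        scores = rng.normal(size=(30, 4)) * np.array([2.0, 0.5, 7.0, 1.0])
        z, sds = normalize_scores(scores)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(z * sds, scores, atol=1e-12)

    def test_already_normalized_unchanged(self, rng):
        z0, _ = normalize_scores(rng.normal(size=(50, 3)))
        z1, _ = normalize_scores(z0)
        np.testing.assert_allclose(z1, z0, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(InvalidParameterError):
            normalize_scores(np.ones((10, 2)))


def _covariates(rng, n, litters=2):
    table = pd.DataFrame(
        {
            "genotype": ["HET" if i % 2 else "WT" for i in range(n)],
            "sex": ["M" if (i // 2) % 2 else "F" for i in range(n)],
            "litter": [f"L{(i // 3) % litters}" for i in range(n)],
        }
    )
    return build_covariates(table)


class TestPartialEffect:
    def test_zero_when_scores_orthogonal_to_contrast(self, rng):
        cov = _covariates(rng, 16)
        y = rng.normal(size=(16, 3))
        # project out both nuisance and genotype from y: exact null
        design = np.column_stack([cov.nuisance, cov.genotype])
        y -= design @ np.linalg.lstsq(design, y, rcond=None)[0]
        r2, _ = partial_effect(y, cov)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_one_when_scores_linear_in_genotype(self, rng):
        n = 12
        table = pd.DataFrame(
            {
                "genotype": ["HET" if i % 2 else "WT" for i in range(n)],
                "sex": ["F"] * n,
                "litter": ["L0"] * n,
            }
        )
        cov = build_covariates(table, factors=())
        y = np.outer(cov.genotype, [1.0, -2.0])
        r2, _ = partial_effect(y, cov)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_sse_oracle_on_small_case(self, rng):
        cov = _covariates(rng, 8)
        y = rng.normal(size=(8, 2))
        r2, _ = partial_effect(y, cov)
        assert r2 == pytest.approx(_sse_oracle(y, cov), abs=1e-10)

    def test_oracle_equivalence_property(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 25))
            m = int(rng.integers(1, 5))
            cov = _covariates(rng, n, litters=int(rng.integers(1, 4)))
            y = rng.normal(size=(n, m))
            r2, _ = partial_effect(y, cov)
            assert 0.0 <= r2 <= 1.0
            assert r2 == pytest.approx(_sse_oracle(y, cov), abs=1e-10)

    def test_invariant_to_nuisance_rescaling(self, rng):
        cov = _covariates(rng, 20)
        y = rng.normal(size=(20, 3))
        r2, _ = partial_effect(y, cov)
        scaled = CovariateTable(cov.genotype, cov.nuisance * np.array(
            [1.0] + [3.5] * (cov.nuisance.shape[1] - 1)))
        r2s, _ = partial_effect(y, scaled)
        assert r2s == pytest.approx(r2, abs=1e-12)

    def test_reference_swap_flips_coefficient_only(self, rng):
        cov = _covariates(rng, 20)
        y = rng.normal(size=(20, 3))
        r2, beta = partial_effect(y, cov)
        swapped = CovariateTable(1.0 - cov.genotype, cov.nuisance)
        r2s, beta_s = partial_effect(y, swapped)
        assert r2s == pytest.approx(r2, abs=1e-12)
        np.testing.assert_allclose(beta_s, -beta, atol=1e-12)

    def test_genotype_in_nuisance_span_rejected(self):
        n = 8
        table = pd.DataFrame(
            {
                "genotype": ["HET" if i % 2 else "WT" for i in range(n)],
                "sex": ["M" if i % 2 else "F" for i in range(n)],  # = genotype
                "litter": ["L0"] * n,
            }
        )
        with pytest.raises(CollinearityError):
            build_covariates(table)


class TestPermutationTest:
    def test_p_value_formula_extremes(self, rng):
        n = 10
        cov = _covariates(rng, n, litters=1)
        strong = np.outer(cov.genotype - cov.genotype.mean(), [1.0, 0.5])
        strong += 0.01 * rng.normal(size=strong.shape)
        _, p, perm_r2 = permutation_test(strong, cov, n_permutations=999, seed=0)
        assert p >= 1.0 / 1000.0
        if (perm_r2 < _obs(strong, cov)).all():
            assert p == pytest.approx(0.001)

    def test_observed_below_all_permuted_gives_one(self, rng):
        # scores exactly orthogonal to the contrast: observed R2 = 0,
        # every permutation ties or beats it
        cov = _covariates(rng, 16)
        y = rng.normal(size=(16, 3))
        design = np.column_stack([cov.nuisance, cov.genotype])
        y -= design @ np.linalg.lstsq(design, y, rcond=None)[0]
        _, p, _ = permutation_test(y, cov, n_permutations=99, seed=1)
        assert p == pytest.approx(1.0)

    def test_deterministic_given_seed(self, rng):
        cov = _covariates(rng, 20)
        y = rng.normal(size=(20, 4))
        out1 = permutation_test(y, cov, 200, seed=5)
        out2 = permutation_test(y, cov, 200, seed=5)
        assert out1[1] == out2[1]
        np.testing.assert_array_equal(out1[2], out2[2])

    def test_super_uniform_under_null(self, rng):
        """P(p <= alpha) <= alpha + 1/(n_perm+1) on exchangeable null data."""
        n_perm, alpha, reps = 99, 0.1, 120
        hits = 0
        cov = _covariates(rng, 18)
        for _ in range(reps):
            y = rng.normal(size=(18, 3))
            _, p, _ = permutation_test(y, cov, n_perm, seed=int(rng.integers(2**31)))
            hits += p <= alpha
        bound = alpha + 1.0 / (n_perm + 1)
        # allow 3 binomial standard errors above the bound
        assert hits / reps <= bound + 3 * np.sqrt(bound * (1 - bound) / reps)


class TestPerVertexEffects:
    def test_localization_of_injected_patch(self, template, effect_cohort):
        aligned, cov, model, scores, z, _ = analyze_cohort(effect_cohort)
        r2, coeff = per_vertex_effects(model, scores, cov)
        patch = set(effect_cohort.ground_truth.effect_patch.tolist())
        assert int(np.argmax(r2)) in patch
        assert np.all((0.0 <= r2) & (r2 <= 1.0))

    def test_outward_bump_gives_positive_displacement_in_patch(self, template):
        from craniomorph import default_effect_patch

        # compact patch: keeps the global size-renormalisation compensation
        # ("Pinocchio effect") well below the injected signal
        patch = default_effect_patch(template, n_rings=1)
        spec = CohortSpec(
            genotype_effect_amplitude=0.08, sex_effect_amplitude=0.0,
            litter_sd=0.0, noise_sd=1e-4, litter_count=1, seed=21,
            effect_patch=patch,
        )
        cohort = generate_cohort(template, spec)
        aligned, cov, model, scores, z, _ = analyze_cohort(cohort)
        r2, coeff = per_vertex_effects(model, scores, cov)
        disp = normal_displacement(model.mean_shape, template.faces, coeff)
        patch = cohort.ground_truth.effect_patch
        core = patch[np.argsort(
            -np.linalg.norm(cohort.ground_truth.effect_field[patch], axis=1))[:10]]
        outside = np.setdiff1d(np.arange(len(disp)), patch)
        assert np.all(disp[core] > 0)
        assert np.abs(disp[core]).min() > 5 * np.abs(disp[outside]).max()

    def test_null_r2_near_analytic_expectation(self, template, null_cohort):
        aligned, cov, model, scores, z, _ = analyze_cohort(null_cohort)
        r2, _ = per_vertex_effects(model, scores, cov)
        n, q = len(z), cov.nuisance.shape[1]
        expected = 1.0 / (n - q - 1)
        assert 0.3 * expected < r2.mean() < 3.0 * expected

    def test_dimension_mismatch_rejected(self, rng):
        aligned = _aligned_from_scores(rng, n=20)
        model, scores = fit_pca(aligned, 0.96)
        cov = _covariates(rng, 20)
        with pytest.raises(InvalidParameterError):
            per_vertex_effects(model, scores[:, :1], cov)

    def test_back_projection_consistency(self, rng):
        """With every component retained, vertex-space fitted values equal a
        direct vertex-space regression (the projection is lossless)."""
        aligned = _aligned_from_scores(rng, n=24, v=10)
        model, scores = fit_pca(aligned, threshold=1.0)
        cov = _covariates(rng, 24)
        z, sds = normalize_scores(scores)

        def residualize(y, zblock):
            return y - zblock @ np.linalg.lstsq(zblock, y, rcond=None)[0]

        zr = residualize(z, cov.nuisance)
        gr = residualize(cov.genotype[:, None], cov.nuisance).ravel()
        beta = gr @ zr / (gr @ gr)
        fitted_pc = np.outer(gr, beta * sds) @ model.retained_components

        x = aligned.shapes.reshape(24, -1) - aligned.shapes.reshape(24, -1).mean(0)
        xr = residualize(x, cov.nuisance)
        beta_x = gr @ xr / (gr @ gr)
        np.testing.assert_allclose(fitted_pc, np.outer(gr, beta_x), atol=1e-8)


class TestNormalDisplacement:
    def test_coefficient_equal_to_normal_gives_ones(self, template_small):
        v = np.asarray(template_small.vertices)
        normals = vertex_normals(v, template_small.faces)
        disp = normal_displacement(v, template_small.faces, normals)
        np.testing.assert_allclose(disp, 1.0, atol=1e-12)

    def test_tangent_field_gives_zero(self, template_small):
        v = np.asarray(template_small.vertices)
        normals = vertex_normals(v, template_small.faces)
        rng = np.random.default_rng(0)
        raw = rng.normal(size=v.shape)
        tangent = raw - (raw * normals).sum(axis=1, keepdims=True) * normals
        disp = normal_displacement(v, template_small.faces, tangent)
        np.testing.assert_allclose(disp, 0.0, atol=1e-8)

    def test_orientation_flip_negates_exactly(self, template_small, rng):
        v = np.asarray(template_small.vertices)
        faces = np.asarray(template_small.faces)
        field = rng.normal(size=v.shape)
        d1 = normal_displacement(v, faces, field)
        d2 = normal_displacement(v, faces[:, ::-1], field)
        np.testing.assert_array_equal(d2, -d1)


def _sse_oracle(y, cov):
    """Independent check: explicit full-vs-reduced least-squares fits."""
    z = cov.nuisance
    full = np.column_stack([z, cov.genotype])

    def sse(design):
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        return float(((y - design @ beta) ** 2).sum())

    sse_reduced = sse(z)
    sse_full = sse(full)
    return (sse_reduced - sse_full) / sse_reduced


def _obs(y, cov):
    r2, _ = partial_effect(y, cov)
    return r2
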