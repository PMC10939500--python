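import numpy as np
import pytest

from craniomorph import CohortSpec, generate_cohort, gpa, make_template
from craniomorph.stats import build_covariates, fit_pca, normalize_scores


@pytest.fixture(scope="session")
def template_small():
    """Coarse template for registration tests (V ~ 200)."""
    return make_template(8)


@pytest.fixture(scope="session")
def template():
    """Study-scale template (V ~ 500)."""
    return make_template(12)


@pytest.fixture(scope="session")
def effect_cohort(template):
    """Cohort with the default injected genotype effect, no transforms."""
    return generate_cohort(template, CohortSpec(seed=7))


@pytest.fixture(scope="session")
def null_cohort(template):
    """Cohort with the genotype effect switched off."""
    return generate_cohort(
        template, CohortSpec(genotype_effect_amplitude=0.0, seed=11)
    )


def analyze_cohort(cohort, n_permutations=500, threshold=0.96, seed=0):
    """Shared shortcut: GPA + PCA + normalised scores + covariates."""
    aligned = gpa(cohort.true_corresponded(), cohort.specimen_ids)
    covariates = build_covariates(cohort.covariates)
    model, scores = fit_pca(aligned, threshold)
    z, sds = normalize_scores(scores)
    return aligned, covariates, model, scores, z, sds


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
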