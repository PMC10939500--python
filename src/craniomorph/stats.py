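"""Shape-effect statistics: PCA reduction, dummy-coded partial regression,
permutation testing and per-vertex effect maps.

Aligned shapes are flattened and reduced to the principal components that
explain a target fraction of variance (default 96%). The genotype effect,
adjusted for nuisance covariates (sex, litter; each k-level factor coded as
k-1 dummy columns), is measured as a partial R²: PC scores are normalised
to unit variance, both scores and genotype contrast are residualised on the
nuisance design (Frisch–Waugh), and the partial R² is the variance the
residual contrast explains in the residual scores. With a single binary
contrast the one-component partial-least-squares step coincides exactly
with this least-squares solution.

Significance comes from a Freedman–Lane permutation test: the residualised
contrast is permuted, preserving the nuisance structure under the null, and
the p-value carries the +1 correction so its floor is 1/(n_perm + 1).

Per-vertex maps reverse the PC projection: fitted values and residuals are
de-normalised (multiplied by each PC's standard deviation) and carried back
to vertex space through the retained components, and a partial R² is formed
per vertex by pooling the x, y, z sums of squares. The genotype coefficient
back-projects to a per-vertex 3-vector (aligned-shape units per unit
contrast), summarised as signed displacement along the outward normal of
the mean shape (positive = protrusion, negative = depression).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CollinearityError, InvalidParameterError
from .geometry import vertex_normals
from .gpa import AlignedCohort
from .seeding import substream

__all__ = [
    "ShapeModel",
    "CovariateTable",
    "EffectResult",
    "fit_pca",
    "normalize_scores",
    "build_covariates",
    "partial_effect",
    "permutation_test",
    "per_vertex_effects",
    "normal_displacement",
    "genotype_effect",
]


@dataclass
class ShapeModel:
    mean_shape: np.ndarray  # (V, 3)
    components: np.ndarray  # (m_total, 3V), orthonormal rows
    variances: np.ndarray  # (m_total,), descending
    retained_m: int
    variance_threshold: float

    @property
    def retained_components(self) -> np.ndarray:
        return self.components[: self.retained_m]

    @property
    def retained_variances(self) -> np.ndarray:
        return self.variances[: self.retained_m]


@dataclass
class CovariateTable:
    """Binary genotype contrast plus an intercept-bearing nuisance block."""

    genotype: np.ndarray  # (N,) 0/1
    nuisance: np.ndarray  # (N, q) including intercept column
    nuisance_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype, dtype=float)
        self.nuisance = np.asarray(self.nuisance, dtype=float)
        n = len(self.genotype)
        if self.nuisance.shape[0] != n:
            raise InvalidParameterError("genotype / nuisance row mismatch")
        design = np.column_stack([self.nuisance, self.genotype])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            if np.linalg.matrix_rank(self.nuisance) < self.nuisance.shape[1]:
                raise CollinearityError("nuisance design is rank-deficient")
            raise CollinearityError(
                "genotype contrast lies in the span of the nuisance covariates"
            )


@dataclass
class EffectResult:
    global_partial_R2: float
    global_p: float
    n_permutations: int
    per_vertex_R2: np.ndarray  # (V,)
    coefficient_field: np.ndarray  # (V, 3)
    normal_displacement: np.ndarray  # (V,)
    retained_m: int
    seed: int | None = None


def build_covariates(
    table: pd.DataFrame,
    contrast: tuple[str, str] = ("WT", "HET"),
    factors: tuple[str, ...] = ("sex", "litter"),
) -> CovariateTable:
    """Dummy-code a manifest covariate table.

    ``contrast`` is (reference_label, variant_label) for the genotype
    column; each nuisance factor with k observed levels contributes k-1
    binary columns (first level is the baseline), plus one intercept.
    """
    ref, var = contrast
    geno_labels = table["genotype"].astype(str)
    unknown = set(geno_labels) - {ref, var}
    if unknown:
        raise InvalidParameterError(
            f"genotype labels {sorted(unknown)} not in contrast {contrast}"
        )
    genotype = (geno_labels == var).to_numpy(dtype=float)

    cols = [np.ones(len(table))]
    names = ["intercept"]
    for factor in factors:
        levels = sorted(table[factor].astype(str).unique())
        for level in levels[1:]:
            cols.append((table[factor].astype(str) == level).to_numpy(dtype=float))
            names.append(f"{factor}[{level}]")
    return CovariateTable(genotype, np.column_stack(cols), names)


def fit_pca(
    aligned: AlignedCohort, threshold: float = 0.96
) -> tuple[ShapeModel, np.ndarray]:
    """PCA of flattened aligned shapes; returns the model and (N, m) scores.

    ``retained_m`` is the smallest m whose cumulative variance fraction
    reaches ``threshold``.
    """
    if not 0.0 < threshold <= 1.0:
        raise InvalidParameterError("variance threshold must lie in (0, 1]")
    shapes = aligned.shapes
    n = len(shapes)
    if n < 2:
        raise InvalidParameterError("PCA needs at least 2 specimens")
    x = shapes.reshape(n, -1)
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    variances = s**2 / (n - 1)
    nonzero = variances > max(1e-30, variances[0] * 1e-14) if len(variances) else []
    components = vt[nonzero]
    variances = variances[nonzero]
    frac = np.cumsum(variances) / variances.sum()
    retained_m = int(np.searchsorted(frac, threshold - 1e-12) + 1)
    retained_m = min(retained_m, len(variances))
    model = ShapeModel(
        mean_shape=mean.reshape(-1, 3),
        components=components,
        variances=variances,
        retained_m=retained_m,
        variance_threshold=threshold,
    )
    scores = xc @ components[:retained_m].T
    return model, scores


def normalize_scores(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale each PC column to unit (sample) variance; returns (Z, sds)."""
    scores = np.asarray(scores, dtype=float)
    sds = scores.std(axis=0, ddof=1)
    if np.any(sds <= 0) or not np.all(np.isfinite(sds)):
        raise InvalidParameterError("zero-variance principal component score")
    return scores / sds, sds


def _residualize(y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Least-squares residual of y on the column space of z."""
    beta, *_ = np.linalg.lstsq(z, y, rcond=None)
    return y - z @ beta


def partial_effect(
    scores: np.ndarray, covariates: CovariateTable
) -> tuple[float, np.ndarray]:
    """Partial R² of the genotype contrast on (normalised) PC scores.

    Both scores and contrast are residualised on the nuisance block; the
    single-predictor regression of residual scores on the residual contrast
    gives R² = ESS / TSS pooled over all PC columns, equal to
    (SSE_reduced - SSE_full) / SSE_reduced of the full-vs-nuisance fits.
    Returns (partial_R2, genotype coefficient vector in PC space).
    """
    y = np.atleast_2d(np.asarray(scores, dtype=float))
    yr = _residualize(y, covariates.nuisance)
    gr = _residualize(covariates.genotype[:, None], covariates.nuisance).ravel()
    gg = float(gr @ gr)
    if gg <= 1e-12 * len(gr):
        raise CollinearityError(
            "genotype contrast is (numerically) collinear with nuisance block"
        )
    beta = (gr @ yr) / gg
    ess = float(gg * (beta @ beta))
    tss = float((yr * yr).sum())
    if tss == 0.0:
        raise InvalidParameterError("scores have zero residual variance")
    return ess / tss, beta


def permutation_test(
    scores: np.ndarray,
    covariates: CovariateTable,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Freedman–Lane permutation p-value for the global partial R².

    The residualised contrast is permuted (nuisance structure is preserved
    under the null), re-residualised on the nuisance block — a permuted
    vector is no longer orthogonal to it, and skipping this step deflates
    the permutation distribution — and the statistic is recomputed;
    p = (1 + #{R²_perm >= R²_obs}) / (1 + n_permutations).
    Returns (observed R², p, permuted R² values).
    """
    if n_permutations < 1:
        raise InvalidParameterError("n_permutations must be >= 1")
    y = np.atleast_2d(np.asarray(scores, dtype=float))
    yr = _residualize(y, covariates.nuisance)
    gr = _residualize(covariates.genotype[:, None], covariates.nuisance).ravel()
    gg = float(gr @ gr)
    if gg <= 1e-12 * len(gr):
        raise CollinearityError("degenerate residual contrast")
    tss = float((yr * yr).sum())
    observed = float(((gr @ yr) ** 2).sum() / gg) / tss

    rng = substream(seed, "freedman-lane-permutations")
    n = len(gr)
    perms = np.empty((n_permutations, n))
    for k in range(n_permutations):
        perms[k] = gr[rng.permutation(n)]
    perms -= np.linalg.lstsq(covariates.nuisance, perms.T, rcond=None)[0].T @ covariates.nuisance.T
    gg_perm = (perms * perms).sum(axis=1)
    num = perms @ yr  # (n_perm, m)
    r2 = (num * num).sum(axis=1) / np.maximum(gg_perm, 1e-300) / tss
    p = (1.0 + int(np.count_nonzero(r2 >= observed))) / (1.0 + n_permutations)
    return observed, p, r2


def per_vertex_effects(
    model: ShapeModel,
    scores: np.ndarray,
    covariates: CovariateTable,
) -> tuple[np.ndarray, np.ndarray]:
    """Reverse the PC projection and compute a partial R² per vertex.

    Returns (per_vertex_R2 (V,), coefficient_field (V, 3)); the coefficient
    field is in aligned-shape units per unit genotype contrast.
    """
    z, sds = normalize_scores(scores)
    if z.shape[1] != model.retained_m:
        raise InvalidParameterError(
            f"scores have {z.shape[1]} columns, model retains {model.retained_m}"
        )
    comps = model.retained_components  # (m, 3V)
    zr = _residualize(z, covariates.nuisance)
    gr = _residualize(covariates.genotype[:, None], covariates.nuisance).ravel()
    gg = float(gr @ gr)
    beta = (gr @ zr) / gg  # PC-space coefficients on normalised scores

    # de-normalise and back-project to vertex space
    resid_reduced = (zr * sds) @ comps  # (N, 3V)
    resid_full = ((zr - np.outer(gr, beta)) * sds) @ comps
    nv = model.mean_shape.shape[0]
    sse_reduced = (resid_reduced**2).reshape(len(zr), nv, 3).sum(axis=(0, 2))
    sse_full = (resid_full**2).reshape(len(zr), nv, 3).sum(axis=(0, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sse_reduced > 0, (sse_reduced - sse_full) / sse_reduced, 0.0)
    coefficient_field = ((beta * sds) @ comps).reshape(nv, 3)
    return r2, coefficient_field


def normal_displacement(
    mean_shape: np.ndarray, faces: np.ndarray, coefficient_field: np.ndarray
) -> np.ndarray:
    """Signed displacement along outward vertex normals of the mean shape
    (area-weighted face-normal average); positive = outward."""
    normals = vertex_normals(mean_shape, faces)
    field = np.asarray(coefficient_field, dtype=float)
    if field.shape != normals.shape:
        raise InvalidParameterError("coefficient field / mesh size mismatch")
    return np.einsum("ij,ij->i", field, normals)


def genotype_effect(
    aligned: AlignedCohort,
    covariates: CovariateTable,
    faces: np.ndarray,
    variance_threshold: float = 0.96,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> EffectResult:
    """Full effect analysis on an aligned cohort (the per-bone workflow)."""
    model, scores = fit_pca(aligned, variance_threshold)
    z, _ = normalize_scores(scores)
    r2, p, _ = permutation_test(z, covariates, n_permutations, seed)
    vertex_r2, coeff = per_vertex_effects(model, scores, covariates)
    disp = normal_displacement(model.mean_shape, faces, coeff)
    return EffectResult(
        global_partial_R2=r2,
        global_p=p,
        n_permutations=n_permutations,
        per_vertex_R2=vertex_r2,
        coefficient_field=coeff,
        normal_displacement=disp,
        retained_m=model.retained_m,
        seed=seed,
    )
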