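# Methods

## Synthetic cohorts

The generator produces the statistical structure the downstream analysis
assumes, with known ground truth for recovery tests.

**Template.** A deterministic closed genus-0 surface: a unit sphere mapped
through a superellipsoid exponent (0.75), scaled to semi-axes
(1.0, 0.62, 0.38) and given a smooth dorsal ridge. The anisotropy makes
rotations and reflections identifiable; the ridge gives registration a
curvature feature to lock onto. `resolution` controls the UV sphere density
(resolution 12 → 482 vertices, the scale used throughout the studies here).
Coordinates are in arbitrary length units of order 1.

**Specimen model.** Specimen *i* in litter ℓ with genotype g∈{0,1} and sex
s∈{0,1} is

    x_i = template
        + g · A_g · bump(patch) · n̂        (localized genotype effect)
        + s · A_s · f(x) · n̂               (smooth global sex effect)
        + B a_ℓ                            (litter random field)
        + ε,  ε ~ N(0, σ²_noise I)

optionally followed by a random similarity transform (rotation from a
QR-orthonormalised Gaussian matrix, log-normal scale sd 0.1, translation sd
0.25·bbox diagonal). `bump` is a cos² profile of BFS ring depth, exactly
zero outside the patch; `f` is a low-frequency sine along the
anteroposterior axis; `B` is a row-normalised Gaussian radial basis on 10
farthest-point centers (length scale 0.25·bbox diagonal), so with
coefficients a_ℓ ~ N(0, σ²_litter) every vertex coordinate of the litter
field has variance exactly σ²_litter, shared within a litter. Litter is
thus a *structured* confounder — smooth and litter-shared — not iid noise.

**Design.** Genotypes interleave; litters rotate round-robin within each
genotype group (every litter appears in both groups whenever
litter_count ≤ group size); sex alternates in litter-sized blocks so it is
not collinear with litter. Default cohort: 20 reference + 24 variant
specimens across 7 litters.

**Default amplitudes.** The source study reports permutation p-values but no
physical effect sizes, so these are free parameters chosen once: noise sd
0.01 (~1% of the bone's long axis — registration/segmentation-scale error),
litter sd 0.005, sex amplitude 0.01, genotype amplitude 0.05 on a 3-ring
patch (~100 of 482 vertices). This places the genotype effect in the
"subtle but statistically detectable at N≈44" regime that motivates dense
morphometrics in the first place; the parameter-recovery studies are
self-referential by construction, which is what a calibration of the
machinery requires.

**Decorrespondence.** To give registration a genuine task, targets are
midpoint-subdivided (≈4× the vertices, no shared tessellation) and their
vertices randomly relabelled. The true position of every template vertex is
retained, so correspondence error is measurable exactly. This is a
re-tessellation rather than a full isotropic remesh; it preserves the
surface exactly, which makes ground truth exact as well.

**Randomness.** Every stochastic quantity draws from a named substream of a
single user seed (`seeding.substream`), so cohorts are bit-reproducible and
independent stages do not perturb one another's draws.

What the generator does *not* emulate: imaging/segmentation artefacts,
missing or partial surfaces, bilateral symmetry, allometry, and
measurement-correlated noise. Passing tests therefore demonstrate that the
statistical machinery is calibrated and recovers effects under its own
assumptions — not that those assumptions hold for any particular micro-CT
dataset.

## Registration

Two phases. (1) A least-squares similarity transform (Umeyama's solution;
reflections disallowed) fitted to ≥3 named fiducial landmarks; collinear
configurations are rejected. (2) Non-rigid ICP: each template vertex moves a
fraction `step` (default 0.5) of its Gaussian-smoothed displacement toward
its closest point on the target surface. Closest points are vertex-to-
*triangle* (kd-tree vertex candidates, exact point–triangle projection), so
re-tessellated targets need no shared vertices. Smoothing weights are
Gaussian in template edge-graph distances (a geodesic proxy) with width
annealed geometrically from 0.4 to 0.05 of the template diameter over 40
iterations — coarse alignment first, local detail last. In the σ→∞ limit
the update degenerates to a global translation. Defaults were tuned on
synthetic targets only; on decorresponded, similarity-transformed targets
the mean correspondence error is ~5–15% of the target's median edge length.
Non-convergence (no new best residual within a 5-iteration patience window)
is flagged in the result, not fatal.

## Generalized Procrustes analysis

Full Procrustes: shapes are centered, scaled to unit centroid size, and
rotated (Kabsch, det +1 enforced — bones are chiral) to the evolving mean,
which is renormalised each round; iteration stops when the mean moves less
than `tol` (default 1e-10, max 100 iterations). The optimum is defined only
up to a global rotation; the implementation anchors the result by a single
final rotation onto the input orientation. This makes GPA a fixed point on
already-aligned cohorts (idempotence) and keeps output deterministic in the
input ordering up to that invariance. No tangent-space projection is
applied before PCA: shape variation in this setting is small (Procrustes
distances ≪ 1), where the linear approximation is standard practice. No
semilandmark sliding, no symmetrisation.

## Effect statistics

- **PCA**: SVD of the flattened aligned shapes about their mean; retain the
  smallest m whose cumulative variance fraction reaches the threshold
  (default 0.96). Scores are normalised to unit sample variance (ddof 1).
- **Partial R²**: double residualisation (Frisch–Waugh) of scores and
  genotype contrast on the nuisance block (intercept + k−1 dummies per
  factor). With a single binary contrast, one-component PLS coincides with
  this least-squares solution, so the implementation *is* the degenerate
  PLS. Equal to (SSE_reduced − SSE_full)/SSE_reduced; property-tested
  against that oracle at 1e-10.
- **Permutation test**: the residualised contrast is permuted and
  *re-residualised* on the nuisance block each time. The re-residualisation
  matters: a permuted vector is no longer orthogonal to the nuisance space,
  and skipping the step deflates the permutation distribution (observed
  type-I error ~0.70 at nominal 0.05 before the fix). p-values carry the +1
  correction, so min p = 1/(n_perm+1) and the test is valid at any n_perm.
- **Per-vertex maps**: fitted values and residuals are de-normalised
  (multiplied by each PC's sd) and carried to vertex space through the
  retained components; per vertex, x/y/z sums of squares are pooled into a
  single partial R². The genotype coefficient back-projects to a [V×3]
  field in aligned-shape units per unit contrast, summarised as its dot
  product with the outward unit vertex normal (area-weighted average of
  incident face normals, assembled in a canonical edge order so an
  orientation flip negates the field exactly). No multiple-testing
  correction across vertices: the per-vertex output is an effect-size map.
- Because GPA rescales every specimen to unit size, a purely outward local
  effect induces a small compensatory inward signal elsewhere (the
  "Pinocchio effect" of size renormalisation). This is inherent to
  Procrustes shape space, visible in the synthetic constructed cases, and
  bounded by patch-size/total-size; interpret per-vertex maps accordingly.

## Population differentiation and ddPCR

`hudson_fst` is the two-population Hudson estimator
(p₁−p₂)²/(p₁(1−p₂)+p₂(1−p₁)) without finite-sample correction (correction
terms are O(1/n), negligible at reference-panel sample sizes);
`wright_fst` is the heterozygosity partition (H_T−H_S)/H_T with explicit
population weights. Both are undefined when both populations are fixed for
the same allele and error accordingly.

ddPCR concentration: λ = −ln(1 − k/D) copies/droplet from k positive of D
droplets; saturation (k = D) is an error, not infinity. The allelic
fraction λ₁/(λ₁+λ₂) gets a 95% CI by delta-method propagation of each
channel's binomial variance, Var(λ̂) ≈ p/(D(1−p)) — closed-form and, by
Monte-Carlo simulation at D = 20,000, covering the truth ~95–98% of the
time. The duplex-assay simulator lets both alleles occupy the same droplet
(double positives count in both channels). `expression_change` reports the
percent *decrease* of the edited allele's concentration ratio relative to a
genomic-DNA calibration ratio (positive = reduced expression); CIs are not
propagated through this ratio-of-ratios.

## Numerical choices and degenerate inputs

- Vertex indexing is 0-based internally; OBJ's 1-based indices are converted
  only at file boundaries. Units are an opaque string (default µm); no
  conversion.
- Zero-size (all-coincident) shapes, collinear landmark sets, empty targets,
  rank-deficient designs, contrasts inside the nuisance span, zero-variance
  PC columns, ddPCR saturation, and F_ST's 0/0 cases all raise typed errors
  rather than propagating NaNs.
- Permutation ties count as exceedances (≥), keeping the test conservative.
- The pipeline writes a report with config echo, input SHA-256 hashes, seed
  and package version; reruns with identical config and seed are
  byte-identical apart from user-chosen paths.

## Problem sizes used in the checked studies

Template resolution 12 (V=482) for all cohort-level studies; N=44 cohorts;
500 permutations and 100–200 replicates for the calibration/power/
localization simulations; 10,000 permutations for the single reference
analysis; registration recovery at resolution 8 (V=194) with subdivided
targets (~770 vertices). These sizes give stable rates (binomial se ≈ 2% at
200 replicates) while keeping the full suite and the acceptance script in
the tens of seconds on one CPU.

## Known limitations

- The registration is a deliberately compact two-phase scheme, not a
  re-implementation of a production registration toolbox: no symmetric
  term, no missing-data handling, no stiffness scheduling beyond the
  annealed Gaussian width.
- Litter enters as a fixed dummy-coded nuisance factor, not a random
  effect; with 7 litters and N=44 this costs 6 df but avoids mixed-model
  machinery in the permutation scheme.
- Multi-predictor PLS (several simultaneous contrasts) is not implemented;
  the single-contrast case is exact as least squares.
- The kd-tree candidate search for closest triangles (k=8 nearest vertices'
  incident faces) is exact on smooth, reasonably uniform meshes but could
  miss the true nearest face on wildly non-uniform tessellations.
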