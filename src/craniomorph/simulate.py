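"""Synthetic cohorts of corresponded bone-like surfaces with known ground
truth, and a droplet-digital PCR simulator.

The generator emulates the statistical structure a litter-based knockout
cross produces: a localized genotype effect along the outward surface
normals, a smooth global sex effect, litter-shared smooth random
displacement fields (litter is a structured confounder, not iid noise),
iid per-vertex Gaussian noise, and an arbitrary similarity transform per
specimen (each animal is scanned in its own position, orientation and
scale). Optionally the surfaces are re-tessellated and vertex-relabelled
("decorresponded") so the registration stage has a genuine task.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .ddpcr import DropletCounts
from .exceptions import InvalidParameterError
from .geometry import (
    SimilarityTransform,
    as_mesh,
    bounding_box_diagonal,
    vertex_normals,
    vertex_rings,
)
from .meshio import (
    CohortManifest,
    LandmarkSet,
    write_landmarks_csv,
    write_manifest,
    write_obj,
)
from .seeding import substream

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "SyntheticCohort",
    "make_template",
    "template_landmarks",
    "default_effect_patch",
    "generate_cohort",
    "write_cohort",
    "simulate_ddpcr",
]

GENOTYPE_LABELS = ("WT", "HET")
SEX_LABELS = ("F", "M")


def make_template(resolution: int) -> trimesh.Trimesh:
    """Deterministic closed bone-like template surface.

    A flattened superellipsoid (squared-off cross sections, distinct
    semi-axes) with a smooth dorsal ridge — enough anisotropy and local
    curvature that rotations, reflections and localized effects are all
    identifiable. Vertex count grows monotonically with ``resolution``.
    """
    if resolution < 3:
        raise InvalidParameterError("resolution must be >= 3")
    sphere = trimesh.creation.uv_sphere(radius=1.0, count=(resolution, 2 * resolution))
    u = np.asarray(sphere.vertices, dtype=float)

    # superellipsoid exponent: push points toward the unit cube corners
    exponent = 0.75
    v = np.sign(u) * np.abs(u) ** exponent
    # elongated, flattened semi-axes (arbitrary length units)
    v = v * np.array([1.0, 0.62, 0.38])
    # smooth dorsal ridge: raised z on the upper side near x ~ +0.3
    upper = 0.5 * (1.0 + np.tanh(v[:, 2] / 0.1))
    ridge = 0.10 * np.exp(-((v[:, 0] - 0.3) ** 2 + v[:, 1] ** 2) / 0.08)
    v[:, 2] += upper * ridge
    return as_mesh(v, sphere.faces)


def template_landmarks(template: trimesh.Trimesh) -> tuple[LandmarkSet, np.ndarray]:
    """Six sparse fiducials at the template's axis extremes.

    Returns the landmark set and the template vertex indices it samples,
    so corresponding fiducials can be placed exactly on any deformed copy.
    """
    v = np.asarray(template.vertices, dtype=float)
    idx, names = [], []
    for axis, (lo, hi) in enumerate(
        [("posterior", "anterior"), ("right", "left"), ("ventral", "dorsal")]
    ):
        idx += [int(np.argmin(v[:, axis])), int(np.argmax(v[:, axis]))]
        names += [lo, hi]
    idx = np.asarray(idx, dtype=np.int64)
    return LandmarkSet(names, v[idx]), idx


def default_effect_patch(template: trimesh.Trimesh, center: int | None = None,
                         n_rings: int = 3) -> np.ndarray:
    """A connected vertex patch: ``n_rings`` edge rings around a center.

    Default center is the vertex nearest the ridge apex, mimicking an
    effect concentrated on one anatomical feature.
    """
    v = np.asarray(template.vertices, dtype=float)
    if center is None:
        target = np.array([0.3, 0.0, v[:, 2].max()])
        center = int(np.argmin(np.linalg.norm(v - target, axis=1)))
    return vertex_rings(template.faces, len(v), [center], n_rings)


@dataclass
class CohortSpec:
    """Study-condition parameters for one synthetic cohort.

    ``n_per_group`` may be a single integer (balanced design) or a
    ``(n_reference, n_variant)`` pair for unbalanced cohorts. Amplitudes
    and standard deviations are in template length units.
    """

    n_per_group: int | tuple[int, int] = (20, 24)
    genotype_effect_amplitude: float = 0.05
    effect_patch: np.ndarray | None = None
    sex_effect_amplitude: float = 0.01
    litter_count: int = 7
    litter_sd: float = 0.005
    noise_sd: float = 0.01
    apply_similarity_transforms: bool = False
    decorrespond: bool = False
    seed: int = 0

    def group_sizes(self) -> tuple[int, int]:
        if isinstance(self.n_per_group, (int, np.integer)):
            return int(self.n_per_group), int(self.n_per_group)
        n0, n1 = self.n_per_group
        return int(n0), int(n1)

    def validate(self) -> None:
        n0, n1 = self.group_sizes()
        if n0 < 0 or n1 < 0:
            raise InvalidParameterError("group sizes must be non-negative")
        if n0 + n1 == 0:
            raise InvalidParameterError("empty cohort: both group sizes are zero")
        for name in ("genotype_effect_amplitude", "sex_effect_amplitude",
                     "litter_sd", "noise_sd"):
            val = getattr(self, name)
            if not np.isfinite(val):
                raise InvalidParameterError(f"{name} must be finite")
        if self.litter_sd < 0 or self.noise_sd < 0:
            raise InvalidParameterError("standard deviations must be >= 0")
        if self.litter_count < 1:
            raise InvalidParameterError("litter_count must be >= 1")
        if self.genotype_effect_amplitude != 0 and (
            self.effect_patch is not None and len(self.effect_patch) == 0
        ):
            raise InvalidParameterError(
                "empty effect_patch with nonzero genotype amplitude"
            )


@dataclass
class GroundTruth:
    """Everything a recovery test needs about how the cohort was made."""

    transforms: list[SimilarityTransform]
    true_coordinates: np.ndarray  # (N, V, 3) template vertices in target frame
    effect_field: np.ndarray  # (V, 3) genotype displacement per unit contrast
    effect_patch: np.ndarray  # vertex indices carrying the effect
    correspondence: list[np.ndarray]  # per specimen: target idx of template vtx i
    # (bijective onto the original vertices when decorrespond is off)


@dataclass
class SyntheticCohort:
    template: trimesh.Trimesh
    specimen_ids: list[str]
    meshes: list[trimesh.Trimesh]  # target-frame surfaces
    landmarks: list[LandmarkSet]  # target-frame fiducials
    covariates: pd.DataFrame  # specimen_id, genotype, sex, litter
    ground_truth: GroundTruth
    spec: CohortSpec = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.specimen_ids)

    def true_corresponded(self) -> np.ndarray:
        """Ground-truth corresponded coordinates, (N, V, 3)."""
        return self.ground_truth.true_coordinates.copy()


def _bump_profile(template: trimesh.Trimesh, patch: np.ndarray) -> np.ndarray:
    """Smooth profile in [0, 1] supported exactly on ``patch`` (cos^2 of
    normalized BFS ring depth from the patch center), zero elsewhere."""
    faces = np.asarray(template.faces, dtype=np.int64)
    nv = len(template.vertices)
    in_patch = np.zeros(nv, dtype=bool)
    in_patch[patch] = True
    # ring depth measured from the patch "core": vertices whose full ring
    # neighbourhood stays inside the patch
    depth = np.full(nv, np.inf)
    centroid = np.asarray(template.vertices, dtype=float)[patch].mean(axis=0)
    core = patch[
        np.argmin(
            np.linalg.norm(
                np.asarray(template.vertices, dtype=float)[patch] - centroid, axis=1
            )
        )
    ]
    frontier = {int(core)}
    depth[core] = 0
    d = 0
    while frontier:
        d += 1
        ring = vertex_rings(faces, nv, list(frontier), 1)
        nxt = {int(i) for i in ring if in_patch[i] and depth[i] == np.inf}
        for i in nxt:
            depth[i] = d
        frontier = nxt
    profile = np.zeros(nv)
    finite = np.isfinite(depth)
    if d > 0:
        profile[finite] = np.cos(0.5 * np.pi * depth[finite] / (d + 1)) ** 2
    else:
        profile[finite] = 1.0
    return profile


def _sex_field(template: trimesh.Trimesh, normals: np.ndarray) -> np.ndarray:
    """Smooth unit-amplitude global field: low-frequency modulation along
    the anteroposterior axis, displacing along outward normals."""
    x = np.asarray(template.vertices, dtype=float)[:, 0]
    span = x.max() - x.min()
    f = np.sin(2.0 * np.pi * (x - x.min()) / span)
    return f[:, None] * normals


def _litter_basis(template: trimesh.Trimesh, n_basis: int = 10) -> np.ndarray:
    """Row-normalised Gaussian radial basis (V, n_basis) on farthest-point
    centers; with N(0, sd^2) coefficients each vertex coordinate of the
    litter field has variance exactly sd^2."""
    v = np.asarray(template.vertices, dtype=float)
    centers = [0]
    dist = np.linalg.norm(v - v[0], axis=1)
    for _ in range(n_basis - 1):
        nxt = int(np.argmax(dist))
        centers.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(v - v[nxt], axis=1))
    scale = 0.25 * bounding_box_diagonal(v)
    d = np.linalg.norm(v[:, None, :] - v[None, centers, :], axis=2)
    basis = np.exp(-0.5 * (d / scale) ** 2)
    return basis / np.linalg.norm(basis, axis=1, keepdims=True)


def _random_similarity(rng: np.random.Generator, extent: float) -> SimilarityTransform:
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    scale = float(np.exp(rng.normal(0.0, 0.1)))
    translation = rng.normal(0.0, 0.25 * extent, size=3)
    return SimilarityTransform(scale, q, translation)


def _decorrespond(mesh: trimesh.Trimesh, rng: np.random.Generator) -> trimesh.Trimesh:
    """Break vertex correspondence: midpoint-subdivide (new, denser
    tessellation) then randomly relabel all vertices."""
    new_v, new_f = trimesh.remesh.subdivide(
        np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces, dtype=np.int64)
    )
    perm = rng.permutation(len(new_v))
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return as_mesh(new_v[perm], inv[new_f])


def generate_cohort(template: trimesh.Trimesh, spec: CohortSpec) -> SyntheticCohort:
    """Simulate one cohort; bit-identical for a fixed ``spec.seed``.

    Each specimen's true shape is
    ``template + g_i * amplitude * bump * normal + s_i * sex_field
    + litter_field(litter_i) + noise``, optionally followed by a random
    similarity transform and (optionally) de-correspondence.
    """
    spec.validate()
    n0, n1 = spec.group_sizes()
    verts = np.asarray(template.vertices, dtype=float)
    nv = len(verts)
    normals = vertex_normals(verts, template.faces)

    patch = (
        np.asarray(spec.effect_patch, dtype=np.int64)
        if spec.effect_patch is not None
        else default_effect_patch(template)
    )
    effect_field = (
        spec.genotype_effect_amplitude * _bump_profile(template, patch)[:, None] * normals
    )
    sex_field = spec.sex_effect_amplitude * _sex_field(template, normals)

    # design: interleave genotypes; litters round-robin within each group so
    # every litter appears in both groups whenever litter_count <= group size;
    # sex alternates in litter-sized blocks so it is not confounded with litter
    order: list[tuple[int, int, int]] = []  # (genotype, litter, sex)
    for g, n in ((0, n0), (1, n1)):
        for j in range(n):
            order.append((g, j % spec.litter_count, (j // spec.litter_count) % 2))
    # interleave the two groups to avoid any accidental ordering structure
    interleaved: list[tuple[int, int, int]] = []
    g0 = [o for o in order if o[0] == 0]
    g1 = [o for o in order if o[0] == 1]
    for k in range(max(len(g0), len(g1))):
        if k < len(g0):
            interleaved.append(g0[k])
        if k < len(g1):
            interleaved.append(g1[k])
    n_total = len(interleaved)

    rng_litter = substream(spec.seed, "litter-fields")
    rng_noise = substream(spec.seed, "vertex-noise")
    rng_xform = substream(spec.seed, "similarity-transforms")
    rng_mesh = substream(spec.seed, "decorrespond")

    basis = _litter_basis(template)
    litter_fields = {
        lit: basis @ rng_litter.normal(0.0, spec.litter_sd, size=(basis.shape[1], 3))
        for lit in range(spec.litter_count)
    }

    lm_set, lm_idx = template_landmarks(template)
    extent = bounding_box_diagonal(verts)

    ids, meshes, lm_list, rows = [], [], [], []
    transforms, truth, corr = [], [], []
    for i, (g, lit, sex) in enumerate(interleaved):
        shape = verts + g * effect_field + sex * sex_field + litter_fields[lit]
        shape = shape + rng_noise.normal(0.0, spec.noise_sd, size=(nv, 3))
        if spec.apply_similarity_transforms:
            xf = _random_similarity(rng_xform, extent)
        else:
            xf = SimilarityTransform.identity()
        shape_t = xf.apply(shape)
        target = as_mesh(shape_t, template.faces)
        mapping = np.arange(nv)
        if spec.decorrespond:
            target = _decorrespond(target, rng_mesh)
            # template vertex i's true position is still shape_t[i]; after
            # subdivision+permutation its index in the target is unknown by
            # construction, so the map is positional truth only
            mapping = np.full(nv, -1)

        sid = f"S{i:03d}"
        ids.append(sid)
        meshes.append(target)
        lm_list.append(LandmarkSet(list(lm_set.names), shape_t[lm_idx]))
        rows.append(
            {
                "specimen_id": sid,
                "genotype": GENOTYPE_LABELS[g],
                "sex": SEX_LABELS[sex],
                "litter": f"L{lit}",
            }
        )
        transforms.append(xf)
        truth.append(shape_t)
        corr.append(mapping)

    gt = GroundTruth(
        transforms=transforms,
        true_coordinates=np.stack(truth) if truth else np.zeros((0, nv, 3)),
        effect_field=effect_field,
        effect_patch=patch,
        correspondence=corr,
    )
    covariates = pd.DataFrame(rows)
    return SyntheticCohort(template, ids, meshes, lm_list, covariates, gt, spec)


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Write per-specimen OBJ + landmark CSVs, a manifest CSV, and ground
    truth (JSON metadata + NPZ coordinate arrays). Returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_obj(cohort.template, outdir / "template.obj")
    tmpl_lms, _ = template_landmarks(cohort.template)
    write_landmarks_csv(tmpl_lms, outdir / "template_landmarks.csv")

    rows = []
    for sid, mesh, lms, (_, cov) in zip(
        cohort.specimen_ids, cohort.meshes, cohort.landmarks,
        cohort.covariates.iterrows(),
    ):
        write_obj(mesh, outdir / f"{sid}.obj")
        write_landmarks_csv(lms, outdir / f"{sid}_landmarks.csv")
        rows.append(
            {
                "specimen_id": sid,
                "mesh_path": f"{sid}.obj",
                "landmark_path": f"{sid}_landmarks.csv",
                "genotype": cov["genotype"],
                "sex": cov["sex"],
                "litter": cov["litter"],
            }
        )
    manifest = CohortManifest(pd.DataFrame(rows), list(GENOTYPE_LABELS))
    manifest_path = outdir / "manifest.csv"
    write_manifest(manifest, manifest_path)

    gt = cohort.ground_truth
    np.savez(
        outdir / "ground_truth.npz",
        true_coordinates=gt.true_coordinates,
        effect_field=gt.effect_field,
        effect_patch=gt.effect_patch,
    )
    meta = {
        "transforms": [
            {
                "scale": t.scale,
                "rotation": np.asarray(t.rotation).tolist(),
                "translation": np.asarray(t.translation).tolist(),
            }
            for t in gt.transforms
        ],
        "effect_patch": gt.effect_patch.tolist(),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(meta, indent=1))
    return manifest_path


def simulate_ddpcr(
    total_molecules: int, allele_fraction: float, droplets: int, seed: int
) -> DropletCounts:
    """Partition two allelic template species into droplets.

    Each of ``total_molecules`` is allele 1 with probability
    ``allele_fraction`` (FAM probe) else allele 2 (HEX probe); molecules
    land in droplets uniformly at random; a droplet is channel-positive if
    it holds >= 1 molecule of that channel's allele. Double-positives count
    in both channels, as in a duplex assay.
    """
    if droplets < 1:
        raise InvalidParameterError("droplets must be >= 1")
    if not 0.0 <= allele_fraction <= 1.0:
        raise InvalidParameterError("allele_fraction must lie in [0, 1]")
    if total_molecules < 0:
        raise InvalidParameterError("total_molecules must be >= 0")
    rng = substream(seed, "ddpcr-droplets")
    n1 = int(rng.binomial(total_molecules, allele_fraction))
    n2 = total_molecules - n1
    fam = int(np.count_nonzero(np.bincount(
        rng.integers(0, droplets, size=n1), minlength=droplets))) if n1 else 0
    hexp = int(np.count_nonzero(np.bincount(
        rng.integers(0, droplets, size=n2), minlength=droplets))) if n2 else 0
    return DropletCounts(droplets=droplets, fam_positive=fam, hex_positive=hexp)
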