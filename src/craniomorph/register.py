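"""Dense surface correspondence via template registration.

Every specimen surface is brought into the vertex topology of one template
mesh by a two-phase scheme: a least-squares similarity fit on sparse named
fiducial landmarks, then a non-rigid iterative-closest-point refinement in
which per-vertex displacements toward the target surface are smoothed with
a Gaussian kernel over template edge-graph (geodesic proxy) distances. The
kernel width anneals from coarse to fine so large-scale shape differences
are absorbed before local detail. After registration, template vertex ``i``
denotes the same anatomical locus on every specimen — a spatially dense
analogue of a traditional landmark.

Nearest-point queries are point-to-surface (vertex to triangle), never
vertex-to-vertex: re-tessellated targets share no vertices with the
template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .exceptions import DegenerateGeometryError, InvalidParameterError, ManifestError
from .geometry import (
    SimilarityTransform,
    SurfaceLocator,
    graph_distances,
)
from .meshio import CohortManifest, LandmarkSet, read_landmarks_csv, read_obj

__all__ = [
    "CorrespondedCohort",
    "RegistrationParams",
    "RegistrationResult",
    "rigid_initialize",
    "nonrigid_register",
    "build_cohort",
    "save_cohort_archive",
    "load_cohort_archive",
]


@dataclass
class CorrespondedCohort:
    """Cohort expressed in template topology: (N, V, 3) coordinate block."""

    coordinates: np.ndarray
    specimen_ids: list[str]
    template: trimesh.Trimesh | None = None
    diagnostics: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise InvalidParameterError("coordinates must be (N, V, 3)")
        if self.template is not None and self.coordinates.shape[1] != len(
            self.template.vertices
        ):
            raise InvalidParameterError("V does not match template vertex count")
        if not np.all(np.isfinite(self.coordinates)):
            raise InvalidParameterError("non-finite coordinates in cohort")

    def __len__(self) -> int:
        return len(self.specimen_ids)


@dataclass
class RegistrationParams:
    """Non-rigid refinement controls.

    ``sigma_start``/``sigma_end`` are the first/last Gaussian smoothing
    widths in units of the template bounding-box diagonal; annealing is
    geometric across iterations. ``step`` is the fraction of the smoothed
    displacement applied per iteration.
    """

    iterations: int = 40
    sigma_start: float = 0.4
    sigma_end: float = 0.05
    step: float = 0.5
    patience: int = 5

    def validate(self) -> None:
        if min(self.iterations, self.patience) < 1 or min(
            self.sigma_start, self.sigma_end, self.step
        ) <= 0:
            raise InvalidParameterError("registration parameters must be positive")


@dataclass
class RegistrationResult:
    mapped_vertices: np.ndarray  # (V, 3) template vertices on the target
    residuals: np.ndarray  # mean vertex-to-surface distance per iteration
    converged: bool


def rigid_initialize(
    template_landmarks: LandmarkSet, target_landmarks: LandmarkSet
) -> SimilarityTransform:
    """Least-squares similarity transform mapping template fiducials onto
    target fiducials (Umeyama's solution of the orthogonal Procrustes
    problem with isotropic scale; reflections disallowed)."""
    tgt = target_landmarks.reordered_like(template_landmarks)
    a = np.asarray(template_landmarks.coordinates, dtype=float)
    b = np.asarray(tgt.coordinates, dtype=float)
    if len(a) < 3:
        raise DegenerateGeometryError("need at least 3 landmarks")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    ac, bc = a - mu_a, b - mu_b
    if np.linalg.matrix_rank(ac, tol=1e-9 * max(1.0, np.abs(ac).max())) < 2:
        raise DegenerateGeometryError("landmarks are collinear")
    cov = bc.T @ ac / len(a)
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, d])
    rot = u @ diag @ vt
    var_a = (ac * ac).sum() / len(a)
    scale = float((s * np.diag(diag)).sum() / var_a)
    if scale <= 0:
        raise DegenerateGeometryError("degenerate landmark configuration")
    trans = mu_b - scale * rot @ mu_a
    return SimilarityTransform(scale, rot, trans)


def _smoothing_weights(dists: np.ndarray, sigma: float) -> np.ndarray:
    w = np.exp(-0.5 * (dists / sigma) ** 2)
    return w / w.sum(axis=1, keepdims=True)


def nonrigid_register(
    template: trimesh.Trimesh,
    target: trimesh.Trimesh,
    init: SimilarityTransform | None = None,
    params: RegistrationParams | None = None,
    _template_distances: np.ndarray | None = None,
) -> RegistrationResult:
    """Deform the (initialised) template onto the target surface.

    Each iteration moves every template vertex a fraction ``step`` of its
    Gaussian-smoothed displacement toward its closest point on the target;
    the smoothing couples neighbouring vertices so the mapping stays a
    coherent deformation rather than independent projections. Deterministic
    given its inputs. Non-convergence (no new best residual within a
    patience window) is flagged, not fatal.
    """
    params = params or RegistrationParams()
    params.validate()
    if len(target.vertices) == 0 or len(target.faces) == 0:
        raise DegenerateGeometryError("empty target surface")
    init = init or SimilarityTransform.identity()

    x = init.apply(np.asarray(template.vertices, dtype=float))
    if _template_distances is None:
        _template_distances = graph_distances(template.vertices, template.faces)
    # sigmas are fractions of the template's graph diameter: the smoothing
    # couples vertices in the template's own parametrisation, which keeps the
    # deformation model independent of the target's scale
    diag = float(_template_distances.max())
    locator = SurfaceLocator(target.vertices, target.faces)

    sigmas = np.geomspace(
        params.sigma_start * diag, params.sigma_end * diag, params.iterations
    )
    residuals = []
    best = np.inf
    since_best = 0
    for sigma in sigmas:
        closest, dist = locator.query(x)
        residuals.append(float(dist.mean()))
        if residuals[-1] < best - 1e-15:
            best = residuals[-1]
            since_best = 0
        else:
            since_best += 1
        w = _smoothing_weights(_template_distances, sigma)
        x = x + params.step * (w @ (closest - x))
    # final projection residual
    _, dist = locator.query(x)
    residuals.append(float(dist.mean()))
    converged = since_best < params.patience
    return RegistrationResult(
        mapped_vertices=x, residuals=np.asarray(residuals), converged=converged
    )


def build_cohort(
    manifest: CohortManifest,
    template: trimesh.Trimesh,
    template_landmarks: LandmarkSet,
    params: RegistrationParams | None = None,
    base_dir=None,
) -> CorrespondedCohort:
    """Register every manifest specimen; order follows the manifest."""
    params = params or RegistrationParams()
    base = Path(base_dir) if base_dir is not None else Path(".")
    tmpl_d = graph_distances(template.vertices, template.faces)

    coords, ids, diags = [], [], []
    for _, row in manifest.table.iterrows():
        sid = row["specimen_id"]
        mesh_path = base / row["mesh_path"]
        if not mesh_path.exists():
            raise ManifestError(f"specimen {sid!r}: missing mesh file {mesh_path}")
        try:
            target = read_obj(mesh_path)
            lm_path = row.get("landmark_path")
            if lm_path and isinstance(lm_path, str):
                target_lms = read_landmarks_csv(base / lm_path)
                init = rigid_initialize(template_landmarks, target_lms)
            else:
                init = SimilarityTransform.identity()
            result = nonrigid_register(
                template, target, init, params, _template_distances=tmpl_d
            )
        except (OSError, ValueError) as exc:
            raise ManifestError(f"specimen {sid!r} failed: {exc}") from exc
        coords.append(result.mapped_vertices)
        ids.append(sid)
        diags.append(
            {
                "specimen_id": sid,
                "final_residual": float(result.residuals[-1]),
                "converged": bool(result.converged),
            }
        )
    if not ids:
        raise ManifestError("manifest contains no specimens")
    return CorrespondedCohort(
        coordinates=np.stack(coords), specimen_ids=ids, template=template,
        diagnostics=diags,
    )


ARCHIVE_VERSION = 1


def save_cohort_archive(cohort: CorrespondedCohort, path) -> None:
    """NPZ archive: one coordinate block plus ids, versioned."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    extras = {}
    if cohort.template is not None:
        extras["template_vertices"] = np.asarray(cohort.template.vertices, dtype=float)
        extras["template_faces"] = np.asarray(cohort.template.faces, dtype=np.int64)
    np.savez(
        path,
        version=np.int64(ARCHIVE_VERSION),
        coordinates=cohort.coordinates,
        specimen_ids=np.asarray(cohort.specimen_ids, dtype=str),
        **extras,
    )


def load_cohort_archive(path) -> CorrespondedCohort:
    from .geometry import as_mesh

    with np.load(path, allow_pickle=False) as z:
        if int(z["version"]) != ARCHIVE_VERSION:
            raise InvalidParameterError(f"unsupported archive version {z['version']}")
        template = None
        if "template_vertices" in z:
            template = as_mesh(z["template_vertices"], z["template_faces"])
        return CorrespondedCohort(
            coordinates=z["coordinates"],
            specimen_ids=[str(s) for s in z["specimen_ids"]],
            template=template,
        )
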