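"""File formats: Wavefront OBJ surfaces, fiducial landmark CSVs, cohort
manifests, and per-vertex scalar fields (CSV + colour-mapped ASCII PLY).

OBJ files use 1-based vertex indices; everything inside the package is
0-based, and the conversion happens only here. Coordinates carry an opaque
unit string (default micrometres, the resolution class of small-animal
micro-CT) — no conversion is ever attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from matplotlib import colormaps

from .exceptions import InvalidParameterError, ManifestError, ParseError
from .geometry import as_mesh

__all__ = [
    "LandmarkSet",
    "CohortManifest",
    "read_obj",
    "write_obj",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "write_vertex_field",
    "read_manifest",
    "write_manifest",
]

DEFAULT_UNITS = "um"


@dataclass
class LandmarkSet:
    """Named sparse fiducial points in the same frame/units as the mesh."""

    names: list[str]
    coordinates: np.ndarray  # (k, 3)
    units: str = DEFAULT_UNITS

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if len(self.names) != len(self.coordinates):
            raise InvalidParameterError("names and coordinates length mismatch")
        if len(set(self.names)) != len(self.names):
            raise InvalidParameterError("landmark names must be unique")
        if not np.all(np.isfinite(self.coordinates)):
            raise InvalidParameterError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def reordered_like(self, other: "LandmarkSet") -> "LandmarkSet":
        """Return this set reordered to match ``other``'s name order."""
        if set(self.names) != set(other.names):
            raise InvalidParameterError(
                "landmark name mismatch: "
                f"{sorted(set(self.names) ^ set(other.names))}"
            )
        idx = [self.names.index(n) for n in other.names]
        return LandmarkSet(list(other.names), self.coordinates[idx], self.units)


@dataclass
class CohortManifest:
    """Specimen table: id, mesh path, optional landmark path, labels."""

    table: pd.DataFrame
    genotype_levels: list[str] = field(default_factory=list)

    REQUIRED = ("specimen_id", "mesh_path", "genotype", "sex", "litter")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ManifestError(f"manifest missing columns: {missing}")
        ids = self.table["specimen_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ManifestError(f"duplicate specimen_id: {dup!r}")
        if self.genotype_levels:
            bad = set(self.table["genotype"]) - set(self.genotype_levels)
            if bad:
                raise ManifestError(
                    f"undeclared genotype labels {sorted(bad)}; "
                    f"declared: {self.genotype_levels}"
                )

    def __len__(self) -> int:
        return len(self.table)


def read_obj(path, strict: bool = False) -> trimesh.Trimesh:
    """Parse an ASCII Wavefront OBJ into a mesh (0-based faces).

    Only ``v`` and ``f`` records are honoured; normals, texture coordinates
    and all other record types are ignored. Polygonal faces are
    fan-triangulated unless ``strict`` is set, in which case they raise.
    """
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            tag = tokens[0]
            if tag == "v":
                if len(tokens) < 4:
                    raise ParseError(f"{path}:{lineno}: vertex needs 3 coordinates")
                try:
                    vertices.append([float(t) for t in tokens[1:4]])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
            elif tag == "f":
                idx = []
                for tok in tokens[1:]:
                    head = tok.split("/")[0]
                    try:
                        i = int(head)
                    except ValueError as exc:
                        raise ParseError(
                            f"{path}:{lineno}: bad face index {tok!r}"
                        ) from exc
                    idx.append(i - 1 if i > 0 else len(vertices) + i)
                if len(idx) < 3:
                    raise ParseError(
                        f"{path}:{lineno}: face needs at least 3 vertices"
                    )
                if len(idx) > 3 and strict:
                    raise ParseError(
                        f"{path}:{lineno}: non-triangular face in strict mode"
                    )
                for k in range(1, len(idx) - 1):  # fan triangulation
                    faces.append([idx[0], idx[k], idx[k + 1]])
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    if len(f) and (f.min() < 0 or f.max() >= len(v)):
        raise ParseError(f"{path}: face index out of range [0, {len(v)})")
    return as_mesh(v, f)


def write_obj(mesh: trimesh.Trimesh, path) -> None:
    """Write vertices and triangles as ASCII OBJ (1-based indices)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for x, y, z in np.asarray(mesh.vertices, dtype=float):
            fh.write(f"v {x:.9g} {y:.9g} {z:.9g}\n")
        for a, b, c in np.asarray(mesh.faces, dtype=np.int64) + 1:
            fh.write(f"f {a} {b} {c}\n")


def read_landmarks_csv(path, units: str = DEFAULT_UNITS) -> LandmarkSet:
    """Read a fiducial CSV with (case-insensitive) name,x,y,z columns.

    Extra columns are ignored; rows stay in file order.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    missing = [c for c in ("name", "x", "y", "z") if c not in cols]
    if missing:
        raise ParseError(f"{path}: missing landmark columns {missing}")
    names = df[cols["name"]].astype(str).tolist()
    if len(set(names)) != len(names):
        raise ParseError(f"{path}: duplicate landmark names")
    try:
        coords = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric coordinate ({exc})") from exc
    return LandmarkSet(names, coords, units)


def write_landmarks_csv(landmarks: LandmarkSet, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "name": landmarks.names,
            "x": landmarks.coordinates[:, 0],
            "y": landmarks.coordinates[:, 1],
            "z": landmarks.coordinates[:, 2],
        }
    ).to_csv(path, index=False)


def _diverging_colors(field: np.ndarray) -> np.ndarray:
    """Map a signed field to RGB bytes, blue→white→red, centred at zero."""
    amp = float(np.max(np.abs(field))) if len(field) else 0.0
    t = 0.5 * np.ones_like(field) if amp == 0 else 0.5 + 0.5 * field / amp
    rgba = colormaps["bwr"](np.clip(t, 0.0, 1.0))
    return (rgba[:, :3] * 255).astype(np.uint8)


def write_vertex_field(mesh: trimesh.Trimesh, field: np.ndarray, stem) -> dict:
    """Write a per-vertex signed field as ``<stem>.csv`` + coloured ``<stem>.ply``.

    Negative values render blue (inward), positive red (outward), zero the
    neutral midpoint of the diverging map. The CSV uses a fixed decimal
    format so a round-trip reproduces the field exactly as printed.
    """
    field = np.asarray(field, dtype=float).ravel()
    if len(field) != len(mesh.vertices):
        raise InvalidParameterError(
            f"field length {len(field)} != vertex count {len(mesh.vertices)}"
        )
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    csv_path = stem.with_suffix(".csv")
    ply_path = stem.with_suffix(".ply")

    with open(csv_path, "w") as fh:
        fh.write("vertex_index,value\n")
        for i, v in enumerate(field):
            fh.write(f"{i},{v:.10e}\n")

    colors = _diverging_colors(field)
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    with open(ply_path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(verts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        fh.write(f"element face {len(faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for (x, y, z), (r, g, b) in zip(verts, colors):
            fh.write(f"{x:.9g} {y:.9g} {z:.9g} {r} {g} {b}\n")
        for a, b_, c in faces:
            fh.write(f"3 {a} {b_} {c}\n")
    return {"csv": csv_path, "ply": ply_path, "colors": colors}


def read_manifest(path, genotype_levels=None, check_paths: bool = True) -> CohortManifest:
    """Load a cohort manifest CSV and fail fast on inconsistencies."""
    df = pd.read_csv(path, dtype=str)
    manifest = CohortManifest(df, list(genotype_levels or []))
    if check_paths:
        base = Path(path).parent
        for _, row in df.iterrows():
            mesh_path = (base / row["mesh_path"]).resolve()
            if not mesh_path.exists():
                raise ManifestError(
                    f"specimen {row['specimen_id']!r}: missing mesh {mesh_path}"
                )
    return manifest


def write_manifest(manifest: CohortManifest, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.table.to_csv(path, index=False)
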