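"""Surface-mesh I/O and the role-labelled anatomy set.

The planner consumes one STL surface per anatomical structure, produced by an
upstream segmentation pipeline.  Conventions, declared rather than guessed:

* units are millimetres,
* the frame is RAS (+x right, +y anterior, +z superior),
* meshes need not be watertight (manual segmentations rarely are).

Five roles are mandatory: SM (stapedius muscle, the target), FN (facial
nerve), SS (sigmoid sinus), VC (vestibulocochlear system) and TB (temporal
bone).  Any other structure in a manifest is kept for visualization only and
never enters a planning computation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
import yaml

from .errors import ConfigurationError, InputError

log = logging.getLogger(__name__)

#: mandatory anatomical roles, in canonical order
ROLES = ("SM", "FN", "SS", "VC", "TB")

#: vertices closer than this (mm) are merged on read
MERGE_TOL_MM = 1e-6

#: face counts above this trigger a warning (export caps are usually ~10k)
FACE_WARN_THRESHOLD = 200_000


@dataclass(frozen=True)
class SurfaceMesh:
    """A triangulated surface in RAS millimetres.

    ``vertices``: ``(n, 3)`` float array; ``faces``: ``(m, 3)`` int array of
    vertex indices.  Open (non-watertight) surfaces are allowed.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if f.ndim != 2 or f.shape[1] != 3 or len(f) < 1:
            raise InputError("mesh must have at least one triangular face")
        if v.ndim != 2 or v.shape[1] != 3:
            raise InputError("vertices must be an (n, 3) array")
        if not np.all(np.isfinite(v)):
            raise InputError("mesh contains non-finite vertex coordinates")
        if f.min() < 0 or f.max() >= len(v):
            raise InputError("face references a missing vertex")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """Triangle corner coordinates, shape ``(m, 3, 3)``."""
        return self.vertices[self.faces]

    @property
    def face_areas(self) -> np.ndarray:
        t = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    @property
    def centroid(self) -> np.ndarray:
        """Area-weighted surface centroid (robust for open meshes)."""
        t = self.triangles
        w = self.face_areas
        total = w.sum()
        if total <= 0:
            return self.vertices.mean(axis=0)
        return (t.mean(axis=1) * w[:, None]).sum(axis=0) / total

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(np.asarray(mesh.vertices, float), np.asarray(mesh.faces))


def _dedupe_vertices(vertices: np.ndarray, faces: np.ndarray, tol: float):
    """Merge vertices that coincide within ``tol`` (grid snap)."""
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    return vertices[first], inverse[faces]


def read_stl(path) -> SurfaceMesh:
    """Read a binary or ASCII STL file into a :class:`SurfaceMesh`.

    Duplicate vertices are merged within ``MERGE_TOL_MM``; the face count is
    preserved.  Raises :class:`InputError` for missing, empty or unparsable
    files.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"STL file not found: {path}")
    try:
        raw = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - surface the path in the error
        raise InputError(f"could not parse STL file {path}: {exc}") from exc
    verts = np.asarray(raw.vertices, dtype=float)
    faces = np.asarray(raw.faces, dtype=np.int64)
    if len(faces) == 0:
        raise InputError(f"STL file {path} contains no triangles")
    verts, faces = _dedupe_vertices(verts, faces, MERGE_TOL_MM)
    if len(faces) > FACE_WARN_THRESHOLD:
        log.warning("%s has %d faces; expect slow planning", path, len(faces))
    return SurfaceMesh(verts, faces)


def write_stl(mesh: SurfaceMesh, path, ascii: bool = False) -> None:
    """Write a mesh as STL (binary by default)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.as_trimesh().export(str(path), file_type="stl_ascii" if ascii else "stl")


def write_metadata_sidecar(path, source: str = "stapplan") -> None:
    """JSON sidecar declaring units and frame next to an STL export."""
    meta = {"units": "mm", "frame": "RAS", "source": source}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


@dataclass
class AnatomySet:
    """Role-labelled meshes for one surgical side.

    ``structures`` holds the five mandatory roles; ``extras`` holds anything
    else (visualization only -- no planning computation ever reads them).
    """

    structures: dict
    side: str
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ConfigurationError(f"side must be 'left' or 'right', got {self.side!r}")
        missing = [r for r in ROLES if r not in self.structures]
        if missing:
            raise ConfigurationError(
                "anatomy set is missing mandatory structure(s): " + ", ".join(missing)
            )

    def __getitem__(self, role: str) -> SurfaceMesh:
        return self.structures[role]


def load_anatomy_set(manifest: dict, side: str) -> AnatomySet:
    """Load an anatomy set from a ``role -> STL path`` mapping.

    Unknown roles are loaded into ``extras``.  A missing mandatory role is a
    configuration error naming the role(s).
    """
    missing = [r for r in ROLES if r not in manifest]
    if missing:
        raise ConfigurationError(
            "manifest is missing mandatory structure(s): " + ", ".join(missing)
        )
    structures = {role: read_stl(manifest[role]) for role in ROLES}
    extras = {
        name: read_stl(p) for name, p in manifest.items() if name not in ROLES
    }
    return AnatomySet(structures=structures, side=side, extras=extras)


def read_manifest(path) -> AnatomySet:
    """Read a YAML manifest file with keys ``side`` and ``structures``.

    Structure paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"manifest not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise InputError(f"could not parse manifest {path}: {exc}") from exc
    if not isinstance(doc, dict) or "structures" not in doc or "side" not in doc:
        raise ConfigurationError(
            f"manifest {path} must define 'side' and a 'structures' mapping"
        )
    base = path.parent
    mapping = {
        role: (base / p if not Path(p).is_absolute() else Path(p))
        for role, p in doc["structures"].items()
    }
    return load_anatomy_set(mapping, doc["side"])


def write_manifest(path, structures: dict, side: str) -> None:
    """Write a YAML manifest (``role -> relative path``) next to STL exports."""
    doc = {"side": side, "structures": {k: str(v) for k, v in structures.items()}}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def mirror_mesh(mesh: SurfaceMesh) -> SurfaceMesh:
    """Reflect across the sagittal plane R=0 and restore outward winding."""
    v = mesh.vertices.copy()
    v[:, 0] *= -1.0
    return SurfaceMesh(v, mesh.faces[:, ::-1].copy())


def mirror_anatomy(anatomy: AnatomySet) -> AnatomySet:
    """Mirror every structure across R=0 and toggle the side label.

    An involution: mirroring twice restores the original coordinates exactly.
    """
    return AnatomySet(
        structures={r: mirror_mesh(m) for r, m in anatomy.structures.items()},
        side="left" if anatomy.side == "right" else "right",
        extras={n: mirror_mesh(m) for n, m in anatomy.extras.items()},
    )


__all__ = [
    "ROLES",
    "SurfaceMesh",
    "AnatomySet",
    "read_stl",
    "write_stl",
    "write_metadata_sidecar",
    "load_anatomy_set",
    "read_manifest",
    "write_manifest",
    "mirror_mesh",
    "mirror_anatomy",
]
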