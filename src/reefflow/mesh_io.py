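"""Reading, validating and orienting triangle meshes of coral colonies.

A colony mesh is a triangulated surface of a single coral colony in metric
coordinates with the seabed at z = 0 and z pointing up.  Flow is always
along +x in the working frame; :func:`rotate_to_azimuth` maps a requested
flow azimuth onto that convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "ColonyMesh",
    "MeshFormatError",
    "MeshValidationError",
    "OrientationError",
    "UNIT_SCALES",
    "load_mesh",
    "save_mesh",
    "rotate_to_azimuth",
]

#: Multiplier applied to input coordinates to obtain metres.
UNIT_SCALES = {"m": 1.0, "cm": 0.01, "mm": 0.001}

_SUPPORTED_SUFFIXES = {".stl", ".obj", ".ply"}


class MeshFormatError(ValueError):
    """The file could not be read as a triangle mesh."""


class MeshValidationError(ValueError):
    """The mesh violates a structural invariant (empty, degenerate, non-finite)."""


class OrientationError(ValueError):
    """A closed mesh has inconsistently wound (mixed inward/outward) faces."""


@dataclass(frozen=True)
class ColonyMesh:
    """A triangulated coral colony surface, base on the bed plane.

    Attributes
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in metres; ``min(z) == 0`` after loading.
    faces : (m, 3) int array
        Triangles as vertex-index triples, wound so normals point outward
        on closed surfaces.
    units_scale : float
        Multiplier that was applied at load time to reach metres.
    watertight : bool
        True when every edge is shared by exactly two faces.
    """

    vertices: np.ndarray
    faces: np.ndarray
    units_scale: float = 1.0
    watertight: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3 or len(v) == 0:
            raise MeshValidationError("vertices must be a non-empty (n, 3) array")
        if f.ndim != 2 or f.shape[1] != 3 or len(f) == 0:
            raise MeshValidationError("faces must be a non-empty (m, 3) array")
        if not np.isfinite(v).all():
            raise MeshValidationError("mesh has non-finite vertex coordinates")
        if f.min() < 0 or f.max() >= len(v):
            raise MeshValidationError("face indices out of range")
        if (f[:, 0] == f[:, 1]).any() or (f[:, 1] == f[:, 2]).any() or (f[:, 0] == f[:, 2]).any():
            raise MeshValidationError("faces must reference three distinct vertices")
        if self.units_scale <= 0:
            raise MeshValidationError("units_scale must be positive")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    # -- derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def bounds(self) -> np.ndarray:
        """(2, 3) array of per-axis (min, max) coordinates."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def face_cross_products(self) -> np.ndarray:
        """Per-face cross products (v1-v0) x (v2-v0); norm is twice the face area."""
        tri = self.vertices[self.faces]
        return np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_cross_products(), axis=1)

    def to_trimesh(self) -> trimesh.Trimesh:
        """Unprocessed trimesh view (no vertex merging or re-winding)."""
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


def _is_watertight(tm: trimesh.Trimesh) -> bool:
    # every edge shared by exactly two faces
    edges = np.sort(tm.edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool(len(counts) > 0 and (counts == 2).all())


def load_mesh(path: str | Path, units: str = "m") -> ColonyMesh:
    """Load an STL/OBJ/PLY colony mesh, convert to metres and drop it onto the bed.

    Duplicate vertices are merged (needed for closed-surface detection on STL,
    which stores per-facet vertices) and degenerate faces removed; the geometry
    itself is never re-meshed.  The mesh is translated so that ``min(z) = 0``.
    On closed surfaces the winding is normalised so face normals point outward.

    Parameters
    ----------
    path
        Path to an STL (ascii/binary), OBJ or PLY (ascii/binary) file.
    units
        Length unit of the file: ``"m"``, ``"cm"`` or ``"mm"``.
    """
    path = Path(path)
    if units not in UNIT_SCALES:
        raise ValueError(f"unknown unit {units!r}; expected one of {sorted(UNIT_SCALES)}")
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise MeshFormatError(f"unsupported mesh format {path.suffix!r} (use STL, OBJ or PLY)")
    try:
        tm = trimesh.load(str(path), force="mesh")
    except Exception as exc:  # noqa: BLE001 - normalise loader errors
        raise MeshFormatError(f"could not read {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or tm.faces is None or len(tm.faces) == 0:
        raise MeshFormatError(f"{path} contains no triangle faces")

    tm = tm.copy()
    tm.merge_vertices()
    tm.update_faces(tm.nondegenerate_faces())
    tm.remove_unreferenced_vertices()
    if len(tm.faces) == 0 or tm.area <= 0:
        raise MeshValidationError(f"{path}: mesh has zero surface area")

    watertight = _is_watertight(tm)
    if watertight:
        if not tm.is_winding_consistent:
            raise OrientationError(f"{path}: closed mesh with inconsistent face winding")
        if tm.volume < 0:  # normals point inward: flip
            tm.invert()

    scale = UNIT_SCALES[units]
    vertices = np.asarray(tm.vertices, dtype=float) * scale
    vertices[:, 2] -= vertices[:, 2].min()
    return ColonyMesh(
        vertices=vertices,
        faces=np.asarray(tm.faces, dtype=np.int64),
        units_scale=scale,
        watertight=watertight,
    )


def save_mesh(mesh: ColonyMesh, path: str | Path) -> None:
    """Write a colony mesh to STL/OBJ/PLY (format from the file suffix), in metres."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise MeshFormatError(f"unsupported mesh format {path.suffix!r} (use STL, OBJ or PLY)")
    mesh.to_trimesh().export(str(path))


def rotate_to_azimuth(mesh: ColonyMesh, theta: float) -> ColonyMesh:
    """Rotate the colony so a flow approaching from azimuth ``theta`` runs along +x.

    The mesh is rotated by ``-theta`` about the vertical axis; z coordinates are
    unchanged, so height, volume and the watertight flag are preserved.  An
    azimuth of 0 leaves the mesh in its as-digitised orientation (for the
    massive archetype, narrow end into the flow).

    Parameters
    ----------
    theta : float
        Flow azimuth in degrees, measured in the as-loaded frame.
    """
    if not math.isfinite(theta):
        raise ValueError("theta must be finite")
    a = math.radians(-theta)
    c, s = math.cos(a), math.sin(a)
    rot = np.array([[c, -s], [s, c]])
    vertices = mesh.vertices.copy()
    vertices[:, :2] = vertices[:, :2] @ rot.T
    return replace(mesh, vertices=vertices)
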