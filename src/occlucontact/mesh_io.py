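"""Triangle-mesh and landmark I/O with a strict unit and integrity contract.

All geometry in this package is in millimetres. Meshes read here are
validated (finite coordinates, in-range indices, no degenerate faces) so
that downstream alignment and contact-area code can assume a clean surface.
Dental scanner exports routinely contain sliver triangles and duplicate
faces; these are repaired silently with logged counts rather than raised.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

log = logging.getLogger(__name__)

#: faces below this area (mm^2) are considered degenerate and removed
DEGENERATE_AREA_MM2 = 1e-9

#: landmark triangles below this area (mm^2) are considered collinear
COLLINEAR_AREA_MM2 = 1e-6

_SUPPORTED_FORMATS = {".stl", ".ply", ".obj"}


class MeshFormatError(ValueError):
    """File is not a readable STL/PLY/OBJ mesh."""


class MeshContentError(ValueError):
    """Mesh violates the SurfaceMesh integrity contract."""


class LandmarkSchemaError(KeyError):
    """Landmark file is missing a required key or has a malformed point."""


class LandmarkGeometryError(ValueError):
    """Landmark points are collinear and cannot define an occlusal plane."""


@dataclass
class SurfaceMesh:
    """A validated triangle mesh of one jaw, coordinates in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
    name : free-text label, e.g. ``"maxilla"`` or ``"mandible"``.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    # -- derived geometry ---------------------------------------------------

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        tri = self.triangles
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def area(self) -> float:
        """Total surface area in mm^2."""
        return float(self.face_areas().sum())

    def centroid(self) -> np.ndarray:
        """Area-weighted surface centroid."""
        tri = self.triangles
        w = self.face_areas()
        centers = tri.mean(axis=1)
        return (centers * w[:, None]).sum(axis=0) / w.sum()

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceMesh":
        """Return a rigidly transformed copy (v -> R v + t)."""
        v = self.vertices @ np.asarray(rotation).T + np.asarray(translation)
        return SurfaceMesh(v, self.faces.copy(), self.name)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(), self.name)


@dataclass
class ValidationReport:
    """Counts of repairs applied by :func:`validate_mesh`."""

    degenerate_faces: int = 0
    duplicate_faces: int = 0
    unreferenced_vertices: int = 0
    out_of_range_faces: int = 0

    def total_repairs(self) -> int:
        return (self.degenerate_faces + self.duplicate_faces
                + self.unreferenced_vertices + self.out_of_range_faces)


@dataclass
class LandmarkSet:
    """The three occlusal-plane landmarks on the mandible.

    ``incisal_point``: contact point of the incisal edges of the lower
    central incisors (teeth 31/41); ``left_molar_cusp`` / ``right_molar_cusp``:
    distobuccal cusps of the lower first molars (teeth 36/46).
    """

    incisal_point: np.ndarray
    left_molar_cusp: np.ndarray
    right_molar_cusp: np.ndarray

    def __post_init__(self) -> None:
        self.incisal_point = np.asarray(self.incisal_point, dtype=np.float64).reshape(3)
        self.left_molar_cusp = np.asarray(self.left_molar_cusp, dtype=np.float64).reshape(3)
        self.right_molar_cusp = np.asarray(self.right_molar_cusp, dtype=np.float64).reshape(3)
        area = 0.5 * np.linalg.norm(
            np.cross(self.left_molar_cusp - self.incisal_point,
                     self.right_molar_cusp - self.incisal_point))
        if not np.all(np.isfinite(self.as_array())):
            raise LandmarkGeometryError("landmark coordinates must be finite")
        if area <= COLLINEAR_AREA_MM2:
            raise LandmarkGeometryError(
                f"landmarks are collinear (triangle area {area:.3g} mm^2); "
                "cannot define an occlusal plane")

    def as_array(self) -> np.ndarray:
        return np.stack([self.incisal_point, self.left_molar_cusp, self.right_molar_cusp])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        pts = self.as_array() @ np.asarray(rotation).T + np.asarray(translation)
        return LandmarkSet(pts[0], pts[1], pts[2])


# ---------------------------------------------------------------------------
# validation


def validate_mesh(vertices: np.ndarray, faces: np.ndarray, name: str = "",
                  ) -> tuple[SurfaceMesh, ValidationReport]:
    """Repair a raw vertex/face soup into a valid :class:`SurfaceMesh`.

    Removes out-of-range and repeated-index faces, exact duplicate faces
    (orientation-insensitive), faces with area < 1e-9 mm^2, and vertices no
    face references. Raises :class:`MeshContentError` on non-finite
    coordinates or if nothing survives.
    """
    vertices = np.asarray(vertices, dtype=np.float64).reshape(-1, 3)
    faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    report = ValidationReport()

    if vertices.size and not np.all(np.isfinite(vertices)):
        raise MeshContentError(f"mesh '{name}': non-finite vertex coordinates")

    n = len(vertices)
    in_range = np.all((faces >= 0) & (faces < n), axis=1) if len(faces) else np.zeros(0, bool)
    distinct = (
        (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    ) if len(faces) else np.zeros(0, bool)
    ok = in_range & distinct
    report.out_of_range_faces = int((~in_range).sum())
    faces = faces[ok]

    # orientation-insensitive duplicate removal, first occurrence wins
    if len(faces):
        key = np.sort(faces, axis=1)
        _, first = np.unique(key, axis=0, return_index=True)
        report.duplicate_faces = len(faces) - len(first)
        faces = faces[np.sort(first)]

    if len(faces):
        tri = vertices[faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        keep = areas >= DEGENERATE_AREA_MM2
        report.degenerate_faces = int((~keep).sum())
        faces = faces[keep]

    # drop unreferenced vertices and re-index
    used = np.zeros(n, dtype=bool)
    if len(faces):
        used[faces.ravel()] = True
    report.unreferenced_vertices = int(n - used.sum())
    remap = np.cumsum(used) - 1
    vertices = vertices[used]
    faces = remap[faces] if len(faces) else faces

    if len(faces) == 0 or len(vertices) == 0:
        raise MeshContentError(f"mesh '{name}': empty after validation")

    if report.total_repairs():
        log.info("mesh '%s': removed %d degenerate, %d duplicate, %d out-of-range "
                 "faces and %d unreferenced vertices", name, report.degenerate_faces,
                 report.duplicate_faces, report.out_of_range_faces,
                 report.unreferenced_vertices)
    return SurfaceMesh(vertices, faces, name), report


# ---------------------------------------------------------------------------
# file I/O


def read_mesh(path: str | Path, expected_units: str = "mm") -> SurfaceMesh:
    """Read and validate an STL/PLY/OBJ mesh; coordinates are taken as mm."""
    path = Path(path)
    if expected_units != "mm":
        raise ValueError("only millimetre meshes are supported")
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() not in _SUPPORTED_FORMATS:
        raise MeshFormatError(f"unsupported mesh format: {path.suffix!r}")
    try:
        raw = trimesh.load_mesh(str(path), process=False, validate=False)
    except Exception as exc:  # trimesh raises many concrete types
        raise MeshFormatError(f"could not parse {path}: {exc}") from exc
    if isinstance(raw, trimesh.Scene):
        geoms = list(raw.geometry.values())
        if not geoms:
            raise MeshContentError(f"{path}: no geometry")
        raw = trimesh.util.concatenate(geoms)
    vertices = np.asarray(raw.vertices, dtype=np.float64)
    faces = np.asarray(raw.faces, dtype=np.int64)
    if vertices.size and not np.all(np.isfinite(vertices)):
        raise MeshContentError(f"{path}: non-finite vertex coordinates")
    mesh, _ = validate_mesh(vertices, faces, name=path.stem)
    return mesh


def write_mesh(mesh: SurfaceMesh, path: str | Path, fmt: str | None = None) -> Path:
    """Write a mesh as STL (binary), PLY or OBJ; format from ``fmt`` or suffix."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if f".{fmt}" not in _SUPPORTED_FORMATS:
        raise MeshFormatError(f"unsupported output format: {fmt!r}")
    if len(mesh.faces) == 0:
        raise MeshContentError("refusing to write an empty mesh")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    path.parent.mkdir(parents=True, exist_ok=True)
    tm.export(str(path), file_type=fmt)
    return path


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read the three occlusal-plane landmarks from a JSON file.

    Expected keys: ``incisal_point``, ``left_molar_cusp``, ``right_molar_cusp``,
    each an ``[x, y, z]`` array in mm.
    """
    with open(path) as fh:
        data = json.load(fh)
    pts = {}
    for key in ("incisal_point", "left_molar_cusp", "right_molar_cusp"):
        if key not in data:
            raise LandmarkSchemaError(f"landmark file missing key {key!r}")
        p = np.asarray(data[key], dtype=np.float64)
        if p.shape != (3,):
            raise LandmarkSchemaError(f"landmark {key!r} is not a 3D point")
        pts[key] = p
    return LandmarkSet(**pts)


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({
            "incisal_point": landmarks.incisal_point.tolist(),
            "left_molar_cusp": landmarks.left_molar_cusp.tolist(),
            "right_molar_cusp": landmarks.right_molar_cusp.tolist(),
        }, fh, indent=2)
    return path
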