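"""Rigid orientation of a jaw pair into the occlusal-plane frame.

The occlusal plane is defined by three mandibular landmarks: the incisal
contact point of teeth 31/41 and the distobuccal cusps of teeth 36/46.
``orient_pair`` applies one rigid transform to both jaws so this plane is
the z = 0 plane with the landmark centroid at the origin and +z pointing
toward the maxilla. ``rigid_register`` is an iterative-closest-point
refinement for bringing an approximately posed maxilla into maximum
intercuspation against a reference surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh_io import LandmarkGeometryError, LandmarkSet, MeshContentError, SurfaceMesh

log = logging.getLogger(__name__)


class OrientationError(ValueError):
    """The plane-normal sign toward the maxilla could not be resolved."""


@dataclass
class RigidTransform:
    """A proper rigid motion x -> R x + t, rotation orthonormal, det +1."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-7 or abs(np.linalg.det(self.rotation) - 1.0) > 1e-7:
            raise ValueError("rotation must be orthonormal with determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass
class AlignedJawPair:
    """Mandible and maxilla posed with the occlusal plane parallel to xy.

    Invariants: the (transformed) landmarks share z = ``occlusal_plane_z``
    and the maxilla lies on the +z side of the plane.
    """

    mandible: SurfaceMesh
    maxilla: SurfaceMesh
    occlusal_plane_z: float = 0.0
    landmarks: LandmarkSet | None = None
    provenance: dict = field(default_factory=dict)


def plane_from_landmarks(landmarks: LandmarkSet) -> tuple[np.ndarray, np.ndarray]:
    """Unit normal and a point (the landmark centroid) of the occlusal plane.

    The normal's sign is not resolved here; ``orient_pair`` flips it toward
    the maxilla centroid.
    """
    pts = landmarks.as_array()
    n = np.cross(pts[1] - pts[0], pts[2] - pts[0])
    norm = np.linalg.norm(n)
    if norm <= 2 * 1e-6:  # matches the LandmarkSet collinearity gate
        raise LandmarkGeometryError("collinear landmarks")
    return n / norm, pts.mean(axis=0)


def _rotation_to_z(normal: np.ndarray) -> np.ndarray:
    """Minimal rotation taking ``normal`` to +z (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(normal, z)
    c = float(np.dot(normal, z))
    s = np.linalg.norm(v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about x
        return np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))


def orient_pair(mandible: SurfaceMesh, maxilla: SurfaceMesh,
                landmarks: LandmarkSet,
                landmark_tol_mm: float = 2.0) -> AlignedJawPair:
    """Rigidly move both jaws so the occlusal plane becomes z = 0.

    Both meshes receive the *same* transform, so the relative intercuspation
    pose is untouched. The landmark centroid maps to the origin; +z points
    from the mandible toward the maxilla.
    """
    normal, center = plane_from_landmarks(landmarks)

    # resolve sign: +normal must point toward the maxilla centroid
    side = float(np.dot(maxilla.centroid() - center, normal))
    if abs(side) < 1e-9:
        raise OrientationError("maxilla centroid lies on the occlusal plane; "
                               "cannot resolve the plane normal sign")
    if side < 0:
        normal = -normal

    # warn if landmarks are far from the mandible surface (probable mixup)
    from .oca_core import surface_distance  # local import to avoid a cycle
    d = surface_distance(landmarks.as_array(), mandible)
    if d.max() > landmark_tol_mm:
        log.warning("landmark(s) up to %.2f mm away from the mandible surface "
                    "(tolerance %.1f mm)", d.max(), landmark_tol_mm)

    rot = _rotation_to_z(normal)
    trans = -rot @ center  # landmark centroid -> origin
    transform = RigidTransform(rot, trans)

    mand = mandible.transformed(rot, trans)
    mx = maxilla.transformed(rot, trans)
    lm = landmarks.transformed(rot, trans)
    z = lm.as_array()[:, 2]
    assert np.ptp(z) < 1e-6, "landmarks not coplanar after orientation"
    return AlignedJawPair(mandible=mand, maxilla=mx, occlusal_plane_z=0.0,
                          landmarks=lm,
                          provenance={"orient_transform": transform.matrix.tolist()})


# ---------------------------------------------------------------------------
# ICP refinement


@dataclass
class RegistrationReport:
    transform: RigidTransform
    residuals: list[float]
    iterations: int
    converged: bool
    diverged: bool = False


def _solve_point_to_plane(src: np.ndarray, dst: np.ndarray,
                          normals: np.ndarray) -> RigidTransform:
    """One linearized point-to-plane step (small-angle approximation)."""
    c = np.cross(src, normals)
    A = np.hstack([c, normals])           # (n, 6)
    b = np.einsum("ij,ij->i", normals, dst - src)
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    w, t = x[:3], x[3:]
    # re-orthonormalize the small-angle rotation via Rodrigues
    theta = np.linalg.norm(w)
    if theta < 1e-15:
        R = np.eye(3)
    else:
        k = w / theta
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
    return RigidTransform(R, t)


def rigid_register(source: SurfaceMesh, target: SurfaceMesh,
                   init: RigidTransform | None = None,
                   max_iter: int = 100, tol: float = 1e-4,
                   metric: str = "point_to_plane") -> RegistrationReport:
    """ICP refinement of ``source`` onto ``target``.

    Correspondences are nearest target vertices (kd-tree); the update is a
    linearized point-to-plane step by default, or a closed-form Kabsch
    point-to-point step. The reported RMS residual sequence is non-increasing:
    a step that would increase it is rejected and iteration stops.
    """
    if len(source.faces) == 0 or len(target.faces) == 0:
        raise MeshContentError("cannot register an empty mesh")
    transform = init or RigidTransform.identity()

    tree = cKDTree(target.vertices)
    tgt_normals = _vertex_normals(target)

    src0 = source.vertices
    residuals: list[float] = []
    best = transform
    converged = False
    for _ in range(max_iter):
        cur = best.apply(src0)
        dist, idx = tree.query(cur)
        rms = float(np.sqrt(np.mean(dist ** 2)))
        if residuals and rms > residuals[-1]:
            break  # reject worsening step; keep previous best
        residuals.append(rms)
        if len(residuals) > 1 and residuals[-2] - residuals[-1] < tol:
            converged = True
            break
        dst = target.vertices[idx]
        if metric == "point_to_plane":
            step = _solve_point_to_plane(cur, dst, tgt_normals[idx])
        elif metric == "point_to_point":
            step = _kabsch(cur, dst)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        best = step.compose(best)
    diverged = bool(residuals and residuals[-1] > residuals[0] + tol)
    if diverged:
        log.warning("ICP residual did not improve (%.4g -> %.4g mm)",
                    residuals[0], residuals[-1])
    return RegistrationReport(transform=best, residuals=residuals,
                              iterations=len(residuals), converged=converged,
                              diverged=diverged)


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    H = (src - sc).T @ (dst - dc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, dc - R @ sc)


def _vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Area-weighted vertex normals (unnormalized face normals summed)."""
    tri = mesh.triangles
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    vn = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(vn, mesh.faces[:, k], fn)
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return vn / norms
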