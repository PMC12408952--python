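"""Occlusal contact area (OCA) from an aligned jaw pair.

The contact area at interocclusal distance ``t`` is the sub-surface of the
mandible lying within ``t`` of the maxilla surface. Conceptually this is
the intersection of the mandible with the maxilla enlarged ("offset") by
``t``; it is computed here as an unsigned-distance sublevel set, which is
equivalent for offsets small against local feature size and stays
well-defined where an explicit offset surface would self-intersect (deep
fissures at large offsets). Distances are unsigned, so scan
interpenetration counts as contact at any threshold.

Each contact patch is measured twice: as a true 3D surface area (sum of
trimmed-fragment areas) and as the area of the union of the fragments
projected onto the occlusal plane (the 2D area, the digital analogue of a
transilluminated wax record). Nine default offsets from 100 to 2000 μm give
18 evaluations per subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .jaw_alignment import AlignedJawPair
from .mesh_io import MeshContentError, SurfaceMesh

log = logging.getLogger(__name__)

#: the nine interocclusal distances evaluated by default, in μm
DEFAULT_OFFSETS_UM = (100.0, 150.0, 200.0, 250.0, 300.0, 350.0, 400.0, 800.0, 2000.0)

#: default max triangle edge (mm) in the refined contact band
DEFAULT_REFINE_MAX_EDGE_MM = 0.1

#: default rasterization resolution for 2D projected areas (pixels per mm)
DEFAULT_RASTER_PX_MM = 100.0


@dataclass(frozen=True)
class OffsetProfile:
    """Ordered set of interocclusal distances (μm) to evaluate."""

    offsets_um: tuple = DEFAULT_OFFSETS_UM

    def __post_init__(self) -> None:
        off = tuple(float(t) for t in self.offsets_um)
        if len(off) == 0:
            raise ValueError("offset profile is empty")
        if any(t <= 0 for t in off):
            raise ValueError("offsets must be positive")
        if any(b <= a for a, b in zip(off, off[1:])):
            raise ValueError("offsets must be strictly increasing")
        object.__setattr__(self, "offsets_um", off)

    def __len__(self) -> int:
        return len(self.offsets_um)


# ---------------------------------------------------------------------------
# exact unsigned distance to a triangle mesh


def _point_segment_distance_sq(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    s = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    d = p - (a + s[:, None] * ab)
    return np.einsum("ij,ij->i", d, d)


def _point_triangle_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                             c: np.ndarray) -> np.ndarray:
    """Exact distances for paired points/triangles, all shaped (n, 3).

    The closest point is either the in-plane projection (when its
    barycentric coordinates are non-negative) or lies on one of the edges.
    """
    ab, ac, ap = b - a, c - a, p - a
    n = np.cross(ab, ac)
    nn = np.einsum("ij,ij->i", n, n)
    nn_safe = np.where(nn == 0, 1.0, nn)
    t = np.einsum("ij,ij->i", ap, n) / nn_safe
    proj = ap - t[:, None] * n  # projection of p into the plane, rel. to a

    d00 = np.einsum("ij,ij->i", ab, ab)
    d01 = np.einsum("ij,ij->i", ab, ac)
    d11 = np.einsum("ij,ij->i", ac, ac)
    d20 = np.einsum("ij,ij->i", proj, ab)
    d21 = np.einsum("ij,ij->i", proj, ac)
    denom = d00 * d11 - d01 * d01
    denom = np.where(denom == 0, 1.0, denom)
    u = (d11 * d20 - d01 * d21) / denom
    v = (d00 * d21 - d01 * d20) / denom
    inside = (u >= 0) & (v >= 0) & (u + v <= 1) & (nn > 0)

    plane_sq = t * t * nn_safe
    edge_sq = np.minimum(
        _point_segment_distance_sq(p, a, b),
        np.minimum(_point_segment_distance_sq(p, b, c),
                   _point_segment_distance_sq(p, a, c)))
    return np.sqrt(np.where(inside, np.minimum(plane_sq, edge_sq), edge_sq))


class SurfaceDistanceQuery:
    """Accelerated exact unsigned distance from points to a mesh surface.

    A kd-tree over face centroids yields a tight upper bound (the exact
    distance to the face with the nearest centroid). Any face containing
    the true closest point has its centroid within ``bound + r_max`` of the
    query, where ``r_max`` is the largest centroid-to-vertex distance of
    the mesh, so minimizing the exact point-to-triangle distance over the
    faces inside that ball reproduces the exhaustive minimum.
    """

    def __init__(self, mesh: SurfaceMesh):
        if len(mesh.faces) == 0:
            raise MeshContentError("cannot build a distance query on an empty mesh")
        self.mesh = mesh
        self._tri = mesh.triangles
        centroids = self._tri.mean(axis=1)
        self._ctree = cKDTree(centroids)
        self._r_max = float(
            np.linalg.norm(self._tri - centroids[:, None, :], axis=2).max())
        edges = np.stack([
            np.linalg.norm(self._tri[:, 1] - self._tri[:, 0], axis=1),
            np.linalg.norm(self._tri[:, 2] - self._tri[:, 1], axis=1),
            np.linalg.norm(self._tri[:, 0] - self._tri[:, 2], axis=1),
        ])
        self._max_edge = float(edges.max())

    @property
    def max_edge(self) -> float:
        return self._max_edge

    def __call__(self, points: np.ndarray, batch: int = 20000,
                 cutoff: float | None = None) -> np.ndarray:
        """Distances to the surface; exact everywhere by default.

        With ``cutoff`` set, points whose upper bound exceeds it keep that
        bound — it overestimates the exact distance by at most one edge
        length, which is sufficient when only membership in ``d <= t`` for
        ``t <= cutoff - max_edge`` is consumed downstream.
        """
        points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(points)):
            raise ValueError("query points must be finite")
        out = np.empty(len(points))
        for lo in range(0, len(points), batch):
            out[lo:lo + batch] = self._upper_bound(points[lo:lo + batch])
        if cutoff is None:
            near = np.arange(len(points))
        else:
            near = np.flatnonzero(out <= cutoff)
        for lo in range(0, len(near), batch):
            sel = near[lo:lo + batch]
            out[sel] = self._exact(points[sel], out[sel])
        return out

    def _upper_bound(self, pts: np.ndarray) -> np.ndarray:
        """Exact distance to the face with the nearest centroid."""
        _, f0 = self._ctree.query(pts)
        t = self._tri[f0]
        return _point_triangle_distance(pts, t[:, 0], t[:, 1], t[:, 2])

    def _exact(self, pts: np.ndarray, ub: np.ndarray) -> np.ndarray:
        radii = ub + self._r_max * (1 + 1e-12) + 1e-12
        balls = self._ctree.query_ball_point(pts, radii)
        counts = np.fromiter((len(b) for b in balls), dtype=np.int64,
                             count=len(balls))
        if counts.sum() == 0:
            return ub
        face_idx = np.concatenate([np.asarray(b, dtype=np.int64) for b in balls])
        pt_idx = np.repeat(np.arange(len(pts)), counts)
        t = self._tri[face_idx]
        d = _point_triangle_distance(pts[pt_idx], t[:, 0], t[:, 1], t[:, 2])
        out = ub.copy()
        nonempty = counts > 0
        starts = np.concatenate([[0], np.cumsum(counts)])[:-1][nonempty]
        out[nonempty] = np.minimum(out[nonempty], np.minimum.reduceat(d, starts))
        return out


def surface_distance(points: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    """Exact minimum Euclidean distance (mm) from each point to the mesh."""
    return SurfaceDistanceQuery(mesh)(points)


def points_within_distance(points: np.ndarray, mesh: SurfaceMesh,
                           t_mm: float) -> np.ndarray:
    """Exact boolean membership in {d(p, mesh) <= t_mm}.

    Cheaper than full distances when only membership matters (e.g. Monte
    Carlo area estimates): points beyond the certified cutoff are decided
    from the nearest-vertex bound alone.
    """
    q = SurfaceDistanceQuery(mesh)
    d = q(points, cutoff=t_mm + q.max_edge)
    return d <= t_mm


def surface_distance_bruteforce(points: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    """Exhaustive all-triangle minimum; reference oracle for the query."""
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    tri = mesh.triangles
    out = np.empty(len(points))
    for i, p in enumerate(points):
        pp = np.broadcast_to(p, (len(tri), 3))
        out[i] = _point_triangle_distance(pp, tri[:, 0], tri[:, 1], tri[:, 2]).min()
    return out


# ---------------------------------------------------------------------------
# contact patch extraction


@dataclass
class ContactPatch:
    """Mandible sub-surface within ``offset_um`` of the maxilla.

    Fragments are grouped by polygon class for vectorized processing:
    whole kept triangles, clipped triangles and clipped quads, each an
    (n, k, 3) array. Every fragment lies within one (possibly subdivided)
    mandible face.
    """

    offset_um: float
    whole: np.ndarray        # (n0, 3, 3)
    clipped_tris: np.ndarray  # (n1, 3, 3)
    clipped_quads: np.ndarray  # (n2, 4, 3)
    area_3d: float = 0.0
    area_2d: float = 0.0

    @property
    def fragments(self) -> list:
        """All fragments as a flat list of (k, 3) polygon arrays."""
        out = [f for f in self.whole]
        out += [f for f in self.clipped_tris]
        out += [f for f in self.clipped_quads]
        return out

    @property
    def n_fragments(self) -> int:
        return len(self.whole) + len(self.clipped_tris) + len(self.clipped_quads)

    def is_empty(self) -> bool:
        return self.n_fragments == 0


@dataclass
class OCAProfile:
    """Per-offset 3D and 2D contact areas for one subject."""

    subject_id: str
    offsets_um: tuple
    areas_3d_mm2: np.ndarray
    areas_2d_mm2: np.ndarray

    @property
    def evaluation_count(self) -> int:
        return 2 * len(self.offsets_um)

    def as_dict(self) -> dict:
        """Strategy map keyed by (offset_um, projection)."""
        d = {}
        for t, a3, a2 in zip(self.offsets_um, self.areas_3d_mm2, self.areas_2d_mm2):
            d[(t, "3d")] = float(a3)
            d[(t, "2d")] = float(a2)
        return d


def _polygon_areas(poly: np.ndarray) -> np.ndarray:
    """Areas of planar polygons given as (n, k, 3); shoelace via cross sums."""
    if len(poly) == 0:
        return np.zeros(0)
    center = poly.mean(axis=1, keepdims=True)
    s = np.zeros((len(poly), 3))
    k = poly.shape[1]
    for i in range(k):
        a = poly[:, i] - center[:, 0]
        b = poly[:, (i + 1) % k] - center[:, 0]
        s += np.cross(a, b)
    return 0.5 * np.linalg.norm(s, axis=1)


def _subdivide_to_edge(tris: np.ndarray, max_edge: float) -> np.ndarray:
    """4-way midpoint subdivision of a triangle soup until edges <= max_edge."""
    while len(tris):
        e = np.stack([
            np.linalg.norm(tris[:, 1] - tris[:, 0], axis=1),
            np.linalg.norm(tris[:, 2] - tris[:, 1], axis=1),
            np.linalg.norm(tris[:, 0] - tris[:, 2], axis=1),
        ]).max(axis=0)
        big = e > max_edge
        if not big.any():
            break
        keep, split = tris[~big], tris[big]
        a, b, c = split[:, 0], split[:, 1], split[:, 2]
        ab, bc, ca = 0.5 * (a + b), 0.5 * (b + c), 0.5 * (c + a)
        tris = np.concatenate([
            keep,
            np.stack([a, ab, ca], axis=1),
            np.stack([ab, b, bc], axis=1),
            np.stack([ca, bc, c], axis=1),
            np.stack([ab, bc, ca], axis=1),
        ])
    return tris


class ContactField:
    """Refined mandible triangle soup with per-vertex maxilla distances.

    Built once per jaw pair for the largest offset of interest, then
    evaluated at any smaller offset by marching-triangles clipping of the
    same piecewise-linear distance field — which makes the extracted
    regions exactly nested across offsets.
    """

    def __init__(self, pair: AlignedJawPair, max_offset_um: float,
                 refine_max_edge_mm: float = DEFAULT_REFINE_MAX_EDGE_MM,
                 offsets_um: tuple | None = None):
        if refine_max_edge_mm <= 0:
            raise ValueError("refine_max_edge_mm must be positive")
        self.pair = pair
        self.query = SurfaceDistanceQuery(pair.maxilla)
        t_max = max_offset_um / 1000.0

        mand = pair.mandible
        tri = mand.triangles
        mand_edges = np.concatenate([
            np.linalg.norm(tri[:, 1] - tri[:, 0], axis=1),
            np.linalg.norm(tri[:, 2] - tri[:, 1], axis=1),
            np.linalg.norm(tri[:, 0] - tri[:, 2], axis=1),
        ])
        # exact distances are only needed near the contact band; beyond the
        # cutoff a certified upper bound cannot change any in/out decision
        self._cutoff = t_max + float(mand_edges.max()) + self.query.max_edge
        vd = self.query(mand.vertices, cutoff=self._cutoff)
        fd = vd[mand.faces]
        longest = np.stack([
            np.linalg.norm(tri[:, 1] - tri[:, 0], axis=1),
            np.linalg.norm(tri[:, 2] - tri[:, 1], axis=1),
            np.linalg.norm(tri[:, 0] - tri[:, 2], axis=1),
        ]).max(axis=0)
        fmin = fd.min(axis=1)

        # faces that can touch the sublevel set at all (Lipschitz bound)
        reach = fmin <= t_max + longest
        # faces whose iso-contour at some requested offset may cross them
        # get refined; faces certainly inside every relevant offset stay coarse
        ts = np.asarray(offsets_um if offsets_um is not None else [max_offset_um]) / 1000.0
        ambiguous = np.zeros(len(tri), dtype=bool)
        for t in ts:
            ambiguous |= (fmin > t - longest) & (fmin <= t + longest)
        ambiguous &= reach

        coarse = tri[reach & ~ambiguous]
        fine = _subdivide_to_edge(tri[ambiguous], refine_max_edge_mm)
        soup = np.concatenate([coarse, fine]) if len(coarse) or len(fine) \
            else np.empty((0, 3, 3))
        self.triangles = soup
        self.vertex_distances = self._distances_dedup(soup)
        log.debug("contact field: %d coarse + %d refined triangles in band",
                  len(coarse), len(fine))

    def _distances_dedup(self, soup: np.ndarray) -> np.ndarray:
        if len(soup) == 0:
            return np.empty((0, 3))
        flat = soup.reshape(-1, 3)
        uniq, inv = np.unique(flat, axis=0, return_inverse=True)
        d = self.query(uniq, cutoff=self._cutoff)
        return d[inv].reshape(-1, 3)

    def extract(self, offset_um: float) -> ContactPatch:
        """Clip the field at d = offset and return the contact patch."""
        if offset_um <= 0:
            raise ValueError("offset must be positive")
        t = offset_um / 1000.0
        tri, d = self.triangles, self.vertex_distances
        if len(tri) == 0:
            return ContactPatch(offset_um, *(np.empty((0, k, 3)) for k in (3, 3, 4)))
        inside = d <= t
        k = inside.sum(axis=1)

        whole = tri[k == 3]

        # one vertex inside -> clipped triangle (A, X_AB, X_AC)
        t1, d1 = tri[k == 1], d[k == 1]
        if len(t1):
            ia = np.argmax(inside[k == 1], axis=1)
            A, B, C = _rolled(t1, ia)
            dA, dB, dC = _rolled_vals(d1, ia)
            xab = _iso_point(A, dA, B, dB, t)
            xac = _iso_point(A, dA, C, dC, t)
            clipped_tris = np.stack([A, xab, xac], axis=1)
        else:
            clipped_tris = np.empty((0, 3, 3))

        # two vertices inside -> quad (A, B, X_BC, X_AC); C is outside
        t2, d2 = tri[k == 2], d[k == 2]
        if len(t2):
            ic = np.argmax(~inside[k == 2], axis=1)
            # roll so the outside vertex sits at position 2
            C, A, B = _rolled(t2, ic)
            dC, dA, dB = _rolled_vals(d2, ic)
            xbc = _iso_point(B, dB, C, dC, t)
            xac = _iso_point(A, dA, C, dC, t)
            clipped_quads = np.stack([A, B, xbc, xac], axis=1)
        else:
            clipped_quads = np.empty((0, 4, 3))

        patch = ContactPatch(offset_um, whole, clipped_tris, clipped_quads)
        patch.area_3d = float(_polygon_areas(whole).sum()
                              + _polygon_areas(clipped_tris).sum()
                              + _polygon_areas(clipped_quads).sum())
        return patch


def _rolled(tri: np.ndarray, i0: np.ndarray):
    """Corner arrays rolled so corner ``i0`` comes first."""
    n = np.arange(len(tri))
    return tri[n, i0], tri[n, (i0 + 1) % 3], tri[n, (i0 + 2) % 3]


def _rolled_vals(d: np.ndarray, i0: np.ndarray):
    n = np.arange(len(d))
    return d[n, i0], d[n, (i0 + 1) % 3], d[n, (i0 + 2) % 3]


def _iso_point(p_in: np.ndarray, d_in: np.ndarray, p_out: np.ndarray,
               d_out: np.ndarray, t: float) -> np.ndarray:
    """Linear interpolation of the d = t crossing on an edge."""
    s = (t - d_in) / (d_out - d_in)
    return p_in + s[:, None] * (p_out - p_in)


def extract_contact_patch(pair: AlignedJawPair, offset_um: float,
                          refine_max_edge_mm: float = DEFAULT_REFINE_MAX_EDGE_MM,
                          raster_px_mm: float = DEFAULT_RASTER_PX_MM) -> ContactPatch:
    """Contact patch of the mandible at one interocclusal distance (μm)."""
    field = ContactField(pair, offset_um, refine_max_edge_mm,
                         offsets_um=(offset_um,))
    patch = field.extract(offset_um)
    patch.area_2d = patch_area_2d(patch, raster_px_mm=raster_px_mm)
    return patch


# ---------------------------------------------------------------------------
# 2D projected area


def patch_area_2d(patch: ContactPatch, method: str = "raster",
                  raster_px_mm: float = DEFAULT_RASTER_PX_MM) -> float:
    """Area of the union of fragment projections onto the occlusal plane.

    ``raster`` marks pixel centers covered by any projected fragment on a
    grid aligned to the global origin (so nested patches yield monotone
    areas); ``exact_union`` uses polygon boolean union and is the
    verification reference.
    """
    if patch.is_empty():
        return 0.0
    if method == "exact_union":
        return _exact_union_area(patch)
    if method != "raster":
        raise ValueError(f"unknown 2D area method {method!r}")
    if raster_px_mm <= 0:
        raise ValueError("raster resolution must be positive")

    px = 1.0 / raster_px_mm
    tris = _as_triangles_2d(patch)
    # grid snapped to multiples of the pixel size at the global origin, so
    # nested patches see identical pixel centers and areas stay monotone
    xy = tris.reshape(-1, 2)
    i0 = int(np.floor(xy[:, 0].min() / px)) - 1
    j0 = int(np.floor(xy[:, 1].min() / px)) - 1
    ni = int(np.ceil(xy[:, 0].max() / px)) + 2 - i0
    nj = int(np.ceil(xy[:, 1].max() / px)) + 2 - j0
    grid = np.zeros(ni * nj, dtype=bool)
    v = tris / px - np.array([i0, j0])  # pixel units; center of (i,j) = i+.5
    _raster_triangles(v, grid, ni, nj)
    return float(grid.sum()) * px * px


def _as_triangles_2d(patch: ContactPatch) -> np.ndarray:
    """All projected fragments as (n, 3, 2) triangles (quads fanned)."""
    parts = []
    for g in (patch.whole, patch.clipped_tris):
        if len(g):
            parts.append(g[..., :2])
    q = patch.clipped_quads
    if len(q):
        parts.append(q[:, (0, 1, 2), :2])
        parts.append(q[:, (0, 2, 3), :2])
    return np.concatenate(parts)


def _raster_triangles(v: np.ndarray, grid: np.ndarray, ni: int, nj: int,
                      chunk: int = 4_000_000) -> None:
    """Mark pixel centers covered by any triangle; fully vectorized.

    ``v`` is (n, 3, 2) in pixel units; ``grid`` is a flat boolean of
    ni * nj cells. Candidate pixels come from per-triangle bounding boxes;
    membership is an inclusive half-plane test robust to either winding.
    """
    lo = np.maximum(np.ceil(v.min(axis=1) - 0.5), 0).astype(np.int64)
    hi = np.minimum(np.floor(v.max(axis=1) - 0.5), [ni - 1, nj - 1]).astype(np.int64)
    w = np.maximum(hi[:, 0] - lo[:, 0] + 1, 0)
    h = np.maximum(hi[:, 1] - lo[:, 1] + 1, 0)
    cells = w * h
    order = np.arange(len(v))
    csum = np.cumsum(cells)
    start = 0
    while start < len(v):
        stop = int(np.searchsorted(csum, (csum[start - 1] if start else 0) + chunk)) + 1
        sel = order[start:stop]
        _raster_chunk(v[sel], lo[sel], w[sel], h[sel], grid, nj)
        start = stop


def _raster_chunk(v, lo, w, h, grid, nj) -> None:
    cells = w * h
    keep = cells > 0
    v, lo, w, h, cells = v[keep], lo[keep], w[keep], h[keep], cells[keep]
    if len(v) == 0:
        return
    # force counter-clockwise winding so one inclusive half-plane test suffices
    signed = ((v[:, 1, 0] - v[:, 0, 0]) * (v[:, 2, 1] - v[:, 0, 1])
              - (v[:, 1, 1] - v[:, 0, 1]) * (v[:, 2, 0] - v[:, 0, 0]))
    flip = signed < 0
    v[flip] = v[flip][:, ::-1]

    tri_id = np.repeat(np.arange(len(v)), cells)
    local = np.arange(int(cells.sum())) - np.repeat(
        np.concatenate([[0], np.cumsum(cells)[:-1]]), cells)
    hh = h[tri_id]
    di, dj = local // hh, local % hh
    pi = lo[tri_id, 0] + di
    pj = lo[tri_id, 1] + dj
    px = pi + 0.5
    py = pj + 0.5

    ax, ay = v[tri_id, 0, 0], v[tri_id, 0, 1]
    bx, by = v[tri_id, 1, 0], v[tri_id, 1, 1]
    cx, cy = v[tri_id, 2, 0], v[tri_id, 2, 1]
    eps = 1e-12
    inside = ((bx - ax) * (py - ay) - (by - ay) * (px - ax) >= -eps)
    inside &= ((cx - bx) * (py - by) - (cy - by) * (px - bx) >= -eps)
    inside &= ((ax - cx) * (py - cy) - (ay - cy) * (px - cx) >= -eps)
    grid[pi[inside] * nj + pj[inside]] = True


def _exact_union_area(patch: ContactPatch) -> float:
    import shapely

    polys = []
    for g in (patch.whole, patch.clipped_tris, patch.clipped_quads):
        if len(g):
            rings = np.concatenate([g[..., :2], g[:, :1, :2]], axis=1)
            p = shapely.polygons(rings)
            polys.append(shapely.make_valid(p))
    if not polys:
        return 0.0
    return float(shapely.union_all(np.concatenate(polys)).area)


def patch_area_2d_sum(patch: ContactPatch) -> float:
    """Sum (not union) of projected fragment areas; sensitivity analysis only."""
    total = 0.0
    for g in (patch.whole, patch.clipped_tris, patch.clipped_quads):
        if len(g):
            flat = g.copy()
            flat[..., 2] = 0.0
            total += float(_polygon_areas(flat).sum())
    return total


# ---------------------------------------------------------------------------
# full profile


def compute_oca_profile(pair: AlignedJawPair,
                        profile: OffsetProfile | None = None,
                        refine_max_edge_mm: float = DEFAULT_REFINE_MAX_EDGE_MM,
                        raster_px_mm: float = DEFAULT_RASTER_PX_MM,
                        subject_id: str = "") -> OCAProfile:
    """3D and 2D contact areas at every offset of the profile (default nine).

    One shared refined distance field serves all offsets, so the patches are
    exactly nested and both area sequences are non-decreasing in t.
    """
    profile = profile or OffsetProfile()
    field = ContactField(pair, max(profile.offsets_um), refine_max_edge_mm,
                         offsets_um=profile.offsets_um)
    a3, a2 = [], []
    for t in profile.offsets_um:
        patch = field.extract(t)
        patch.area_2d = patch_area_2d(patch, raster_px_mm=raster_px_mm)
        a3.append(patch.area_3d)
        a2.append(patch.area_2d)
    return OCAProfile(subject_id=subject_id, offsets_um=profile.offsets_um,
                      areas_3d_mm2=np.asarray(a3), areas_2d_mm2=np.asarray(a2))
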