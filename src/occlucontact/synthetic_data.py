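"""Synthetic inputs with known ground truth for the whole pipeline.

Real inputs — digitised gypsum casts in maximum intercuspation, flatbed
scans of chewed silicone particles, and a two-group cohort table — are
clinical and not publicly deposited, so every stage here has a generator
whose truth is known by construction:

* analytic jaw fixtures (plates, sphere-on-plane, tilted patch, overhang)
  with closed-form contact areas at any offset;
* parametric cusped jaw phantoms with a controllable minimum interocclusal
  gap;
* particle images whose diameters are drawn so that the mass-weighted
  cumulative size distribution follows a prescribed Rosin–Rammler law;
* cohorts with a planted Pearson correlation between one OCA evaluation
  strategy and X50, and a group-level X50 shift.

All randomness flows through one ``numpy.random.Generator`` derived from an
explicit seed; identical parameters and seed give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .jaw_alignment import AlignedJawPair
from .mesh_io import LandmarkSet, SurfaceMesh

DEFAULT_OFFSET_BASE_EXPONENT = 1.327  # log-slope of mean OCA vs offset


# ---------------------------------------------------------------------------
# mesh building blocks


def grid_mesh(x0: float, x1: float, y0: float, y1: float, step: float,
              zfun=None, name: str = "") -> SurfaceMesh:
    """Triangulated rectangular height field; ``zfun(x, y)`` or z = 0."""
    nx = max(2, int(round((x1 - x0) / step)) + 1)
    ny = max(2, int(round((y1 - y0) / step)) + 1)
    xs = np.linspace(x0, x1, nx)
    ys = np.linspace(y0, y1, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = zfun(X, Y) if zfun is not None else np.zeros_like(X)
    verts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    idx = np.arange(nx * ny).reshape(nx, ny)
    a, b, c, d = idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:], idx[:-1, 1:]
    faces = np.concatenate([
        np.stack([a.ravel(), b.ravel(), c.ravel()], axis=1),
        np.stack([a.ravel(), c.ravel(), d.ravel()], axis=1),
    ])
    return SurfaceMesh(verts, faces, name)


def icosphere(radius: float, center, subdivisions: int = 6,
              name: str = "sphere") -> SurfaceMesh:
    import trimesh
    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(s.vertices) + np.asarray(center),
                       np.asarray(s.faces), name)


def sample_surface_points(mesh: SurfaceMesh, n: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Uniform area-weighted random points on the mesh surface."""
    areas = mesh.face_areas()
    fi = rng.choice(len(areas), size=n, p=areas / areas.sum())
    tri = mesh.triangles[fi]
    r1, r2 = rng.random(n), rng.random(n)
    swap = r1 + r2 > 1
    r1[swap], r2[swap] = 1 - r1[swap], 1 - r2[swap]
    return (tri[:, 0] + r1[:, None] * (tri[:, 1] - tri[:, 0])
            + r2[:, None] * (tri[:, 2] - tri[:, 0]))


# ---------------------------------------------------------------------------
# analytic fixtures with closed-form contact areas


def make_analytic_fixture(kind: str, **params):
    """Aligned fixture pair plus its exact ``area(t_um) -> (a3d, a2d)``.

    Kinds
    -----
    ``parallel_plates(side, gap, step)``
        Two coaxial square plates; area is a step function of t at the gap.
    ``sphere_on_plane(radius, gap, half_extent, step)``
        Sphere apex a gap above a flat plate; the contact patch on the
        plate is the disk rho^2 <= (R+t)^2 - (R+gap)^2.
    ``tilted_patch(theta_deg, gap, side, step)``
        Plane strip tilted theta from horizontal with a parallel opposing
        strip at normal distance gap; 2D/3D area ratio is cos(theta).
    ``overhang(side, dz, gap, step)``
        Two congruent horizontal facets stacked dz apart sharing one xy
        footprint; the projected union equals one footprint, not two.
    """
    makers = {
        "parallel_plates": _fixture_plates,
        "sphere_on_plane": _fixture_sphere,
        "tilted_patch": _fixture_tilted,
        "overhang": _fixture_overhang,
    }
    if kind not in makers:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return makers[kind](**params)


def _check_gap(gap: float) -> None:
    if gap < 0:
        raise ValueError("gap must be non-negative")


def _fixture_plates(side: float = 10.0, gap: float = 0.05, step: float = 0.25):
    _check_gap(gap)
    h = side / 2
    mand = grid_mesh(-h, h, -h, h, step, name="mandible")
    mx = grid_mesh(-h, h, -h, h, step, zfun=lambda x, y: np.full_like(x, gap),
                   name="maxilla")
    area = side * side

    def exact(t_um: float):
        a = area if t_um / 1000.0 >= gap else 0.0
        return a, a

    return AlignedJawPair(mandible=mand, maxilla=mx), exact


def _fixture_sphere(radius: float = 5.0, gap: float = 0.1,
                    half_extent: float = 4.0, step: float = 0.2,
                    subdivisions: int = 6):
    _check_gap(gap)
    mand = grid_mesh(-half_extent, half_extent, -half_extent, half_extent,
                     step, name="mandible")
    mx = icosphere(radius, (0.0, 0.0, gap + radius), subdivisions, name="maxilla")

    def exact(t_um: float):
        t = t_um / 1000.0
        if t < gap:
            return 0.0, 0.0
        a = math.pi * ((radius + t) ** 2 - (radius + gap) ** 2)
        return a, a  # the patch lies on the flat plate

    return AlignedJawPair(mandible=mand, maxilla=mx), exact


def _fixture_tilted(theta_deg: float = 60.0, gap: float = 0.05,
                    side: float = 6.0, step: float = 0.15):
    _check_gap(gap)
    th = math.radians(theta_deg)
    normal = np.array([math.sin(th), 0.0, math.cos(th)])
    u = np.array([math.cos(th), 0.0, -math.sin(th)])  # in-plane downslope
    v = np.array([0.0, 1.0, 0.0])

    def strip(margin: float, z_shift: np.ndarray, name: str) -> SurfaceMesh:
        h = side / 2 + margin
        mesh = grid_mesh(-h, h, -h, h, step, name=name)
        verts = (mesh.vertices[:, :1] * u + mesh.vertices[:, 1:2] * v + z_shift)
        return SurfaceMesh(verts, mesh.faces, name)

    mand = strip(0.0, np.zeros(3), "mandible")
    # opposing strip offset along the shared normal, oversized so every
    # mandible point sees a perpendicular gap
    mx = strip(3.0, gap * normal, "maxilla")
    area3 = side * side

    def exact(t_um: float):
        t = t_um / 1000.0
        if t < gap:
            return 0.0, 0.0
        return area3, area3 * math.cos(th)

    return AlignedJawPair(mandible=mand, maxilla=mx), exact


def _fixture_overhang(side: float = 4.0, dz: float = 0.1, gap: float = 0.05,
                      step: float = 0.2):
    _check_gap(gap)
    h = side / 2
    lower = grid_mesh(-h, h, -h, h, step, zfun=lambda x, y: np.full_like(x, -dz))
    upper = grid_mesh(-h, h, -h, h, step)
    mand = SurfaceMesh(
        np.concatenate([lower.vertices, upper.vertices]),
        np.concatenate([lower.faces, upper.faces + len(lower.vertices)]),
        "mandible")
    mx = grid_mesh(-h, h, -h, h, step, zfun=lambda x, y: np.full_like(x, gap),
                   name="maxilla")
    area = side * side

    def exact(t_um: float):
        t = t_um / 1000.0
        a3 = (t >= gap) * area + (t >= gap + dz) * area
        a2 = area if t >= gap else 0.0
        return float(a3), float(a2)

    return AlignedJawPair(mandible=mand, maxilla=mx), exact


# ---------------------------------------------------------------------------
# cusped jaw phantoms


@dataclass
class JawPhantomParams:
    """Parameters of the cusped two-surface jaw phantom (units mm)."""

    arch_length: float = 14.0
    arch_width: float = 14.0
    cusp_count: int = 6
    cusp_sigma: float = 2.0      # Gaussian cusp width
    cusp_height: float = 1.5     # peak height before plateau capping
    plateau_frac: float = 0.8    # cusps are flat-capped at this fraction of height
    gap: float = 0.1             # minimum interocclusal distance
    opening_scale: float = 1.5   # how fast the gap opens away from cusp tops
    resolution: float = 0.25     # max grid edge length
    height_jitter: float = 0.0   # relative jitter of non-landmark cusp heights
    position_jitter: float = 0.0  # absolute (mm) jitter of cusp centers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap < 0:
            raise ValueError("gap must be non-negative")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.cusp_count < 3:
            raise ValueError("need at least 3 cusps to place landmarks")
        # sagitta of the linear interpolation over one cell vs. the smallest
        # curvature radius of a cusp must not swamp the gap
        r_curv = self.cusp_sigma ** 2 / max(self.cusp_height, 1e-9)
        sag = self.resolution ** 2 / (8.0 * r_curv)
        if self.gap > 0 and sag > self.gap / 2:
            raise ValueError(
                f"resolution {self.resolution} mm too coarse for gap "
                f"{self.gap} mm (interpolation tolerance {sag:.3g} mm)")


def make_jaw_pair(params: JawPhantomParams) -> tuple[AlignedJawPair, LandmarkSet]:
    """Opposing cusped surfaces with minimum interocclusal distance ≈ gap.

    The mandible is a height field of Gaussian cusps arranged along a
    U-shaped arch, flat-capped at ``plateau_frac`` of the cusp height. The
    maxilla is the mandible raised by ``gap`` plus an opening term that is
    exactly zero on the plateaus, so the surfaces come closest (vertical
    distance = gap, surfaces locally flat) over the cusp tops. Landmark
    analogs sit on three full-height plateaus: the front cusp (incisal) and
    the two rearmost cusps (molar analogs).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    L, W = p.arch_length, p.arch_width

    # cusp centers along a U-arch from back-left, around the front, to
    # back-right; angle pi (back-left) -> pi/2 (front) -> 0 (back-right)
    s = np.linspace(0.0, 1.0, p.cusp_count)
    ang = math.pi * (1.0 - s)
    margin = p.cusp_sigma + 0.5
    rx = 0.5 * L - margin
    ry = W - 2.0 * margin
    cx = 0.5 * L + rx * np.cos(ang)
    cy = (W - margin) - ry * np.sin(ang)

    heights = np.full(p.cusp_count, p.cusp_height)
    landmark_idx = {0, p.cusp_count // 2, p.cusp_count - 1}
    if p.height_jitter > 0:
        jit = 1.0 + p.height_jitter * rng.uniform(-1.0, 1.0, p.cusp_count)
        for i in range(p.cusp_count):
            if i not in landmark_idx:
                heights[i] *= jit[i]
    if p.position_jitter > 0:
        cx = cx + rng.uniform(-p.position_jitter, p.position_jitter, p.cusp_count)
        cy = cy + rng.uniform(-p.position_jitter, p.position_jitter, p.cusp_count)
    cap = p.plateau_frac * p.cusp_height

    def raw(x, y):
        z = np.zeros_like(x, dtype=float)
        for xi, yi, hi in zip(cx, cy, heights):
            z = z + hi * np.exp(-((x - xi) ** 2 + (y - yi) ** 2)
                                / (2.0 * p.cusp_sigma ** 2))
        return z

    def z_mand(x, y):
        return np.minimum(raw(x, y), cap)

    def z_max(x, y):
        r = raw(x, y)
        opening = p.opening_scale * np.clip(1.0 - r / cap, 0.0, 1.0)
        return np.minimum(r, cap) + p.gap + opening

    mand = grid_mesh(0, L, 0, W, p.resolution, zfun=z_mand, name="mandible")
    mx = grid_mesh(0, L, 0, W, p.resolution, zfun=z_max, name="maxilla")

    li = sorted(landmark_idx)
    front = p.cusp_count // 2
    lm = LandmarkSet(
        incisal_point=np.array([cx[front], cy[front], cap]),
        left_molar_cusp=np.array([cx[li[0]], cy[li[0]], cap]),
        right_molar_cusp=np.array([cx[li[-1]], cy[li[-1]], cap]),
    )
    pair = AlignedJawPair(mandible=mand, maxilla=mx, occlusal_plane_z=cap,
                          landmarks=lm,
                          provenance={"generator": "make_jaw_pair",
                                      "seed": p.seed})
    return pair, lm


# ---------------------------------------------------------------------------
# particle images


@dataclass
class ParticlePhantomParams:
    """Parameters of the rendered chewed-particle scan phantom."""

    n_particles: int = 500
    size_law: str = "rosin_rammler"  # or "monodisperse", "mixture"
    x50: float = 4.0                 # mm, mass-based median (rosin_rammler)
    b: float = 3.0                   # Rosin-Rammler spread exponent
    diameter: float = 3.0            # mm (monodisperse)
    mixture: tuple = ((2.0, 0.5), (5.0, 0.5))  # (diameter, weight) pairs
    ppmm: float = 20.0               # rendering resolution, pixels per mm
    margin_mm: float = 0.3           # clearance between particles
    packing_fraction: float = 0.3    # target disk-area / image-area
    d_min: float = 0.5               # smallest rendered diameter, mm
    d_max: float = 12.0
    max_retries: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.ppmm <= 0:
            raise ValueError("need at least one particle and positive resolution")


def rosin_rammler_cdf(x, x50: float, b: float):
    """Mass fraction passing a sieve of size x: Q(x) = 1 - 2^(-(x/x50)^b)."""
    x = np.asarray(x, dtype=float)
    return 1.0 - np.power(2.0, -np.power(np.clip(x, 0, None) / x50, b))


def sample_rosin_rammler_diameters(n: int, x50: float, b: float,
                                   rng: np.random.Generator,
                                   d_min: float = 0.5,
                                   d_max: float = 12.0) -> np.ndarray:
    """Diameters whose d^3-weighted empirical distribution follows Q.

    Q is a *mass*-fraction-passing curve, so the number density of
    particles must be proportional to dQ/dx / x^3 (truncated below d_min,
    where Q is already negligible, to keep it integrable). Stratified
    inverse-transform sampling (one jittered draw per probability stratum)
    keeps the finite population's mass distribution close to the law even
    at moderate n, where i.i.d. draws would let the heavy top decile drift.
    """
    grid = np.linspace(d_min, d_max, 4000)
    q = np.diff(rosin_rammler_cdf(grid, x50, b))
    mid = 0.5 * (grid[:-1] + grid[1:])
    pdf = q / mid ** 3
    cdf = np.concatenate([[0.0], np.cumsum(pdf)])
    cdf /= cdf[-1]
    u = (np.arange(n) + rng.random(n)) / n
    return np.interp(u, cdf, grid)


def _draw_diameters(p: ParticlePhantomParams, rng: np.random.Generator) -> np.ndarray:
    if p.size_law == "rosin_rammler":
        return sample_rosin_rammler_diameters(p.n_particles, p.x50, p.b, rng,
                                              p.d_min, p.d_max)
    if p.size_law == "monodisperse":
        return np.full(p.n_particles, float(p.diameter))
    if p.size_law == "mixture":
        ds = np.array([d for d, _ in p.mixture])
        ws = np.array([w for _, w in p.mixture], dtype=float)
        return rng.choice(ds, size=p.n_particles, p=ws / ws.sum())
    raise ValueError(f"unknown size law {p.size_law!r}")


class PackingError(RuntimeError):
    """Particles could not be placed without overlap."""


def make_particle_image(params: ParticlePhantomParams):
    """Render non-overlapping anti-aliased dark disks on a light background.

    Returns ``(ParticleImage, truth)`` where ``truth`` is a dict with the
    placed diameters (mm), centers (mm) and the population's mass-based
    50%-passing size computed directly from the diameters.
    """
    from .digital_sieving import ParticleImage

    p = params
    rng = np.random.default_rng(p.seed)
    diam = np.sort(_draw_diameters(p, rng))[::-1]  # place large disks first
    radii = diam / 2.0

    disk_area = float(np.sum(np.pi * radii ** 2))
    side_mm = math.sqrt(disk_area / p.packing_fraction)
    side_mm = max(side_mm, 2 * (radii.max() + p.margin_mm) + 2)
    size_px = int(math.ceil(side_mm * p.ppmm))

    centers = np.empty((len(radii), 2))
    placed = 0
    for i, r in enumerate(radii):
        lo, hi = r + p.margin_mm, side_mm - r - p.margin_mm
        for _ in range(p.max_retries):
            c = rng.uniform(lo, hi, size=2)
            if placed == 0:
                break
            d2 = np.sum((centers[:placed] - c) ** 2, axis=1)
            min_sep = radii[:placed] + r + p.margin_mm
            if np.all(d2 > min_sep ** 2):
                break
        else:
            raise PackingError(
                f"could not place particle {i} of {len(radii)} "
                f"(packing fraction {p.packing_fraction} too high)")
        centers[i] = c
        placed += 1

    img = np.full((size_px, size_px), 255, dtype=np.uint8)
    for (cxm, cym), r in zip(centers, radii):
        cx_px, cy_px, r_px = cxm * p.ppmm, cym * p.ppmm, r * p.ppmm
        x0 = max(0, int(cx_px - r_px) - 2)
        x1 = min(size_px, int(cx_px + r_px) + 3)
        y0 = max(0, int(cy_px - r_px) - 2)
        y1 = min(size_px, int(cy_px + r_px) + 3)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.sqrt((xx + 0.5 - cx_px) ** 2 + (yy + 0.5 - cy_px) ** 2)
        coverage = np.clip(r_px + 0.5 - dist, 0.0, 1.0)
        vals = np.round(255 * (1.0 - coverage)).astype(np.uint8)
        img[y0:y1, x0:x1] = np.minimum(img[y0:y1, x0:x1], vals)

    w = diam ** 3
    order = np.argsort(diam)
    cum = np.cumsum(w[order]) / w.sum()
    true_x50 = float(np.interp(0.5, cum, diam[order]))
    truth = {"diameters_mm": diam.copy(), "centers_mm": centers.copy(),
             "mass_x50_mm": true_x50, "side_mm": side_mm}
    return ParticleImage(pixels=img, ppmm=p.ppmm,
                         provenance=f"synthetic seed={p.seed}"), truth


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortSimParams:
    """Two-group cohort with a planted OCA–X50 correlation.

    Defaults echo the study frame: 23 normal-occlusion vs. 18 malocclusion
    subjects, group X50 means 4.58 and 5.35 mm with SDs 0.37 and 0.43, a
    planted raw-scale Pearson r of −0.75 between X50 and the 3D contact
    area at 200 μm in the normal group and no correlation in the
    malocclusion group.
    """

    n_normal: int = 23
    n_malocclusion: int = 18
    x50_mean: dict = field(default_factory=lambda: {
        "normal_occlusion": 4.58, "malocclusion": 5.35})
    x50_sd: dict = field(default_factory=lambda: {
        "normal_occlusion": 0.37, "malocclusion": 0.43})
    target_r: dict = field(default_factory=lambda: {
        "normal_occlusion": -0.75, "malocclusion": 0.0})
    planted_strategy: tuple = (200.0, "3d")
    offsets_um: tuple = (100.0, 150.0, 200.0, 250.0, 300.0, 350.0, 400.0,
                         800.0, 2000.0)
    base_area_100: float = 16.0   # mean 3D OCA at 100 um, mm^2
    base_exponent: float = DEFAULT_OFFSET_BASE_EXPONENT
    subject_log_sd: float = 0.35  # subject-level spread of log OCA
    strategy_log_sd: float = 0.5  # extra per-offset noise (non-planted)
    proj_ratio: float = 0.7       # mean 2D/3D area ratio
    proj_log_sd: float = 0.5      # extra noise on 2D strategies
    seed: int = 0

    def __post_init__(self) -> None:
        for g, r in self.target_r.items():
            if not -1 < r < 1:
                raise ValueError(f"target r for {g} must be in (-1, 1)")
        if any(s <= 0 for s in self.x50_sd.values()):
            raise ValueError("x50 SDs must be positive")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - 0.5 * s2, math.sqrt(s2)


def _log_rho_for_raw_r(target_r: float, s1: float, s2: float) -> float:
    """Latent log-scale correlation giving Pearson r on the raw scale.

    Inverts the bivariate-lognormal identity
    r = (exp(rho*s1*s2) - 1) / sqrt((exp(s1^2)-1)(exp(s2^2)-1)).
    """
    arg = 1.0 + target_r * math.sqrt(
        math.expm1(s1 ** 2) * math.expm1(s2 ** 2))
    if arg <= 0:
        raise ValueError("infeasible correlation/SD combination")
    rho = math.log(arg) / (s1 * s2)
    if not -1 < rho < 1:
        raise ValueError(
            f"infeasible correlation/SD combination (latent rho {rho:.3f})")
    return rho


def simulate_cohort(params: CohortSimParams) -> list:
    """Simulate SubjectRecords with planted statistical structure.

    A per-subject latent "contact quality" u drives the whole OCA profile
    (log-normally); X50 is drawn from a Gaussian copula on the log scale
    whose latent correlation is chosen so the *raw-scale* Pearson r against
    the planted strategy equals the target. Non-planted strategies carry
    extra independent log-noise, so the planted strategy has the strongest
    correlation in expectation. Profiles are forced monotone in offset
    (without touching the planted value) and 2D is kept below 3D.
    """
    from .cohort_stats import SubjectRecord

    p = params
    rng = np.random.default_rng(p.seed)
    offsets = np.asarray(p.offsets_um, dtype=float)
    base = p.base_area_100 * (offsets / 100.0) ** p.base_exponent
    try:
        k_planted = int(np.nonzero(offsets == float(p.planted_strategy[0]))[0][0])
    except IndexError:
        raise ValueError("planted strategy offset not in the offset profile")
    planted_is_3d = p.planted_strategy[1].lower() == "3d"

    records = []
    groups = [("normal_occlusion", p.n_normal), ("malocclusion", p.n_malocclusion)]
    for group, n in groups:
        mu_lx, s_lx = _lognormal_params(p.x50_mean[group], p.x50_sd[group])
        rho = _log_rho_for_raw_r(p.target_r[group], p.subject_log_sd, s_lx)
        for i in range(n):
            u = rng.standard_normal()
            eps = rng.standard_normal()
            x50 = math.exp(mu_lx + s_lx * (rho * u + math.sqrt(1 - rho * rho) * eps))

            noise = rng.normal(0.0, p.strategy_log_sd, len(offsets))
            noise[k_planted] = 0.0
            a3 = base * np.exp(p.subject_log_sd * u + noise)
            # enforce monotonicity outward from the planted offset so the
            # planted value is never modified
            for k in range(k_planted - 1, -1, -1):
                a3[k] = min(a3[k], a3[k + 1] * 0.999)
            for k in range(k_planted + 1, len(offsets)):
                a3[k] = max(a3[k], a3[k - 1] * 1.001)

            # projection ratio through a logistic transform: strictly inside
            # (0, 1), so 2D < 3D holds without clipping-induced value copies
            s_logit = p.proj_log_sd / (1.0 - p.proj_ratio)
            logit0 = math.log(p.proj_ratio / (1.0 - p.proj_ratio))
            nu = rng.normal(0.0, 1.0, len(offsets))
            if not planted_is_3d:
                nu[k_planted] = 0.0
            ratio = 1.0 / (1.0 + np.exp(-(logit0 + s_logit * nu)))
            a2 = a3 * ratio
            # backward minimum pass restores monotonicity by lowering early
            # offsets (never by copying values outward from the planted one)
            a2 = np.minimum.accumulate(a2[::-1])[::-1]

            oca = {}
            for t, v3, v2 in zip(offsets, a3, a2):
                oca[(float(t), "3d")] = float(v3)
                oca[(float(t), "2d")] = float(v2)
            records.append(SubjectRecord(
                subject_id=f"{'N' if group == 'normal_occlusion' else 'M'}{i + 1:03d}",
                group=group, x50=float(x50), oca=oca))
    return records
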