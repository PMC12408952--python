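"""Masticatory performance (X50) by digital sieving of a particle scan.

A chewed standardised test food (17 silicone cubes, 5 mm edge, 15 chewing
strokes) is spread on a flatbed scanner with the particles separated.
Instead of stacking physical sieves, the scan is segmented, each particle
is reduced to the diameter of the circle with its projected area, and a
cumulative size distribution is built with per-particle weights
proportional to the equivalent-sphere volume d^3 (sieving is mass-based
and the test-food density is uniform; area weighting is available as an
alternative). A two-parameter Rosin–Rammler law

    Q(x) = 1 - 2^(-(x / x50)^b)

is fitted by nonlinear least squares; its median x50 — the mesh size of a
theoretical sieve through which half the sample mass would pass — is the
masticatory-performance statistic. Lower X50 means better comminution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

log = logging.getLogger(__name__)

DEFAULT_MIN_AREA_MM2 = 0.05
DEFAULT_RECOVERY_QC_THRESHOLD = 0.9
#: tolerance for recovered weight exceeding initial weight (moisture uptake)
RECOVERY_MAX_RATIO = 1.05


class SievingContentError(ValueError):
    """Input lacks the content needed for a size distribution."""


@dataclass
class ParticleImage:
    """A grayscale scan of separated particles with known resolution."""

    pixels: np.ndarray
    ppmm: float  # pixels per mm
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise SievingContentError("image must be a non-empty 2D array")
        if not self.ppmm > 0:
            raise ValueError("resolution (pixels per mm) must be positive")

    @classmethod
    def from_file(cls, path, ppmm: float | None = None,
                  provenance: str = "") -> "ParticleImage":
        """Load a PNG/TIFF scan; resolution from ``ppmm`` or TIFF metadata."""
        from PIL import Image

        img = Image.open(path)
        if ppmm is None:
            dpi = img.info.get("dpi")
            if dpi:
                ppmm = float(dpi[0]) / 25.4
        if ppmm is None:
            raise ValueError(f"resolution unknown for {path}; pass ppmm")
        arr = np.asarray(img.convert("I" if img.mode in ("I;16", "I") else "L"))
        return cls(pixels=arr, ppmm=ppmm, provenance=provenance or str(path))


@dataclass
class ParticleSet:
    """Segmented particles: projected areas, equivalent diameters, centroids."""

    areas_mm2: np.ndarray
    centroids_mm: np.ndarray

    def __post_init__(self) -> None:
        self.areas_mm2 = np.asarray(self.areas_mm2, dtype=float).reshape(-1)
        self.centroids_mm = np.asarray(self.centroids_mm, dtype=float).reshape(-1, 2)

    @property
    def diameters_mm(self) -> np.ndarray:
        """Equivalent circle diameter d = 2 sqrt(A / pi)."""
        return 2.0 * np.sqrt(self.areas_mm2 / np.pi)

    def __len__(self) -> int:
        return len(self.areas_mm2)


@dataclass
class SizeDistribution:
    """Cumulative weight fraction passing each sieve size (a step function)."""

    sizes_mm: np.ndarray        # ascending distinct sizes
    cumulative: np.ndarray      # Q at each size (fraction of weight <= size)
    basis: str = "volume_proxy"

    def __post_init__(self) -> None:
        self.sizes_mm = np.asarray(self.sizes_mm, dtype=float).reshape(-1)
        self.cumulative = np.asarray(self.cumulative, dtype=float).reshape(-1)
        if len(self.sizes_mm) == 0:
            raise SievingContentError("empty size distribution")
        if np.any(np.diff(self.sizes_mm) <= 0):
            raise ValueError("sizes must be strictly ascending")
        if np.any(np.diff(self.cumulative) < 0) or self.cumulative[-1] > 1 + 1e-9:
            raise ValueError("cumulative fractions must be non-decreasing and <= 1")

    def Q(self, x) -> np.ndarray:
        """Step-function fraction passing a sieve of size x."""
        idx = np.searchsorted(self.sizes_mm, np.asarray(x, dtype=float),
                              side="right")
        padded = np.concatenate([[0.0], self.cumulative])
        return padded[idx]


@dataclass
class X50Fit:
    """Fitted masticatory-performance statistic."""

    x50: float
    b: float
    rmse: float
    fallback: bool = False
    n_points: int = 0

    def curve(self, x) -> np.ndarray:
        return _rosin_rammler(np.asarray(x, dtype=float), self.x50, self.b)


@dataclass
class ChewingSample:
    """Weight accounting for one chewing trial of the standard test food."""

    initial_weight_g: float
    recovered_weight_g: float
    strokes: int = 15
    cube_edge_mm: float = 5.0
    cube_count: int = 17

    def __post_init__(self) -> None:
        if self.initial_weight_g <= 0 or self.recovered_weight_g <= 0:
            raise ValueError("weights must be positive")
        if self.recovered_weight_g > RECOVERY_MAX_RATIO * self.initial_weight_g:
            raise ValueError(
                f"recovered weight {self.recovered_weight_g} g exceeds "
                f"{RECOVERY_MAX_RATIO} x initial {self.initial_weight_g} g")


# ---------------------------------------------------------------------------
# operations


def segment_particles(image: ParticleImage,
                      min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
                      dark_on_light: bool = True) -> ParticleSet:
    """Global Otsu threshold + 8-connected components, small specks removed.

    Touching particles merge into one component: the protocol assumes the
    particles were physically separated on the scanner bed, so no watershed
    splitting is attempted.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    px = image.pixels
    if px.max() == px.min():
        warnings.warn("image has no contrast; returning empty particle set")
        return ParticleSet(np.empty(0), np.empty((0, 2)))
    thr = threshold_otsu(px)
    # skimage convention: foreground = px > thr; dark foreground mirrors it
    mask = px <= thr if dark_on_light else px > thr
    lab = label(mask, connectivity=2)
    areas, cents = [], []
    min_area_px = min_area_mm2 * image.ppmm ** 2
    for region in regionprops(lab):
        if region.area < min_area_px:
            continue
        areas.append(region.area / image.ppmm ** 2)
        cents.append((region.centroid[1] / image.ppmm,
                      region.centroid[0] / image.ppmm))
    if not areas:
        warnings.warn("no particles above the minimum-area threshold")
        return ParticleSet(np.empty(0), np.empty((0, 2)))
    return ParticleSet(np.asarray(areas), np.asarray(cents))


def build_size_distribution(particles: ParticleSet,
                            weighting: str = "volume_proxy") -> SizeDistribution:
    """Cumulative fraction passing, weighted by d^3 (default) or by area."""
    if len(particles) == 0:
        raise SievingContentError("cannot build a distribution from zero particles")
    d = particles.diameters_mm
    if weighting == "volume_proxy":
        w = d ** 3
    elif weighting == "area":
        w = particles.areas_mm2
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    order = np.argsort(d)
    d, w = d[order], w[order]
    sizes, start = np.unique(d, return_index=True)
    cum = np.cumsum(w)
    # cumulative at each distinct size = weight of all particles <= size
    ends = np.concatenate([start[1:], [len(d)]]) - 1
    return SizeDistribution(sizes_mm=sizes, cumulative=cum[ends] / cum[-1],
                            basis=weighting)


def _rosin_rammler(x, x50, b):
    return 1.0 - np.power(2.0, -np.power(np.maximum(x, 0.0) / x50, b))


def fit_x50(dist: SizeDistribution, min_classes: int = 3) -> X50Fit:
    """Least-squares Rosin–Rammler fit of the cumulative curve.

    With fewer than ``min_classes`` distinct sizes, or when the optimizer
    fails, the empirical 50%-passing size is returned with the fallback
    flag set (b is then undefined).
    """
    x, q = dist.sizes_mm, dist.cumulative
    if len(x) < min_classes:
        return _fallback_fit(dist)
    x50_0 = _empirical_x50(dist)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_rosin_rammler, x, q, p0=(x50_0, 1.5),
                                bounds=((1e-9, 0.05), (np.inf, 100.0)),
                                maxfev=10000)
    except (RuntimeError, ValueError):
        return _fallback_fit(dist)
    x50, b = float(popt[0]), float(popt[1])
    resid = _rosin_rammler(x, x50, b) - q
    return X50Fit(x50=x50, b=b, rmse=float(np.sqrt(np.mean(resid ** 2))),
                  fallback=False, n_points=len(x))


def _empirical_x50(dist: SizeDistribution) -> float:
    """Size at which the cumulative curve crosses one half (interpolated)."""
    return float(np.interp(0.5, dist.cumulative, dist.sizes_mm))


def _fallback_fit(dist: SizeDistribution) -> X50Fit:
    x50 = _empirical_x50(dist)
    return X50Fit(x50=x50, b=float("nan"), rmse=float("nan"), fallback=True,
                  n_points=len(dist.sizes_mm))


def recovery_ratio(sample: ChewingSample,
                   qc_threshold: float = DEFAULT_RECOVERY_QC_THRESHOLD,
                   ) -> tuple[float, bool]:
    """Recovered / initial weight and whether it falls below the QC gate.

    The ratio is quality control only; lost material is never imputed into
    the size distribution and the ratio never alters X50.
    """
    ratio = sample.recovered_weight_g / sample.initial_weight_g
    flagged = ratio < qc_threshold
    if flagged:
        log.warning("low sample recovery: %.3f < %.2f", ratio, qc_threshold)
    return ratio, flagged


def x50_from_image(image: ParticleImage, sample: ChewingSample | None = None,
                   min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
                   weighting: str = "volume_proxy",
                   dark_on_light: bool = True) -> tuple[X50Fit, dict]:
    """Full pipeline scan -> segmentation -> distribution -> X50 plus QC."""
    particles = segment_particles(image, min_area_mm2=min_area_mm2,
                                  dark_on_light=dark_on_light)
    if len(particles) == 0:
        raise SievingContentError("no particles found in image")
    dist = build_size_distribution(particles, weighting=weighting)
    fit = fit_x50(dist)
    qc = {
        "n_particles": len(particles),
        "fallback": fit.fallback,
        "rmse": fit.rmse,
        "recovery_ratio": None,
        "recovery_flagged": False,
    }
    if sample is not None:
        ratio, flagged = recovery_ratio(sample)
        qc["recovery_ratio"] = ratio
        qc["recovery_flagged"] = flagged
    return fit, qc


def select_analysis_trial(trials: list):
    """Pick the trial that enters analysis: the second when two are given.

    The first trial lets the subject get accustomed to the test food; only
    the repeat reflects natural, unforced chewing. With a single trial that
    trial is used.
    """
    if not trials:
        raise ValueError("no trials supplied")
    return trials[1] if len(trials) >= 2 else trials[0]
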