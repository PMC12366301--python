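"""Droplet localization in brightfield images and monodispersity statistics.

Droplets appear as dark circular rims; they are located with a circular
Hough transform over a Canny edge map, using the same Gaussian-blur/Canny
operators as the biomass-quantification stage.  Detected circles touching
the image border are flagged rather than measured, because area fractions on
clipped circles are biased; overlapping detections are resolved by
non-maximum suppression on the Hough accumulator score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .errors import FormatError, InsufficientDataError
from .synthetic import DEFAULT_DIAMETER, DEFAULT_PIXEL_SIZE

__all__ = [
    "DetectionConfig",
    "DropletROI",
    "MonodispersityStats",
    "detect_droplets",
    "monodispersity_stats",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Tunables for circular Hough droplet detection.

    ``radius_range`` is inclusive, in pixels; the default spans the expected
    55 µm droplet at 0.5 µm/px ± 25%.  ``sensitivity`` is the minimum
    normalized Hough accumulator score (fraction of the circle's perimeter
    supported by edge pixels) for a detection.  ``max_overlap`` caps the
    allowed intersection between two kept circles as a fraction of the
    smaller circle's area.
    """

    radius_range: tuple[int, int] = (
        int(round(DEFAULT_DIAMETER / DEFAULT_PIXEL_SIZE / 2 * 0.75)),
        int(round(DEFAULT_DIAMETER / DEFAULT_PIXEL_SIZE / 2 * 1.25)),
    )
    sensitivity: float = 0.35
    blur_sigma: float = 1.5
    max_overlap: float = 0.10
    border_policy: str = "exclude"  # 'exclude' flags border-touching droplets

    def __post_init__(self) -> None:
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"radius_range must satisfy 0 < min <= max, got {self.radius_range}")
        if not 0.0 < self.sensitivity <= 1.0:
            raise ValueError(f"sensitivity must be in (0, 1], got {self.sensitivity}")
        if self.border_policy not in ("exclude",):
            raise ValueError(f"unknown border_policy {self.border_policy!r}")


@dataclass(frozen=True)
class DropletROI:
    """One detected (or ground-truth-derived) droplet region of interest."""

    id: int
    center: tuple[float, float]  # (row, col) pixels
    radius: float  # pixels
    image_id: str | None = None
    excluded: str | None = None  # None, or reason: 'border' | 'size' | 'circularity'
    score: float = float("nan")  # normalized Hough accumulator value

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0 px, got {self.radius}")


@dataclass(frozen=True)
class MonodispersityStats:
    """Droplet-population size summary: n, mean/SD diameter (µm), CV."""

    n: int
    mean_diameter: float
    sd_diameter: float
    cv: float


def _normalize_image(image: np.ndarray) -> np.ndarray:
    """Scale an 8- or 16-bit (or float) grayscale image to [0, 1]."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise FormatError(
            f"expected a 2-D grayscale image, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        return arr / 255.0
    if arr.dtype == np.uint16:
        return arr / 65535.0
    arr = arr.astype(float)
    if arr.max() > 1.0:  # integer-like content in a float container
        return arr / arr.max()
    return arr


def _circle_overlap_fraction(
    c1: tuple[float, float], r1: float, c2: tuple[float, float], r2: float
) -> float:
    """Intersection area of two circles as a fraction of the smaller one."""
    d = float(np.hypot(c1[0] - c2[0], c1[1] - c2[1]))
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return 1.0
    # lens area of two intersecting circles
    a1 = r1**2 * np.arccos((d**2 + r1**2 - r2**2) / (2 * d * r1))
    a2 = r2**2 * np.arccos((d**2 + r2**2 - r1**2) / (2 * d * r2))
    a3 = 0.5 * np.sqrt(
        (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    )
    inter = a1 + a2 - a3
    return float(inter / (np.pi * min(r1, r2) ** 2))


def _refine_radius(
    norm: np.ndarray, center: tuple[float, float], radius: float
) -> float:
    """Sub-pixel radius from the minimum of the radial intensity profile.

    The Hough estimate can lock onto the inner or outer edge of the dark
    rim; the rim centerline is the minimum of the mean intensity as a
    function of distance from the center.  A parabolic fit around the
    minimum bin gives sub-pixel precision.
    """
    h, w = norm.shape
    cy, cx = center
    lo = max(1.0, 0.85 * radius)
    hi = min(1.15 * radius, cy, cx, h - 1 - cy, w - 1 - cx)
    if hi <= lo + 2:
        return radius
    r0, r1 = int(cy - hi), int(cy + hi) + 1
    c0, c1 = int(cx - hi), int(cx + hi) + 1
    yy, xx = np.mgrid[max(0, r0):min(h, r1), max(0, c0):min(w, c1)]
    dist = np.hypot(yy - cy, xx - cx)
    sel = (dist >= lo) & (dist <= hi)
    bins = np.round(dist[sel] - lo).astype(int)
    prof = np.bincount(bins, weights=norm[yy[sel], xx[sel]]) / np.maximum(
        np.bincount(bins), 1
    )
    if prof.size < 3:
        return radius
    k = int(np.argmin(prof[1:-1])) + 1
    denom = prof[k - 1] - 2 * prof[k] + prof[k + 1]
    frac = 0.5 * (prof[k - 1] - prof[k + 1]) / denom if denom > 0 else 0.0
    return float(lo + k + np.clip(frac, -0.5, 0.5))


def detect_droplets(
    image: np.ndarray,
    config: DetectionConfig = DetectionConfig(),
    image_id: str | None = None,
) -> list[DropletROI]:
    """Locate circular droplets; border-touching circles are flagged.

    Pipeline: normalize → Gaussian-blurred Canny edge map → circular Hough
    over ``radius_range`` → accumulator peaks above ``sensitivity`` →
    overlap suppression (keep the higher score; ties broken by smaller row,
    then smaller col).  Returns ROIs sorted by id; excluded ROIs carry the
    exclusion reason.
    """
    norm = _normalize_image(image)
    edges = canny(norm, sigma=config.blur_sigma)
    lo, hi = config.radius_range
    radii = np.arange(lo, hi + 1)
    accum = hough_circle(edges, radii)
    n_cand = max(1, int(norm.size / (np.pi * lo**2)))  # generous upper bound
    scores, cols, rows, rads = hough_circle_peaks(
        accum,
        radii,
        min_xdistance=lo,
        min_ydistance=lo,
        threshold=config.sensitivity,
        total_num_peaks=n_cand,
        normalize=False,  # accumulators are already perimeter-normalized
    )
    # sort: best score first; ties -> smaller row, then smaller col
    order = np.lexsort((cols, rows, -scores))
    kept: list[tuple[tuple[float, float], float, float]] = []
    rois: list[DropletROI] = []
    h, w = norm.shape
    for idx in order:
        center = (float(rows[idx]), float(cols[idx]))
        radius = float(rads[idx])
        score = float(scores[idx])
        if any(
            _circle_overlap_fraction(center, radius, c, r) > config.max_overlap
            for c, r, _ in kept
        ):
            continue
        kept.append((center, radius, score))
        radius = _refine_radius(norm, center, radius)
        excluded = None
        if (
            center[0] - radius < 0
            or center[1] - radius < 0
            or center[0] + radius > h - 1
            or center[1] + radius > w - 1
        ):
            excluded = "border"
        rois.append(
            DropletROI(
                id=0,  # reassigned after sorting
                center=center,
                radius=radius,
                image_id=image_id,
                excluded=excluded,
                score=score,
            )
        )
    rois.sort(key=lambda r: (r.center[0], r.center[1]))
    return [
        DropletROI(
            id=i,
            center=r.center,
            radius=r.radius,
            image_id=r.image_id,
            excluded=r.excluded,
            score=r.score,
        )
        for i, r in enumerate(rois)
    ]


def monodispersity_stats(
    rois: list[DropletROI], pixel_size: float
) -> MonodispersityStats:
    """Mean, sample SD (n−1) and CV of non-excluded droplet diameters (µm)."""
    diam = np.array(
        [2.0 * r.radius * pixel_size for r in rois if r.excluded is None]
    )
    if diam.size < 2:
        raise InsufficientDataError(
            f"need >= 2 non-excluded droplets for monodispersity, got {diam.size}"
        )
    mean = float(diam.mean())
    sd = float(diam.std(ddof=1))
    return MonodispersityStats(
        n=int(diam.size), mean_diameter=mean, sd_diameter=sd, cv=sd / mean
    )
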