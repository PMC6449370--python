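"""AFM morphometry of single amyloid aggregates.

Raw height maps are flattened scanline-by-scanline, particles are segmented
above a noise-derived threshold, and each particle is measured for its peak
height, apparent full width at half maximum, major-axis length and aspect
ratio.  Because the probe apex (radius R ~ 10 nm) is comparable to or larger
than the aggregates (lateral size 0.3-10 nm), apparent widths are broadened by
tip convolution; the deconvolution here inverts the spherical-tip /
spherical-cap contact model:

    the dilation of a convex spherical cap (true cap radius Rs, height h) by a
    spherical tip of radius R is again a spherical cap of radius Rs + R, so a
    width measured at any height t on the apparent profile determines Rs + R
    exactly, and the true base diameter follows as 2 * sqrt(2 Rs h - h^2).

Species are classified by cross-sectional height and morphology: monomers
(0.3-0.5 nm tall), spherical oligomers (0.5-2 nm), protofilaments (0.4-1 nm
tall, elongated, length >~ 100 nm) and higher-order aggregates (> 2 nm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as skmeasure

DIAMETER_FLOOR_NM = 0.1

CLASS_MONOMER = "monomer"
CLASS_OLIGOMER = "oligomer"
CLASS_PROTOFILAMENT = "protofilament"
CLASS_HIGHER_ORDER = "higher_order"
CLASS_UNCLASSIFIED = "unclassified"


@dataclass
class HeightMap:
    """A rows x cols topography in nm with its lateral sampling."""

    heights: np.ndarray
    pixel_size_nm: float
    flattened: bool = False

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D array")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")


@dataclass
class TipModel:
    """Spherical apex model of the probe."""

    tip_radius_nm: float = 10.0

    def __post_init__(self) -> None:
        if self.tip_radius_nm <= 0:
            raise ValueError("tip radius must be positive")


@dataclass
class Particle:
    id: int
    max_height_nm: float
    fwhm_width_nm: float
    length_nm: float
    aspect_ratio: float
    deconvolved_diameter_nm: float = float("nan")
    deconvolution_valid: bool = True
    particle_class: str = CLASS_UNCLASSIFIED
    touches_border: bool = False
    area_px: int = 0
    centroid_row: float = 0.0
    centroid_col: float = 0.0


@dataclass
class FractionSummary:
    label: str
    n_particles: int
    class_counts: dict = dc_field(default_factory=dict)
    height_quartiles: tuple[float, float, float] = (float("nan"),) * 3
    height_whiskers: tuple[float, float] = (float("nan"),) * 2
    diameter_quartiles: tuple[float, float, float] = (float("nan"),) * 3
    diameter_whiskers: tuple[float, float] = (float("nan"),) * 2


def flatten_height_map(
    hmap: HeightMap,
    order: int = 1,
    clip_sigma: float = 3.0,
    max_iter: int = 5,
) -> HeightMap:
    """Subtract a per-scanline background polynomial (default: a line).

    Each row is fitted to its background pixels only: pixels deviating by more
    than ``clip_sigma`` residual standard deviations (particles) are excluded
    iteratively before the final fit is subtracted, and the global background
    median is removed so the substrate sits at zero.  Orders above 3 are
    rejected as an over-fitting guard.  Idempotent on already-flat maps.
    """
    if order > 3:
        raise ValueError("flattening order above 3 is not allowed")
    if order < 0:
        raise ValueError("flattening order must be >= 0")
    raw = hmap.heights
    nrows, ncols = raw.shape
    x = np.arange(ncols, dtype=float)
    particle = np.zeros_like(raw, dtype=bool)
    flat = raw.copy()
    for _ in range(max_iter):
        for i in range(nrows):
            keep = ~particle[i]
            if keep.sum() < max(order + 2, 8):
                keep = np.ones(ncols, dtype=bool)
            coeffs = np.polyfit(x[keep], raw[i, keep], order)
            flat[i] = raw[i] - np.polyval(coeffs, x)
        # Robust residual scale; particles protrude upward, so mask one-sided.
        med = np.median(flat)
        sd = 1.4826 * np.median(np.abs(flat - med))
        # Noiseless maps: most residuals are exactly zero; fall back to a tiny
        # scale so features still get masked out of the background fit.
        sd = max(sd, 1e-9 * max(float(np.max(np.abs(flat))), 1e-9))
        new_particle = flat > med + clip_sigma * sd
        if np.array_equal(new_particle, particle):
            break
        particle = new_particle
    flat -= np.median(flat[~particle]) if (~particle).any() else np.median(flat)
    return HeightMap(heights=flat, pixel_size_nm=hmap.pixel_size_nm, flattened=True)


def estimate_noise(hmap: HeightMap, clip_sigma: float = 3.0, max_iter: int = 10) -> float:
    """RMS roughness of the background (particle-free) pixels of a flat map.

    Pixels are iteratively sigma-clipped about the median so that particles do
    not inflate the estimate.
    """
    z = hmap.heights.ravel()
    keep = np.ones(z.size, dtype=bool)
    for _ in range(max_iter):
        med = np.median(z[keep])
        sd = 1.4826 * np.median(np.abs(z[keep] - med))
        if sd == 0:
            return 0.0
        # One-sided clip: particles only ever protrude upward.
        new_keep = z <= med + clip_sigma * sd
        if np.array_equal(new_keep, keep) or new_keep.sum() == 0:
            break
        keep = new_keep
    background = z[keep]
    return float(np.sqrt(np.mean((background - np.median(background)) ** 2)))


def segment_particles(
    hmap: HeightMap,
    noise_nm: float,
    k: float = 3.0,
    min_area_px: int = 4,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Label connected regions (8-connectivity) above ``k * noise``.

    Returns the label image and a table flagging border-touching regions and
    dropping those smaller than ``min_area_px``.  A zero threshold (noiseless
    map with k = 0) is rejected as degenerate.
    """
    threshold = k * noise_nm
    if threshold <= 0:
        raise ValueError("degenerate threshold: noise and k must both be positive")
    mask = hmap.heights > threshold
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    nrows, ncols = labels.shape
    rows = []
    for region in skmeasure.regionprops(labels):
        if region.area < min_area_px:
            labels[labels == region.label] = 0
            continue
        r0, c0, r1, c1 = region.bbox
        rows.append(
            {
                "label": region.label,
                "area_px": int(region.area),
                "touches_border": bool(r0 == 0 or c0 == 0 or r1 == nrows or c1 == ncols),
            }
        )
    table = pd.DataFrame(rows, columns=["label", "area_px", "touches_border"])
    return labels, table


def _profile_width_at_height(
    work: np.ndarray,
    peak_rc: tuple[float, float],
    direction: tuple[float, float],
    target: float,
    pixel_size_nm: float,
    max_extent_px: float,
    n_parallel: int = 1,
    parallel_spacing_px: float = 1.0,
) -> float:
    """Width (nm) of the profile through ``peak_rc`` along ``direction`` at
    level ``target``, by linear interpolation of the first crossing on each
    side of the peak.  Optionally averages a few parallel profiles (offset
    along the orthogonal direction) to suppress pixel noise."""
    dr, dc = direction
    norm = math.hypot(dr, dc)
    dr, dc = dr / norm, dc / norm
    pr, pc = -dc, dr  # orthogonal (along the particle's major axis)
    steps = np.arange(-max_extent_px, max_extent_px + 0.25, 0.25)
    offsets = (np.arange(n_parallel) - (n_parallel - 1) / 2.0) * parallel_spacing_px
    profiles = []
    for off in offsets:
        rows = peak_rc[0] + off * pr + steps * dr
        cols = peak_rc[1] + off * pc + steps * dc
        profiles.append(
            ndimage.map_coordinates(work, np.vstack([rows, cols]), order=1, mode="nearest")
        )
    profile = np.mean(profiles, axis=0)
    center = len(steps) // 2

    def crossing(idx_range) -> float | None:
        prev = None
        for j in idx_range:
            if profile[j] <= target:
                if prev is None:
                    return None
                frac = (profile[prev] - target) / (profile[prev] - profile[j])
                return steps[prev] + frac * (steps[j] - steps[prev])
            prev = j
        return None

    right = crossing(range(center, len(steps)))
    left = crossing(range(center, -1, -1))
    if right is None or left is None:
        return float("nan")
    return float(abs(right - left) * pixel_size_nm)


def measure_particle(
    labels: np.ndarray,
    label_id: int,
    hmap: HeightMap,
    noise_nm: float = 0.0,
    smooth_sigma_nm: float = 0.5,
    measure_frac: float = 0.5,
) -> Particle:
    """Measure one segmented particle: peak height, FWHM, length, aspect ratio.

    The peak height is read from a lightly Gaussian-smoothed map when the map
    is noisy (the smoothing scale is specified in nm so its bias is grid
    independent); on noiseless maps the raw flattened map is used.  The width
    is the full width at ``measure_frac`` of the peak height, measured on the
    1-D profile through the peak perpendicular to the region's major axis with
    sub-pixel linear interpolation.  Length is the extent along the major axis.
    """
    mask = labels == label_id
    if not np.any(mask):
        raise ValueError(f"label {label_id} not present")
    px = hmap.pixel_size_nm
    noisy = noise_nm > 0.01
    if noisy and smooth_sigma_nm > 0:
        work = ndimage.gaussian_filter(hmap.heights, smooth_sigma_nm / px)
    else:
        work = hmap.heights

    region = skmeasure.regionprops(mask.astype(int))[0]
    inside = np.where(mask, work, -np.inf)
    peak_flat = int(np.argmax(inside))
    peak_r, peak_c = np.unravel_index(peak_flat, mask.shape)
    max_height = float(work[peak_r, peak_c])

    # Major axis from the principal component of the region's pixel coordinates.
    coords = region.coords.astype(float)
    rel = coords - coords.mean(axis=0)
    if len(rel) > 1:
        _, evecs = np.linalg.eigh(np.cov(rel.T))
        major_dir = (float(evecs[0, -1]), float(evecs[1, -1]))  # largest eigenvalue
    else:
        major_dir = (0.0, 1.0)
    minor_dir = (major_dir[1], -major_dir[0])
    proj_major = rel @ np.array(major_dir)
    proj_minor = rel @ np.array(minor_dir)
    length_px = proj_major.max() - proj_major.min() + 1.0
    width_px = proj_minor.max() - proj_minor.min() + 1.0
    length_nm = float(length_px * px)
    aspect = float(length_px / max(width_px, 1.0))

    nrows, ncols = mask.shape
    fwhm = _profile_width_at_height(
        work,
        (float(peak_r), float(peak_c)),
        minor_dir,
        measure_frac * max_height,
        px,
        max_extent_px=float(max(nrows, ncols)),
        n_parallel=3 if noisy else 1,
    )
    nrows, ncols = labels.shape
    r0, c0, r1, c1 = region.bbox
    return Particle(
        id=int(label_id),
        max_height_nm=max_height,
        fwhm_width_nm=fwhm,
        length_nm=length_nm,
        aspect_ratio=max(aspect, 1.0),
        touches_border=bool(r0 == 0 or c0 == 0 or r1 == nrows or c1 == ncols),
        area_px=int(region.area),
        centroid_row=float(region.centroid[0]),
        centroid_col=float(region.centroid[1]),
    )


def deconvolve_diameter(
    fwhm_width_nm: float,
    max_height_nm: float,
    tip: TipModel,
    measure_frac: float = 0.5,
) -> tuple[float, bool]:
    """True base diameter of a spherical-cap particle from its apparent width.

    The apparent profile of a convex cap dilated by a spherical tip of radius
    ``R`` is a cap of radius ``Rs + R``; a width ``w`` measured at height
    ``measure_frac * h`` therefore gives

        Rs + R = ((w/2)^2 + (h - t)^2) / (2 (h - t)),   t = measure_frac * h,
        d_true = 2 * sqrt(2 Rs h - h^2).

    The correction vanishes as ``R -> 0`` (the apparent cap is the true cap).
    Outside the model's validity (``h >= 2R``, the tip no longer envelopes the
    feature) the measured width is returned with a ``False`` validity flag;
    degenerate inversions are floored at 0.1 nm.
    """
    r_tip = tip.tip_radius_nm
    h = max_height_nm
    w = fwhm_width_nm
    if not np.isfinite(w) or not np.isfinite(h) or h <= 0 or w <= 0:
        return float("nan"), False
    if h >= 2.0 * r_tip:
        return w, False
    t_prime = h * (1.0 - measure_frac)
    if t_prime <= 0:
        return float("nan"), False
    rs_apparent = ((w / 2.0) ** 2 + t_prime**2) / (2.0 * t_prime)
    rs_true = rs_apparent - r_tip
    d_sq = 4.0 * (2.0 * rs_true * h - h**2)
    if d_sq <= DIAMETER_FLOOR_NM**2:
        return DIAMETER_FLOOR_NM, True
    return float(math.sqrt(d_sq)), True


def classify_particle(
    max_height_nm: float,
    aspect_ratio: float,
    length_nm: float,
) -> str:
    """Assign a species class from cross-sectional height and morphology.

    Shape takes precedence over the (overlapping) height bands: an elongated
    region (aspect >= 3, length >= 100 nm) of protofilament height (0.4-1 nm)
    is a protofilament regardless of the monomer/oligomer height bands.
    """
    h = max_height_nm
    if aspect_ratio >= 3.0 and length_nm >= 100.0 and 0.4 <= h <= 1.0:
        return CLASS_PROTOFILAMENT
    if 0.3 <= h < 0.5:
        return CLASS_MONOMER
    if 0.5 <= h <= 2.0:
        return CLASS_OLIGOMER
    if h > 2.0:
        return CLASS_HIGHER_ORDER
    return CLASS_UNCLASSIFIED


def analyze_height_map(
    hmap: HeightMap,
    tip: TipModel | None = None,
    flatten_order: int = 1,
    k: float = 3.0,
    min_area_px: int = 4,
    exclude_border: bool = True,
    smooth_sigma_nm: float = 0.5,
    already_flat: bool = False,
) -> pd.DataFrame:
    """Full per-map pipeline: flatten, segment, measure, deconvolve, classify."""
    tip = tip or TipModel()
    flat = hmap if (already_flat or hmap.flattened) else flatten_height_map(hmap, flatten_order)
    noise = estimate_noise(flat)
    labels, table = segment_particles(flat, max(noise, 1e-6), k=k, min_area_px=min_area_px)
    rows = []
    for label_id in table["label"]:
        p = measure_particle(labels, int(label_id), flat, noise, smooth_sigma_nm)
        if exclude_border and p.touches_border:
            continue
        d, ok = deconvolve_diameter(p.fwhm_width_nm, p.max_height_nm, tip)
        p.deconvolved_diameter_nm = d
        p.deconvolution_valid = ok
        p.particle_class = classify_particle(p.max_height_nm, p.aspect_ratio, p.length_nm)
        rows.append(
            {
                "particle_id": p.id,
                "max_height_nm": p.max_height_nm,
                "fwhm_width_nm": p.fwhm_width_nm,
                "deconvolved_diameter_nm": p.deconvolved_diameter_nm,
                "deconvolution_valid": p.deconvolution_valid,
                "length_nm": p.length_nm,
                "aspect_ratio": p.aspect_ratio,
                "class": p.particle_class,
                "area_px": p.area_px,
                "centroid_row": p.centroid_row,
                "centroid_col": p.centroid_col,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "particle_id", "max_height_nm", "fwhm_width_nm", "deconvolved_diameter_nm",
            "deconvolution_valid", "length_nm", "aspect_ratio", "class", "area_px",
            "centroid_row", "centroid_col",
        ],
    )


def _box_stats(values: np.ndarray) -> tuple[tuple[float, float, float], tuple[float, float]]:
    q1, med, q3 = (float(v) for v in np.percentile(values, [25, 50, 75]))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return (q1, med, q3), (float(inside.min()), float(inside.max()))


def summarize_fraction(particles: pd.DataFrame, label: str) -> FractionSummary:
    """Box-chart statistics (median, quartiles, 1.5 IQR whiskers) per fraction."""
    if len(particles) == 0:
        raise ValueError("cannot summarize an empty particle list")
    heights = particles["max_height_nm"].to_numpy(dtype=float)
    diameters = particles["deconvolved_diameter_nm"].to_numpy(dtype=float)
    diameters = diameters[np.isfinite(diameters)]
    hq, hw = _box_stats(heights)
    if diameters.size:
        dq, dw = _box_stats(diameters)
    else:
        dq, dw = (float("nan"),) * 3, (float("nan"),) * 2
    counts = particles["class"].value_counts().to_dict()
    return FractionSummary(
        label=label,
        n_particles=int(len(particles)),
        class_counts=counts,
        height_quartiles=hq,
        height_whiskers=hw,
        diameter_quartiles=dq,
        diameter_whiskers=dw,
    )
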