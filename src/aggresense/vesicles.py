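"""Single-vesicle Ca2+-influx quantification from three-phase TIRF stacks.

The assay images the same field of surface-tethered, dye-loaded lipid vesicles in
three phases: a background phase (``F_background``), after adding the aggregate
sample (``F_sample``) and after saturating every vesicle with the Ca2+ ionophore
ionomycin (``F_ionomycin``).  The per-vesicle relative influx is

    influx = (F_sample - F_background) / (F_ionomycin - F_background)

which is 0 for an intact vesicle and 1 for a fully permeabilized one.  Values
outside [0, 1] are retained and flagged rather than clamped, so that condition
means stay unbiased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import difference_of_gaussians
from skimage.registration import phase_cross_correlation

from . import stats as drstats

PHASES = ("background", "sample", "ionomycin")


@dataclass
class FrameStack:
    """A time x rows x cols stack for one acquisition phase of one field."""

    data: np.ndarray  # (frames, rows, cols), arbitrary fluorescence units
    pixel_size_nm: float = 100.0
    exposure_ms: float = 50.0
    phase: str = "background"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("FrameStack needs a (frames, rows, cols) array with >=1 frame")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("FrameStack contains non-finite values")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")

    @property
    def mean_image(self) -> np.ndarray:
        return self.data.mean(axis=0)


@dataclass
class VesicleROI:
    """Fixed-radius circular region of interest around one vesicle."""

    id: int
    row: float
    col: float
    radius: float = 3.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")


@dataclass
class DetectionParams:
    """Parameters of the band-pass + local-maxima vesicle detector."""

    psf_sigma: float = 1.3          # px; low sigma of the difference of Gaussians
    roi_radius: float = 3.0         # px
    min_separation: float | None = None  # px; default 2 * roi_radius
    threshold_factor: float = 5.0   # detection threshold in units of band-passed noise
    saturation_level: float | None = None


@dataclass
class PhaseIntensity:
    """Background-annulus-subtracted spot intensity of one vesicle per phase."""

    vesicle_id: int
    f_background: float
    f_sample: float
    f_ionomycin: float
    qc_geometry: bool = True  # False when the ROI (annulus included) left the field


@dataclass
class InfluxRecord:
    vesicle_id: int
    influx: float  # NaN when the denominator is degenerate
    qc_pass: bool
    qc_reason: str = ""


@dataclass
class FieldSummary:
    field_id: str
    condition: str
    n_vesicles: int
    mean_influx: float
    sd_influx: float
    is_empty: bool = False


def detect_vesicles(stack: FrameStack, params: DetectionParams | None = None) -> list[VesicleROI]:
    """Detect diffraction-limited vesicle spots on the background phase.

    The temporal mean image is band-pass filtered (difference of Gaussians at
    ``psf_sigma`` and ``2 * psf_sigma``) and local maxima above
    ``threshold_factor`` times the robust noise of the filtered image are kept,
    no two closer than the minimum separation.  Centroids are refined by a local
    centre of mass.  An empty image yields an empty list.
    """
    params = params or DetectionParams()
    mean_img = stack.mean_image
    if params.saturation_level is not None and np.any(stack.data >= params.saturation_level):
        raise ValueError("stack contains saturated pixels")
    band = difference_of_gaussians(mean_img, params.psf_sigma, 2.0 * params.psf_sigma)
    # Robust noise of the band-passed image via the median absolute deviation.
    mad = np.median(np.abs(band - np.median(band)))
    noise = 1.4826 * mad
    threshold = params.threshold_factor * noise
    if threshold <= 0:  # noiseless image: any strictly positive response is real
        threshold = 1e-9 * max(band.max(), 1.0)
    min_sep = params.min_separation
    if min_sep is None:
        min_sep = 2.0 * params.roi_radius
    peaks = peak_local_max(
        band,
        min_distance=max(int(round(min_sep)), 1),
        threshold_abs=threshold,
        exclude_border=int(math.ceil(params.roi_radius)),
    )
    rois: list[VesicleROI] = []
    half = max(int(round(params.roi_radius)), 1)
    for i, (pr, pc) in enumerate(peaks):
        r0, r1 = pr - half, pr + half + 1
        c0, c1 = pc - half, pc + half + 1
        patch = mean_img[max(r0, 0):r1, max(c0, 0):c1]
        w = patch - patch.min()
        if w.sum() > 0:
            com = ndimage.center_of_mass(w)
            row = max(r0, 0) + com[0]
            col = max(c0, 0) + com[1]
        else:
            row, col = float(pr), float(pc)
        rois.append(VesicleROI(id=i, row=row, col=col, radius=params.roi_radius))
    return rois


def _disk_annulus_masks(radius: float, inner: float, outer: float) -> tuple[np.ndarray, np.ndarray, int]:
    half = int(math.ceil(outer))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    rr2 = yy**2 + xx**2
    disk = rr2 <= radius**2
    annulus = (rr2 >= inner**2) & (rr2 <= outer**2)
    return disk, annulus, half


def estimate_shift(reference: FrameStack, moving: FrameStack) -> tuple[float, float]:
    """Rigid (row, col) shift of ``moving`` relative to ``reference`` by
    phase cross-correlation of the temporal mean images."""
    shift, _, _ = phase_cross_correlation(
        reference.mean_image, moving.mean_image, upsample_factor=10
    )
    return float(shift[0]), float(shift[1])


def extract_phase_intensities(
    rois: Sequence[VesicleROI],
    stacks: dict[str, FrameStack],
    annulus_gap: float = 2.0,
    annulus_width: float = 3.0,
    correct_shift: bool = False,
) -> list[PhaseIntensity]:
    """Measure the three phase intensities of every ROI.

    For each phase, F is the mean over frames of (disk mean - local annulus
    median); the annulus subtraction removes the camera offset and the local
    background, so F is invariant to any additive constant.  The same ROI
    geometry is used in all three phases (the acquisition keeps the field
    registered); ``correct_shift=True`` additionally applies a rigid shift
    estimated against the background phase.  ROIs whose annulus leaves the
    field are flagged (``qc_geometry=False``).
    """
    for phase in PHASES:
        if phase not in stacks:
            raise ValueError(f"missing stack for phase '{phase}'")
    shifts = {phase: (0.0, 0.0) for phase in PHASES}
    if correct_shift:
        for phase in ("sample", "ionomycin"):
            shifts[phase] = estimate_shift(stacks["background"], stacks[phase])

    results: list[PhaseIntensity] = []
    for roi in rois:
        disk, annulus, half = _disk_annulus_masks(
            roi.radius, roi.radius + annulus_gap, roi.radius + annulus_gap + annulus_width
        )
        values = {}
        ok = True
        for phase in PHASES:
            stk = stacks[phase]
            dr, dc = shifts[phase]
            r = int(round(roi.row - dr))
            c = int(round(roi.col - dc))
            nrows, ncols = stk.data.shape[1:]
            if r - half < 0 or r + half >= nrows or c - half < 0 or c + half >= ncols:
                ok = False
                values[phase] = np.nan
                continue
            patch = stk.data[:, r - half:r + half + 1, c - half:c + half + 1]
            disk_means = patch[:, disk].mean(axis=1)
            ann_medians = np.median(patch[:, annulus], axis=1)
            values[phase] = float(np.mean(disk_means - ann_medians))
        results.append(
            PhaseIntensity(
                vesicle_id=roi.id,
                f_background=values["background"],
                f_sample=values["sample"],
                f_ionomycin=values["ionomycin"],
                qc_geometry=ok,
            )
        )
    return results


def compute_influx(
    pi: PhaseIntensity,
    noise_sd: float = 0.0,
    k_denominator: float = 3.0,
) -> InfluxRecord:
    """Apply the influx ratio to one vesicle's phase intensities.

    ``influx = (F_sample - F_background) / (F_ionomycin - F_background)``.

    QC fails when the denominator is below ``k_denominator * noise_sd`` (a
    dye-free or unresponsive vesicle: the ratio would be dominated by noise) or
    when the geometry flag is down.  The influx value is *not* clamped; values
    outside [0, 1] are reported as-is with a qc reason.
    """
    if not pi.qc_geometry:
        return InfluxRecord(pi.vesicle_id, float("nan"), False, "roi_outside_field")
    denom = pi.f_ionomycin - pi.f_background
    if denom == 0:
        return InfluxRecord(pi.vesicle_id, float("nan"), False, "zero_denominator")
    influx = (pi.f_sample - pi.f_background) / denom
    if denom < k_denominator * noise_sd:
        return InfluxRecord(pi.vesicle_id, influx, False, "weak_ionomycin_response")
    if not (0.0 <= influx <= 1.0):
        return InfluxRecord(pi.vesicle_id, influx, True, "outside_unit_interval")
    return InfluxRecord(pi.vesicle_id, influx, True, "")


def compute_influx_table(
    intensities: Sequence[PhaseIntensity],
    noise_sd: float = 0.0,
    k_denominator: float = 3.0,
) -> pd.DataFrame:
    records = [compute_influx(pi, noise_sd, k_denominator) for pi in intensities]
    return pd.DataFrame(
        {
            "vesicle_id": [r.vesicle_id for r in records],
            "influx": [r.influx for r in records],
            "qc_pass": [r.qc_pass for r in records],
            "qc_reason": [r.qc_reason for r in records],
        }
    )


def summarize_field(
    records: pd.DataFrame | Sequence[InfluxRecord],
    condition: str = "",
    field_id: str = "",
) -> FieldSummary:
    """Mean and sd of influx over the QC-passing vesicles of one field of view."""
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(
            {"influx": [r.influx for r in records], "qc_pass": [r.qc_pass for r in records]}
        )
    good = records.loc[records["qc_pass"], "influx"].to_numpy(dtype=float)
    if good.size == 0:
        return FieldSummary(field_id, condition, 0, float("nan"), float("nan"), is_empty=True)
    return FieldSummary(
        field_id,
        condition,
        int(good.size),
        float(np.mean(good)),
        float(np.std(good, ddof=1)) if good.size > 1 else 0.0,
    )


def compare_conditions(
    summaries_a: Sequence[FieldSummary],
    summaries_b: Sequence[FieldSummary],
    variant: str = "pooled",
) -> dict:
    """Ratio of condition means (A over B) with an unpaired t-test over field means.

    With fewer than two fields per condition only the ratio is returned and the
    test is marked unavailable.
    """
    means_a = np.array([s.mean_influx for s in summaries_a if not s.is_empty])
    means_b = np.array([s.mean_influx for s in summaries_b if not s.is_empty])
    if means_a.size == 0 or means_b.size == 0:
        raise ValueError("need at least one non-empty field summary per condition")
    mean_a, mean_b = float(means_a.mean()), float(means_b.mean())
    ratio = mean_a / mean_b if mean_b != 0 else float("inf")
    if mean_a == 0:
        ratio = 0.0
    out = {"mean_a": mean_a, "mean_b": mean_b, "ratio": ratio, "test": None}
    if means_a.size >= 2 and means_b.size >= 2:
        out["test"] = drstats.unpaired_t_test(means_a, means_b, variant=variant)
    return out
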