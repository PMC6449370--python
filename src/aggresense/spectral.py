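"""Spectrally resolved PAINT hydrophobicity mapping of single aggregates.

Transient Nile-red binding events yield a stream of localizations, each with an
emission-spectrum readout dispersed by a diffraction grating onto the camera.
A linear dispersion calibration maps spectral pixels to wavelength; each
localization is reduced to its intensity-weighted mean emission wavelength
(spectral centroid); localizations are grouped per aggregate by density-based
clustering; and each aggregate is summarized by the mean emission wavelength of
its members.  Because Nile red blueshifts in hydrophobic environments, a lower
mean emission wavelength reads as a more hydrophobic aggregate surface, and
group comparisons report the shift ``mean(B) - mean(A)`` (positive = group A
blueshifted, i.e. more hydrophobic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from . import stats as drstats


@dataclass
class DispersionCalibration:
    """Linear spectral-pixel -> wavelength mapping with its fit residual."""

    slope_nm_per_px: float
    intercept_nm: float
    residual_rms_nm: float

    def __post_init__(self) -> None:
        if self.slope_nm_per_px == 0:
            raise ValueError("dispersion slope must be non-zero")

    def wavelength(self, pixel: float | np.ndarray) -> float | np.ndarray:
        return self.intercept_nm + self.slope_nm_per_px * np.asarray(pixel, dtype=float)


@dataclass
class AggregateSpectralSummary:
    cluster_id: int
    centroid_x_nm: float
    centroid_y_nm: float
    n_localizations: int
    mean_emission_nm: float
    sd_emission_nm: float


def calibrate_dispersion(pairs: Sequence[tuple[float, float]]) -> DispersionCalibration:
    """Least-squares line through (spectral pixel, known wavelength) pairs.

    At least two pairs are required; the RMS residual is reported so a user can
    detect grating nonlinearity.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise ValueError("need at least two (pixel, wavelength) pairs")
    slope, intercept = np.polyfit(arr[:, 0], arr[:, 1], 1)
    resid = arr[:, 1] - (intercept + slope * arr[:, 0])
    return DispersionCalibration(
        slope_nm_per_px=float(slope),
        intercept_nm=float(intercept),
        residual_rms_nm=float(np.sqrt(np.mean(resid**2))),
    )


def spectral_centroid(
    spectrum: Sequence[float],
    cal: DispersionCalibration,
    background: float = 0.0,
) -> float:
    """Intensity-weighted mean emission wavelength of one dispersed spectrum.

    ``background`` (a per-pixel offset) is subtracted and negative residuals
    clipped before weighting; invariant under uniform intensity scaling.
    """
    intensity = np.asarray(spectrum, dtype=float) - background
    intensity = np.clip(intensity, 0.0, None)
    total = intensity.sum()
    if total <= 0:
        raise ValueError("spectrum has no positive intensity after background subtraction")
    wavelengths = cal.wavelength(np.arange(intensity.size))
    return float((wavelengths * intensity).sum() / total)


def cluster_localizations(
    locs: pd.DataFrame,
    radius_nm: float = 100.0,
    min_locs: int = 10,
    x_col: str = "x_nm",
    y_col: str = "y_nm",
) -> pd.DataFrame:
    """Group localizations into per-aggregate clusters (DBSCAN).

    Localizations within ``radius_nm`` of a core point join a cluster; clusters
    with fewer than ``min_locs`` members are discarded (labelled -1 together
    with the background noise).  Cluster ids are relabelled in spatial order
    (mean y, then x) so the output is independent of input row order.
    """
    if radius_nm <= 0:
        raise ValueError("radius_nm must be positive")
    out = locs.copy()
    if len(out) == 0:
        out["cluster_id"] = pd.Series(dtype=int)
        return out
    xy = out[[x_col, y_col]].to_numpy(dtype=float)
    labels = DBSCAN(eps=radius_nm, min_samples=3).fit_predict(xy)
    out["cluster_id"] = labels
    sizes = out.groupby("cluster_id")["cluster_id"].transform("size")
    out.loc[(out["cluster_id"] >= 0) & (sizes < min_locs), "cluster_id"] = -1
    # Deterministic relabelling by cluster centroid position.
    kept = out[out["cluster_id"] >= 0]
    if len(kept):
        centroids = kept.groupby("cluster_id")[[y_col, x_col]].mean()
        order = centroids.sort_values([y_col, x_col]).index
        mapping = {old: new for new, old in enumerate(order)}
        out["cluster_id"] = out["cluster_id"].map(lambda c: mapping.get(c, -1))
    return out


def summarize_aggregate(
    cluster: pd.DataFrame,
    cluster_id: int | None = None,
    centroid_col: str = "spectral_centroid_nm",
    x_col: str = "x_nm",
    y_col: str = "y_nm",
    min_locs: int = 10,
) -> AggregateSpectralSummary:
    """Mean emission wavelength (and dispersion) of one aggregate's members."""
    if len(cluster) < min_locs:
        raise ValueError(f"cluster has fewer than min_locs={min_locs} localizations")
    vals = cluster[centroid_col].to_numpy(dtype=float)
    if cluster_id is None:
        cluster_id = int(cluster["cluster_id"].iloc[0]) if "cluster_id" in cluster else -1
    return AggregateSpectralSummary(
        cluster_id=int(cluster_id),
        centroid_x_nm=float(cluster[x_col].mean()),
        centroid_y_nm=float(cluster[y_col].mean()),
        n_localizations=int(len(cluster)),
        mean_emission_nm=float(vals.mean()),
        sd_emission_nm=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
    )


def summarize_aggregates(
    clustered: pd.DataFrame,
    min_locs: int = 10,
    centroid_col: str = "spectral_centroid_nm",
) -> pd.DataFrame:
    """Per-aggregate summary table over all clusters (id >= 0)."""
    rows = []
    for cid, grp in clustered[clustered["cluster_id"] >= 0].groupby("cluster_id"):
        if len(grp) < min_locs:
            continue
        s = summarize_aggregate(grp, int(cid), centroid_col=centroid_col, min_locs=min_locs)
        rows.append(
            {
                "cluster_id": s.cluster_id,
                "x_nm": s.centroid_x_nm,
                "y_nm": s.centroid_y_nm,
                "n_localizations": s.n_localizations,
                "mean_emission_nm": s.mean_emission_nm,
                "sd_emission_nm": s.sd_emission_nm,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "x_nm", "y_nm", "n_localizations",
                 "mean_emission_nm", "sd_emission_nm"],
    )


def compare_groups(
    summaries_a: pd.DataFrame | Sequence[float],
    summaries_b: pd.DataFrame | Sequence[float],
    variant: str = "pooled",
) -> dict:
    """Spectral shift between two aggregate groups with an unpaired t-test.

    ``shift = mean(B) - mean(A)``: positive when group A sits at shorter
    wavelengths, i.e. group A is blueshifted / more hydrophobic.  Requires at
    least three aggregates per group.
    """
    def _means(s):
        if isinstance(s, pd.DataFrame):
            return s["mean_emission_nm"].to_numpy(dtype=float)
        return np.asarray(s, dtype=float)

    a, b = _means(summaries_a), _means(summaries_b)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least three aggregates per group")
    shift = float(b.mean() - a.mean())
    return {
        "shift_nm": shift,
        "mean_a_nm": float(a.mean()),
        "mean_b_nm": float(b.mean()),
        "test": drstats.unpaired_t_test(a, b, variant=variant),
    }
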