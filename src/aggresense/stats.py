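"""Dose-response and hypothesis-testing utilities shared by the assay modules.

All between-condition comparisons in this package reduce to an unpaired
two-sample t-test on a handful of replicates (typically n = 3 biological
repeats or 9 fields of view), plus a half-inhibition concentration read off an
antibody dose-response curve by interpolation in log10 concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TTestResult:
    t: float
    df: float
    p: float  # two-sided
    variant: str  # "pooled" or "welch"


@dataclass
class DoseResponsePoint:
    antibody: str
    concentration_um: float  # micromolar; 0 allowed for the untreated control
    response: float          # fraction of the untreated mean
    sem: float | None = None
    n: int = 1


def unpaired_t_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    variant: str = "pooled",
) -> TTestResult:
    """Two-sided unpaired two-sample t-test.

    The default is the pooled-variance (equal-variance Student) form, matching
    the convention of common analysis spreadsheets; ``variant="welch"`` selects
    the unequal-variance form.  Degenerate samples with zero variance in both
    groups return p = 1 when the means are equal and p = 0 otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2
            return TTestResult(0.0, float(df), 1.0, variant)
        return TTestResult(math.inf if a.mean() > b.mean() else -math.inf,
                           float(a.size + b.size - 2), 0.0, variant)
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    df = getattr(res, "df", a.size + b.size - 2)
    return TTestResult(float(res.statistic), float(df), float(res.pvalue), variant)


def normalize_response(
    treated: Sequence[float],
    untreated: Sequence[float],
) -> np.ndarray:
    """Divide treated readouts by the untreated mean, so the control maps to 1."""
    u = np.asarray(untreated, dtype=float)
    if u.size == 0 or u.mean() <= 0:
        raise ValueError("untreated mean must be positive")
    return np.asarray(treated, dtype=float) / u.mean()


def half_inhibition_concentration(points: Sequence[DoseResponsePoint]) -> float | None:
    """Concentration at which the normalized response crosses 0.5.

    The crossing is found by linear interpolation of response against
    log10(concentration) between the bracketing pair of measured points (the
    dose-response convention).  Zero-concentration (untreated) points cannot be
    placed on a log axis and are excluded.  Returns ``None`` when no adjacent
    pair brackets 0.5 — the half-inhibition point was "not reached"; the curve
    is never extrapolated.
    """
    usable = sorted(
        (p for p in points if p.concentration_um > 0), key=lambda p: p.concentration_um
    )
    if len(usable) < 1:
        raise ValueError("need at least one point with positive concentration")
    for p in usable:
        if p.response == 0.5:
            return float(p.concentration_um)
    for lo, hi in zip(usable[:-1], usable[1:]):
        if (lo.response - 0.5) * (hi.response - 0.5) < 0:
            lx, hx = math.log10(lo.concentration_um), math.log10(hi.concentration_um)
            frac = (0.5 - lo.response) / (hi.response - lo.response)
            return float(10.0 ** (lx + frac * (hx - lx)))
    return None


def build_dose_response_table(
    measurements: pd.DataFrame,
    antibody_col: str = "antibody",
    concentration_col: str = "concentration_um",
    value_col: str = "value",
    grouping_unit: str = "field",
) -> list[DoseResponsePoint]:
    """Aggregate per-field (or per-well) measurements into dose-response points.

    Each (antibody, concentration) group yields its mean response and the
    standard error of that mean; a single measurement gives an undefined sem.
    """
    points: list[DoseResponsePoint] = []
    grouped = measurements.groupby([antibody_col, concentration_col], sort=True)
    for (ab, conc), grp in grouped:
        vals = grp[value_col].to_numpy(dtype=float)
        if vals.size == 0:
            continue
        sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else None
        points.append(
            DoseResponsePoint(
                antibody=str(ab),
                concentration_um=float(conc),
                response=float(vals.mean()),
                sem=sem,
                n=int(vals.size),
            )
        )
    return points
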