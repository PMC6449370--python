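"""Synthetic spectrally resolved localization streams (PAINT with Nile red).

Aggregates are point clusters in a wide-field; every transient binding event
yields a localization jittered by the localization precision and a spectral
centroid drawn around the aggregate's true mean emission wavelength (the group
mean plus a per-aggregate offset).  Group-wise mean shifts of ~10 nm emulate
hydrophobicity differences between sucrose-gradient fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._render import RNG_ALGORITHM, make_rng


@dataclass
class SpectralGroup:
    """One aggregate population (e.g. a sucrose fraction)."""

    label: str
    n_aggregates: int = 30
    mean_emission_nm: float = 635.0


@dataclass
class SpectralSimConfig:
    groups: list[SpectralGroup] = field(
        default_factory=lambda: [
            SpectralGroup("20pct", 30, 630.0),
            SpectralGroup("30pct", 30, 640.0),
        ]
    )
    locs_per_aggregate_mean: float = 50.0   # Poisson mean of binding events
    within_aggregate_sd_nm: float = 5.0     # spectral sd of single events
    aggregate_offset_sd_nm: float = 3.0     # aggregate-to-aggregate heterogeneity
    localization_precision_nm: float = 20.0
    field_size_nm: float = 20000.0
    min_separation_nm: float = 1000.0
    n_frames: int = 5000
    detection_band_nm: tuple[float, float] = (550.0, 750.0)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.detection_band_nm
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be distinct")
        for g in self.groups:
            if g.n_aggregates < 0:
                raise ValueError("n_aggregates must be >= 0")
            if not (lo <= g.mean_emission_nm <= hi):
                raise ValueError("group mean emission outside the detection band")
        if self.within_aggregate_sd_nm < 0 or self.aggregate_offset_sd_nm < 0:
            raise ValueError("spectral sds must be >= 0")
        if self.localization_precision_nm < 0:
            raise ValueError("localization precision must be >= 0")


def simulate_spectral_localizations(
    config: SpectralSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate the localization table and its per-aggregate ground truth.

    Returns ``(locs, truth, metadata)``.  ``locs`` columns: x_nm, y_nm, frame,
    photons, spectral_centroid_nm.  ``truth`` has one row per aggregate with
    its group, position and true mean emission.
    """
    config.validate()
    rng = make_rng(config.seed)
    total = sum(g.n_aggregates for g in config.groups)

    # Rejection-sample aggregate positions with the minimum pairwise spacing.
    positions: list[tuple[float, float]] = []
    tries = 0
    while len(positions) < total:
        if tries > 200000:
            raise ValueError("cannot place aggregates at the requested separation")
        tries += 1
        x = rng.uniform(0, config.field_size_nm)
        y = rng.uniform(0, config.field_size_nm)
        if all((x - px) ** 2 + (y - py) ** 2 >= config.min_separation_nm**2
               for px, py in positions):
            positions.append((x, y))

    truth_rows = []
    loc_rows = []
    agg_id = 0
    lo, hi = config.detection_band_nm
    for g in config.groups:
        for _ in range(g.n_aggregates):
            x, y = positions[agg_id]
            true_mean = g.mean_emission_nm + rng.normal(0.0, config.aggregate_offset_sd_nm)
            n_locs = max(int(rng.poisson(config.locs_per_aggregate_mean)), 1)
            xs = x + rng.normal(0.0, config.localization_precision_nm, n_locs)
            ys = y + rng.normal(0.0, config.localization_precision_nm, n_locs)
            frames = rng.integers(0, config.n_frames, n_locs)
            photons = np.maximum(rng.normal(500.0, 100.0, n_locs), 50.0)
            centroids = np.clip(
                true_mean + rng.normal(0.0, config.within_aggregate_sd_nm, n_locs), lo, hi
            )
            for i in range(n_locs):
                loc_rows.append(
                    {
                        "x_nm": xs[i],
                        "y_nm": ys[i],
                        "frame": int(frames[i]),
                        "photons": photons[i],
                        "spectral_centroid_nm": centroids[i],
                    }
                )
            truth_rows.append(
                {
                    "aggregate_id": agg_id,
                    "group": g.label,
                    "x_nm": x,
                    "y_nm": y,
                    "true_mean_emission_nm": true_mean,
                    "group_mean_emission_nm": g.mean_emission_nm,
                    "n_localizations": n_locs,
                }
            )
            agg_id += 1

    locs = pd.DataFrame(
        loc_rows, columns=["x_nm", "y_nm", "frame", "photons", "spectral_centroid_nm"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["aggregate_id", "group", "x_nm", "y_nm", "true_mean_emission_nm",
                 "group_mean_emission_nm", "n_localizations"],
    )
    metadata = {"config": config, "rng": RNG_ALGORITHM, "seed": config.seed}
    return locs, truth, metadata
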