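"""Synthetic three-phase TIRF stacks for the single-vesicle influx assay.

Each simulated vesicle is a diffraction-limited Gaussian spot whose brightness
in the three phases obeys the influx ratio by construction:

    amp_sample = amp_background + influx * (amp_ionomycin - amp_background)

so the generating parameters are the exact ground truth the analysis pipeline
must recover.  The acquisition protocol it emulates takes 50 frames of 50 ms
exposure per phase with the field held registered between phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from ..vesicles import FrameStack
from ._render import RNG_ALGORITHM, add_gaussian_spot, make_rng, place_points


@dataclass
class VesicleSimConfig:
    n_vesicles: int = 100
    field_size: tuple[int, int] = (256, 256)  # rows, cols in px
    psf_sigma: float = 1.3                    # px
    pixel_size_nm: float = 100.0
    frames_per_phase: int = 50
    exposure_ms: float = 50.0
    background_level: float = 100.0           # camera offset + ambient, a.u.
    background_noise_sd: float = 10.0         # a.u. per pixel per frame
    vesicle_amplitude_range: tuple[float, float] = (80.0, 160.0)  # baseline dye signal
    ionomycin_gain: float = 400.0             # added peak amplitude at saturation
    true_influx_distribution: dict[str, Any] = field(
        default_factory=lambda: {"name": "beta_mean_sd", "mean": 0.5, "sd": 0.15}
    )
    min_separation: float = 8.0               # px between vesicle centres
    margin: float = 10.0                      # px kept free at the field border
    phase_shift: tuple[float, float] = (0.0, 0.0)  # optional rigid drift per phase step
    seed: int = 0

    def validate(self) -> None:
        if self.n_vesicles < 0:
            raise ValueError("n_vesicles must be >= 0")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.frames_per_phase < 1:
            raise ValueError("frames_per_phase must be >= 1")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")
        if self.ionomycin_gain <= 0:
            raise ValueError("ionomycin_gain must be positive")


def sample_influx(rng: np.random.Generator, n: int, dist: dict[str, Any]) -> np.ndarray:
    """Draw per-vesicle true influx fractions from a named distribution on [0, 1]."""
    name = dist.get("name", "beta_mean_sd")
    if name == "fixed":
        vals = np.full(n, float(dist["value"]))
    elif name == "uniform":
        vals = rng.uniform(dist.get("low", 0.0), dist.get("high", 1.0), n)
    elif name == "beta":
        vals = rng.beta(dist["a"], dist["b"], n)
    elif name == "beta_mean_sd":
        # Parametrize a Beta by its mean and sd; keeps every draw inside [0, 1].
        m, s = float(dist["mean"]), float(dist["sd"])
        if not 0 < m < 1:
            raise ValueError("beta_mean_sd mean must be in (0, 1)")
        nu = m * (1 - m) / s**2 - 1
        if nu <= 0:
            raise ValueError("beta_mean_sd sd too large for the given mean")
        vals = rng.beta(m * nu, (1 - m) * nu, n)
    else:
        raise ValueError(f"unknown influx distribution '{name}'")
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("sampled influx values must lie in [0, 1]")
    return vals


def simulate_vesicle_experiment(
    config: VesicleSimConfig,
) -> tuple[dict[str, FrameStack], pd.DataFrame, dict]:
    """Simulate the three co-registered phase stacks of one field of view.

    Returns ``(stacks, truth, metadata)`` where ``stacks`` maps phase name to a
    :class:`FrameStack`, ``truth`` holds one row per vesicle (position, phase
    amplitudes, true influx) and ``metadata`` records the full configuration
    and the random generator used.
    """
    config.validate()
    rng = make_rng(config.seed)
    nrows, ncols = config.field_size
    positions = place_points(
        rng,
        config.n_vesicles,
        config.field_size,
        config.min_separation,
        config.margin,
    )
    amp_bg = rng.uniform(*config.vesicle_amplitude_range, config.n_vesicles)
    influx = sample_influx(rng, config.n_vesicles, config.true_influx_distribution)
    amp_ion = amp_bg + config.ionomycin_gain
    amp_sample = amp_bg + influx * (amp_ion - amp_bg)

    phase_amps = {"background": amp_bg, "sample": amp_sample, "ionomycin": amp_ion}
    stacks: dict[str, FrameStack] = {}
    for k, phase in enumerate(("background", "sample", "ionomycin")):
        base = np.full((nrows, ncols), config.background_level, dtype=float)
        dr = k * config.phase_shift[0]
        dc = k * config.phase_shift[1]
        for i in range(config.n_vesicles):
            add_gaussian_spot(
                base,
                positions[i, 0] + dr,
                positions[i, 1] + dc,
                phase_amps[phase][i],
                config.psf_sigma,
            )
        stack = np.broadcast_to(base, (config.frames_per_phase, nrows, ncols)).copy()
        if config.background_noise_sd > 0:
            stack += rng.normal(0.0, config.background_noise_sd, stack.shape)
        stacks[phase] = FrameStack(
            data=stack,
            pixel_size_nm=config.pixel_size_nm,
            exposure_ms=config.exposure_ms,
            phase=phase,
        )

    truth = pd.DataFrame(
        {
            "vesicle_id": np.arange(config.n_vesicles),
            "row": positions[:, 0] if config.n_vesicles else np.array([]),
            "col": positions[:, 1] if config.n_vesicles else np.array([]),
            "amp_background": amp_bg,
            "amp_sample": amp_sample,
            "amp_ionomycin": amp_ion,
            "true_influx": influx,
        }
    )
    metadata = {"config": config, "rng": RNG_ALGORITHM, "seed": config.seed}
    return stacks, truth, metadata
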