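"""Synthetic sparse-spot TIRF images for ThT spot-count fixtures."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._render import RNG_ALGORITHM, add_gaussian_spot, make_rng, place_points


@dataclass
class SpotSimConfig:
    n_spots: int = 7
    field_size: tuple[int, int] = (128, 128)
    psf_sigma: float = 1.5                    # px
    amplitude_range: tuple[float, float] = (500.0, 1000.0)
    background_level: float = 100.0
    noise_sd: float = 10.0
    min_separation: float = 8.0               # px
    margin: float = 6.0
    n_frames: int = 1                         # >1 emulates a 100-frame acquisition
    seed: int = 0

    def validate(self) -> None:
        if self.n_spots < 0:
            raise ValueError("n_spots must be >= 0")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")


def simulate_spot_image(config: SpotSimConfig) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Simulate Gaussian spots of known positions/amplitudes on a noisy background.

    Returns ``(image_or_stack, truth, metadata)``: a 2-D image for
    ``n_frames == 1``, else a (frames, rows, cols) stack with independent noise
    per frame.  Spots honour the configured minimum separation so the ground
    truth count is unambiguous.
    """
    config.validate()
    rng = make_rng(config.seed)
    positions = place_points(
        rng, config.n_spots, config.field_size, config.min_separation, config.margin
    )
    amplitudes = rng.uniform(*config.amplitude_range, config.n_spots)
    base = np.full(config.field_size, config.background_level, dtype=float)
    for i in range(config.n_spots):
        add_gaussian_spot(base, positions[i, 0], positions[i, 1], amplitudes[i], config.psf_sigma)
    shape = (config.n_frames, *config.field_size)
    data = np.broadcast_to(base, shape).copy()
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, shape)
    if config.n_frames == 1:
        data = data[0]
    truth = pd.DataFrame(
        {
            "spot_id": np.arange(config.n_spots),
            "row": positions[:, 0] if config.n_spots else np.array([]),
            "col": positions[:, 1] if config.n_spots else np.array([]),
            "amplitude": amplitudes,
        }
    )
    metadata = {"config": config, "rng": RNG_ALGORITHM, "seed": config.seed}
    return data, truth, metadata
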