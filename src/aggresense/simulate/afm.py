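"""Synthetic AFM height maps of surface-deposited aggregates.

True shapes (spherical caps and rounded-end filaments) are rendered on a flat
substrate, then imaged through a spherical probe apex by grey-scale dilation —
the brute-force tip-convolution oracle the analytical deconvolution is
validated against — and finally degraded by a background tilt plane and
sub-angstrom Gaussian roughness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ..afm import HeightMap, classify_particle
from ._render import RNG_ALGORITHM, make_rng

SHAPE_CAP = "spherical_cap"
SHAPE_FILAMENT = "filament"


@dataclass
class ParticleSpec:
    """Ground-truth geometry of one particle before tip convolution.

    ``diameter_nm`` is the base diameter of a spherical cap; filaments use
    ``length_nm`` (total base extent along the spine) and ``width_nm`` (base
    width of the cap-shaped cross-section).  Positions are map coordinates in
    nm; ``theta`` is the filament spine angle in radians (0 = along columns).
    """

    shape: str
    height_nm: float
    row_nm: float
    col_nm: float
    diameter_nm: float | None = None
    length_nm: float | None = None
    width_nm: float | None = None
    theta: float = 0.0

    def validate(self) -> None:
        if self.height_nm <= 0:
            raise ValueError("particle height must be positive")
        if self.shape == SHAPE_CAP:
            if self.diameter_nm is None or self.diameter_nm <= 0:
                raise ValueError("spherical_cap needs a positive diameter_nm")
            if self.height_nm > self.diameter_nm / 2.0:
                raise ValueError(
                    "spherical_cap height must not exceed its base radius "
                    "(surface-flattened particles are at most hemispherical)"
                )
        elif self.shape == SHAPE_FILAMENT:
            if not self.length_nm or not self.width_nm or self.length_nm <= 0 or self.width_nm <= 0:
                raise ValueError("filament needs positive length_nm and width_nm")
            if self.height_nm > self.width_nm / 2.0:
                raise ValueError("filament height must not exceed half its width")
        else:
            raise ValueError(f"unknown shape '{self.shape}'")

    @property
    def true_class(self) -> str:
        if self.shape == SHAPE_FILAMENT:
            aspect = self.length_nm / self.width_nm
            return classify_particle(self.height_nm, aspect, self.length_nm)
        return classify_particle(self.height_nm, 1.0, self.diameter_nm)


@dataclass
class AfmSimConfig:
    map_size: tuple[int, int] = (400, 400)   # rows, cols in px
    pixel_size_nm: float = 0.25
    particles: list[ParticleSpec] = field(default_factory=list)
    tip_radius_nm: float = 10.0
    roughness_sd_nm: float = 0.05            # experimental noise, well below 0.1 nm
    tilt: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (offset nm, nm/px row, nm/px col)
    seed: int = 0

    def validate(self) -> None:
        if self.tip_radius_nm <= 0:
            raise ValueError("tip_radius_nm must be positive")
        if self.roughness_sd_nm < 0:
            raise ValueError("roughness_sd_nm must be >= 0")
        nrows, ncols = self.map_size
        for p in self.particles:
            p.validate()
            if not (0 <= p.row_nm <= nrows * self.pixel_size_nm) or not (
                0 <= p.col_nm <= ncols * self.pixel_size_nm
            ):
                raise ValueError("particle position outside the map")


def _cap_profile(r2: np.ndarray, base_radius: float, height: float) -> np.ndarray:
    """Height of a spherical cap (base radius a, apex height h) vs squared
    lateral distance from its axis."""
    rs = (base_radius**2 + height**2) / (2.0 * height)  # cap sphere radius
    z = np.sqrt(np.maximum(rs**2 - r2, 0.0)) - (rs - height)
    z[r2 > base_radius**2] = 0.0
    return np.maximum(z, 0.0)


def render_true_surface(config: AfmSimConfig) -> np.ndarray:
    """Render the pre-dilation (true) topography in nm."""
    nrows, ncols = config.map_size
    px = config.pixel_size_nm
    z = np.zeros((nrows, ncols), dtype=float)
    rr, cc = np.mgrid[0:nrows, 0:ncols].astype(float)
    rr *= px
    cc *= px
    for p in config.particles:
        if p.shape == SHAPE_CAP:
            r2 = (rr - p.row_nm) ** 2 + (cc - p.col_nm) ** 2
            z = np.maximum(z, _cap_profile(r2, p.diameter_nm / 2.0, p.height_nm))
        else:
            a = p.width_nm / 2.0
            half_spine = max(p.length_nm / 2.0 - a, 0.0)
            dr = math.sin(p.theta)
            dc = math.cos(p.theta)
            u = (rr - p.row_nm) * dr + (cc - p.col_nm) * dc       # along spine
            v = -(rr - p.row_nm) * dc + (cc - p.col_nm) * dr      # across spine
            u_clamped = np.clip(u, -half_spine, half_spine)
            d2 = (u - u_clamped) ** 2 + v**2
            z = np.maximum(z, _cap_profile(d2, a, p.height_nm))
    return z


def spherical_tip_element(
    tip_radius_nm: float, pixel_size_nm: float, max_height_nm: float
) -> np.ndarray:
    """Structuring element for grey dilation by a spherical apex.

    Entries are minus the tip sag at each lateral offset; offsets whose sag
    exceeds the tallest feature can never win the dilation maximum against the
    zero substrate and are trimmed for speed.
    """
    r = tip_radius_nm
    sag_limit = min(max_height_nm, r)
    reach = math.sqrt(max(2.0 * r * sag_limit - sag_limit**2, 0.0))
    half = int(math.ceil(reach / pixel_size_nm)) + 1
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    rho2 = (yy**2 + xx**2) * pixel_size_nm**2
    sag = np.where(rho2 <= r**2, r - np.sqrt(np.maximum(r**2 - rho2, 0.0)), np.inf)
    return -sag


def dilate_by_spherical_tip(
    surface: np.ndarray, tip_radius_nm: float, pixel_size_nm: float
) -> np.ndarray:
    """Tip-convolve a topography: grey-scale dilation by the spherical apex.

    This is the physical imaging model (the recorded height at x is the
    highest position the apex can reach without the tip body intersecting the
    sample) and serves as the brute-force oracle for the deconvolution.
    """
    if tip_radius_nm <= 0:
        raise ValueError("tip_radius_nm must be positive")
    max_h = float(surface.max()) if surface.size else 0.0
    if max_h <= 0:
        return surface.copy()
    st = spherical_tip_element(tip_radius_nm, pixel_size_nm, max_h)
    footprint = np.isfinite(st)
    return ndimage.grey_dilation(
        surface, footprint=footprint, structure=np.where(footprint, st, 0.0), mode="nearest"
    )


def simulate_afm_map(config: AfmSimConfig) -> tuple[HeightMap, pd.DataFrame, dict]:
    """Simulate a recorded AFM map: true shapes, tip dilation, tilt, roughness.

    Returns ``(height_map, truth, metadata)``; ``truth`` stores the
    pre-dilation geometry and the class label implied by it.
    """
    config.validate()
    rng = make_rng(config.seed)
    true_surface = render_true_surface(config)
    recorded = dilate_by_spherical_tip(true_surface, config.tip_radius_nm, config.pixel_size_nm)
    nrows, ncols = config.map_size
    c0, cr, cc_ = config.tilt
    if any(config.tilt):
        rr, cc = np.mgrid[0:nrows, 0:ncols].astype(float)
        recorded = recorded + c0 + cr * rr + cc_ * cc
    if config.roughness_sd_nm > 0:
        recorded = recorded + rng.normal(0.0, config.roughness_sd_nm, recorded.shape)

    truth = pd.DataFrame(
        [
            {
                "particle_id": i,
                "shape": p.shape,
                "height_nm": p.height_nm,
                "diameter_nm": p.diameter_nm,
                "length_nm": p.length_nm,
                "width_nm": p.width_nm,
                "row_px": p.row_nm / config.pixel_size_nm,
                "col_px": p.col_nm / config.pixel_size_nm,
                "theta": p.theta,
                "true_class": p.true_class,
            }
            for i, p in enumerate(config.particles)
        ],
        columns=[
            "particle_id", "shape", "height_nm", "diameter_nm", "length_nm",
            "width_nm", "row_px", "col_px", "theta", "true_class",
        ],
    )
    hmap = HeightMap(heights=recorded, pixel_size_nm=config.pixel_size_nm, flattened=False)
    metadata = {"config": config, "rng": RNG_ALGORITHM, "seed": config.seed}
    return hmap, truth, metadata
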