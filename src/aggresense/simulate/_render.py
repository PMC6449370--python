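"""Shared rendering primitives for the synthetic-data generators."""

from __future__ import annotations

import numpy as np

#: Name of the random bit generator; recorded in every simulation's metadata so a
#: run can be reproduced bit-for-bit from its sidecar.
RNG_ALGORITHM = "PCG64"


def make_rng(seed: int) -> np.random.Generator:
    """Return the package-wide random generator (PCG64) for a given seed."""
    return np.random.Generator(np.random.PCG64(seed))


def add_gaussian_spot(
    image: np.ndarray,
    row: float,
    col: float,
    amplitude: float,
    sigma_px: float,
) -> None:
    """Add an isotropic 2-D Gaussian spot (peak ``amplitude``) to ``image`` in place.

    Only a patch of +-5 sigma around the centre is touched; beyond that the
    Gaussian is below 4e-6 of the peak and irrelevant for any downstream test.
    """
    nrows, ncols = image.shape
    half = int(np.ceil(5.0 * sigma_px))
    r0 = max(int(np.floor(row)) - half, 0)
    r1 = min(int(np.ceil(row)) + half + 1, nrows)
    c0 = max(int(np.floor(col)) - half, 0)
    c1 = min(int(np.ceil(col)) + half + 1, ncols)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    image[r0:r1, c0:c1] += amplitude * np.exp(-(rr**2 + cc**2) / (2.0 * sigma_px**2))


def place_points(
    rng: np.random.Generator,
    n: int,
    field_shape: tuple[int, int],
    min_separation: float,
    margin: float,
    max_tries: int | None = None,
) -> np.ndarray:
    """Draw ``n`` (row, col) positions with a minimum pairwise separation.

    Rejection sampling; raises ``ValueError`` when the requested packing cannot
    be achieved (the ground truth would otherwise be ambiguous).
    """
    nrows, ncols = field_shape
    if n == 0:
        return np.empty((0, 2))
    if max_tries is None:
        max_tries = 20000 + 500 * n
    lo_r, hi_r = margin, nrows - 1 - margin
    lo_c, hi_c = margin, ncols - 1 - margin
    if hi_r <= lo_r or hi_c <= lo_c:
        raise ValueError("field too small for the requested margin")
    placed: list[tuple[float, float]] = []
    # Spatial hash on a min_separation grid keeps the check O(1) per candidate.
    cell = max(min_separation, 1e-9)
    grid: dict[tuple[int, int], list[int]] = {}
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n} objects at min separation "
                f"{min_separation} px in a {nrows}x{ncols} field"
            )
        tries += 1
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(lo_c, hi_c)
        gr, gc = int(r // cell), int(c // cell)
        ok = True
        for dgr in (-1, 0, 1):
            for dgc in (-1, 0, 1):
                for j in grid.get((gr + dgr, gc + dgc), ()):
                    pr, pc = placed[j]
                    if (pr - r) ** 2 + (pc - c) ** 2 < min_separation**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault((gr, gc), []).append(len(placed))
            placed.append((r, c))
    return np.asarray(placed)
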