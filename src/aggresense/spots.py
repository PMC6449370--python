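"""ThT-active spot counting with a constant noise-tolerance criterion.

A spot is a local maximum whose prominence — its height above the highest
saddle connecting it to a region with a strictly higher maximum — is at least
the noise tolerance, mirroring the semantics of maxima finding with a noise
tolerance in common image-analysis tools.  Prominences are computed exactly by
a descending watershed-by-flooding (union-find) sweep; plateau maxima are
counted once, at their centroid.  The globally highest maximum has no higher
region to merge into; its prominence is referenced to the image median (the
background level), so a blank noise image at a tolerance of several noise sd
yields zero spots.

Counting is translation invariant and equivariant under simultaneous scaling
of intensity and tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import stats as drstats

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SpotCountResult:
    image_id: str
    noise_tolerance: float
    n_spots: int
    coordinates: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    prominences: np.ndarray = field(default_factory=lambda: np.empty(0))


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        parent = self.parent
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    def union(self, winner: int, loser: int) -> None:
        self.parent[self.find(loser)] = self.find(winner)


def compute_prominences(image: np.ndarray) -> list[tuple[int, int, float, float]]:
    """Exact prominences of all local maxima of a 2-D image.

    Returns a list of ``(row, col, peak_value, prominence)`` with one entry per
    maximum (one per plateau).  Pixels are activated in descending value order;
    connected components merge at saddles, and a maximum's prominence is its
    peak height minus the saddle at which its component joins one with a
    strictly higher peak.  Maxima that never meet a higher component (the
    global maxima) are referenced to the image median.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    nrows, ncols = img.shape
    flat = img.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))
    rank = np.empty(flat.size, dtype=np.int64)
    rank[order] = np.arange(flat.size)

    uf = _UnionFind(flat.size)
    peak: dict[int, float] = {}
    open_maxima: dict[int, list[int]] = {}
    died: list[tuple[int, float]] = []  # (representative pixel, prominence)

    for pos, p in enumerate(order):
        r, c = divmod(int(p), ncols)
        v = flat[p]
        roots = []
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols:
                q = rr * ncols + cc
                if rank[q] < pos:
                    root = uf.find(q)
                    if root not in roots:
                        roots.append(root)
        if not roots:
            peak[int(p)] = v
            open_maxima[int(p)] = [int(p)]
            continue
        # Attach p to the component with the highest peak, then merge the rest.
        winner = max(roots, key=lambda rt: (peak[rt], -rt))
        uf.parent[int(p)] = winner
        for rt in roots:
            if rt == winner:
                continue
            if peak[rt] < peak[winner]:
                # rt's open maxima die here: the saddle to a higher region is v.
                # Zero prominence means the "maximum" touches higher ground at
                # its own level (a plateau edge), i.e. it is not a maximum.
                if peak[rt] > v:
                    for rep in open_maxima[rt]:
                        died.append((rep, peak[rt] - v))
            elif peak[rt] == v:
                # Same plateau as the winner, forming right now: one maximum.
                pass
            else:
                # Equal peaks joined at a lower saddle: both maxima stay open.
                open_maxima[winner].extend(open_maxima[rt])
            uf.union(winner, rt)
            del open_maxima[rt], peak[rt]

    reference = float(np.median(flat))
    results = []
    for rt, reps in open_maxima.items():
        for rep in reps:
            results.append((rep, peak[rt] - reference))
    results.extend(died)

    out = []
    for rep, prom in results:
        r, c = divmod(rep, ncols)
        out.append((r, c, float(flat[rep]), float(prom)))
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


def _plateau_centroid(img: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Centroid of the connected equal-value plateau containing (r, c)."""
    nrows, ncols = img.shape
    v = img[r, c]
    seen = {(r, c)}
    stack = [(r, c)]
    while stack:
        cr, cc = stack.pop()
        for dr, dc in _NEIGHBORS:
            rr, xx = cr + dr, cc + dc
            if 0 <= rr < nrows and 0 <= xx < ncols and (rr, xx) not in seen and img[rr, xx] == v:
                seen.add((rr, xx))
                stack.append((rr, xx))
    pts = np.array(sorted(seen), dtype=float)
    return float(pts[:, 0].mean()), float(pts[:, 1].mean())


def count_spots(
    image: np.ndarray,
    noise_tolerance: float,
    image_id: str = "",
) -> SpotCountResult:
    """Count spots whose prominence is at least ``noise_tolerance``.

    A 3-D input is treated as a (frames, rows, cols) stack and reduced to its
    temporal mean first (the convention for multi-frame ThT acquisitions).
    """
    if noise_tolerance <= 0:
        raise ValueError("noise tolerance must be positive")
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=0)
    maxima = compute_prominences(img)
    coords = []
    proms = []
    for r, c, _, prom in maxima:
        if prom >= noise_tolerance:
            coords.append(_plateau_centroid(img, r, c))
            proms.append(prom)
    return SpotCountResult(
        image_id=image_id,
        noise_tolerance=float(noise_tolerance),
        n_spots=len(coords),
        coordinates=np.asarray(coords) if coords else np.empty((0, 2)),
        prominences=np.asarray(proms),
    )


def compare_spot_counts(
    counts_before: list[int] | np.ndarray,
    counts_after: list[int] | np.ndarray,
    variant: str = "pooled",
) -> dict:
    """Ratio of mean spot counts (after over before) with an unpaired t-test.

    Used to test whether aggregates persist after antibody incubation: a ratio
    near 1 with a non-significant test indicates no detectable disaggregation.
    """
    before = np.asarray(counts_before, dtype=float)
    after = np.asarray(counts_after, dtype=float)
    if before.size < 2 or after.size < 2:
        raise ValueError("need at least two fields of view per condition")
    if before.mean() == 0:
        raise ValueError("mean count before is zero; ratio undefined")
    return {
        "mean_before": float(before.mean()),
        "mean_after": float(after.mean()),
        "ratio": float(after.mean() / before.mean()),
        "test": drstats.unpaired_t_test(before, after, variant=variant),
    }
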