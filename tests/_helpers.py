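"""Shared test utilities: point matching and independent brute-force oracles.

The oracles here deliberately use the most literal possible formulation of
each computation (linear scans, per-level flood fills, exhaustive label
permutations) so they stay independent of the vectorized implementations they
check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial import cKDTree


def match_points(detected: np.ndarray, truth: np.ndarray, radius: float) -> tuple[float, float]:
    """(precision, recall) of detected points vs ground truth within a radius."""
    if len(detected) == 0:
        return (1.0, 0.0 if len(truth) else 1.0)
    if len(truth) == 0:
        return (0.0, 1.0)
    tree = cKDTree(truth)
    dists, idx = tree.query(detected)
    hit = dists <= radius
    precision = hit.mean()
    recall = len(set(idx[hit])) / len(truth)
    return float(precision), float(recall)


def brute_force_bursts(
    total_counts: np.ndarray,
    threshold: float,
    merge_gap_bins: int = 1,
    min_bins: int = 1,
) -> list[tuple[int, int]]:
    """Literal scan over bins enumerating threshold-crossing runs."""
    runs: list[list[int]] = []
    in_run = False
    for i, v in enumerate(total_counts):
        if v > threshold:
            if not in_run:
                runs.append([i, i])
                in_run = True
            else:
                runs[-1][1] = i
        else:
            in_run = False
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 < merge_gap_bins:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s + 1 >= min_bins]


def _plateaus(img: np.ndarray) -> list[tuple[list[tuple[int, int]], float]]:
    """Connected equal-value plateaus that are local maxima, via flood fill."""
    nrows, ncols = img.shape
    seen = np.zeros(img.shape, dtype=bool)
    out = []
    for r in range(nrows):
        for c in range(ncols):
            if seen[r, c]:
                continue
            v = img[r, c]
            region = [(r, c)]
            seen[r, c] = True
            stack = [(r, c)]
            is_max = True
            while stack:
                cr, cc = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, xx = cr + dr, cc + dc
                        if 0 <= rr < nrows and 0 <= xx < ncols and (dr or dc):
                            if img[rr, xx] == v and not seen[rr, xx]:
                                seen[rr, xx] = True
                                region.append((rr, xx))
                                stack.append((rr, xx))
                            elif img[rr, xx] > v:
                                is_max = False
            if is_max:
                out.append((region, float(v)))
    return out


def brute_force_prominences(img: np.ndarray) -> list[tuple[float, float, float]]:
    """Exhaustive prominence of every local-maximum plateau.

    For each maximum, flood the image at every level below its peak (descending)
    until the connected component containing it holds a strictly higher pixel;
    the first such level is the saddle.  Global maxima that never meet higher
    ground are referenced to the image median.  Returns (peak, prominence,
    plateau centroid row) triples sorted for comparison.
    """
    from scipy import ndimage

    levels = np.unique(img)[::-1]
    median = float(np.median(img))
    results = []
    for region, v in _plateaus(img):
        prom = None
        for lev in levels:
            if lev > v:
                continue
            mask = img >= lev
            labels, _ = ndimage.label(mask, structure=np.ones((3, 3), int))
            lab = labels[region[0]]
            comp = labels == lab
            if np.any(img[comp] > v):
                prom = v - float(lev)
                break
        if prom is None:
            prom = v - median
        rows = np.array([p[0] for p in region], dtype=float)
        results.append((v, prom, float(rows.mean())))
    return sorted(results)


def permutation_t_pvalue(
    a: np.ndarray,
    b: np.ndarray,
    n_reps: int = 100_000,
    rng: np.random.Generator | None = None,
    exact: bool = False,
    mid_p: bool = False,
) -> float:
    """Permutation two-sided p-value of the pooled t statistic.

    ``exact=True`` enumerates every group relabelling; otherwise ``n_reps``
    random relabellings are drawn and the standard add-one estimator is used.
    ``mid_p`` counts ties as one half (the mid-p convention for discrete
    nulls).
    """
    from scipy import stats as sps

    pooled = np.concatenate([a, b])
    na = len(a)
    t_obs = abs(sps.ttest_ind(a, b, equal_var=True).statistic)

    def t_for(mask: np.ndarray) -> float:
        return abs(sps.ttest_ind(pooled[mask], pooled[~mask], equal_var=True).statistic)

    if exact:
        greater = ties = total = 0
        for comb in itertools.combinations(range(len(pooled)), na):
            mask = np.zeros(len(pooled), bool)
            mask[list(comb)] = True
            t = t_for(mask)
            total += 1
            if t > t_obs + 1e-12:
                greater += 1
            elif abs(t - t_obs) <= 1e-12:
                ties += 1
        if mid_p:
            return (greater + 0.5 * ties) / total
        return (greater + ties) / total

    rng = rng or np.random.default_rng(0)
    n = len(pooled)
    nb = n - na
    order = np.argsort(rng.random((n_reps, n)), axis=1)
    ga = pooled[order[:, :na]]
    gb = pooled[order[:, na:]]
    ma, mb = ga.mean(axis=1), gb.mean(axis=1)
    va = ga.var(axis=1, ddof=1)
    vb = gb.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs((ma - mb) / denom)
    t = np.where(np.isfinite(t), t, np.inf)
    count = int(np.sum(t >= t_obs - 1e-12))
    return (count + 1) / (n_reps + 1)
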