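"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written in plain Python loops against the
stated rules, not against the package's implementation, so the two routes
can disagree when the implementation is wrong.
"""

from __future__ import annotations

import math

import numpy as np


def log_kernel(sigma: float, radius: int) -> np.ndarray:
    """Analytically sampled scale-normalized negated LoG kernel.

    -sigma^2 * LoG(x, y) sampled on an integer grid; convolving an image
    with this kernel is the reference for the detector's response map.
    """
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2
    s2 = sigma**2
    # LoG(x,y) = (r^2 - 2 s^2) / s^4 * G(x,y); negated and scale-normalized
    g = np.exp(-r2 / (2 * s2)) / (2 * math.pi * s2)
    return -s2 * (r2 - 2 * s2) / (s2**2) * g


def brute_force_local_maxima(
    response: np.ndarray, threshold: float, min_separation: float
) -> list[tuple[int, int, float]]:
    """Exhaustive local-maxima detection with greedy Euclidean suppression.

    Scans every interior-and-border pixel for 8-neighbourhood maxima above
    the threshold, then greedily keeps the highest-quality ones with no
    kept maximum closer than ``min_separation``.  Returns (y, x, quality)
    sorted by descending quality.
    """
    h, w = response.shape
    maxima = []
    for y in range(h):
        for x in range(w):
            v = response[y, x]
            if v <= threshold:
                continue
            is_max = True
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == 0 and dx == 0:
                        continue
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and response[ny, nx] > v:
                        is_max = False
            if is_max:
                maxima.append((y, x, float(v)))
    maxima.sort(key=lambda t: (-t[2], t[0], t[1]))
    kept: list[tuple[int, int, float]] = []
    for y, x, v in maxima:
        if all(
            (y - ky) ** 2 + (x - kx) ** 2 >= min_separation**2 for ky, kx, _ in kept
        ):
            kept.append((y, x, v))
    return kept


def runs_above(samples, cutoff: float) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of maximal runs strictly > cutoff."""
    out = []
    start = None
    for i, v in enumerate(samples):
        above = (v == v) and v > cutoff  # NaN-safe
        if above and start is None:
            start = i
        elif not above and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(samples)))
    return out


def classify_oracle(
    vesicle,
    marker,
    cutoff: float = 100.0,
    threshold: float = 0.5,
) -> tuple[bool, float]:
    """Brute-force line-profile colocalization call: (is_positive, share).

    Implements the stated rules sample by sample: vesicle peak = supra-
    cutoff run containing (or nearest to, ties to larger raw-sum area then
    smaller start) the profile midpoint; marker peak = run with maximal
    support overlap with it (ties to the run nearest the vesicle peak
    centre); overlap area = sum of min(vesicle, marker) over the index
    intersection; positive iff overlap > threshold * marker area (strict).
    """
    n = len(vesicle)
    mid = (n - 1) / 2.0
    v_runs = runs_above(vesicle, cutoff)
    m_runs = runs_above(marker, cutoff)
    if not v_runs or not m_runs:
        return False, 0.0

    def interval_dist(run, point):
        s, e = run
        return max(s - point, point - (e - 1), 0.0)

    def area(samples, run):
        return float(sum(samples[i] for i in range(run[0], run[1])))

    v_run = min(
        v_runs, key=lambda r: (interval_dist(r, mid), -area(vesicle, r), r[0])
    )
    v_mid = (v_run[0] + v_run[1] - 1) / 2.0
    best, best_ov = None, -1
    for r in m_runs:
        ov = max(min(r[1], v_run[1]) - max(r[0], v_run[0]), 0)
        if ov > best_ov or (
            ov == best_ov and interval_dist(r, v_mid) < interval_dist(best, v_mid)
        ):
            best, best_ov = r, ov
    m_area = area(marker, best)
    lo, hi = max(v_run[0], best[0]), min(v_run[1], best[1])
    overlap = float(sum(min(vesicle[i], marker[i]) for i in range(lo, hi)))
    share = overlap / m_area if m_area > 0 else 0.0
    return overlap > threshold * m_area, share


def nearest_mask_pixel_oracle(point, mask) -> tuple[int, int, float]:
    """Exhaustive nearest-neighbour search over all mask pixels.

    Returns (y, x, distance) with (y, x)-lexicographic tie-breaking.
    """
    x0, y0 = point
    best = None
    for y in range(mask.shape[0]):
        for x in range(mask.shape[1]):
            if not mask[y, x]:
                continue
            d = math.hypot(x - x0, y - y0)
            if best is None or d < best[2] - 1e-12:
                best = (y, x, d)
    return best


def pearson_oracle(a, b) -> float:
    """Pearson r via the covariance formula, written out long-hand."""
    a = [float(v) for v in np.asarray(a).ravel()]
    b = [float(v) for v in np.asarray(b).ravel()]
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / n
    va = sum((x - ma) ** 2 for x in a) / n
    vb = sum((y - mb) ** 2 for y in b) / n
    return cov / math.sqrt(va * vb)


def pooled_t_oracle(a, b) -> tuple[float, float, int]:
    """Closed-form pooled-variance Student's t evaluated long-hand."""
    from scipy.stats import t as t_dist

    a = [float(v) for v in a]
    b = [float(v) for v in b]
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * t_dist.sf(abs(t), df)
    return t, p, df


def gaussian_sum_oracle(points, voxel_coord, sigma: float) -> float:
    """Closed-form sum of unit-integral 3D Gaussians at one voxel centre."""
    total = 0.0
    norm = (2 * math.pi * sigma**2) ** -1.5
    for p in points:
        d2 = sum((p[ax] - voxel_coord[ax]) ** 2 for ax in range(3))
        total += norm * math.exp(-d2 / (2 * sigma**2))
    return total
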