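"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration or naive
loops, sharing only the contract (response definition, filter rules)
with the production code path, never its vectorized machinery for
candidate search or suppression.
"""

from __future__ import annotations

import numpy as np

from conecensus.detection import (
    CANDIDATE_FLOOR_FACTOR,
    CellCensus,
    DetectionParams,
    _refine_spots,
    log_response,
)


def oracle_detect(image: np.ndarray, params: DetectionParams) -> CellCensus:
    """Pixel-scan detection: enumerate every pixel, test the strict
    local-maximum condition in the min-separation neighborhood with
    explicit loops, apply the same amplitude/variance filters, and run
    an O(n^2) greedy suppression."""
    image = np.asarray(image, dtype=np.float64)
    resp = log_response(image, params.sigma_expected)
    h, w = resp.shape
    r = max(1.0, params.min_separation)
    ri = int(np.floor(r))
    floor = CANDIDATE_FLOOR_FACTOR * params.peak_threshold
    cand = []
    for row in range(h):
        for col in range(w):
            v = resp[row, col]
            if not v > floor:
                continue
            is_max = True
            for dy in range(-ri, ri + 1):
                for dx in range(-ri, ri + 1):
                    if dx == 0 and dy == 0:
                        continue
                    if dx * dx + dy * dy > r * r:
                        continue
                    rr, cc = row + dy, col + dx
                    if not (0 <= rr < h and 0 <= cc < w):
                        continue
                    # strict vs earlier neighbors, >= vs later ones
                    before = dy < 0 or (dy == 0 and dx < 0)
                    other = resp[rr, cc]
                    if (before and not v > other) or (not before and not v >= other):
                        is_max = False
                        break
                if not is_max:
                    break
            if is_max:
                cand.append((row, col))
    cand = np.asarray(cand, dtype=int).reshape(-1, 2)
    x, y, amp, var, valid = _refine_spots(image, cand, params.sigma_expected)
    lo, hi = params.variance_bounds
    keep = valid & (amp >= params.peak_threshold) & (var >= lo) & (var <= hi)
    x, y, amp, var = x[keep], y[keep], amp[keep], var[keep]

    # naive greedy NMS: strongest first, ties by lower (y, x)
    order = sorted(range(x.size), key=lambda i: (-amp[i], y[i], x[i]))
    kept: list[int] = []
    for i in order:
        ok = True
        for j in kept:
            if np.hypot(x[i] - x[j], y[i] - y[j]) < params.min_separation:
                ok = False
                break
        if ok:
            kept.append(i)
    kept = sorted(kept)
    return CellCensus(x=x[kept], y=y[kept], amplitude=amp[kept], variance=var[kept])


def match_spots(detected_xy: np.ndarray, truth_xy: np.ndarray, tol: float) -> int:
    """Greedy one-to-one matching by increasing distance; returns #matches."""
    if len(detected_xy) == 0 or len(truth_xy) == 0:
        return 0
    from scipy.spatial import cKDTree

    d, idx = cKDTree(truth_xy).query(detected_xy, k=1)
    order = np.argsort(d)
    used: set[int] = set()
    tp = 0
    for i in order:
        if d[i] <= tol and int(idx[i]) not in used:
            used.add(int(idx[i]))
            tp += 1
    return tp


def binomial_ci_99(n: int, p: float) -> tuple[float, float]:
    """Exact (Clopper-Pearson) central 99% interval for a Binomial(n, p)
    count, returned as fractions of n."""
    from scipy.stats import binom

    lo = binom.ppf(0.005, n, p) / n
    hi = binom.ppf(0.995, n, p) / n
    return float(lo), float(hi)
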