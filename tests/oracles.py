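"""Brute-force reference implementations used only to check the library.

Everything here is written as directly as possible (double loops, full
enumeration) and stays independent of the code paths under test.
"""

from itertools import combinations
from math import floor

import numpy as np


def ball_heights(radius: int):
    r = int(radius)
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = r * r - x * x - y * y
    inside = d2 >= 0
    return np.where(inside, np.sqrt(np.clip(d2, 0, None)), np.nan), inside


def rolling_ball_background(image: np.ndarray, radius: int) -> np.ndarray:
    """Min-then-max filter with a ball structuring element, replicate edges."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    heights, inside = ball_heights(radius)
    r = int(radius)

    def sample(arr, i, j):
        return arr[min(max(i, 0), h - 1), min(max(j, 0), w - 1)]

    eroded = np.empty_like(img)
    for i in range(h):
        for j in range(w):
            best = np.inf
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if inside[di + r, dj + r]:
                        v = sample(img, i + di, j + dj) - heights[di + r, dj + r]
                        best = min(best, v)
            eroded[i, j] = best
    dilated = np.empty_like(img)
    for i in range(h):
        for j in range(w):
            best = -np.inf
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if inside[di + r, dj + r]:
                        v = sample(eroded, i + di, j + dj) + heights[di + r, dj + r]
                        best = max(best, v)
            dilated[i, j] = best
    return dilated


def mean_filter(image: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel neighbourhood average with replicate padding (double loop)."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    k = window // 2
    out = np.empty_like(img)
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for di in range(-k, k + 1):
                for dj in range(-k, k + 1):
                    acc += img[min(max(i + di, 0), h - 1), min(max(j + dj, 0), w - 1)]
            out[i, j] = acc / (window * window)
    return out


def intermeans_fixed_points(values: np.ndarray):
    """All integer fixed points of the intermeans rule, plus the class means.

    A candidate integer threshold t partitions pixels into {<= t} and
    {> t}; t is a fixed point when floor((mean_low + mean_high) / 2) == t.
    Returns the list of fixed points and the update function f.
    """
    vals = np.asarray(values).ravel().astype(float)
    lo, hi = int(vals.min()), int(vals.max())

    def f(t):
        low = vals[vals <= t]
        high = vals[vals > t]
        if low.size == 0:
            return high.mean()
        if high.size == 0:
            return low.mean()
        return 0.5 * (low.mean() + high.mean())

    fps = [t for t in range(lo, hi) if floor(f(t)) == t]
    return fps, f


def intermeans_exhaustive(values: np.ndarray) -> float:
    """Exhaustive fixed-point search for the intermeans threshold.

    The update map is monotone non-decreasing, so iteration started at the
    image mean converges to the nearest fixed point in its direction of
    movement; that fixed point is selected from the exhaustively
    enumerated set.
    """
    vals = np.asarray(values).ravel().astype(float)
    fps, f = intermeans_fixed_points(vals)
    assert fps, "no fixed point found"
    start = floor(vals.mean())
    if start in fps:
        return f(start)
    if f(start) > start:
        above = [t for t in fps if t > start]
        return f(min(above)) if above else f(max(fps))
    below = [t for t in fps if t < start]
    return f(max(below)) if below else f(min(fps))


def mann_whitney_exact(a, b):
    """Exact two-sided Mann-Whitney U by enumerating all rank splits."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n_a, n_b = len(a), len(b)

    def u_stat(x, y):
        u = 0.0
        for xi in x:
            for yi in y:
                if xi > yi:
                    u += 1.0
                elif xi == yi:
                    u += 0.5
        return u

    u_obs = u_stat(a, b)
    m = n_a * n_b
    lo_tail = min(u_obs, m - u_obs)
    hi_tail = max(u_obs, m - u_obs)
    count = 0
    total = 0
    idx = range(len(pooled))
    for comb in combinations(idx, n_a):
        sel = set(comb)
        x = [pooled[i] for i in idx if i in sel]
        y = [pooled[i] for i in idx if i not in sel]
        u = u_stat(x, y)
        if u <= lo_tail or u >= hi_tail:
            count += 1
        total += 1
    return u_obs, min(1.0, count / total)


def student_t(a, b):
    """Closed-form pooled-variance two-sample t statistic and df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return t, na + nb - 2
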