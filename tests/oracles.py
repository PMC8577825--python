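"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (explicit loops over every candidate
split / every pixel pair) so they share no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np

# near-ties (identical criterion up to floating-point noise, e.g. splits
# within a run of empty bins) resolve to the lower bin, matching the
# package's documented convention
TIE_RTOL = 1e-9


def _better(crit, best) -> bool:
    if best == -math.inf:
        return True
    return crit > best + TIE_RTOL * max(abs(best), 1.0)


def brute_otsu(counts) -> int:
    """Exhaustive search of the between-class variance over all 255 splits."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    best_t, best_crit = 0, -math.inf
    for t in range(255):
        w0 = counts[: t + 1].sum() / n
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        idx = np.arange(256)
        mu0 = (counts[: t + 1] * idx[: t + 1]).sum() / counts[: t + 1].sum()
        mu1 = (counts[t + 1 :] * idx[t + 1 :]).sum() / counts[t + 1 :].sum()
        crit = w0 * w1 * (mu0 - mu1) ** 2
        if _better(crit, best_crit):
            best_crit, best_t = crit, t
    return best_t


def brute_kapur(counts) -> int:
    """Exhaustive search of summed background/foreground Shannon entropy."""
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    best_t, best_crit = 0, -math.inf
    for t in range(255):
        p0 = p[: t + 1]
        p1 = p[t + 1 :]
        P0, P1 = p0.sum(), p1.sum()
        if P0 == 0 or P1 == 0:
            continue
        h0 = -sum(q / P0 * math.log(q / P0) for q in p0 if q > 0)
        h1 = -sum(q / P1 * math.log(q / P1) for q in p1 if q > 0)
        crit = h0 + h1
        if _better(crit, best_crit):
            best_crit, best_t = crit, t
    return best_t


def brute_triangle(counts) -> int:
    """Geometric construction: max perpendicular distance to the peak-end line.

    Longer tail = more bins between peak and outermost populated bin; exact
    tie goes to the right tail; argmax ties to the lower bin.
    """
    counts = np.asarray(counts, dtype=float)
    peak = int(np.argmax(counts))
    nz = np.nonzero(counts)[0]
    first, last = int(nz[0]), int(nz[-1])
    use_right = (last - peak) >= (peak - first)
    end = last if use_right else first
    x0, y0 = peak, counts[peak]
    x1, y1 = end, counts[end]
    norm = math.hypot(x1 - x0, y1 - y0)
    if norm == 0:
        return peak
    lo, hi = min(peak, end), max(peak, end)
    best_t, best_d = lo, -1.0
    for t in range(lo, hi + 1):
        d = abs((y1 - y0) * t - (x1 - x0) * counts[t] + x1 * y0 - y1 * x0) / norm
        if _better(d, best_d):
            best_d, best_t = d, t
    return best_t


def brute_signed_edt(mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """All-pairs nearest-pixel search; O(N^2) over foreground/background sets."""
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape, dtype=float)
    for (y, x) in np.ndindex(mask.shape):
        targets = bg if mask[y, x] else fg
        d2 = ((targets - np.array([y, x])) ** 2).sum(axis=1)
        d = math.sqrt(d2.min())
        out[y, x] = -d if mask[y, x] else d
    return out * pixel_size_um


def flood_fill_count(mask: np.ndarray) -> int:
    """Count 8-connected components via explicit BFS flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    count = 0
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            count += 1
            stack = [(sy, sx)]
            seen[sy, sx] = True
            while stack:
                y, x = stack.pop()
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
    return count


def random_histogram(rng: np.random.Generator) -> np.ndarray:
    """Random 256-bin histograms spanning sparse, dense and bimodal shapes."""
    kind = rng.integers(3)
    counts = np.zeros(256, dtype=np.int64)
    if kind == 0:          # dense uniform noise
        counts[:] = rng.integers(0, 50, size=256)
    elif kind == 1:        # sparse spikes
        k = int(rng.integers(2, 20))
        bins = rng.choice(256, size=k, replace=False)
        counts[bins] = rng.integers(1, 1000, size=k)
    else:                  # two-mode mixture
        for mu, sd, n in ((rng.integers(20, 100), 8, 4000), (rng.integers(140, 230), 12, 2500)):
            samples = np.clip(rng.normal(mu, sd, size=n).round().astype(int), 0, 255)
            counts += np.bincount(samples, minlength=256)
    if np.count_nonzero(counts) < 2:   # ensure a valid histogram
        counts[10] += 1
        counts[200] += 1
    return counts
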