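"""From-scratch image operators shared by both quantification pipelines.

The three automatic histogram thresholding criteria (Otsu's between-class
variance, the Triangle/Zack geometric construction and Kapur's maximum
entropy) are implemented here directly on a fixed 256-bin histogram built
over the ``[min, max]`` range of the source image, so float images are
handled without pre-casting to 8-bit.  Conventions:

* a threshold is a *bin index* ``t``; foreground is intensity strictly
  greater than the upper edge of bin ``t``;
* argmax ties break toward the lower bin;
* filters use reflective (half-sample symmetric) boundaries;
* connected components use 8-connectivity;
* the signed Euclidean distance transform is negative inside the
  foreground, positive outside, measured between pixel centres, in μm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import BinaryMask, Image2D, ImageStack, LabelMap, check_same_geometry
from .errors import (
    ConfigError,
    DegenerateHistogramError,
    DegenerateMaskError,
)

N_BINS = 256

THRESHOLD_METHODS = ("otsu", "triangle", "kapur")


# ---------------------------------------------------------------------------
# histogram

@dataclass
class HistogramT:
    """256-bin intensity histogram over the [min, max] range of an image."""

    counts: np.ndarray        # (256,) non-negative ints
    bin_edges: np.ndarray     # (257,) monotonically increasing

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.counts.shape != (N_BINS,) or self.bin_edges.shape != (N_BINS + 1,):
            raise ConfigError("HistogramT must have 256 bins and 257 edges")
        if np.any(self.counts < 0):
            raise ConfigError("histogram counts must be non-negative")

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    def upper_edge(self, t: int) -> float:
        """Upper edge of bin ``t`` — the binarization cut for threshold t."""
        return float(self.bin_edges[t + 1])


def image_histogram(img: Image2D) -> HistogramT:
    """256-bin histogram over ``[min, max]`` of the image.

    Raises :class:`DegenerateHistogramError` for a constant image, for which
    no intensity range (and hence no threshold) exists.
    """
    lo = float(img.values.min())
    hi = float(img.values.max())
    if hi <= lo:
        raise DegenerateHistogramError("constant image: histogram has a single value")
    counts, edges = np.histogram(img.values, bins=N_BINS, range=(lo, hi))
    return HistogramT(counts, edges)


# ---------------------------------------------------------------------------
# thresholding criteria

def _check_valid_hist(hist: HistogramT) -> None:
    if int(np.count_nonzero(hist.counts)) < 2:
        raise DegenerateHistogramError(
            "degenerate histogram: fewer than two populated bins"
        )


_TIE_RTOL = 1e-9


def _argmax_lowest(crit: np.ndarray) -> int:
    """Lowest index within relative tolerance of the maximum.

    Criterion values that differ only by floating-point noise (e.g. splits
    across runs of empty bins) are treated as exact ties, which the
    documented convention breaks toward the lower bin.
    """
    best = float(np.max(crit))
    tol = _TIE_RTOL * max(abs(best), 1.0)
    return int(np.flatnonzero(crit >= best - tol)[0])


def otsu_threshold(hist: HistogramT) -> int:
    """Bin index maximizing the between-class variance ω0·ω1·(μ0−μ1)²."""
    _check_valid_hist(hist)
    p = hist.counts.astype(float) / hist.n_pixels
    # bin indices as the intensity scale: affine-invariant for equal-width
    # bins, and exactly the classic 8-bit formulation
    idx = np.arange(N_BINS, dtype=float)
    w0 = np.cumsum(p)[:-1]                    # background weight for t=0..254
    w1 = 1.0 - w0
    cum_mean = np.cumsum(p * idx)[:-1]
    total_mean = float(np.sum(p * idx))
    valid = (w0 > 0) & (w1 > 0)
    crit = np.full(N_BINS - 1, -np.inf)
    mu0 = np.divide(cum_mean, w0, out=np.zeros_like(w0), where=w0 > 0)
    mu1 = np.divide(total_mean - cum_mean, w1, out=np.zeros_like(w1), where=w1 > 0)
    crit[valid] = (w0 * w1 * (mu0 - mu1) ** 2)[valid]
    return _argmax_lowest(crit)


def kapur_threshold(hist: HistogramT) -> int:
    """Bin index maximizing Kapur's summed background/foreground entropy."""
    _check_valid_hist(hist)
    p = hist.counts.astype(float) / hist.n_pixels
    plogp = np.where(p > 0, p * np.log(p, where=p > 0, out=np.zeros_like(p)), 0.0)
    P0 = np.cumsum(p)[:-1]
    P1 = 1.0 - P0
    S0 = np.cumsum(plogp)[:-1]
    S1 = float(plogp.sum()) - S0
    valid = (P0 > 0) & (P1 > 0)
    crit = np.full(N_BINS - 1, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = np.log(P0) - S0 / P0
        h1 = np.log(P1) - S1 / P1
    crit[valid] = (h0 + h1)[valid]
    return _argmax_lowest(crit)


def triangle_threshold(hist: HistogramT) -> int:
    """Triangle (Zack) threshold.

    A line is drawn from the histogram peak to the last populated bin on the
    longer-tail side; the threshold is the bin with maximum perpendicular
    distance between the histogram and that line.  The longer tail is the
    side with more bins between the peak and the outermost populated bin
    (exact tie -> right tail); argmax ties break toward the lower bin.
    """
    _check_valid_hist(hist)
    counts = hist.counts.astype(float)
    peak = int(np.argmax(counts))             # ties -> lower bin
    nz = np.nonzero(counts)[0]
    first, last = int(nz[0]), int(nz[-1])
    right_span = last - peak
    left_span = peak - first
    use_right = right_span >= left_span
    end = last if use_right else first

    x0, y0 = float(peak), counts[peak]
    x1, y1 = float(end), counts[end]
    lo, hi = (peak, end) if use_right else (end, peak)
    xs = np.arange(lo, hi + 1, dtype=float)
    ys = counts[lo : hi + 1]
    # perpendicular distance from (x, h(x)) to the peak–end line
    norm = np.hypot(x1 - x0, y1 - y0)
    if norm == 0:
        return peak
    dist = np.abs((y1 - y0) * xs - (x1 - x0) * ys + x1 * y0 - y1 * x0) / norm
    return int(lo + _argmax_lowest(dist))


_THRESHOLD_FUNCS = {
    "otsu": otsu_threshold,
    "triangle": triangle_threshold,
    "kapur": kapur_threshold,
}


def auto_threshold(hist: HistogramT, method: str) -> int:
    """Dispatch to one of the three automatic thresholding criteria."""
    try:
        func = _THRESHOLD_FUNCS[method]
    except KeyError:
        raise ConfigError(
            f"unknown threshold method {method!r}; choose from {THRESHOLD_METHODS}"
        ) from None
    return func(hist)


# ---------------------------------------------------------------------------
# projections and filters

def max_project(stack: ImageStack, channel: str) -> Image2D:
    """Maximum-intensity z-projection of one channel."""
    data = stack.channel(channel)
    return Image2D(data.max(axis=0), stack.pixel_size_um)


def gaussian_smooth(img: Image2D, sigma_px: float) -> Image2D:
    """Gaussian blur with reflective boundary; ``sigma_px = 0`` is identity."""
    if sigma_px < 0:
        raise ConfigError("sigma_px must be non-negative")
    if sigma_px == 0:
        return Image2D(img.values.copy(), img.pixel_size_um)
    out = ndimage.gaussian_filter(img.values, sigma=sigma_px, mode="reflect")
    return Image2D(out, img.pixel_size_um)


def difference_of_gaussians(
    img: Image2D, sigma_small_px: float, sigma_large_px: float
) -> Image2D:
    """Band-pass: small-σ blur minus large-σ blur."""
    if not 0 < sigma_small_px < sigma_large_px:
        raise ConfigError("require 0 < sigma_small_px < sigma_large_px")
    small = gaussian_smooth(img, sigma_small_px)
    large = gaussian_smooth(img, sigma_large_px)
    return Image2D(small.values - large.values, img.pixel_size_um)


def _disk_footprint(radius_px: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    return (yy**2 + xx**2) <= radius_px**2


def local_variance(img: Image2D, radius_px: int) -> Image2D:
    """Per-pixel variance over a circular window (reflective boundary)."""
    if radius_px < 1:
        raise ConfigError("radius_px must be >= 1")
    fp = _disk_footprint(int(radius_px)).astype(float)
    fp /= fp.sum()
    mean = ndimage.correlate(img.values, fp, mode="reflect")
    mean_sq = ndimage.correlate(img.values**2, fp, mode="reflect")
    var = np.clip(mean_sq - mean**2, 0.0, None)
    return Image2D(var, img.pixel_size_um)


# ---------------------------------------------------------------------------
# components, binarization, signed EDT

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


def connected_components(mask: BinaryMask) -> LabelMap:
    """8-connected components with per-label area/centroid/bbox table."""
    labels, n = ndimage.label(mask.values, structure=_EIGHT_CONN)
    ps = mask.pixel_size_um
    rows = []
    if n:
        areas = ndimage.sum_labels(
            np.ones_like(labels), labels, index=np.arange(1, n + 1)
        ).astype(int)
        centroids = ndimage.center_of_mass(
            mask.values, labels, index=np.arange(1, n + 1)
        )
        slices = ndimage.find_objects(labels)
        for k in range(n):
            cy, cx = centroids[k]
            sy, sx = slices[k]
            rows.append(
                dict(
                    label=k + 1,
                    area_px=int(areas[k]),
                    area_um2=float(areas[k]) * ps**2,
                    centroid_y_px=float(cy),
                    centroid_x_px=float(cx),
                    centroid_y_um=float(cy) * ps,
                    centroid_x_um=float(cx) * ps,
                    bbox_y0=sy.start,
                    bbox_x0=sx.start,
                    bbox_y1=sy.stop,
                    bbox_x1=sx.stop,
                )
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "label", "area_px", "area_um2",
            "centroid_y_px", "centroid_x_px", "centroid_y_um", "centroid_x_um",
            "bbox_y0", "bbox_x0", "bbox_y1", "bbox_x1",
        ],
    )
    return LabelMap(labels.astype(np.int32), ps, table)


def relabel_sequential(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Compress arbitrary positive labels to contiguous 1..K (order-preserving)."""
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[present] = np.arange(1, len(present) + 1, dtype=np.int32)
    return lut[labels], len(present)


def remove_small_components(mask: BinaryMask, min_area_um2: float) -> BinaryMask:
    """Drop 8-connected components with physical area below the cutoff."""
    if min_area_um2 < 0:
        raise ConfigError("min_area_um2 must be >= 0")
    if min_area_um2 == 0 or not mask.values.any():
        return BinaryMask(mask.values.copy(), mask.pixel_size_um)
    lm = connected_components(mask)
    keep = lm.table.loc[lm.table.area_um2 >= min_area_um2, "label"].to_numpy()
    out = np.isin(lm.values, keep) & mask.values
    return BinaryMask(out, mask.pixel_size_um)


def binarize(img: Image2D, hist: HistogramT, t: int) -> BinaryMask:
    """Foreground = intensity strictly greater than the upper edge of bin t."""
    return BinaryMask(img.values > hist.upper_edge(t), img.pixel_size_um)


def binarize_and_clean(
    img: Image2D,
    smooth_sigma_px: float,
    method: str,
    min_area_um2: float,
) -> BinaryMask:
    """Smooth → histogram → auto-threshold → drop sub-area components.

    A constant (background-only) field raises
    :class:`DegenerateHistogramError`; callers that must survive blank
    fields catch it and substitute an empty mask.
    """
    smoothed = gaussian_smooth(img, smooth_sigma_px)
    try:
        hist = image_histogram(smoothed)
        t = auto_threshold(hist, method)
    except DegenerateHistogramError as err:
        raise DegenerateHistogramError(
            f"cannot threshold image with method {method!r}: {err}"
        ) from err
    mask = binarize(smoothed, hist, t)
    return remove_small_components(mask, min_area_um2)


def signed_edt(mask: BinaryMask) -> Image2D:
    """Signed Euclidean distance transform, in μm.

    Positive outside the mask (distance to the nearest foreground pixel
    centre), negative inside (distance to the nearest background pixel
    centre).  Requires at least one foreground and one background pixel.
    """
    fg = mask.values
    if fg.all() or not fg.any():
        raise DegenerateMaskError(
            "signed EDT undefined for an all-foreground or all-background mask"
        )
    dist_to_fg = ndimage.distance_transform_edt(~fg)
    dist_to_bg = ndimage.distance_transform_edt(fg)
    signed = np.where(fg, -dist_to_bg, dist_to_fg) * mask.pixel_size_um
    return Image2D(signed, mask.pixel_size_um)
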