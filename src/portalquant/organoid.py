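"""Chimeric organoid analyzer.

Measures a mesenchyme-ductal organoid in a single z-slice chosen for optimal
focus: the organoid footprint is mapped from brightfield texture (smoothed
local variance + Triangle threshold, largest component), the Hes1-GFP region
by Otsu on the smoothed GFP channel, and discrete tdTomato cell clusters by
Kapur's maximum-entropy threshold on a difference-of-Gaussians band-pass.
GFP/tomato areas are reported inside the organoid; GFP intensity is
normalized to organoid area (a whole-image-normalized variant is also
emitted, since either reading of "normalized to total area" is defensible).

Noise robustness: a histogram threshold always splits even a pure-noise
channel, so fluorescence masks are accepted only when the foreground-to-
background contrast exceeds ``min_contrast_sd`` background standard
deviations; blank channels then yield empty masks and batch runs never
abort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import BinaryMask, Image2D, ImageStack, LabelMap
from .errors import ConfigError, DegenerateHistogramError
from .imaging import (
    auto_threshold,
    binarize,
    connected_components,
    difference_of_gaussians,
    gaussian_smooth,
    image_histogram,
    local_variance,
    remove_small_components,
)
from scipy import ndimage


@dataclass
class AnalyzerParams:
    """Tunable parameters of the organoid analyzer."""

    variance_radius_px: int = 4
    variance_smooth_sigma_px: float = 2.0
    gfp_smooth_sigma_px: float = 2.0
    dog_sigma_small_px: float = 2.0
    dog_sigma_large_px: float = 8.0
    min_cluster_area_um2: float = 20.0
    min_contrast_sd: float = 4.0
    edge_compensation: bool = True   # erode organoid mask by variance radius

    def validate(self) -> None:
        if not 0 < self.dog_sigma_small_px < self.dog_sigma_large_px:
            raise ConfigError("require 0 < dog_sigma_small_px < dog_sigma_large_px")
        if min(
            self.variance_radius_px,
            self.variance_smooth_sigma_px,
            self.gfp_smooth_sigma_px,
        ) <= 0:
            raise ConfigError("analyzer sigmas/radii must be positive")
        if self.min_cluster_area_um2 < 0 or self.min_contrast_sd < 0:
            raise ConfigError("gates must be >= 0")


@dataclass
class OrganoidMeasurement:
    """Per-stack measurement row; ``organoid_found`` is False for null rows."""

    focus_z: int
    organoid_found: bool
    organoid_area_um2: float = float("nan")
    gfp_area_um2: float = float("nan")
    tomato_area_um2: float = float("nan")
    n_tomato_clusters: int = 0
    gfp_mean_intensity_norm: float = float("nan")
    gfp_mean_intensity_norm_total: float = float("nan")
    gfp_area_fraction: float = float("nan")
    contacted: bool = False
    provenance: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return dict(
            focus_z=self.focus_z,
            organoid_found=int(self.organoid_found),
            organoid_area_um2=self.organoid_area_um2,
            gfp_area_um2=self.gfp_area_um2,
            gfp_area_fraction=self.gfp_area_fraction,
            gfp_mean_intensity_norm=self.gfp_mean_intensity_norm,
            gfp_mean_intensity_norm_total=self.gfp_mean_intensity_norm_total,
            tomato_area_um2=self.tomato_area_um2,
            n_tomato_clusters=self.n_tomato_clusters,
            contacted=int(self.contacted),
        )


def select_focus_slice(stack: ImageStack, channel: str = "brightfield") -> int:
    """z-index with maximal normalized variance (variance / mean²); ties → lowest z."""
    data = stack.channel(channel)
    scores = []
    for z in range(data.shape[0]):
        plane = data[z]
        mu = float(plane.mean())
        var = float(plane.var())
        scores.append(var / mu**2 if mu != 0 else var)
    return int(np.argmax(scores))


def _contrast_ok(img_values: np.ndarray, mask: np.ndarray, k: float) -> bool:
    """Accept a mask only if fg/bg contrast clears k background SDs."""
    if not mask.any() or mask.all():
        return False
    fg = img_values[mask]
    bg = img_values[~mask]
    sd = float(bg.std())
    if sd == 0:
        return True
    return (float(fg.mean()) - float(bg.mean())) >= k * sd


def segment_organoid_area(bf: Image2D, params: AnalyzerParams) -> BinaryMask | None:
    """Organoid footprint from brightfield texture; ``None`` if no organoid.

    Smoothed local variance → Triangle threshold → largest 8-connected
    component.  The variance window smears texture past the true boundary by
    its radius and the subsequent Gaussian smoothing extends that skirt by
    about two sigma (where the Triangle threshold, which sits near the
    histogram tail, still fires), so the mask is eroded back by
    ``variance_radius_px + 2·variance_smooth_sigma_px`` (``edge_compensation``).
    """
    params.validate()
    var = local_variance(bf, params.variance_radius_px)
    smoothed = gaussian_smooth(var, params.variance_smooth_sigma_px)
    try:
        hist = image_histogram(smoothed)
        t = auto_threshold(hist, "triangle")
    except DegenerateHistogramError:
        return None
    mask = binarize(smoothed, hist, t)
    if not mask.values.any():
        return None
    lm = connected_components(mask)
    largest = int(lm.table.loc[lm.table.area_px.idxmax(), "label"])
    sel = lm.values == largest
    if params.edge_compensation:
        r = int(round(params.variance_radius_px + 2 * params.variance_smooth_sigma_px))
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        sel = ndimage.binary_erosion(sel, structure=(yy**2 + xx**2) <= r**2)
        if not sel.any():
            return None
    return BinaryMask(sel, bf.pixel_size_um)


def segment_gfp_area(gfp: Image2D, params: AnalyzerParams) -> BinaryMask:
    """GFP mask: Otsu on the smoothed channel, all components kept.

    Returns an empty mask for degenerate or contrast-failing (noise-only)
    channels.
    """
    params.validate()
    smoothed = gaussian_smooth(gfp, params.gfp_smooth_sigma_px)
    try:
        hist = image_histogram(smoothed)
        t = auto_threshold(hist, "otsu")
    except DegenerateHistogramError:
        return BinaryMask.empty_like(gfp)
    mask = binarize(smoothed, hist, t)
    if not _contrast_ok(smoothed.values, mask.values, params.min_contrast_sd):
        return BinaryMask.empty_like(gfp)
    return mask


def segment_tomato_clusters(tom: Image2D, params: AnalyzerParams) -> LabelMap:
    """Tomato clusters: Kapur max-entropy on a DoG band-pass, area-filtered."""
    params.validate()
    dog = difference_of_gaussians(tom, params.dog_sigma_small_px, params.dog_sigma_large_px)
    empty = connected_components(BinaryMask.empty_like(tom))
    try:
        hist = image_histogram(dog)
        t = auto_threshold(hist, "kapur")
    except DegenerateHistogramError:
        return empty
    mask = binarize(dog, hist, t)
    if not _contrast_ok(dog.values, mask.values, params.min_contrast_sd):
        return empty
    mask = remove_small_components(mask, params.min_cluster_area_um2)
    return connected_components(mask)


def measure_chimeric_organoid(
    stack: ImageStack, params: AnalyzerParams | None = None
) -> OrganoidMeasurement:
    """Full analyzer: focus slice → organoid, GFP, tomato → areas/intensities.

    GFP and tomato areas are intersections with the organoid mask; a field
    with no detectable organoid produces a null measurement row rather than
    an error.
    """
    params = params or AnalyzerParams()
    z = select_focus_slice(stack, "brightfield")
    ps = stack.pixel_size_um
    prov = dict(focus_metric="normalized_variance", params=vars(params).copy())

    bf = stack.plane("brightfield", z)
    organoid_mask = segment_organoid_area(bf, params)
    if organoid_mask is None or not organoid_mask.values.any():
        return OrganoidMeasurement(focus_z=z, organoid_found=False, provenance=prov)

    org = organoid_mask.values
    organoid_area = organoid_mask.area_um2()

    gfp_img = stack.plane("gfp", z)
    gfp_mask = segment_gfp_area(gfp_img, params).values & org
    gfp_area = float(gfp_mask.sum()) * ps**2

    tom_img = stack.plane("tomato", z)
    clusters = segment_tomato_clusters(tom_img, params)
    inside = np.unique(clusters.values[org])
    inside = inside[inside > 0]
    tomato_area = float(np.isin(clusters.values, inside).sum()) * ps**2

    px_area = ps**2
    integrated_gfp = float(gfp_img.values[org].sum()) * px_area
    total_area = gfp_img.values.size * px_area
    return OrganoidMeasurement(
        focus_z=z,
        organoid_found=True,
        organoid_area_um2=organoid_area,
        gfp_area_um2=gfp_area,
        tomato_area_um2=tomato_area,
        n_tomato_clusters=int(len(inside)),
        gfp_mean_intensity_norm=integrated_gfp / organoid_area,
        gfp_mean_intensity_norm_total=integrated_gfp / total_area,
        gfp_area_fraction=gfp_area / organoid_area,
        contacted=bool(len(inside) >= 1),
        provenance=prov,
    )
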