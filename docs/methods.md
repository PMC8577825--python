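# Methods

This note documents the models, conventions and design choices behind
portalquant: what the synthetic scenes emulate, how the operators are
defined, which parameters matter, and what the recovery tests do and do not
demonstrate about real microscopy.

## Coordinate and image conventions

Arrays are `[z, c, y, x]`; pixel indices are 0-based; physical coordinates
are in μm measured at pixel centres with the origin at the centre of the
top-left pixel; pixels are square (anisotropy is not supported). Filters use
reflective (half-sample symmetric) boundaries, which preserves the image
mean exactly for symmetric kernels. Connected components use
8-connectivity. All intervals are half-open.

## Histograms and automatic thresholding

Thresholding operates on a fixed 256-bin histogram spanning `[min, max]` of
the (smoothed) image, so float images are handled without an 8-bit cast
while reproducing the classic 8-bit behaviour. A threshold is a bin index
`t`; foreground is intensity strictly greater than the upper edge of bin
`t`. A constant image has no intensity range and raises a
`DegenerateHistogramError`; pipeline stages that must survive blank fields
catch it and substitute an empty mask.

Three criteria are implemented directly:

* **Otsu** — maximize the between-class variance ω₀ω₁(μ₀−μ₁)² over the 255
  candidate splits, with bin index as the intensity scale (affine-invariant
  for equal-width bins).
* **Kapur** — maximize the summed Shannon entropy of the background and
  foreground distributions, −Σ(p/P)ln(p/P) over populated bins.
* **Triangle (Zack)** — draw a line from the histogram peak to the last
  populated bin on the longer-tail side (more bins between peak and
  outermost populated bin; exact tie → right tail) and take the bin of
  maximum perpendicular distance to that line.

Argmax ties break toward the lower bin. Ties are detected with a relative
tolerance of 1e-9: splits that differ only through floating-point summation
order (e.g. candidate thresholds inside a run of empty bins, where the
criterion is mathematically constant) are treated as exact ties. Each
method is tested for exact agreement with an independent exhaustive search
of its criterion on 200 random histograms.

## Signed Euclidean distance transform

`signed_edt` is negative inside the foreground (distance to the nearest
background pixel centre) and positive outside (distance to the nearest
foreground pixel centre), in μm. With this convention a nucleus overlapping
the niche area has a mean signed distance ≤ 0, and the single-pixel 3-4-5
case gives exactly +5 μm outside and −1 μm on the pixel itself. The
underlying unsigned transforms use the exact Euclidean distance transform
from scipy.ndimage; the signed composition, units and degenerate-mask
handling are defined here and verified against an O(N²) all-pairs search.

## The distance pipeline

Per channel: max-intensity z-projection → Gaussian smoothing → automatic
threshold → area filter → optional raw-mean intensity gate that discards
components whose mean projected intensity is too low to be signal. The gate
is what makes unsupervised batch runs safe: a background-only channel
produces an empty mask rather than an arbitrary noise split. Double masks
(pixelwise AND) isolate nucleus classes — Hoechst ∧ OPN for ductal nuclei,
Hoechst ∧ nuclear PDGFRα-GFP for mesenchymal nuclei. "At least 5 μm²" is
read literally (area = pixel count · pixel-size², kept when ≥ 5).

Each labelled nucleus gets the mean and the minimum of the signed EDT of a
configurable target mask over its pixels. The **distance statistic** is the
mean (as in the original workflow); the **contact call** uses the minimum
against the desmin-protrusion mask: `contacted ⇔ min ≤ τ`, τ default 1 μm,
recorded in provenance. The minimum is used deliberately: a thin protrusion
touching the nuclear boundary drives the minimum to ≈ 0 for any nucleus
size, whereas the mean of a touched nucleus is ≈ 1.13·r (r = nucleus
radius) and therefore cannot express "touching" on a fixed scale. Increasing
τ can only add contacts (monotonicity is tested).

Default per-channel parameters (`default_tissue_config`) follow the
structures being segmented: σ = 1 px smoothing for nuclear channels (keeps
adjacent nuclei separate), σ = 1.5 px for the broad SCA1 area, σ = 1 px for
thin desmin protrusions; Otsu throughout. All are configurable; no claim is
made that they are bit-compatible with the original Fiji/Jython scripts,
whose numeric settings are not published.

## The organoid analyzer

Focus selection maximizes the normalized variance (variance/mean²) of the
brightfield channel across z; ties go to the lowest slice. The organoid
footprint is the largest 8-connected component of
Triangle-thresholded smoothed local variance (circular window, radius 4 px
default). Because the variance window spreads texture past the true edge by
its radius and the smoothing extends that skirt by about 2σ, the mask is
eroded back by `radius + 2σ` ("edge compensation", on by default); on
synthetic ellipses this brings the area error from ≈ +14% to ≈ −4%.

GFP is segmented by Otsu on the smoothed channel, tomato clusters by Kapur
on a DoG band-pass (σ 2/8 px default) with a minimum-area filter. The area
filter acts on the segmented band-pass blob, which the DoG spreads by
roughly σ_small beyond the physical cluster — the cutoff (default 20 μm²)
should be chosen with that spread in mind.

A histogram threshold always splits even a pure-noise channel (the optimal
Otsu split of a Gaussian yields a fg−bg contrast of ≈ 1.6σ), so fluorescence
masks are accepted only when the contrast exceeds `min_contrast_sd` (default
4) background standard deviations. This is the same motivation as the
distance pipeline's intensity gate, and it is what makes a planted
GFP-fraction of 0 recoverable as 0 on noisy renders.

GFP intensity is reported two ways, because "normalized to total area" is
ambiguous: `gfp_mean_intensity_norm` divides the integrated GFP intensity
inside the organoid by the organoid area (so a uniform level g reads back
as g), and `gfp_mean_intensity_norm_total` divides by the whole-image area.

## Synthetic scenes

**Tissue.** A portal tract is emulated as a ring of ductal (OPN⁺) nuclei
(radius 2.5 μm default, edge gap 4 μm) around the portal-vein centre, with
mesenchymal nuclei (radius 1.5 μm) placed around the duct at log-normal
surface distances. `planted_distance_um` is the exact distance from the
mesenchymal nucleus centre to the nearest duct-nucleus boundary — the same
quantity the signed-EDT pipeline measures, which is what makes parameter
recovery well-posed; the radial distance from the tract centre is stored
separately. Each cell's distance is drawn once (truncated to the
geometrically feasible window) and only its angular placement is
rejection-sampled, so packing constraints do not bias the planted
distribution; placement failure raises an explicit "field too crowded"
error. Defaults emulate homeostasis: median 8 μm, log-σ 0.4, 93% of duct
nuclei contacted, 0.3 Msc per DC. The log-σ of 0.4 is a realism choice (it
gives an interquartile spread of roughly 6–11 μm around an 8 μm median);
the study conditions fix only the median.

Desmin protrusions connect a mesenchymal cell to each contacted duct
nucleus, routed along an arc held 4 μm clear of the duct surface on the
cell's own side of the ring and terminating 0.25 μm inside the target
boundary. The routing guarantees that non-contacted nuclei stay ≥ ~3 μm
from every polyline, so the planted contact flags are unambiguous at the
default τ.

**Organoid.** An ellipse (semi-axes 55 × 40 μm default) with a concentric
GFP sub-ellipse whose axes are scaled by √fraction (analytically exact area
fraction), disjoint tomato-cluster disks placed well inside, and a z-stack
with one uniformly drawn in-focus slice.

**Rendering.** Objects are painted as anti-aliased disks of their stated
radius (protrusions as ≤ 2 px lines) and blurred with a Gaussian PSF proxy
(σ = 1 px default). A blurred disk's half-maximum contour sits at the disk
edge, so threshold segmentation recovers the stated areas and the 5 μm²
filter acts on the planted geometry — this is why nuclei are disks rather
than Gaussian blobs. Brightfield texture is smoothed white noise confined
to the organoid; out-of-focus slices are blurred with σ growing linearly in
|z − focus|. Noise follows the standard camera model — Poisson shot noise
on the noiseless signal, then additive Gaussian read noise (σ = 3 default,
signal amplitudes 80–120 over background 10, an 8-bit-confocal-like
regime) — and all randomness flows from one integer seed, making renders
bit-identical per (scene, config).

What the synthetic data does *not* emulate: real PSF structure, 3-D nucleus
shape, intensity heterogeneity within cells, autofluorescence, tissue
deformation, or touching-nucleus clumps that would need instance splitting.
Recovery tests therefore demonstrate the correctness and calibration of the
measurement chain, not segmentation robustness on difficult real tissue.

## Statistics

Quartiles use linear interpolation between order statistics; Tukey whiskers
are the most extreme points within 1.5·IQR of the quartiles, everything
outside is listed as an outlier. Census ratios with zero ductal cells
propagate as NaN (never 0 or ∞) and are excluded from group summaries. The
Mann–Whitney U test is two-sided: the exact null enumerates all C(n, n₁)
group assignments of the midranks (automatic for n₁+n₂ ≤ 20 without ties;
forcible up to 24, valid with ties), with p = P(|U − n₁n₂/2| ≥ observed);
larger samples use the tie-corrected normal approximation with continuity
correction, which matches the reference implementation in scipy and holds
the nominal 5% type-I error within [0.035, 0.065] in null simulations.
Welch's t is a thin wrapper over scipy and included only for convenience.

## Encapsulation model

Independent Poisson loadings λa, λb give closed-form occupancy fractions
(empty / a-only / b-only / both); λ is derived from concentration and
spherical droplet volume, λ = c·(π/6)d³·10⁻⁹ for c in cells/μL and d in μm.
The module is a null model only: it does not represent cell settling,
clumping, or droplet-size dispersion, and concentrations are always passed
explicitly by the caller.

## Reproducibility

No output contains timestamps; provenance JSON records inputs, parameters,
seed and package version, and a SHA-256 manifest covers every artifact, so
a rerun with the same config and seed is byte-identical. The acceptance
script (`scripts/acceptance.py`) recomputes the headline quantities at
moderate problem sizes — single fields of 100 ductal nuclei, 20-scene
organoid sweeps, 10⁵ droplets — chosen so the whole run completes in well
under a minute while keeping sampling error far inside the documented
tolerances.
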