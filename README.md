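# portalquant

Quantification toolkit for the liver portal-tract niche: the spatial
relationship between biliary ductal cells (DCs, marked by osteopontin/OPN)
and the PDGFRα⁺SCA1⁺ periportal mesenchyme (Msc) that wraps them, and for
mesenchyme–ductal ("chimeric") organoid co-cultures built by microfluidic
co-encapsulation.

It is written for microscopists and quantitative biologists who need these
measurements reproducible and testable end to end. Because section and
organoid micrographs of this kind are rarely public, the package ships a
first-class synthetic-data module that generates portal-tract and organoid
scenes with *planted* ground truth (distances, contact flags, ratios, areas)
and renders them to realistic noisy multi-channel TIFF stacks — every
pipeline stage is validated by parameter recovery against those plants.

## What it computes

**Liver Cell Distances pipeline** (`portalquant.distances`). Signal masks
are built per channel from maximum-intensity z-projections with automatic
histogram thresholding and an optional raw-intensity gate (so background-only
fields yield empty masks, not crashes). Double-labelled masks isolate nuclei
of one class (e.g. Hoechst ∧ OPN for ductal nuclei); nuclei smaller than
5 μm² are discarded. Each nucleus *i* is scored by the signed Euclidean
distance transform (EDT) of a target mask *T*:

&nbsp;&nbsp;&nbsp;&nbsp;d(i) = mean over pixels p ∈ nucleus i of sEDT_T(p),&nbsp;&nbsp;
sEDT_T(p) = +dist(p, T) outside, −dist(p, ∂T) inside (μm)

so a nucleus overlapping the SCA1/GFP niche area scores ≤ 0. A nucleus is
called *contacted* when its minimum signed distance to the desmin-protrusion
mask is ≤ τ (default 1 μm).

**Chimeric Organoid Analyzer** (`portalquant.organoid`). Works on the z-slice
of maximal normalized brightfield variance (optimal focus): the organoid
footprint is segmented from smoothed local variance with the Triangle
threshold (largest component), the Hes1-GFP region by Otsu on the smoothed
GFP channel, and discrete tdTomato cell clusters by Kapur's maximum-entropy
threshold on a difference-of-Gaussians band-pass. It reports areas inside
the organoid, the GFP area fraction, and GFP intensity normalized to
organoid area.

**Census & statistics** (`portalquant.stats`). Per-field counts of DC and
Msc classes, the Msc:DC ratio (0.3 : 1 is the homeostatic scale), contacted
percentage, organoid formation efficiency (organoids per 100 seeded EpCAM⁺
cells), fold-change normalization to monocultures, Tukey box summaries
(median, quartiles, 1.5·IQR whiskers, explicit outliers) and a two-sided
Mann–Whitney U test with an exact enumerated null for small samples.

**Droplet co-encapsulation** (`portalquant.encapsulation`). For two cell
types loaded independently into droplets at Poisson means λa, λb
(λ = c·(π/6)d³ for concentration c and droplet diameter d), the fraction of
droplets containing both types is (1−e^{−λa})(1−e^{−λb}); closed form and
seeded simulation are both provided. At λa = λb = 0.28 (70 μm microgels)
the model gives ≈ 6% co-encapsulation.

**Image operators** (`portalquant.imaging`). The shared primitives — max
projection, Gaussian smoothing, DoG, circular-window local variance, 256-bin
histograms with Otsu / Triangle (Zack) / Kapur thresholding, signed EDT and
8-connected components — each tested against independent brute-force oracles.

## Worked example

```bash
echo '{"n_dc": 30, "n_msc": 9, "contact_fraction": 0.93, "field_um": 300}' > tissue.json
portalquant simulate tissue --config tissue.json --seed 7 --out sim/
portalquant distances run --in sim/stack.tif --out fov/
portalquant encapsulate --lambda-a 0.28 --lambda-b 0.28 --n 100000 --seed 7 --out enc.json
```

prints

```
wrote tissue scene with 30 duct nuclei to sim
30 nuclei; median distance 10.21 μm; 93.3% contacted
co-encapsulation: 5.97% of droplets
```

The second line is the per-field summary of `fov/fov.csv`: all 30 planted
ductal nuclei were segmented; their median signed distance to the SCA1/GFP
mesenchyme area is 10.2 μm for this 9-cell mesenchymal field; 93.3% carry a
desmin protrusion contact, matching the planted 93% contact fraction. The
last line is the simulated Poisson co-encapsulation rate at the 0.28/0.28
loading — about 6 of every 100 microgels receive both cell types.
`fov/fov.csv` holds one row per nucleus
(`fov_id,label,x_um,y_um,area_um2,...,mean_signed_distance_um,contacted`),
and every run writes `provenance.json` plus a SHA-256 `manifest.json`;
reruns with the same seed are byte-identical.

The same measurements are available as library calls
(`run_distance_pipeline`, `measure_chimeric_organoid`, `fov_census`,
`occupancy_probabilities`, …); see `docs/methods.md` for the model details
and conventions.

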