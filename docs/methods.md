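# Methods

## Scene model and forward simulation

A phantom is a list of cells on a pixel grid (pixel-centred, 0-based,
row-major; polygons as (x, y) = (column, row)). Each cell is an
ellipse-like blob: an ellipse with the sampled area A and aspect ratio q
(semi-axes a = √(Aq/π), b = √(A/(πq))), perturbed radially by cosine
harmonics m ∈ {3, 4, 5} with amplitudes ≤ 0.04 and renormalised so the
enclosed area stays A. Harmonics of order ≥ 3 leave the second central
moments unchanged to first order, which keeps the recorded aspect ratio
equal to the measurable one; an m = 2 term would itself be an elliptical
deformation and was deliberately excluded. Cells are placed by rejection
sampling on bounding circles, so they never overlap; failure to place
raises an error naming the class.

Per-cell morphology is drawn from class-specific normal distributions
truncated at ±3 sd (and at physical lower bounds). Defaults, chosen to
encode the morphological contrasts the protocol exploits:

| class      | area (px²) | aspect ratio | height peak (nm) | substrate gap (nm) |
|------------|-----------:|-------------:|-----------------:|-------------------:|
| progenitor | 800 ± 150  | 2.5 ± 0.4    | 1300 ± 150       | 80 ± 30            |
| neuron     | 600 ± 120  | 2.8 ± 0.5    | 1500 ± 200       | 500 ± 80           |
| astrocyte  | 2500 ± 400 | 1.3 ± 0.15   | 400 ± 80         | 30 ± 15            |

What matters is the ordering, not the absolute values: astrocytes are
larger and rounder than neurons, flat (little phase delay) and adherent
(strong evanescent contrast); neurons are tall and lifted off the
substrate; progenitors sit in between and are visible to both channels.
Heights follow a dome profile h_peak·√(1 − ρ²) over the
boundary-normalised elliptical radius ρ; the substrate gap is uniform per
cell. The truncation also keeps the scene inside the reconstruction's
|E1| < |E0| validity region (below).

**Optics defaults**: λ = 660 nm, δ = π/2, 4 steps, n_medium = 1.33,
n_cell = 1.38, penetration depth d = 150 nm (midpoint of the
hundreds-of-nanometres evanescent scale), background intensity 1,
additive Gaussian intensity noise (default 0). The refractive indices are
assumptions — typical cytoplasm against culture medium — and are
configurable; only their difference enters the height conversion.
Poisson shot noise is deliberately omitted so round-trip tolerances stay
analytic; additive Gaussian noise covers the qualitative role.

**QPC forward model.** The scene is a thin phase-amplitude object
t = a·exp(iθ) with θ = 2π·Δn·h/λ and a the per-cell amplitude
transmittance (drawn from (0.93, 1)). The zero order is the spatial mean
of t — the Zernike picture of an unscattered background wave — and the
scattered field is t minus that mean, pointwise. The global phase is
rotated so the zero order is real; an interferometer has exactly this
freedom in choosing its phase origin. Frames follow the two-beam
interference law with additive noise, clipped at zero. If the scene is so
strong that |E1| ≥ |E0| anywhere, the renderer raises rather than
silently violating the disambiguation assumption the reconstruction
rests on.

Because the zero order carries the mean scene phase, the reconstructed θ
is offset from the ground-truth θ by that constant. `phase_delay` offers
`reference="background"`, which subtracts the median θ over the
lowest-|E1| decile of pixels (pure background in any sparse scene); after
re-referencing, noiseless round trips recover θ to ~10⁻¹⁵ rad. No phase
unwrapping is performed; default scene heights keep |θ| < π/2 so height
maps are unambiguous.

**TIRM forward model.** I = I_bg outside cells and
I_bg·(1 − c_max·exp(−z/d)) inside, with coupling constant c_max = 0.9 by
default. Only the decay scale d is physically grounded; the exponential
frustrated-TIR law and c_max are explicit simplifications, so
quantitative gap-contrast values are model-internal. The model is
strictly monotone in the gap, which is the property the channel's
biological reading relies on.

## Reconstruction numerics

Four-quadrant `atan2` replaces the single-argument arctangent throughout
(standard phase-shifting practice; atan cannot cover (−π, π]). The
product estimate P = √((I3−I1)² + (I0−I2)²)/4 carries a 1/4 that the bare
difference formulas require for the quadratic u² − Su + P² = 0 to return
the true squared amplitudes (I0 − I2 = 4·E0·E1·cos Δφ, I3 − I1 =
4·E0·E1·sin Δφ). Noise can push the discriminant S² − 4P² below zero;
such pixels are clipped to a double root E0 = E1 = √(S/2), counted, and
logged. The same convention covers exact E0 = E1 ties.

## Autofocus

Local Shannon entropy of the gray-level histogram in a 9 × 9 window,
image quantized to 256 levels over its min–max range, replicate-edge
padding (both unspecified by the procedure the filter follows; exact
entropy values are therefore implementation-defined, the selected plane
is insensitive). Counts use per-level integer summed-area tables, so the
map matches a naive per-pixel histogram bit for bit. The best plane is
the argmax of the per-plane mean entropy, ties to the lowest index
(logged). Mean entropy decreases monotonically with blur in the
noise-suppression regime (Gaussian σ up to ~1 px on the synthetic
textures); far beyond it the comparison flattens, which is a known limit
of histogram-entropy focus metrics — plane selection is unaffected in all
tested stacks.

## Morphometry

The manual-tracing workflow is simulated: ground-truth polygons are drawn
as 1-px closed contours, located with a 3 × 3 Sobel filter, binarised
(Otsu on the gradient magnitude by default, overridable), hole-filled
morphologically, and reduced to the largest 8-connected component. The
Sobel response of a 1-px trace spans ~3 px, so the filled mask overhangs
the traced boundary by about its half-width; `measure_roi` compensates
with a single binary erosion, which matters most for small elongated
cells whose minor axis the band would otherwise inflate. Area is the
pixel count; axis lengths are 4·√(eigenvalues) of the coordinate
covariance with a +1/12 unit-square correction per axis — the convention
of the common region-analysis routines, adopted for comparability. For an
axis-aligned discrete rectangle the correction makes the axes exactly
4L/√12, so its aspect ratio is exact.

## Statistics

**Boxplots** use linear-interpolation quantiles (conventions differ at
small n, so the choice is stated), 1.5·IQR whisker fences, outliers
returned individually.

**Rank-sum test**: midranks for ties; W is the rank sum of the smaller
sample (of x at equal sizes); p from the normal approximation with
tie-corrected variance and ±0.5 continuity correction; for pooled sizes
≤ 12 the exact null distribution is enumerated (every rank assignment
equally likely) and the two-sided p doubles the smaller tail including
the observed point mass, capped at 1. The approximation tracks the exact
p to < 0.02 wherever the exact p ≤ 0.1 — the region where a 5% decision
could hinge on it; near the centre of the discrete null no smooth
approximation can follow the point-mass jumps, so no uniform bound
exists. No multiple-testing correction is applied across days: each day
is tested on its own, matching the per-day protocol.

**k-means** (k = 2, Lloyd, 20 seeded restarts, best inertia) runs on
z-scored (median area, median aspect ratio) by default: raw pixel areas
(~10²–10⁴) would dominate the squared Euclidean distance over aspect
ratios (~1–3). `standardize=False` gives the raw-feature behaviour.
Cluster naming uses the score z_area − z_aspect_ratio: the higher-scoring
cluster (large and round) is astrocyte-like — a total order even if the
two defining conditions ever disagreed.

**Division day**: the smallest day from which rejection persists for all
later days, requiring both metrics by default (`division_rule="any"`
relaxes to either). The persistence requirement makes isolated early
false positives harmless unless they occur on the last pre-division day.

## Campaign design

The default 15-day schedule places 40 progenitors/day on a 900 × 900 grid
for days 1–5 and 14 neurons + 14 astrocytes/day for days 6–15. ROI export
emulates the analyst tracing what is visible per channel: TIRM ROIs need
evanescent contrast exp(−gap/d) ≥ 0.2, QPC ROIs a peak phase delay
≥ 0.35 rad. Under the defaults these rules make neurons QPC-only and
astrocytes TIRM-only with certainty, while progenitors qualify for both
and are assigned to exactly one channel by a seeded split — keeping the
two per-day samples disjoint and independent, as the rank-sum test
assumes (tracing the same cell in both channels would make them paired).

Stage seeds derive from the master seed by SHA-256 over
(master, stage, day), truncated below 2³¹ — stable across platforms and
call order. The metrics-level campaign (`simulate_metrics`) runs the
whole phantom → trace → segment → measure chain without rendering optical
images; the rendering path is exercised by `run_experiment` and by the
reconstruction round-trip tests. The repeated-seed recovery test uses the
metrics-level path at 100 seeds, a problem size chosen to keep the suite
at desk scale while leaving the Monte-Carlo margin wide (observed: 99/100
seeds recover division day 6 with a perfect modality split; the single
failure was a day-5 double false positive of the null tests, an expected
event at the 5% level).

## What the synthetic data does not show

The generator produces isolated, simply-connected, dome-profiled cells
with class-wise independent morphology draws and uniform substrate gaps.
Real cultures have touching and overlapping cells, processes and
lamellipodia, intra-class correlations, focal-adhesion-patterned gaps,
shot noise, and optical artifacts (halo, shade-off, aberrations) that are
all out of scope here. Passing tests therefore validate the computational
chain — reconstruction, measurement, statistics — not the biological
discriminability of real cell populations, which depends on effect sizes
the simulation fixes by construction.

## Known limitations

- No phase unwrapping; heights are ambiguous beyond |θ| = π.
- No diffraction/PSF/coherence modelling; the forward model is a thin
  phase-amplitude object under ideal imaging.
- The TIRM gap-contrast law is a one-parameter simplification.
- Manual tracing is replaced by ground-truth polygons; real-image ROIs
  are accepted as external JSON but no automatic segmentation exists.
- The discrimination protocol operates on per-day medians, not individual
  cells; k is fixed at 2 by hypothesis.
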