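# Methods

## Problem and model

A membrane protein such as E-cadherin concentrates, in healthy epithelia,
in a narrow ridge along cell–cell contacts; mislocalizing variants show a
weaker membrane signal and may accumulate in cytoplasmic compartments
(e.g. perinuclear retention in the endoplasmic reticulum). The package
quantifies this from two-channel immunofluorescence by reducing cells to
1D intensity profiles rather than attempting whole-cell segmentation:
when the membrane signal is weak the cell outline is precisely what
cannot be segmented reliably, whereas nuclei (counterstained) always can.

Two profile geometries cover complementary territory. The internuclear
(IN) profile samples the protein channel along the segment joining the
nucleus centers of two contiguous cells; it crosses both cytoplasms and
the shared membrane, which for similar-sized cells lands near position
0.5 of the length-normalized axis. The radial (RD) profile samples rays
from one nucleus center at evenly spaced angles and covers the cytoplasm
off the internuclear axis. All profiles are resampled to L = 100 samples
on the inclusive grid x_j = j/(L−1) (linear interpolation), which makes a
length-100 profile pass through unchanged and preserves the endpoints and
extremes of monotone profiles.

## Segmentation

Nuclei: Gaussian pre-smoothing (sigma 1 px), Otsu binarization, then
watershed on the negated Euclidean distance transform, seeded at distance
maxima separated by at least 5 px; every connected component is
guaranteed a seed, so watershed can only split components, never merge
them. Components under `min_area` = 30 px² are dropped; survivors are
relabeled 1..K with geometric (intensity-unweighted) centroids, since
profiles are anchored at the geometrical centers of the nuclei. Otsu is
computed from the histogram (native 256 levels for 8-bit or small-integer
data; 256 equal bins otherwise) with ties broken toward the lowest
threshold; the returned value realizes the optimal split as
`pixels > threshold`. A constant image has no threshold and is an error,
while an image whose foreground all falls below `min_area` yields an
empty label map (K = 0) — an empty field of view is data, not an error.

Operator points are matched to the nucleus containing them, or snapped to
the nearest labeled pixel within `max_snap_distance` = 10 px (distance to
the region, not to the centroid, so large nuclei do not penalize nearby
clicks); anything farther is excluded with a warning and counted.

## Denoising

Fluorescence is photon-limited, so the map noise model is Poisson
(variance proportional to signal). The map is transformed with the
Anscombe variance-stabilizer A(x) = 2√(x + 3/8) — approximately unit
noise SD — smoothed with total-variation (Chambolle) at weight
`strength`, and mapped back with the closed-form exact unbiased inverse
(quartic-in-1/D correction terms), clipped at zero. The `gain` parameter
(photon counts per stored intensity unit) converts intensities to counts
first; with the default 1.0 the stored values are treated as counts.
Default `strength` = 0.5: in the stabilized domain the noise SD is 1, and
this weight more than halves the per-row SD of a constant Poisson map of
mean 50 while leaving step-edge positions (argmax of the discrete
gradient) untouched; the mean bias of the round trip on such maps is
below 2%. `strength` = 0 bypasses the transform entirely.

## Geometric compensation

Cell-to-cell variation in size, shape and nucleus position shifts the
membrane peak horizontally between columns of the map. Compensation warps
each column with a monotone piecewise-linear map w(0)=0, w(1)=1 with
`n_knots` = 5 interior knots at k/6, each displaced at most
`max_shift` = 0.15 on the normalized axis (knots may not cross; minimum
spacing 10⁻³). Fitting is blockwise coordinate descent in a penalized
least-squares (MAP) formulation: data term = squared distance between the
warped column and the current row-mean profile; prior = quadratic penalty
on knot displacements with weight `smoothness` = 10⁻⁴ (scaled by the map
power, so the prior is scale-equivariant and breaks ties toward small
warps). Columns are updated Jacobi-style against the previous iteration's
mean, making the result independent of column order. Per knot the
displacement is chosen from a symmetric 17-point candidate grid (plus the
current value and zero), candidates ordered smallest-displacement-first
so equal objectives resolve to the least deformation.

Because the current warp is always a candidate, the penalized objective —
Σ_rows (across-column variance) + prior — never increases; this is
asserted at every iteration. Convergence: relative objective decrease
below `tol` = 10⁻⁴ or 50 iterations. On simulations with known uniform
column shifts of ±5 normalized units the composed warps recover the
shifts with mean absolute error well under 1.5 units (under 2 units with
Poisson noise at 10 counts/unit), reduce the alignment variance by over
90%, raise the peak of the mean profile, and shrink the per-row SD — the
variance-reduction and peak-sharpening behavior the method exists for.

Order of operations is denoise → compensate; both stages are exposed as
scikit-learn transformers (`PoissonMapDenoiser`, `GeometricCompensator`,
profiles as rows) so they compose with sklearn pipelines and
model-selection tooling, and as functional wrappers over `ProfileMap`
objects (profiles as columns) inside the pipeline.

## Statistics

Features are computed per individual compensated profile and then
summarized (mean ± SE = SD/√n), so population tables carry the number of
profiles, not the number of images. Membrane mean fluorescence averages
the samples at positions 0.5 ± `membrane_window` (default 0.05, i.e. 11
of 100 samples — how wide the "membrane" window should be is a judgment
call, so it is config-exposed). MMR = max/mean is ≥ 1 with equality only
for constant profiles and is invariant to intensity rescaling, making it
comparable across staining batches.

Mann–Whitney U is two-sided. When both samples have ≤ `exact_max_n` = 8
observations the p-value is exact: all C(n_a+n_b, n_a) group labelings of
the pooled midranks are enumerated and p = P(|U′ − n_a n_b/2| ≥
|U_obs − n_a n_b/2|), which handles ties naturally; larger samples use
the tie-corrected normal approximation. Bonferroni's denominator is the
total number of tests in the batch (populations × features), reported
explicitly in every result row since the corrected threshold is only
interpretable with its denominator.

## Virtual cell

Per-angle mean compensated RD profiles form an A×100 polar matrix,
rendered onto a disk of fixed radius 100 px by inverse polar mapping with
bilinear interpolation in angle (wrap-around) and radius; radial sample i
maps to radius i/99·100, pixels beyond the disk are background, and the
center pixel is the mean of the radius-0 samples. The fixed radius is
deliberate: the virtual cell shows the population-typical distribution on
normalized geometry, excluding per-cell morphology. Angles are
compensated independently (each angle's columns are one alignment
problem); reconstruction from per-angle averages rather than averaging
per-cell reconstructions is a design choice — it weights every cell
equally per angle and keeps each alignment problem small. Contrast
enhancement is a 1st–99th percentile linear stretch over the disk pixels
(rank-preserving up to clipping ties); a constant disk is returned
unchanged with a flag. Virtual cells are qualitative renderings only —
all quantitative claims go through the profile statistics.

## Synthetic data generator

The generator emulates a confluent epithelial monolayer: cells are
Voronoi regions of a hexagonally offset grid of seed points jittered by
`shape_jitter` (hexagonal packing is the natural geometry of confluent
epithelia and keeps cells roughly isotropic), each with a disk nucleus at
a jittered interior point. The protein channel is a cytoplasm baseline
plus a Gaussian ridge along inter-cell boundaries (sigma =
`membrane_thickness_px`/2 = 2 px, so profiles have finite-width membrane
peaks) and, optionally, a perinuclear Gaussian annulus centered at
`perinuclear_peak_position` of the nucleus-center-to-membrane distance
(u = d_center/(d_center+d_boundary)), emulating endoplasmic-reticulum
retention. Poisson noise is drawn as photon counts at `photon_scale`
(default 10 counts per intensity unit) and rescaled. The default study
conditions are membrane amplitude 100 (wild-type-like) vs 40 with a
perinuclear peak of amplitude 80 at position 0.8 (mutant-like), baseline
20, on 49-cell 512×512 scenes (≈120 adjacent pairs), jitter 0.2. A single
integer seed drives all randomness; identical inputs give bit-identical
TIFFs.

What the generator does *not* emulate: point-spread-function blur, uneven
illumination, chromatic aberration, 3D structure, nuclear exclusion of
the cytoplasmic signal, or biological covariance between cell shape and
expression level. Passing tests therefore demonstrate that the algorithms
recover the localization phenotypes they model under realistic photon
noise and geometric variability — not that any specific real cell line
would produce particular values.

## Analysis choices and degenerate inputs

- IN axis spans centroid to centroid (nucleus points are what operators
  click); whether the membrane falls exactly at 0.5 depends on relative
  cell sizes, which is exactly what compensation absorbs.
- RD ray length is a fixed per-population config value rather than
  per-cell boundary detection (membranes are unreliable in mutants). For
  synthetic studies a good choice is the median nucleus-to-membrane
  distance over cells and angles divided by 0.95
  (`synthetic.median_membrane_distance`), so rays end just past the
  typical membrane crossing; compensation then aligns the residual
  spread. Rays leaving the image are excluded and counted; cells whose
  rays cannot all fit are excluded from the radial analysis.
- Profile maps with a single column cannot be compensated (error); their
  summary SD is reported as zeros with `sd_defined=False`.
- Every exclusion (unmatched point, invalid segment, clipped ray) is
  logged with a reason; used + excluded always equals the input count.
- Problem sizes in the shipped tests and the acceptance script (49-cell
  scenes for internuclear statistics, 25-cell scenes with 24 angles for
  the radial/virtual-cell analysis, 50-column alignment simulations) were
  chosen as the smallest populations at which the statistics are stable;
  all scale linearly if larger studies are needed.

## Known limitations

- The compensation's discrete candidate grid bounds warp resolution to
  max_shift/8 ≈ 2 normalized units per knot step; sub-grid alignment
  comes only from the piecewise-linear interpolation between knots.
- The denoiser smooths the map as a 2D image, coupling neighboring
  columns; with very few columns this borrows statistical strength but
  can bleed structure between dissimilar profiles.
- Bonferroni is conservative for correlated features (membrane mean and
  MMR are correlated); no FDR alternative is currently wired in.
- The exact Mann–Whitney path enumerates C(n_a+n_b, n_a) labelings and is
  kept to small samples by `exact_max_n`.
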