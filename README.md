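# profilecad

Quantification of the level and spatial distribution of a membrane protein
(the motivating case is E-cadherin, whose missense variants can lose
membrane localization and accumulate in the cytoplasm) from two-channel
*in situ* immunofluorescence images: a DAPI-like nuclear counterstain and a
protein channel.

Visual inspection of immunofluorescence is qualitative and
operator-dependent. `profilecad` instead reduces each selected cell (or
pair of contiguous cells) to a 1D fluorescence intensity profile, aligns
profiles across a morphologically heterogeneous population, and summarizes
membrane localization with two per-profile statistics that can be compared
between cell lines. It is aimed at groups doing variant characterization or
any protein-mislocalization phenotype who want numbers instead of
impressions, without needing whole-cell segmentation (which fails exactly
when the membrane signal is lost).

## Method

1. **Cell selection.** Operators provide nucleus click-points in a CSV
   (semi-automated workflow); nuclei are segmented by Otsu thresholding +
   distance-transform-seeded watershed, and each point is matched to a
   nucleus whose *geometric center* anchors the profiles.
2. **Profile extraction.** Two geometries:
   *internuclear* (IN) — intensity sampled by bilinear interpolation along
   the segment joining the nucleus centers of two contiguous cells, so the
   shared plasma membrane appears near position 0.5 of the normalized
   axis; *radial* (RD) — rays from a nucleus center at `n_angles` evenly
   spaced angles. Every profile is resampled to a constant length of
   L = 100 arbitrary units.
3. **Map building and denoising.** Profiles are stacked as the columns of
   an L×N map M. Fluorescence noise is treated as Poisson: M is
   variance-stabilized with the Anscombe transform A(x) = 2√(x + 3/8),
   smoothed with an edge-preserving total-variation prior, and inverted
   with the closed-form exact unbiased inverse.
4. **Geometric compensation.** Each column j is warped by a monotone
   piecewise-linear map w_j with fixed endpoints and bounded knot
   displacements, fitted by penalized least squares against the evolving
   row-mean profile, minimizing the across-column (horizontal) variability
   Σ_x Var_j M(x, w_j(x)). This aligns the membrane peak across cells of
   different sizes and shapes; the objective is provably non-increasing.
5. **Statistics.** Per compensated profile p:
   membrane mean fluorescence = mean of p on positions 0.5 ± 0.05, and
   **MMR** (maximum mean ratio) = max(p) / mean(p) ≥ 1, a scale-invariant
   measure of membrane-peak sharpness. Populations are compared
   feature-wise with two-sided Mann–Whitney U tests (exact by enumeration
   for small samples) under Bonferroni correction.
6. **Virtual cell.** Per-angle average compensated RD profiles form a
   polar matrix that is inverse-polar-mapped into a qualitative 2D
   "typical cell" image (plus a percentile-stretched contrast-enhanced
   version).

A fully parameterized synthetic-data generator (`profilecad.synthetic`)
renders confluent monolayers — jittered hexagonal Voronoi cells with
membrane ridges, optional perinuclear accumulation at a chosen fraction of
the nucleus-to-membrane distance, and Poisson photon noise — with complete
ground truth, so the whole pipeline is testable without microscope data.

## Worked example

Simulate a wild-type-like and a mutant-like population (mutant: membrane
amplitude 40 vs 100, perinuclear accumulation at 0.8 of the
nucleus-to-membrane distance), then run the full pipeline:

```bash
profilecad simulate --n-cells 25 --phenotype wt     --shape 384 384 --seed 1 --out demo/wt
profilecad simulate --n-cells 25 --phenotype mutant --shape 384 384 --seed 2 --out demo/mutant
echo '{"n_angles": 24, "ray_length": 44.0, "seed": 1}' > demo/config.json
profilecad run --config demo/config.json \
    --population WT:demo/wt/nuclear.tif:demo/wt/protein.tif:demo/wt/selections.csv \
    --population mutant:demo/mutant/nuclear.tif:demo/mutant/protein.tif:demo/mutant/selections.csv \
    --reference WT --out demo/run
cat demo/run/report/report.txt
```

```
Population summary (membrane mean fluorescence and MMR, mean +/- SE)

            WT  n=56    membrane mean  5687.38 (+/-18.360)  MMR  4.220 (+/-0.0108)
        mutant  n=56    membrane mean  3114.27 (+/-12.477)  MMR  2.918 (+/-0.0077)

Pairwise Mann-Whitney tests vs reference (Bonferroni-corrected)

        mutant vs WT  membrane_mean  U=       0.0  p=7.402e-20  alpha_corr=0.0250 (2 tests)  SIGNIFICANT
        mutant vs WT  mmr            U=       0.0  p=7.402e-20  alpha_corr=0.0250 (2 tests)  SIGNIFICANT
```

Each population contributed 56 internuclear profiles (one per adjacent
cell pair in the tessellation). Membrane mean fluorescence is in stored
TIFF intensity units (divide by the `intensity_scale` in the fixture
manifest, 64, to get generator units: 88.9 vs 48.7); MMR is dimensionless
and scale-invariant. The mutant population shows both the reduced
membrane signal and the blunter membrane peak (lower MMR), and both
differences are significant at the Bonferroni-corrected threshold
0.05 / 2 = 0.025. Per-population outputs under `demo/run/<population>/`
include the raw and compensated profile maps (CSV), fitted warps (JSON),
average ± SD profiles, per-profile features, and the virtual-cell PNGs.

The same stages are available programmatically; the denoiser and the
compensator are scikit-learn transformers:

```python
from sklearn.pipeline import Pipeline
from profilecad import PoissonMapDenoiser, GeometricCompensator

aligner = Pipeline([("denoise", PoissonMapDenoiser(gain=10.0)),
                    ("align", GeometricCompensator(n_knots=5, max_shift=0.15))])
aligned = aligner.fit_transform(profiles)   # (n_profiles, 100)
```

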