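# eosiquant

Quantification of lipid bodies (LBs) in eosinophils and eosinophil-like
cells (EoL-1) across three label-free/fluorescence imaging modalities:

* **CARS** — coherent anti-Stokes Raman scattering micrographs tuned to the
  2850 cm⁻¹ CH₂ stretch, where LBs appear as bright 2–20 px spots: a fixed
  operator chain (rolling-ball background subtraction, Laplacian of
  Gaussian, FFT bandpass, 8-bit inversion, Rényi-entropy or relative-mean
  thresholding, circularity/area particle gates) yields a spot set, and a
  trainable pixel classifier plus mask cleaning attaches per-cell counts.
* **Fluorescence** — Hoechst-stained nuclei (area > 5 µm²) and
  BODIPY-stained LBs (area > 2 µm²) counted per image; LBs/cell reported as
  mean of image means ± SEM, with a multi-parametric morphology profile
  (area, roundness, symmetry, compactness, intensity) and exact
  Mann–Whitney group comparisons.
* **Raman** — hyperspectral cubes despiked (filter size 3, dynamic factor
  8), baseline-corrected (iterative polynomial, degree 3), segmented by
  k-means into cytoplasm / LB / nucleus / background, and summarized by the
  lipid-unsaturation ratio I(1660)/I(1440) calibrated against fatty acids
  of known C=C count, per-group ANOVA with Dunnett comparisons, and PCA of
  cytoplasm spectra in the 600–1800 cm⁻¹ fingerprint region.

Because per-cell LB counts are heavily tied small integers (most cells show
no LB in the focal plane), dispersion is summarized by nearest-rank
percentiles (percent-rank analysis) rather than standard deviations.

A first-class synthetic-data module generates CARS/TPEF scenes,
two-channel fluorescence scenes, fatty-acid reference spectra and Raman
cubes with exact ground truth, so every stage is verifiable by parameter
recovery: generate data with a known per-cell LB law (or a known mean C=C
count), run the full pipeline, and check the estimate against the truth.

## Core quantities

* Particle circularity gate: 4πA/P² ≥ 0.5, area within
  [(2 px)²π/4, (20 px)²π/4].
* Cell cleaning: holes < 500 px filled, distance-transform watershed,
  cells < 2500 px or touching the frame edge excluded (fully audited).
* Unsaturation: the integrated 1660 cm⁻¹ (ν C=C) / 1440 cm⁻¹ (δ CH₂) band
  ratio is linear in the number of C=C bonds; the calibration line fitted
  on oleic (18:1), linoleic (18:2) and α-linolenic (18:3) references is
  inverted to estimate the mean double-bond count of LB lipids.

## Worked example

```bash
python examples/per_cell_counts.py
```

prints (exactly, for the seed baked into the script):

```
cells retained:   25 (of 25 candidates)
spots assigned:   54 (+0 orphaned off-cell)
mean LBs/cell:    2.16   (generating mean 1.94)
median:           2
25-75 pct range:  (1.0, 3.0)
5-95 pct range:   (1.0, 4.0)
zero fraction:    0.04
```

Here 25 synthetic cells were generated with per-cell LB counts drawn from
a Poisson law of mean 1.94; the full chain (pixel classifier → mask
cleaning → LB detection with the Rényi threshold → centroid assignment)
recovers a group mean of 2.16 LBs/cell, consistent with the generating
law at this sample size, and the percent-rank summary shows the tied,
skewed count distribution the analysis is designed for.  The other
scripts in `examples/` demonstrate spot detection alone, the fluorescence
ratio + Mann–Whitney comparison, and the Raman segmentation +
unsaturation calibration.

A thin CLI mirrors the library (`eosiquant simulate | cars-detect | cells |
fluor | raman | stats | run`); see `eosiquant --help`.

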