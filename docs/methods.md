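# Methods

This note documents the models, parameter choices and numerical decisions
behind eosiquant, and what the synthetic-data experiments do and do not
demonstrate.

## CARS lipid-body detection

The detector is a fixed, auditable chain; every stage records its
parameters in the resulting `SpotSet`.

1. **Rolling-ball background subtraction** (radius 3 px) via the classic
   ball construction (`skimage.restoration.rolling_ball`).  With a 3 px
   ball, structures wider than the ball are partially flattened — a large
   LB can come out of the chain as a ring rather than a filled disk.  This
   is inherent to the protocol's small ball radius and is compensated at
   the particle-measurement stage (below).
2. **Laplacian of Gaussian** (smoothing scale σ = 1 px), realized as
   Gaussian smoothing followed by the discrete 4-neighbour Laplacian, so
   the operator is linear and separable-testable.  Bright spots give a
   negative response at their centres.
3. **FFT bandpass** passing spatial periods between 2 and 20 px.  The
   transfer function is a product of two Gaussian roll-offs with half
   amplitude exactly at each band edge; DC is removed exactly.  The exact
   windowing of the reference implementation is not documented anywhere,
   so the profile is configurable; a sinusoid of period 8 px passes within
   10 %, one of period 60 px is attenuated below 10 %.
4. **Inversion + 8-bit quantization**: min–max rescale to [0, 255] then
   v → 255 − v, so the most negative Laplacian response (spot centres)
   maps to 255.  Rescaling before inversion makes double inversion an
   exact involution on the 8-bit result and is threshold-equivalent to the
   opposite order.  A constant image maps to all zeros by convention.
5. **Global threshold** — either the Rényi-entropy method (the
   Sahoo–Wilkins–Yeager three-order combination: thresholds maximizing the
   two-class Rényi entropy sum at orders ½, 1, 2, blended by the published
   weighting rule; this matches the behaviour of the widely used 8-bit
   auto-threshold implementation) or 1.4 × mean brightness of the image
   being thresholded.  Ties at the threshold go to background (strict
   `>`).  The mean for the relative threshold is computed on the inverted
   8-bit image, i.e. the image actually being thresholded; this choice is
   recorded in the configuration.
6. **Particle filtering**: 8-connected components; circularity
   4πA/P² clamped at 1.0; retained when circularity ≥ 0.5 and area within
   [(2 px)²π/4, (20 px)²π/4].  The perimeter is a Crofton estimate **on
   the hole-filled component**, i.e. the outer contour only — this mirrors
   particle analyzers that trace the outside boundary of each particle,
   and it is what keeps ring-shaped responses of large LBs (see stage 1)
   countable as one round particle.  Every excluded candidate is recorded
   with its reason.

## Cell segmentation and per-cell counts

The CARS and TPEF channels are composed into an RGB image (red: CARS,
green: TPEF, blue: 0) after contrast stretching with 3.5 % total
saturation (1.75 % per tail).  A supervised per-pixel model — a random
forest over a multi-scale filter bank (Gaussian intensity, gradient
magnitude and Hessian-eigenvalue texture at σ ∈ {1, 2, 4, 8} per channel,
via `skimage.feature.multiscale_basic_features`) — is trained on labelled
composites and thresholded at probability 0.5.  Because the per-image
contrast stretch makes absolute channel levels depend on scene
composition (an image with many bright LBs maps its cytoplasm lower),
the classifier must be trained on images representative of the dataset it
will segment; the pipeline therefore trains on two labelled images drawn
from the same imaging condition, which is also how the semi-automated
reference workflow was used in practice.

Mask cleaning: holes < 500 px are filled; touching cells are split by a
watershed on the negated distance transform with h-maxima suppression
(h = 2 px, configurable) to avoid oversegmentation of noisy masks;
components whose maxima are all suppressed receive a fallback marker at
their distance maximum, so the watershed can never lose or merge a
component.  Candidates smaller than 2500 px or touching the frame edge
are excluded with an audit reason ("small" / "edge").  Manual correction
is a replayable edit script (`remove` / `merge` / `add` operations);
replaying a script on its own output is a no-op, and references to labels
that never existed fail loudly.

Each detected spot is assigned to the retained cell containing its
centroid — unambiguous for spots straddling boundaries; off-cell spots are
tallied as orphans so that assigned + orphaned = detected always holds.

## Fluorescence quantification

Nucleus detection is Gaussian smoothing (σ = 2 px) + Otsu threshold +
hole filling + distance-transform watershed, with the area > 5 µm² gate
applied in physical units (pixel size required).  Spot detection is a
white top-hat (disk radius 5 px) with a robust-noise threshold
(10 × 1.4826·MAD of the top-hat residual) and the area > 2 µm² gate.  The
reference software's detection internals are proprietary; these are
behaviourally equivalent surrogates with every parameter exposed.

Morphology features per object: area (µm²), roundness 4πA/P² (clamped at
1), **symmetry** = overlap fraction between the mask and its 180°
rotation about the centroid, **compactness** = area / convex-hull area,
object mean intensity, and background-corrected spot intensity (object
mean minus image median).  Symmetry and compactness are named but nowhere
defined by the reference software, so these definitions are documented
surrogates, monotone in the intuitive direction.  Group profiles are
reported relative to a designated reference group (reference mean ≡ 1).

The Mann–Whitney U test uses midranks and, whenever C(n₁+n₂, n₁) ≤
200 000, enumerates the permutation distribution exhaustively; the
two-sided p-value is P(|U − n₁n₂/2| ≥ |u − n₁n₂/2|), exploiting the
symmetry of the permutation distribution (which holds with ties).  Larger
samples fall back to the tie-corrected normal approximation.  Significance
stars (*, **, ***) are mapped at 0.05 / 0.01 / 0.001 on raw p-values, with
no multiplicity correction, matching common figure-caption practice.

## Raman pipeline

* **Cosmic-ray removal** (filter size 3, dynamic factor 8): a sample is a
  spike when its deviation from the 3-sample window median exceeds 8 × the
  local robust scale (a 21-sample running median of absolute residuals,
  floored by a spectrum-wide noise sigma estimated from robust first
  differences).  The local scale keeps the shoulders of genuine narrow
  bands from being flagged, while 1–2-channel spikes stand far above it.
  The filter is idempotent: a second pass on despiked data replaces
  nothing.
* **Baseline correction**: iterative polynomial fitting of degree 3
  (fit, clip points above the fit, refit — the classic modified-polyfit
  scheme).  Convergence is geometric, and the fitted baseline stops
  improving long before the iterate stabilizes pointwise (the residual
  baseline error is dominated by the method's intrinsic bias from ~30
  iterations on), so the stop criterion is the relative change of the
  baseline norm between iterations with tolerance 1e-4 and a 500-iteration
  cap; exhausting the cap raises with diagnostics.
* **Band integration**: trapezoidal integral after subtracting the local
  linear baseline (the chord through the window edges).  Marker windows:
  organic matter 2800–3030, lipids 2830–2900, DNA 780–800 cm⁻¹;
  unsaturation windows 1660 ± 20 and 1440 ± 25 cm⁻¹ (centers are protocol
  values, half-widths are package defaults and configurable).
* **Segmentation**: spectra are vector-normalized (unit area over
  600–1800 cm⁻¹, removing focal-volume intensity differences; switchable),
  clustered by k-means (k = 4 by default — cytoplasm, LB, nucleus plus the
  off-cell background present in any cube; k-means++ init, 10 restarts,
  fixed seed, best inertia kept).  Clusters are auto-labelled by marker
  scores on the un-normalized spectra: highest lipid integral → LB,
  highest DNA integral → nucleus, lowest organic total → background,
  remainder → cytoplasm.  A marker only claims a cluster when its winner
  is decisive relative to a common scale (so a cube without nuclei does
  not mislabel noise), and a cluster decisively winning two markers is an
  error, not a silent choice.
* **Unsaturation calibration**: the 1660/1440 integrated-intensity ratio
  of the generated fatty-acid references is exactly proportional to their
  C=C count by construction, so the least-squares line has R² = 1 to
  machine precision and inverting it on a reference's own ratio returns
  its count exactly; for any nonnegative mixture of references the
  estimate is the mixture-weighted mean count (linearity of integration).
* **Group statistics**: one-way ANOVA (scipy) with Dunnett many-to-one
  comparisons against the control group; star mapping as above.
* **PCA**: mean-centered PCA of per-cell cytoplasm mean spectra restricted
  to 600–1800 cm⁻¹ (per-pixel optional); loadings are sign-fixed so each
  component's largest-magnitude element is positive.

## Percent-rank statistics

Per-cell LB counts are summarized with the nearest-rank percentile
convention: percentile P of n sorted values is the value at 1-based index
⌈P·n/100⌉ (P = 0 returns the minimum).  On heavily tied integer data this
makes percentiles "fall together" on the same count, which is precisely
the behaviour the percent-rank presentation is designed to expose; median,
mean, the 25–75 and 5–95 boxes and the zero-count fraction are reported.

## Synthetic-data model

The generators emulate the statistical structure the analysis assumes, not
the optics:

* **CARS/TPEF scenes.**  Cells are disks (radius 34–42 px) on a jittered
  grid — never overlapping, never touching the frame edge — with textured
  cytoplasm (smoothed Gaussian noise, SD 120 on a base level of 900 counts
  over a background of 100) whose boundary is blurred by σ = 2.5 px, since
  real membranes are diffraction-limited, not 1-px steps.  LBs are
  isotropic Gaussians; "radius" is 2σ, so a thresholded spot covers ≈ πr²
  px and the 2–20 px diameter gate is meaningful.  Default radii are
  3–6 px.  Peak brightness scales as r^2.5 (between cross-section r² and
  volume r³ — a larger droplet puts more lipid into the focal volume) with
  a narrow per-droplet uniform factor (8000–11000 counts at the 4.5 px
  reference radius), so size, not packing density, drives most brightness
  variation.  Spot centres keep a pairwise separation of 2.4 × the larger
  radius (relaxed gradually in crowded cells so the drawn count is always
  honoured).  The TPEF channel holds one Gaussian nucleus per cell.
  Additive Gaussian noise (SD 30) on 16-bit output.
* **Fluorescence scenes.**  Nuclei are smooth disks of 9–12 µm diameter
  (area ≫ the 5 µm² gate); LB spots are Gaussians of 1.0–1.6 µm nominal
  radius (area > 2 µm²) placed in the cytoplasm around each nucleus; the
  default pixel size is 0.65 µm/px.
* **Spectra.**  Components (lipid, protein, DNA, EPO) are sums of Gaussian
  bands at their marker positions (lipid: 2850, 1744, 1660, 1440, 1304,
  1269 cm⁻¹; DNA: 788 cm⁻¹ backbone band inside 780–800; EPO: 753, 1311,
  1374, 1554, 1564, 1588 cm⁻¹) on a 600–3100 cm⁻¹ axis with 2 cm⁻¹ steps.
  Fatty-acid references scale the 1660 and 1269 cm⁻¹ band areas with the
  C=C count and keep 1440 fixed.  Cubes mix components per class, add a
  polynomial baseline (degree ≤ 3), single-channel cosmic-ray spikes with
  recorded positions, and Gaussian noise.
* **Count laws** are pluggable: constant, Poisson, zero-inflated Poisson
  (the zero-inflated law mirrors real per-cell data where the largest
  fraction of cells shows no LB in the focal plane).
* All randomness flows from one explicit seed through a single generator
  stream per scene; identical arguments and seed give bit-identical
  output.  End-to-end runs fan one global seed out to named per-stage
  substreams (SHA-256 of "seed:stage"), so stages are reproducible in
  isolation.

**What passing recovery tests show — and what they do not.**  The
synthetic scenes are high-SNR with isolated, in-focal-plane, in-gate LBs
and cleanly separable cells; recovery of the generating mean therefore
validates the correctness of the operator chain, the gates, the
bookkeeping and the statistics, not the detector's robustness to
out-of-focus LBs, overlapping cells, aggregated droplets, or nonresonant
CARS background — all of which make real counts systematic undercounts, as
single-focal-plane imaging inherently does.

## Verification experiments (problem sizes)

The acceptance script generates 300 cells per CARS condition (the larger
sample narrows the Poisson sampling error of the group mean to ~4 %),
4 × 75 cells per fluorescence condition, and 50 mixture spectra for the
unsaturation recovery; the test suite uses the same designs at 150 cells.
Per-spectrum mixture weights for the unsaturation experiment are drawn
uniformly around the target (spread ±0.25 in the linoleic weight), so the
recovered mean has a genuine, reportable SEM.

## Known limitations

* Single-focal-plane analysis only; no z-stacks.
* The Columbus-/WEKA-/WITec-specific numeric behaviours are replaced by
  documented open surrogates; results are behaviourally, not numerically,
  equivalent to those tools.
* The rolling-ball + LoG chain systematically attenuates LBs near the
  upper size gate (ring responses); counts remain correct, but per-spot
  mean intensities of large LBs are not quantitative.
* `estimate_double_bonds` extrapolates linearly outside the 1–3 C=C
  calibration range.
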