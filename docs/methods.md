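# Methods

## Signal model

The task is a breath-hold (BH) protocol: 60 s of free breathing, then 10
cycles of a 20 s post-expiratory breath hold followed by 40 s of recovery
breathing (660 s total; TR 5 s, 132 frames; 12 breaths/min; capnograph
sampled at 20 Hz).  Apnea raises arterial CO2; the expiratory-plateau
(end-tidal) CO2 pressure PetCO2 is the stimulus proxy.

The hemodynamic forward model is linear and isometabolic:

* CBF: `f(t) = 1 + (CVR_ASL / 100) * dPetCO2(t - lag)`, with `dPetCO2` the
  end-tidal change from rest (mmHg), `CVR_ASL` in %CBF/mmHg, and a voxel
  lag on the ±10 s grid.
* BOLD: `b(t) = (c_micro * v_micro + c_macro * v_macro) * (f(t) - 1)`.
  Because a breath hold barely changes oxygen metabolism, BOLD is treated
  as proportional to the CBF change; the proportionality splits into a
  microvascular term (uniform bed, `v_micro = 0.5`) and a macrovascular
  term whose weight `v_macro` follows a per-ROI venous-density table.  The
  SE weighting's macro share is suppressed (5% of its coupling vs 40% for
  GE) — the refocusing pulse removes static dephasing around large veins.
  No Davis-style nonlinearity is modelled.

The estimator inverts exactly this model class: ordinary least squares of
the filtered percent-change signal on the filtered, lag-shifted PetCO2
regressor, with the lag (grid: integer TR multiples within ±10 s, finer
steps by linear interpolation) chosen to maximise R², ties broken toward
the smaller |lag| and then the negative one.  `z = beta / SE(beta)` is the
confidence score (a `beta / CI-half-width` convention is available in the
run configuration); z of numerically perfect fits is capped at 1e6.  The
regression keeps an intercept (residual DC guard) and applies no
prewhitening — a known limitation, as the surround operations colour the
noise.

## Processing choices

* **Peak detection** — prominence-and-separation local maxima (defaults
  5 mmHg, 2 s).  The end-tidal trace interpolates linearly through peaks
  and holds the nearest peak value beyond the first/last peak, so no
  extrapolation enters the regressor.  During apnea no peaks occur and the
  interpolation bridges the hold with a ramp.
* **Filtering** — zero-phase (forward–reverse) Butterworth band-pass,
  one-way design order 4 (the double pass squares the magnitude response),
  cutoff periods 150 s and 10.1 s, i.e. 6.7–99 mHz against a 100 mHz
  Nyquist.  Reflective ("even") padding of length `min(n-1, 6*order)`
  suppresses edge transients on the 132-frame series; 3×order left visible
  transients.  Order of operations for the regressor: resample at the TR
  grid → shift by the sampling-line delay → filter.
* **Surround stencils** — perfusion: `±(s_i − (s_{i−1}+s_{i+1})/2)`, sign
  positive on control frames; BOLD: `(s_i + (s_{i−1}+s_{i+1})/2)/2`.
  Edge frames fall back to the single available neighbour.  Both stencils
  are second-order: linear drifts (subtraction) and exactly
  parity-alternating contamination (averaging) cancel at interior frames.
* **Design matching** — the stencils act on the data as a temporal
  smoother with average transfer `cos²(π f TR)`; regressing
  surround-processed data on the raw filtered PetCO2 would attenuate beta
  by ~8% under this protocol's stimulus spectrum.  Each candidate lagged
  regressor is therefore passed through the same stencil and band-pass as
  the data before the fit ("filter the design like the data").  Noiseless
  recovery of (beta, lag) is then exact on the lag grid to <0.1% (GE/SE)
  and <0.4% (ASL, limited by the small BOLD-like common mode on the ASL
  frames, a real confound of dual-echo ASL readouts).
* **Fractional change** — voxelwise `(s − m)/m`, `m` the mean over frames
  before 50 s; the perfusion series is normalised by its own baseline
  difference (positive-baseline voxels only; others are NaN-masked and
  counted).
* **Group analysis** — the ASL-confidence mask `{GM, z_ASL > z_thr}` is
  computed per subject and applied to all three weightings.  The
  difference of the two dependent overlapping correlations (GE-vs-ASL and
  SE-vs-ASL share ASL) uses Steiger's Z; multiple comparisons across the
  48 ROIs use Benjamini–Hochberg at q = 0.05.  Bootstrap
  spatial-correlation curves resample subjects with replacement at every
  k, including k = N, with a seeded generator (bit-reproducible).
  Venous-density stratification binarises the 48 ROI values at their 50th
  percentile.

## Synthetic cohort: what it emulates, and what it does not

Subject-level true GM-mean CVRs are drawn from the reported group
distributions — ASL 5.3 ± 1.8 %CBF/mmHg, GE 0.18 ± 0.05, SE
0.09 ± 0.03 % BOLD/mmHg — through a two-factor structure: a shared
vasodilatory factor (loadings 0.55 for GE, 0.75 for SE) and a venous
factor loading only on GE (0.60), which also modulates the subject's
macrovascular coupling share.  This makes part of the GE variance
independent of ASL and concentrated in high-venous-density ROIs, so the
ensemble ordering r(SE, ASL) > r(GE, ASL) — across subjects and across
space — emerges from the generative mechanism rather than being imposed.
PetCO2 rest levels are 35.0 ± 1.4 mmHg; the programmed post-BH rise is
calibrated (factor 1.279) so the filtered-trace 95th–5th percentile range
matches its 6.7 ± 2.1 mmHg target; post-BH end-tidal decay is exponential
with a 15 s constant.  Spatial CVR fields share one smooth pattern
(SD 0.25, GM mean 1) with 15% voxelwise subject noise, renormalised so
each subject's GM mean equals the drawn target exactly.  The grid is
12×12×8 voxels with an ellipsoidal GM mask (~440 voxels) split into 48
parcels; the venous-density table is a fixed right-skewed synthetic atlas
(deterministic internal seed).  Noise is white per frame (defaults: ASL
1.5, GE 9.0, SE 6.5 raw units on a baseline of 1000, i.e. 0.15–0.9%)
plus an order-2 Legendre drift that the 150 s high-pass must remove.

Default noise levels and the lag search interact: at very low SNR the
max-R² lag selection inflates |beta| (at a GM ASL z-mean of ~2.5 the
inflation of the GM-mean ASL CVR is ~18%; ~5% at z ≈ 3.3; ~2% at z ≈ 6.7
— measured on this generator).  The defaults are set where that selection
bias is within the Monte-Carlo tolerance of the recovery experiments
while preserving the SNR ordering z(ASL) < z(GE); the low-SNR regime
remains reachable through `GroundTruth.noise_sd`, and analyses run there
should expect the inflation.  A related, deliberate realism: the recovered
mean ASL CVR increases with the ASL z threshold (selection bias of
confidence masking), which the threshold-curve analysis records.

Not emulated: MR acquisition physics (labeling efficiency, background
suppression, transit times, slice timing), motion and its correction,
susceptibility distortion, registration (all inputs share one voxel
grid), white matter (the perfusion model is unreliable there), CMRO2
changes under hypercapnia, and respiratory-volume effects.  Passing the
recovery suites therefore demonstrates correctness of the estimation
chain under the stated generative model, not robustness to those
real-data effects.

## Problem sizes

The replicate-cohort experiments use 20 cohorts of 20 subjects on the
12×12×8 grid (132 frames), about half a minute of compute in total; the
bootstrap ensemble uses 3 cohorts × 30 iterations per k.  Per-cohort
seeds derive from `SeedSequence(seed).generate_state`, keeping cohorts
statistically independent and every run bit-reproducible.

## Degenerate inputs and numerical conventions

Fewer than two expiratory peaks raises an error (interpolation
impossible); cutoffs at/above Nyquist are rejected; a constant shifted
regressor raises a degenerate-regressor error; an all-zero voxel returns
beta = z = lag = 0; zero across-subject variance in the second-level t-map
yields signed infinity (nonzero mean) or NaN (zero mean); maps use NaN as
the missing-value sentinel; percentiles use the linear-interpolation
convention; CoV uses the n−1 SD.  Voxels whose selected lag sits at
±max_lag are counted and logged as a fit-quality warning.
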