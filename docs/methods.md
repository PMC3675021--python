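# Methods

## Scope and data model

`metabopls` implements the frequency-domain half of an NMR metabonomics
study: it starts from already-processed 1D ¹H spectra (Fourier transform,
phasing and baseline correction are assumed done upstream) and carries
them through bucketing, multivariate modeling, validation and metabolite
assignment.  Time-domain simulation, pulse-sequence physics, peak
alignment/warping and probabilistic-quotient normalization are
deliberately out of scope — the workflow being reproduced used none of
them.

A `Spectrum` is a strictly monotone (stored high→low) ppm axis plus an
intensity trace and sample metadata.  A `BucketTable` is the samples ×
retained-buckets matrix together with its `BucketScheme` (region, width,
exclusions, reference peak) and normalization state, so every table is
self-describing on disk.

## The synthetic cohort generator

**What it emulates.**  600 MHz serum and urine spectra of a two-group
(COPD vs. healthy control) cohort, default 32 vs. 21 subjects.  Each
metabolite is a set of idealized first-order multiplets (s, d, t, q, dd,
m with line ratios 1; 1:1; 1:2:1; 1:3:3:1; 1:1:1:1; five equal lines).
Each line is a Lorentzian whose *area* is proportional to concentration
× proton weight, so integrated intensities are exactly linear in
concentration.  Serum includes broad (FWHM 0.03 ppm) HDL/VLDL envelope
multiplets to mimic the macromolecular background; urine includes a TSP
reference singlet at 0.00 ppm.  Concentrations are log-normal within
group: `c = base · 2^(effect·[copd]) · exp(ε)`, `sd(ε) = sqrt(log(1+cv²))`.

**Which features of real data it does not have.**  No pH-dependent
systematic shift drift (citrate, histidine), no peak-shape distortions,
no baseline roll requiring correction, no J-coupling second-order
effects, no inter-metabolite concentration correlations beyond the one
induced by total-area normalization.  Passing tests therefore demonstrate
the *machinery* is correct and well calibrated — not that real COPD serum
would yield any particular Q².

**Key defaults and why.**

| parameter | default | rationale |
| --- | --- | --- |
| `n_copd`, `n_control` | 32, 21 | the emulated study design |
| window / points | −0.5…10.5 ppm, 32768 | covers both integration regions plus TSP; ~3.4·10⁻⁴ ppm/point |
| `lorentz_fwhm` | 0.002 ppm | ≈1.2 Hz at 600 MHz, typical processed linewidth |
| `j_spacing` | 0.012 ppm | ≈7 Hz coupling at 600 MHz |
| `group_log2_effect` | ±0.5 | discriminators change ~1.4-fold; recovered \|r\| then straddles the 0.4 scale of the reference coefficient tables |
| `cv_within_group` | 0.25 | typical biological variability for urinary/serum metabolites |
| `noise_sd` | 5 intensity units | peak SNR of order 10²–10³, consistent with 64-scan acquisitions |
| `shift_jitter_sd` | 0.001 ppm | residual *post-referencing* misalignment; kept below the bucket width because fine (0.002–0.005 ppm) bucketing is only meaningful in that regime, and the pipeline intentionally has no alignment step.  At bucket-scale jitter peaks hop between buckets and per-bucket correlations collapse |
| `baseline_amplitude` | 0 | upstream processing is assumed to have removed the baseline; a non-negative random quadratic is available for robustness experiments |

Effect *signs* are fixed by the library (e.g. creatinine, lactate and
1-methylnicotinamide lower in COPD urine; glycerophosphocholine higher in
COPD serum); only the magnitude is a knob.  Magnitudes are simulation
settings, not estimates of the original study, whose concentrations were
never published.

## Preprocessing

* **Referencing** is a rigid axis shift placing the apex of the tallest
  peak within ±half-window of the target (lactate 1.33 ppm serum, TSP
  0 ppm urine) exactly on the target.  The apex must exceed 3× the median
  intensity, otherwise the reference is declared missing.  Referencing is
  *only* an axis operation; intensity normalization is the separate
  total-area step (doing both against the reference peak would
  double-normalize).
* **Bucketing** integrates by trapezoid on the native axis (with linear
  interpolation at interval edges), so results are invariant to sampling
  density and bucket sums telescope exactly to the region integral.
  Buckets are half-open `[low, low+width)` on a grid anchored at the
  region's low edge.  All exclusion bounds of the built-in schemes are
  exact grid multiples, so buckets are never split; excluded buckets are
  dropped via the retained mask, giving 3925/4250 serum and 1580/1900
  urine buckets.
* **Normalization** divides each retained-bucket row by its sum.
* **Scaling**: `mean_center` or `unit_variance` (autoscaling).  Columns
  with zero SD under autoscaling are centered and left at zero — never
  divided by zero — and are reported with r = 0 downstream.

## Models and numerics

* **PCA** by NIPALS (iterate `p ∝ X't`, `t = Xp` to 1·10⁻¹² relative
  change, cap 500 iterations), deflating after each component.  Component
  sign is fixed by making the largest-|loading| entry positive, so runs
  are reproducible.  Verified against an SVD oracle to 1·10⁻⁸.
* **PLS1** by the closed-form NIPALS sequence `w ∝ X'y`, `t = Xw`,
  `p = X't/t't`, `q = y't/t't` with X- and y-deflation.  With A = rank(X)
  the fitted values equal the OLS fit.
* **OPLS** (single y): the predictive weight `w ∝ X'y` is invariant under
  orthogonal deflation (orthogonal scores have exactly zero covariance
  with y), so each round computes `w_o ∝ p − (w'p)w`, deflates
  `X ← X − t_o p_o'`, and the final predictive component is fitted on the
  filtered matrix.  `n_ortho = 0` reduces to one-component PLS;
  predictions from OPLS(1 + a) equal PLS(a + 1), which is tested.
* **Class coding** +1 = control, −1 = COPD, centered internally.  The
  dummy-coded alternative differs only by an affine map of ŷ; this coding
  makes positive coefficients/correlations mean "higher in controls".
  Predicted scores are thresholded at 0; an exact tie is classified as
  control (arbitrary, documented, consistent).
* **Component count**: the emulated study never states one.  Default is
  autofit — add PLS components while cross-validated Q² improves by at
  least 0.02, cap 5, choose the maximum — mirroring the common commercial
  autofit heuristic.  OPLS-DA then uses 1 predictive + (A−1) orthogonal
  components.  A fixed count can be configured instead.

## Validation

* **Cross-validation**: stratified k-fold (default 10), with the scaling
  statistics refit inside every training fold.  Fold assignment visits
  samples in a seeded random order and places each in the fold currently
  holding the fewest members of its class; the construction depends only
  on the class partition, so swapping the two labels provably leaves
  folds — and hence the permutation p-value — unchanged.  `Q² = 1 −
  PRESS/SS` with SS about the overall mean.  One source also describes a
  100-fold variant; the fold count is therefore a parameter, default 10.
* **Permutation test** (default 100 permutations): each permutation
  shuffles y, refits the full pipeline with the *original* component
  count (keeping permuted models comparable, as validation plots in
  commercial software do), and records R²Y and Q².  The empirical p-value
  uses the finite-sample `+1` correction.  Intercepts come from OLS lines
  of R²Y and Q² against |corr(y_perm, y)| over the n_perm+1 points.  A
  model is "valid" when every permuted Q² falls below the original and
  the Q² intercept is negative.
* **Outlier screening**: single-pass Hotelling T² on a 2-component
  mean-centered PCA with the F-distribution limit at α = 0.05 (the
  emulated study removed one urinary outlier without stating its
  criterion; T² is the standard scores-plot ellipse).  Removal that would
  empty a class is refused.

## Interpretation

The coefficient profile reports, per retained bucket, `cov(t, xⱼ)` on the
original-unit normalized buckets (peak-shape preserving) and
`r = corr(t, xⱼ)` against the OPLS predictive score.  Using the score
rather than ŷ matches the standard construction; with one predictive
component they differ only by scale, leaving r unchanged.

The default significance cutoff is the critical Pearson r at P < 0.05 for
the modeled n — `r_crit = t_c/√(t_c² + n − 2)` — rather than a hard-coded
0.400: 0.400 corresponds to no df derivable from the modeled group sizes
(n = 46 or 52 give ≈0.29/0.27), so the fixed value is available only as an
explicit override.  Assignment matches bucket centers to library multiplet
centers within 0.010 ppm (serum) / 0.0125 ppm (urine), about five bucket
half-widths; a position may match several metabolites (reported as such)
or none ("unassigned").  The discriminant table keeps metabolites with at
least one significant matched bucket, reporting the extreme-|r| bucket and
the direction label.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on simulated data:
full-size cohorts (53 spectra, 32768 points) for ground-truth recovery and
the headline run, reduced cohorts (8–22 spectra, 4096–16384 points) for
unit and property tests, 200 null runs of the 100-permutation test at
n = 40 for calibration, and 20 seeded repetitions wherever a probabilistic
guarantee (≥90% / ≥95% of seeds) is asserted.

## Known limitations

* Multiplets are idealized first-order patterns; strong coupling and
  second-order distortions are not modeled.
* Total-area normalization induces compositional coupling: a genuinely
  changing dominant metabolite (creatinine) slightly biases apparent
  changes of the rest, and null metabolites can occasionally cross the
  significance cutoff (see the citrate row in the README example).
* The Hotelling limit assumes approximately Gaussian scores; with the
  self-inclusive variance estimate it is conservative at small n, and a
  single sample can never reach the limit for N ≲ 12 with A = 2.
* The serum reference is a lactate *doublet*: the apex rule can settle on
  either line, contributing a ±J/2 referencing offset absorbed by the
  assignment tolerance.
* JCAMP-DX import covers AFFN-encoded `(X++(Y..Y))` data only.
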