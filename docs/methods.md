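# Methods

This note records the scientific and numerical choices behind
`neuroentropy`: what each stage computes, which conventions were adopted
where the literature offers several, what the synthetic cohorts do and do
not emulate, and what the tests can and cannot show about real data.

## Signal model and preprocessing

Recordings are channels × samples matrices in µV with 10–20 labels;
T3/T4/T5/T6 are accepted as synonyms of T7/T8/P7/P8 and canonicalised on
read. The analysis unit is the lobe-averaged series over a fixed montage:
frontal {Fp1, Fp2}, parietal {Pz, P3, P4, P7, P8}, occipital {Oz, O1, O2},
temporal {T7, T8}. Averaging precedes the entropy and spectral
computations; because slicing and channel averaging commute, trimming may
be applied on either side of the average (asserted in the tests).

Filtering is a zero-phase band-pass, default 0.5–60 Hz: an odd-length
linear-phase FIR kernel (Hamming-window `firwin` design, half-octave
transition bands, ≥50 dB one octave outside the band) applied by FFT
convolution with the group delay compensated — the same scheme MNE uses
for resting-state data, chosen over forward–backward IIR for its exactly
linear phase. The kernel length is capped at a third of the signal so
short inputs remain filterable; the first second after filtering is
discarded as edge transient before trimming to the analysis epoch
(default 30 s, i.e. 30 000 samples at 1 kHz). Which 30-s window of a
longer recording is analysed is a free choice; the package takes the
earliest post-transient window.

No artifact rejection, re-referencing or ICA is applied: the pipeline is
designed for minimally perturbed resting-state data, and the synthetic
inputs contain no artifacts to reject.

## Entropy

`sample_entropy` implements −log(A/B) with Chebyshev (max-norm) template
distance and self-matches excluded; both counts use the first N−m
templates so every length-m template has an (m+1)-extension. Defaults
m = 2, r = 0.20. Conventions the literature leaves open, and the choices
made:

* **Tolerance policy** — `fixed` (default): r × SD of the original,
  lobe-averaged series, reused at every scale (the classic multiscale
  convention, which lets coarse-scale entropy fall as averaging removes
  variance); `per-scale` recomputes r from each coarse-grained series.
* **Log base** — natural log by default; a base-2 flag reports bits
  (values divide by ln 2). The base is recorded in all outputs.
* **Undefined values** — when A or B is zero the entropy is recorded as
  NaN with no substitution; bin means are NaN-aware and all-undefined
  cells are dropped from the long table.
* **Length adequacy** — the coarsest series should hold at least 10^m
  points (hard floor) and preferably 20^m; `check_length_adequacy`
  reports fail/warn/pass and `mse_profile(strict_length=True)` enforces
  the floor. At the full design (30 000 samples, 20 scales) the scale-20
  series has 1500 points, comfortably above 20² = 400.

`cross_sample_entropy` matches templates of one series against the other
over all (i, j) pairs — symmetric by construction. For cross-profiles both
series are z-scored first and the absolute tolerance is simply r: lobes
differ in gain, and matching raw µV across regions would conflate
amplitude with structure.

The pairwise counting kernels are numba-compiled loops with early exit on
the first out-of-tolerance element; a full 20-scale profile of a
30 000-sample series takes a few seconds. The test suite verifies both
kernels against exhaustive `cdist`-based enumerations to 1e-12 on
hundreds of random instances.

## Spectral power

PSD is Welch's estimate (2-s Hann segments, 50 % overlap) by default; a
raw periodogram mode exists for exact Parseval checks. Band power is the
rectangle-rule integral of the PSD over [lo, hi), so disjoint bands are
exactly additive. Band edges are the conventional delta 0.5–4, theta 4–8,
alpha 8–13, beta 13–30 Hz (configurable); responses enter the models as
natural-log power, with zero-power cells recorded as missing rather than
−∞.

A closed-form caveat worth recording: for pure 1/f^α noise the *integrated*
band power follows the canonical delta > theta > alpha > beta ordering
only for steep slopes (around α ≥ 2) — for α ≈ 1 the 17-Hz-wide beta band
overtakes alpha. Real resting EEG shows the canonical ordering because of
its alpha rhythm and steeper high-frequency roll-off, neither of which the
synthetic cohorts contain (see limitations).

## Mixed-effects inference

All models are REML-fitted random-intercept LMEs (statsmodels `MixedLM`)
with treatment-coded factors; fixed-effect significance uses Wald z
against the standard normal, with no small-sample df correction. Seven
model specifications are predefined, covering frontal entropy (all
subjects, and users-only with age of first use), the matching spectral
models, regional entropy and power models, and the frontal–parietal
cross-entropy model. Reference levels follow the reported contrasts:
non-users and the fine bin for the entropy models, frequent users and the
alpha band for the spectral models, the coarse bin for the cross-entropy
model.

The default analysis unit is the bin mean (the five scales of each bin
averaged into one response per subject × lobe × bin, 4 rows per
subject-lobe); a per-scale mode (20 rows, bin-labelled) is available.
FDR correction (Benjamini–Hochberg, via statsmodels `multipletests`)
applies within named post-hoc contrast families only — e.g. the six
group × bin contrasts of the frontal entropy model — while omnibus terms
and planned covariates stay uncorrected. Rows with missing responses or
covariates are dropped listwise; designs are rank-checked before fitting
and singular designs fail with the collinear terms named.

On balanced complete data the LME fixed effects equal the OLS estimates of
the same design (random intercepts are orthogonal to the fixed effects);
the tests assert this to 1e-6 and use it for fast bias checks.

## Power simulation

The generator draws the long-format response directly from the assumed
model: for subject i in bin b (numeric coding fine = 0 … very-coarse = 3,
5 replicates per bin),

    y = bin_slope·b + β·b·[group = frequent] + u_i + e,
    u_i ~ N(0, ICC),  e ~ N(0, 1 − ICC),

so total variance is 1 by construction and the empirical ICC matches the
request (verified to ±0.05 at 200 subjects). Each replicate is fitted with
the random-intercept LME `y ~ group × bin` and the frequent-group
interaction slope's Wald p is compared with α; power is the rejection
fraction among converged fits, with a Wilson 95 % interval.

The interaction is a *per-bin-step trend* by design. With 45 subjects in
three equal groups, β = 0.15, α = 0.05 and ICC = 0.50, the closed-form
expectation for this design is a Wald z of β/SE with
SE = √(2σ²ₑ / (n_g·Σ(b−b̄)²)) = √(2·0.5/(15·25)) ≈ 0.0516, giving ≈83 %
power — which the simulation reproduces (the packaged run prints 82.1 %
at seed 1, Monte Carlo SE ≈ 1.2 %). An alternative placement of the whole
effect in the frequent × very-coarse cell (`effect="cell"`) is provided
for sensitivity analysis; it is a far weaker alternative (≈15 % power at
the same β) because the cell contrast uses only two bins' data. A joint
Wald chi-square over all interaction terms is available via
`test="joint"`. Group allocation for N not divisible by 3 puts the
remainder on the earlier groups. Null calibration (β = 0) is part of the
acceptance suite: the rejection rate must lie in 0.05 ± 0.02 at 1000
simulations.

## Synthetic cohorts

`gen_cohort` emulates the study conditions: 57 subjects (18 non-users,
24 low-frequency, 15 frequent users), 3-minute recordings at 1000 Hz by
default, 12 lobe-mapped electrodes. Structure:

* **Regional gradient** — per-lobe 1/f^α exponents (frontal 1.3, parietal
  1.1, occipital 1.0, temporal 0.9): steeper frontal spectra give the
  frontal lobe the lowest entropy, and lobe-average curves rise from fine
  to coarse scales as in resting EEG.
* **Subject consistency** — a per-subject exponent shift shared across
  lobes (SD 0.35·√icc) moves each subject's whole entropy curve, playing
  the role of a random intercept. The *fitted* ICC of a cohort is an
  emergent, noisy quantity; the calibrated ICC contract lives in
  `gen_lme_dataset`, where it holds by construction.
* **Group effect** — a calibrated fraction of the frontal channels'
  slow-band (0.5–5 Hz) stochastic power is swapped for a deterministic
  1 Hz sinusoid (shared phase within subject, variance-preserving).
  Because the fixed SampEn tolerance depends on the scale-1 SD, a purely
  additive slow oscillation would depress *fine*-scale entropy through
  tolerance inflation and flip the interaction's sign; the
  variance-preserving swap leaves fine scales nearly untouched while
  regularising the coarse-grained dynamics. Calibration at the desk scale
  (below) fixed the fractions at 0 / 0.4 / 0.9 for
  non-users / low-frequency / frequent users, producing a frequent ×
  very-coarse coefficient of −0.19 ± 0.07 nats across cohorts — the same
  sign and order of magnitude as a flattened-curve group difference of
  roughly −0.15 bits.
* **Covariates** — SPQ total scores are drawn group-independently
  (N(26, 12²) clipped to 0–74) and age of first use uniformly in 14–25
  years for users; both are non-predictive by default, matching their
  null role, with the group–covariate correlation configurable for
  sensitivity work.

**Problem sizes.** The full design (1000 Hz, 30-s epochs) is the library
default and is used for the noise-signature checks. The end-to-end
cohort-recovery test runs a desk-scale version — 200 Hz, 21-s recordings
trimmed to 20 s — whose scale-20 series has 200 points: inside the
10^m–20^m "warn" band but above the hard floor, and empirically ample for
stable profiles. This keeps a 100-cohort recovery experiment to a few
minutes while exercising every pipeline stage at full scale counts.

**What the cohorts do not emulate.** No eyes-closed alpha rhythm, no
blink/muscle/line-noise artifacts, no non-stationarity, no volume-conduction
mixing beyond within-lobe correlation, and Gaussian amplitude statistics
throughout. Consequently passing tests demonstrate that the *pipeline*
recovers injected effects of realistic size and shape — not that real EEG
satisfies the generative assumptions; in particular the synthetic band
power ordering differs from real EEG in the alpha band (see above).

## Numerical details and degenerate inputs

Constant series have zero SD; the tolerance falls back to the nominal r so
SampEn evaluates to 0 (every template matches) instead of erroring.
Coarse-graining truncates trailing samples when τ ∤ N. All randomness is
routed through numpy Generators seeded from a single per-run seed;
identical seeds give byte-identical cohort CSVs and pipeline outputs.
Mixed-model fits that fail to converge are excluded from power
denominators (warning above 5 %, error at 100 %) and raise with
diagnostics in single-fit use.

## Known limitations

* Entropy at very short lengths (scale-20 series below ~400 points) is
  increasingly biased; the package warns but does not correct for it.
* Wald z inference is anti-conservative in very small samples; no
  Satterthwaite or Kenward–Roger correction is offered because the target
  design uses the normal approximation.
* The cross-entropy normalisation (z-scoring both series) makes XMSE
  invariant to gain but not to differing spectral shapes between lobes.
* The power study assumes the trend-style interaction; if the true
  alternative is confined to a single bin the quoted power overstates
  sensitivity (use `effect="cell"` to explore that case).
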