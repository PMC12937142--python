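# neuroentropy

Multiscale entropy and spectral analysis of resting-state EEG, with
random-intercept mixed-effects inference and a Monte Carlo power study.

`neuroentropy` is aimed at researchers analysing lobe-level complexity of
short eyes-closed EEG recordings — for example comparing cannabis-use
groups, clinical cohorts, or any between-subject factor whose signature is
expected in *slow* (coarse-timescale) brain dynamics rather than in band
power alone. It covers the whole chain:

* **Synthetic cohorts** — 1/f^α multichannel EEG with a per-lobe spectral
  gradient, subject-level consistency, group covariates, and an injectable
  coarse-scale regularisation effect, so every downstream stage is testable
  without any recordings.
* **Preprocessing** — zero-phase FIR band-pass (0.5–60 Hz), trimming to a
  30-s analysis epoch, averaging 10–20 electrodes into frontal, parietal,
  occipital and temporal lobes.
* **Entropy** — coarse-graining, sample entropy, multiscale entropy (MSE)
  over 20 scales, cross-sample entropy between lobes (XMSE), and binning of
  scales into fine (1–5), medium (6–10), coarse (11–15) and very-coarse
  (16–20) ranges.
* **Spectral power** — Welch PSD and integrated log band power in the
  delta/theta/alpha/beta bands.
* **Inference** — predefined random-intercept linear mixed models
  (`entropy ~ group × scale_bin + SPQTotal × scale_bin + (1|subject)` and
  friends) with Wald z tests and Benjamini–Hochberg FDR on post-hoc
  contrast families.
* **Power** — a Monte Carlo power analysis of the group × scale-bin
  interaction test.

## The statistics in brief

Sample entropy of a series *x* with embedding dimension *m* and tolerance
*r* is `SampEn(m, r, N) = −log(A/B)`, where *B* counts pairs of distinct
length-*m* templates within Chebyshev distance *r* and *A* the same count
for length *m+1*; defaults are *m* = 2, *r* = 0.20 × SD. MSE evaluates
SampEn on coarse-grained copies of the series, `y_j(τ) = mean(x[(j−1)τ+1 … jτ])`,
for scale factors τ = 1 … 20. Group inference uses REML-fitted
random-intercept LMEs with treatment coding; the power study simulates the
design (unit-variance response, subject-intercept variance = ICC,
standardized interaction slope β per scale-bin step) and counts Wald
rejections over 1000 simulated datasets.

## Worked example

```python
import neuroentropy as ne

# 57-subject synthetic cohort at desk scale (200 Hz, 20 s analysis epoch)
cohort = ne.gen_cohort(ne.CohortSpec(duration_s=21.0, fs=200.0, seed=1))

profiles = []
for rec in cohort.recordings:
    lobes = ne.preprocess_recording(rec, lo=0.5, hi=60.0, epoch_s=20.0)
    frontal = next(s for s in lobes if s.lobe == "frontal")
    profiles.append(ne.mse_profile(frontal.series, ne.EntropyParams(),
                                   rec.subject_id, "frontal"))

table = ne.build_long_table(profiles, cohort.metadata)
result = ne.fit_lme(table, "1A")
print(result.posthoc_contrasts("group_x_bin"))

power = ne.run_power_simulation(ne.PowerSimSpec(seed=1))
print(f"power = {power.power:.3f}, 95% CI {power.mc_ci95}")
```

prints the FDR-corrected group × scale-bin contrasts of the frontal
entropy model (reference: non-users, fine bin):

```
                             estimate     se      z      p      q
frequent x coarse              -0.100  0.047 -2.156  0.031  0.062
low-frequency x coarse          0.053  0.042  1.260  0.208  0.249
frequent x medium              -0.068  0.047 -1.458  0.145  0.217
low-frequency x medium          0.029  0.042  0.685  0.493  0.493
frequent x very-coarse         -0.148  0.047 -3.184  0.001  0.009
low-frequency x very-coarse     0.095  0.042  2.275  0.023  0.062
power = 0.821, 95% CI (0.7960253362714628, 0.8435178847808108)
```

The negative `frequent x very-coarse` coefficient (−0.148 nats, q ≈ 0.009)
is the injected effect: frequent users' frontal entropy fails to keep
rising at the slowest timescales, flattening their MSE curve relative to
non-users. The power line says that with a standardized interaction slope
of 0.15, α = 0.05, ICC = 0.5 and 45 subjects, the design detects the
interaction in ≈82% of simulated experiments.

The same stages are available from the shell:

```bash
neuroentropy simulate --out cohort --seed 3 --duration 21 --fs 200
neuroentropy preprocess --in cohort/S000.csv --epoch 20 --out lobes.csv
neuroentropy mse --in lobes.csv --out mse.csv
neuroentropy power --beta 0.15 --icc 0.5 --n 45 --sims 1000 --seed 1
neuroentropy run-all --config run.yaml
```

## Documentation

`docs/methods.md` describes the model and procedure in detail: parameter
conventions (tolerance policy, log base, template counting), what the
synthetic generator does and does not emulate, numerical choices, and
known limitations.
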