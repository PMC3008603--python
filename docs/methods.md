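# Methods

## Model

The classifier is a supervised principal-components survival model.
Let `x_i` be sample *i*'s log2 expression over the signature probe set
and `r_i = rank%(x_i)` its within-sample percentile ranks (average rank
for ties, scaled so the minimum maps to 0.00 and the maximum to 100.00
via `100·(rank−1)/(m−1)`; a constant vector maps to 50.00 by
convention). With `c` the per-probe mean of the training ranks and
`v₁, v₂` the first two unit-norm principal axes of the centered training
ranks, the metagene scores are `s_ij = ⟨v_j, r_i − c⟩` and the
prognostic index is the Cox linear predictor

    PI_i = β₁ s_i1 + β₂ s_i2 ,

where `(β₁, β₂)` maximize the Cox partial likelihood of the recurrence
endpoint on the two scores. Component signs are flipped (which flips
the corresponding β exactly) so that every retained β ≥ 0: a higher
index always means a higher estimated hazard. If the second principal
component is numerically degenerate (singular value below 1e-8 of the
first), the model falls back to one metagene with a warning.

The classification rule is `PI ≥ threshold ⇒ high risk`, with the
threshold fixed at the 50th percentile of the leave-one-out
cross-validated training indices. The tie at the boundary goes to high
risk — the conservative side for a treatment-eligibility assay — and is
part of the documented contract. Every valid input receives a call;
there is no unclassifiable zone. Calls whose 95% CI straddles the
threshold are annotated `borderline` rather than withheld.

## Probe screening and stability selection

Each probe is screened with its own multivariate Cox model containing
the probe's log2 expression plus age (years), grade and AJCC stage
(both as ordinal numeric covariates, mirroring single-coefficient
hazard ratios per factor). A probe is selected when its two-sided Wald
p-value is below α = 0.002 and the fit converged. Probes whose fit
diverges (monotone separation, |β| > 20, or a non-finite likelihood) are
recorded as unselected with a reason; the screen never aborts on a
degenerate probe. Screening requires complete covariates and at least
10 events.

Selection is stabilized by leave-one-out cross-validation: for each of
the *n* training samples, the screen **and** the metagene fit are redone
without that sample, and the round's own model scores the held-out
sample. This keeps gene selection inside the loop, so the held-out
indices are honest out-of-sample scores; their median is the
classification threshold, and by construction ⌊n/2⌋ or ⌈n/2⌉ of them
fall below it. Probes selected in ≥ 20% of rounds form the signature
(both α and the frequency threshold are parameters of
`MetageneRiskClassifier`). A round that selects no probe is recorded as
empty; frequency denominators are unchanged and that round contributes
no held-out index.

LOOCV rounds screen on log2 intensities and fit metagenes on
within-round percentile ranks — the same recipe as the final model — so
held-out indices and the final model's indices live on the same scale
and the stored threshold transfers directly.

## Rank transform and invariance

Percentile ranks are computed **within each sample across the signature
probes**, never per probe across the cohort: the deployed assay scores
single chips in isolation, and within-sample ranking is the only
cohort-free reading. The per-probe-across-cohort alternative is a noted
variant, not implemented. As a consequence the trained index is exactly
invariant to any strictly increasing per-sample transform of the raw
intensities (log, scale, offset, lab-specific response curves); the
acceptance suite asserts bit-identity. The trade-off is that the index
ignores between-sample location/scale information, which is precisely
the information most contaminated by inter-laboratory variation.

"Weighted average of the two metagene values" is implemented as the Cox
linear predictor `β₁s₁ + β₂s₂` without dividing by `β₁+β₂`: any positive
rescaling of the index is monotone-equivalent and cannot change
median-threshold classifications, and the linear predictor is the
canonical supervised-PC risk score. PCA is computed on probe-centered
ranks without variance scaling, since ranks already share the 0–100
scale.

## Cox fitter

`prognosig.cox` implements the partial likelihood directly (the screen
refits ~10⁵ small models per training run, so the kernel is
numba-compiled): Newton–Raphson with step-halving (the log partial
likelihood is monotone non-decreasing over accepted steps), convergence
at a maximum coefficient change below 1e-9, at most 100 iterations.
Efron tie handling is the default (exact when there are no ties;
Breslow available). Monotone separation is detected as |β| > 20 or a
non-finite likelihood and raised as an explicit error naming the
covariate — except inside the screen, where such probes are marked
unselected. Inference is Wald: `HR = exp(β)` exactly,
`CI95 = exp(β ± 1.96·se)`, two-sided p from `β/se` against the standard
normal. The fitter is cross-checked in the tests against a brute-force
maximization of the enumerated partial likelihood and against an
independent implementation (lifelines), and the score test at β = 0 is
verified to equal the log-rank chi-square for a binary covariate.

## Preprocessing and QC

* **Intensity filter**: a probe is excluded when its *median* linear
  intensity across training samples is < 100 (a probe exactly at 100 is
  retained). The aggregate-median reading makes the filter
  deterministic and defines a single probe universe; the retained list
  is stored in the model and re-applied verbatim at prediction time.
* **Reference-set centering**: per chip, the log2 median over the
  (nominally 100) low-variance reference probes is subtracted, so the
  per-sample reference median is exactly 0 afterwards. Training
  proceeds if ≥ 50% of the reference set is present (with a warning for
  any absence) and errors below that floor. The reference list is an
  input file; linear input is log2-transformed after flooring at
  intensity 1.
* **Chip QC** (all windows configurable, defaults in `QCConfig`):
  `background_estimate` = mean log2 of the dimmest 2% of probes, window
  (2, 8); `scale_factor` = chip 2%-trimmed mean over the cohort median
  trimmed mean, window (0.25, 4); `signal_to_noise` = log2 dynamic range
  (97.5th−2.5th percentile) of the cohort median chip divided by the
  robust s.d. (1.4826·MAD) of the chip's residual from that consensus,
  minimum 3 (capped at 10⁶ so a chip identical to the consensus stays
  finite); `replicate_probe_cv` = median CV across genes with ≥ 2
  probes, maximum 0.5, reported as NaN and never flagged without a
  probe-to-gene map. A chip is excluded when any metric leaves its
  window. These definitions are this package's own; each maps onto a
  named hybridization failure mode (nonspecific background, aberrant
  normalization factor, poor signal-to-noise, unstable replicate
  probes).

## Reproducibility calibration

Replicate hybridizations of the same RNA pool at several laboratories
quantify the index's measurement error: per pool, the index is averaged
per site and the s.d. across site means is taken; `mean_sd` averages
over pools. Single-sample 95% intervals are `PI ± 1.96·mean_sd`
(symmetric normal-theory interval on the index scale). The model ships
with a default calibration of 0.037 and is recalibrated via
`replicate_stability` + `apply_calibration` when replicate data are
available. `fraction_of_range` reports `mean_sd` relative to the range
(max − min) of the stored cross-validated training indices.
Within-site replicate homogeneity is tested with a one-way ANOVA across
replicate numbers per site (Kruskal–Wallis as an option); p > 0.05 at
every site is reported as "consistent".

## Synthetic cohorts

The generator emulates the structure the pipeline assumes, not
microarray physics. Per cohort: probe-level log2-normal background
(probe means N(8, 1) floored at 7.2 so the median linear intensity
clears the 100 filter; chip noise s.d. 0.4); a planted 10% block of
low-intensity probes (means ≈ log2 23) that the filter must remove
exactly; 100 high-intensity low-variance reference probes (noise s.d.
0.05); and a standard-normal latent risk factor `u_i` per patient on
which every informative probe loads with unit weight plus N(0, 0.5)
probe noise. Survival is exponential proportional hazards,

    λ_i = λ₀ · exp(effect·u_i + 0.01·(age−64) + 0.2·(grade−2) + 0.5·(stage−2.5)),

with λ₀ = 0.01/month, demographics matching a multi-centre colon cohort
(age 64±13.4, 53% male, stage mix 12/31/33/24%), and independent
exponential censoring whose rate is solved by root-finding so the
expected censored fraction hits the target (default 0.30) — the
empirical rate is verified within ±5% across seeds. Defaults are the
standard test-bench conditions: n = 200 samples, 2000 probes, 20
informative at log-hazard 0.8 per s.d. of the latent factor. Replicate
chips add one site effect per laboratory and one noise draw per chip,
both Gaussian on the log2 scale. Everything is reproducible bit-for-bit
from the mandatory seed.

What the generator does **not** emulate — probe-level PM/MM structure,
correlated co-expression networks, batch effects beyond additive site
shifts, non-proportional hazards — bounds what green tests mean:
passing demonstrates correctness of the algorithmics and calibration of
the statistics under the stated model, not clinical performance on real
cohorts.

## Evaluation conventions

Kaplan–Meier estimation and the two-group log-rank test (1 df,
tie-corrected hypergeometric variance) are delegated to lifelines. The
"5-year" horizon is 60 months; subjects event-free beyond it are
censored at 60 for horizon summaries. The HR printed beside a log-rank
p is an unadjusted one-covariate Cox fit on group membership (its
orientation follows the `levels` argument); when one group has no
events that HR is not estimable and is reported as NaN while the
log-rank p remains valid. Adjusted HRs come only from
`multivariate_report`, one Cox fit on age, gender (male = 1), grade,
stage, therapy flags when present and varying, and the risk group;
exactly collinear covariate pairs are an error naming the pair. A
compact closed-form log-rank statistic is also provided for permutation
nulls and is cross-checked against lifelines.

## Numerical and degenerate-input choices

* Scale auto-detection: a matrix whose maximum exceeds 30 is linear.
* Constant expression vectors rank to all-50; constant covariates and
  empty survival inputs are errors; ingest rejects rather than repairs.
* Model JSON serialization stores floats via Python's repr round-trip,
  so reloaded models reproduce indices bit-for-bit; files carry a
  schema version and refuse to load on mismatch or truncation.
* The hypergeometric overlap tail `P(X ≥ k)` is summed exactly in log
  space (gammaln + logsumexp); `P(X ≥ 0) = 1` exactly.
* The whole trainer is deterministic; only the data generator consumes
  seeds.

## Problem sizes in the test bench

The acceptance checks use the generator's default conditions (n = 200,
2000 probes) for the end-to-end run, n = 500 × 50 replicates for Cox
recovery, 1000 null probes for screen calibration, 50,000 permutations
for the log-rank oracle, n = 100 × 5 seeds for the Kaplan–Meier closed
form, and 6 sites × 5 replicates × 4 pools × 20 seeds for the replicate
calibration; unit tests use smaller cohorts (n = 60, 250 probes) chosen
so the full suite stays fast while every code path is exercised.

## Known limitations

* Two metagenes maximum; no univariate/correlation/SAM screens; no
  gene-level probe collapsing.
* No time-varying covariates, stratified Cox, sandwich variances or
  penalization in the Cox fitter.
* No batch-effect correction or cross-platform harmonization; the QC
  module checks chips, it does not repair them.
* The within-sample rank convention discards absolute expression level;
  a signature whose information is mostly in overall level rather than
  relative ordering would lose power under this transform.
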