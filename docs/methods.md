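# Methods

## The FI-Lab

The FI-Lab is a deficit-accumulation frailty index restricted to measured
quantities: 33 items (20 venous-blood tests, 4 arterial-blood-gas values, 6
urine dipstick readings, 3 vital signs), one value per ICU stay, each
dichotomized against a normal reference interval. The score is the number
of deficits divided by the number of items actually measured, so it lies in
[0, 1] and is comparable across records with different completeness. Records
carrying fewer than 27 of the 33 items (the "more than 80%" completeness
rule; 0.8 × 33 = 26.4, so the threshold is 27) get no score and are excluded
from analysis.

Dichotomization conventions:

* interval bounds are **inclusive-normal** — a value strictly beyond a bound
  is a deficit; a value exactly at a bound is not. This reading of "outside
  the reference range" is documented in the registry and configurable by
  editing the registry file;
* one-sided intervals are supported (troponin T has only an upper limit);
* dipstick items carry a single normal category ("negative"); any other
  reading is a deficit;
* missing values pass through and reduce the denominator, never the
  numerator.

The exact reference intervals used by the original cohort are not public;
the shipped registry uses standard adult intervals and is a user-editable
CSV/YAML file whose SHA-256 checksum is recorded in every run manifest, so
any analysis is traceable to the intervals it used. Exact numeric
replication of the original cohort's scores is therefore not attempted —
only the published summary counts, which are interval-independent, are used
as exact anchors.

Quartile categories are assigned cohort-wide from the empirical 25th/50th/
75th percentiles; intervals are left-open/right-closed except Q1, which
includes the minimum, and a score tied with a cut point goes to the lower
quartile. With a discrete score (ratios of small integers) tied blocks fall
entirely on one side of a cut, so quartile sizes can differ by up to the
largest tie block; this is expected, not an error.

## Synthetic cohort generator

The generator emulates the first-ICU-stay critical-AMI population the
analysis was designed for. Per patient a latent illness severity
Z ~ Normal(0, σ) (default σ = 1) drives:

* **items** — each item is abnormal with probability
  logistic(logit(p₀) + βZ); abnormal values are drawn uniformly beyond the
  violated bound within half a reference-span, normal values uniformly
  inside the interval (only in/out of range matters downstream); items are
  then set missing independently at the configured rate (default 0.02);
* **severity scores** — noisy linear transforms of Z rounded and clipped to
  each score's published integer range (SOFA 0–24, APS III 0–215, SAPS II
  0–163, LODS 0–22, OASIS 0–75, SIRS 0–4), so all six rank-correlate with
  Z but with different signal-to-noise, SIRS being weakest;
* **troponin T** — log-normal with location shifted by 0.3·Z, matching the
  right-skewed quartile medians of real cohorts;
* **outcomes** — in-hospital death from a logistic model whose linear
  predictor contains the record's realized FI-Lab (per 0.01) at the
  configured true odds ratio (default 1.06) plus covariate effects (age,
  sex, AMI type, troponin, SOFA); 1-year death is the in-hospital death OR
  an analogous post-discharge draw (true FI-Lab OR default 1.05), which
  enforces the nesting invariant that every in-hospital death is a 1-year
  death.

Defaults were calibrated once, by simulation at n = 30,000, to the published
cohort's marginals and then frozen: item baseline abnormality 0.45 and
severity slope 0.55 reproduce the published FI-Lab median/IQR of 0.45
(0.36–0.55) as 0.45 (0.34–0.56), and outcome intercepts (−6.97, −5.95)
give 22.3%/42.1% in-hospital/1-year mortality against the published
22.1%/41.6%. These defaults are the study conditions under which all
simulation-based tests run.

What the generator does **not** emulate: item–item correlation beyond the
shared latent factor (real laboratory panels have block structure, e.g.
PT/INR), informative missingness, repeat ICU stays, time-varying frailty,
and competing risks for the 1-year outcome. Passing tests therefore
demonstrate the statistical machinery is correct under a faithful but
single-factor data-generating process, not that real-data effect estimates
would match.

Cohort selection applies the study's filters sequentially — AMI diagnosis
codes (the full ICD-9 410.x family with fifth digits 0–2 and ICD-10
I21.0–I21.4 with subcodes, dots ignored), age ≥ 18, survival ≥ 24 h,
organ-donor and pregnancy flags when present, complete key covariates and
severity scores, ≥ 27 measured items, first ICU stay per patient — each on
the survivors of the previous one, so every exclusion is attributed to the
first criterion that fires (no attribution rule is standard; first-hit is
the transparent choice). Absent optional fields skip their criterion and
are logged as "not evaluated".

## Association models

Logistic models are fit by maximum likelihood (statsmodels `Logit`) on
explicit design matrices: the FI-Lab enters either as score/0.01 (so the
coefficient is per 0.01-score increase) or as quartile indicators against
Q1; sex is coded male = 1, ethnicity as White/Black indicators against
Other, AMI type as STEMI = 1; age can be reported per 5 years. Inference is
Wald: 95% CIs are exp(β ± 1.96·SE), log-symmetric about the OR. Complete
cases only, with the number of dropped rows reported per model.
Non-convergence and (quasi-)separation — detected as a singular Hessian or
absurd standard errors — flag the fit instead of failing silently.

*P for trend* re-enters the quartile as a single ordinal term (1–4) and
reports its Wald p; the ordinal-score convention is the most common one and
is isolated in one function so a median-score coding can be swapped in.

The 2×2 odds ratio uses the cross-product with the Woolf CI
exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d)); this is algebraically the crude
single-binary-predictor logistic OR, and the test suite asserts the identity
to 6 significant digits. Zero cells get the Haldane–Anscombe 0.5 correction,
flagged in the result.

The dose-response curve uses a restricted cubic spline (natural cubic,
linear in the tails, truncated-power basis normalized by the squared knot
span) with 3 knots at the 10th/50th/90th percentiles of the FI-Lab — the
standard default when no knot scheme is prescribed — inside the logistic
model adjusted for age, sex, ethnicity, AMI type and SOFA. Odds ratios are
reported against a reference score (default: the cohort 25th percentile)
with a delta-method band; the OR at the reference is exactly 1.

## Incremental value

For each severity score and outcome, the base model (score only) and the
augmented model (score + FI-Lab continuous) are **jointly refit** — not
offset-based — on the same records, and compared in-sample (apparent
performance, matching the convention of clinical risk-model reports;
optimism correction is out of scope).

* **C-statistic**: rank-based Mann–Whitney estimator with ties credited ½,
  computed from midranks in O(n log n); its CI and the paired ΔC test use
  DeLong's structural-component (placement-value) covariance, which the
  tests cross-check against brute-force pair counting, scikit-learn's
  `roc_auc_score`, and a delete-one jackknife of ΔC (agreement within 10%
  at n = 20, the two estimators being asymptotically identical).
* **IDI**: change in discrimination slope; its analytic CI treats the mean
  per-subject improvement among events and non-events as independent.
* **NRI**: category-free, since no risk categories are prescribed and the
  published magnitudes (0.27–0.72) are typical of continuous NRI; exact
  ties in predicted risk count toward neither direction. CI from the
  two-proportion normal approximation.
* A stratified percentile bootstrap is available for both IDI and NRI as a
  cross-check on the analytic intervals.

A caution on null calibration: for **nested models refit on the same data**,
the in-sample ΔC of an uninformative added covariate is biased positive, so
the DeLong test's null calibration cannot be checked that way. The
calibration test instead compares two equally informative noisy predictors
of the same latent risk, under which ΔC is exchangeable about zero and the
p-values are uniform (verified by KS test over 200 replicates at n = 500).

## Numerical and reporting choices

* All intermediate files carry full precision; rounding (2 dp for ORs, 3 dp
  for IDI/NRI) happens only at report writing.
* Quantiles use the default linear-interpolation convention of numpy.
* Predicted probabilities are clipped to (1e−12, 1 − 1e−12) before metric
  computation, which requires strictly interior probabilities.
* Every random draw flows from one `numpy.random.default_rng(seed)`; the
  same config and seed reproduce cohorts and pipeline outputs
  byte-for-byte, and the run manifest (config hash, registry checksum,
  seed, row counts) fully identifies a run.
* Problem sizes: simulation-based tests use cohorts of 1,200–10,000 and
  100-replicate recovery studies at n = 5,000 — large enough for stable
  rank statistics and Wald coverage, small enough to keep the full suite
  in the minutes range. The demonstration cohort size (2,159) mirrors the
  published cohort.

## Known limitations

* Severity scores are generated, never computed from physiology; their
  scoring rules are out of scope and they are treated as given inputs.
* The troponin-T FI-Lab item and the troponin-T covariate are drawn
  independently in the generator (the item through the common abnormality
  mechanism, the covariate log-normally), a simplification a real cohort
  would not show.
* Logistic (odds-ratio) modelling of 1-year mortality follows the source
  convention; no time-to-event analysis, competing risks, imputation or
  external validation machinery is provided.
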