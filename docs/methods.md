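# Methods

## The SNI statistic

A multichannel recording is modelled per channel as an ARIMA(p, d, q)
process. Prewhitening fits that model and keeps the residual (innovation)
series, so that any remaining cross-channel correlation at lag zero reflects
instantaneous coupling rather than shared temporal autocorrelation. The
statistic per unordered sensor pair (i, j) is

    SNI_ij = |arctanh(r_ij)|,

with r_ij the zero-lag Pearson correlation between the two innovation
series. The Fisher transform makes the null sampling distribution of each
pair approximately N(0, 1/(n − 3)) for n innovation samples, which is what
the null-calibration checks exercise. The per-scan scalar is the arithmetic
mean of the per-pair values: the per-pair vector is retained on the result,
and the mean was chosen because it is the simplest order-independent
reduction consistent with treating a scan's overall coupling strength as a
single covariate; no other reduction is implemented.

### Estimation choices

* The ARIMA order is a parameter (`ArimaOrder`, default (50, 1, 3)); the
  estimator is not part of the statistic's definition. The default
  estimator is Hannan–Rissanen (long-AR proxy regression) with stationarity
  and invertibility constraints relaxed, because full maximum likelihood at
  AR order 50 over 61,035 samples per channel is impractically slow and
  numerically fragile when run per channel over hundreds of channels.
  `method="statespace"` selects full MLE when wanted. Differencing is done
  explicitly (`np.diff`), so innovations from a d = 1 fit are one sample
  shorter; the first max(p, q) residuals are additionally discarded as
  filter warm-up, and all channels are truncated to the common innovation
  length before correlation.
* With p = q = 0 the innovations are exactly the demeaned (differenced)
  input — the degenerate case used by the null-calibration studies.
* Whiteness diagnostics per channel: lag-1 autocorrelation of the
  innovations and a Ljung–Box portmanteau test (lags = min(10, n/5)).
  Estimation failures and non-convergence are flagged per channel and the
  channel is excluded from the pair set with a logged warning; they never
  pass silently.
* Pairs with |r| ≥ 1 (possible only for degenerate inputs such as
  duplicated channels) have no finite Fisher z; they are reported as failed
  pairs and excluded from the scalar summary.
* A maximum-amplitude channel screen is available but off by default; it is
  a crude stand-in for visual artifact rejection, which is out of scope.

## Mixed-model inference

All cohort models are linear mixed-effects models with a random intercept
per subject and independent homoscedastic residuals, fitted by REML
(statsmodels MixedLM). Repeated visits are handled through the subject
grouping; visits are coded 0, 1, 2, … within subject. Rows missing any
model variable are dropped listwise, and every fit reports the rows and
subjects actually used. An AR(1)-over-visits residual structure is not
offered: the mixed-model fitter used here has no such residual model, and
with a median of ~2 visits per subject the random intercept already absorbs
the bulk of the within-subject correlation; this is a known limitation.

* **Screen.** One joint model, SNI ~ age + 7 biomarkers (a per-biomarker
  age-controlled mode is available). P-values are two-sided Wald tests,
  uncorrected by default to match the single-look design; a Holm adjustment
  is behind a flag.
* **Moderation.** The interaction model gates the stratified fits at
  α = 0.05 two-sided: slopes are only compared when the parallel-slopes
  null is rejected (forced stratification is available for simulation
  studies). The Paternoster Z is computed exactly from the stored stratified
  slopes, so the reported Z, slopes and SEs are always mutually consistent,
  and relabeling the factor levels negates Z without changing |Z| or p.
* **ApoE contrast.** Only the ε2-group (ε2ε2, ε3ε2) and ε4-group (ε4ε4,
  ε4ε3) genotypes enter the ApoE moderation model; ε3ε3 and ε2ε4 rows are
  excluded because the contrast is defined only between those two groups.
* **Constant factors.** A factor with a single observed level (e.g. a virus
  with 100% seroprevalence) is rejected with an explicit error — there is
  no contrast to test.
* **Confidence intervals.** `FitResult.ci` uses a t quantile with
  subjects-minus-parameters degrees of freedom instead of the Wald normal
  quantile. With few clusters (a small carrier stratum of ~20 subjects) the
  normal interval measurably undercovers; the cluster-count df is the
  standard conservative correction and is what the coverage study uses.

## Synthetic cohort generator

The generator emulates the *statistical* structure of a longitudinal
aging-cohort design — 175 subjects, i.i.d. visit counts with mean ≈ 1.99
(≈ 348 expected acquisitions), ages advancing one year per visit — with all
population parameters held in a `CohortScenario`:

* **Biomarkers** are log-normal, with location/scale solved from printed
  mean/median pairs (μ = ln median, σ = √(2 ln(mean/median)); every
  biomarker has mean > median, consistent with right skew). Only those two
  quantities are available, so higher moments are not matched. A common
  cross-biomarker correlation of 0.3 on the log scale is applied — a modest
  positive dependence typical of serum panels; no empirical covariance was
  available to match.
* **Genotypes and serostatus** are subject-level Bernoulli/categorical
  draws at the template frequencies (DRB1*13:01 carriage 22/175 = 12.6%,
  ApoE genotype distribution with ε4ε4 at 6/174 = 3.4%, HERVK
  seroprevalence 238/348 = 68.4%, …). The varicella-zoster group is absent
  from the scenario: at 100% seroprevalence it carries no contrast.
* **SNI** is generated from an explicit linear model: intercept + age slope
  + (base pTau217 slope + active group offsets)·pTau217 + subject intercept
  + residual. The default preset plants a single moderation effect, the
  protective DRB1*13:01 offset (−0.0025 against a base slope of +0.0015,
  so carriers' slope is negative) — the configuration under which each
  downstream stratified model is correctly specified and CI coverage is
  interpretable. Additional offsets (e.g. positive HHV1/HERVK effects) are
  configurable; note that offsets on factors *not* conditioned on by a
  given analysis act as an unmodelled per-subject random slope and will
  degrade that analysis's nominal coverage — by design, such scenarios are
  opt-in rather than default.
* **MoCA** declines with age and with the pTau217×SNI product; protective
  alleles scale the product slope by (1 − q) with protection fraction
  q = 1 by default, so carrying either allele cancels the effect and
  carrying both cannot overshoot. Scores are rounded and clipped to 0–30.
* **Missingness** is completely at random per column, at rates chosen to
  reproduce the template's per-column Ns (e.g. tTau 318/348). Outcomes are
  generated *before* masking, so missingness never distorts ground truth.

What the generator does **not** emulate: real MEG forward physics, sensor
noise spectra, informative missingness, visit-time irregularity, and any
biomarker–genotype dependence. Passing tests therefore demonstrate that the
pipeline is correct and calibrated under its own modelling assumptions, not
that those assumptions hold in real cohort data.

Identical seed + scenario gives bit-identical output (single
`numpy.random.default_rng` stream per generation call).

## MEG-like recordings

Channels are built as L·W, where W is white standard normal and L is the
symmetric eigendecomposition square root of the target correlation matrix
(scalar ρ expands to an equicorrelation matrix; matrices must be symmetric
PSD with unit diagonal, checked to an eigenvalue tolerance of −1e−8). The
eigen square root handles the singular ρ = 1 (duplicated channels) case
exactly. Optional temporal coloring applies one common AR filter to every
channel, which changes spectra and autocorrelation but provably leaves
zero-lag cross-channel correlations untouched — so the true correlation
structure is known both before and after prewhitening removes the coloring.
The default geometry is 248 channels, 60 s at 1017.25 Hz (61,035 samples,
0.983 ms sampling interval).

## Epitope scan

Window enumeration is exhaustive with stride 1 and 1-based inclusive start
coordinates (the convention of immunology web tools; stated in output
headers). Scoring is backend-agnostic behind a two-method protocol; calls
are cached by (peptide, allele) so duplicate windows are scored once and
identically. The deterministic mock backend hashes (seed, allele, peptide)
to a log-uniform IC50 on [1, 50000] nM — a scale-spanning stand-in used for
tests, not a model of real binding. Windows whose scoring fails (backend
error, non-positive value, unsupported ambiguous residues) are flagged and
excluded from the PBBA with a warning. PBBA is reported in nM at one
decimal in summaries. Percentile-rank outputs are not implemented; the scan
is IC50-only.

## Simulation-study sizes

The calibration studies run at sizes chosen to give useful Monte-Carlo
precision while staying cheap on a single CPU: type-I error uses 500
replicates of a 60-subject cohort (binomial SE ≈ 0.010 at α = 0.05);
interaction-p uniformity uses 200 replicates at 80 subjects; CI coverage
uses 200 replicates of the full 175-subject default preset (SE ≈ 0.015 at
95% coverage); the null z calibration uses 50 channels × 2000 samples
(1225 pairs). Acceptance-band checks (coverage within [0.90, 0.98], type-I
within 0.05 ± 0.025) are read against these sizes.

## Known limitations

* Hannan–Rissanen estimates at very high AR order on short series can be
  noisy; the whiteness diagnostics are the guard, and full MLE is available
  per call.
* Wald p-values from MixedLM are asymptotic in the number of subjects;
  small-stratum p-values are approximate (the CI construction compensates
  with cluster-count df, but p-values themselves are normal-based).
* The scalar SNI reduction (mean over pairs) is a convention; analyses that
  need the full pair vector should use `SniResult.sni_pair`.
* The generator's SNI intercept/slopes were set so that marginal SNI levels
  sit near the template's printed mean (≈ 0.037); they are conventions of
  the synthetic design, not estimates from any real data.
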