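# Methods

## The estimation problem

A chronic-disease prevalence study on administrative data has two coupled
inference problems. First, case ascertainment is incomplete and indirect: a
person is observable only through claims events (hospital discharges with
the disease code, disease-specific drug prescriptions, outpatient contacts
under a disease-specific exemption), so a case-finding rule must be defined
and its operating characteristics estimated against a clinical reference.
Second, the detected case set must be turned into population statements —
age-standardised rates, geographic contrasts, and an estimate of how many
cases all three sources jointly missed.

The package implements the chain end to end. Everything downstream of the
generator works on plain tables (pandas DataFrames / CSV) and can be applied
to real extractions with the same column conventions.

## Synthetic data generator

The generator emulates a Southern-Italian regional claims environment:
5,826,860 persons on the prevalence day (1 January 2018), seven Local
Health Authorities grouped into five provinces, a three-year study window
(2015–2017), and a single-centre clinical registry.

Calibration. Defaults were fixed once, by closed-form arithmetic from the
study conditions being emulated, and are not tuned per run:

- Prevalence 90 per 100,000; case demographics 64.4% female, age
  44.6 ± 12.9 years (normal, truncated to 0–99). Non-case demographics
  follow an approximate regional age structure and a 51.2% female share.
- Area relative risks (Napoli 0.89, Salerno 1.27, Avellino 1.26,
  Benevento 1.01, Caserta 0.92, rescaled to keep the marginal rate exact)
  reproduce the documented provincial gradient.
- Source capture of a true case follows a log-linear model over {0,1}³:
  main-effect logits are per-source capture probabilities (hospital 0.45,
  drug 0.84, outpatient 0.70) and pairwise log-odds interactions encode
  dependence (default 0 = independence). Under independence the joint
  detection probability is 1 − 0.55·0.16·0.30 = 97.4%, i.e. an expected
  undercount of 2.64/97.36 ≈ 2.7% — the condition the capture–recapture
  stage must recover.
- A captured source emits 1 + Poisson(1.2) event rows. The single-record
  probability among detected cases is then 0.228·e^(−1.2) = 6.9%, so the
  ≥2-record rule retains ≈93% of the ≥1-record cases.
- Missingness: birth year 2.5%, registration area 8.8%, MCAR by default;
  an optional MAR mode inflates female masking 1.5× (marginal rate
  preserved) for imputation stress tests.
- Registry: a simple random sample of 1460/5362 ≈ 27.2% of resident cases,
  independent of capture by default; a bias weight can make enrolment
  favour captured cases.
- 2% of persons are non-residents receiving in-region care; they can be
  cases and generate records but are excluded from denominators and from
  the registry.

Because capture truth lives in exactly the model family the
capture–recapture stage fits, parameter recovery is testable exactly.

What the generator does not emulate: realistic code dictionaries (one
placeholder code per source), within-year event dates, mortality between
window and prevalence day, education effects, and registry membership that
depends on clinical severity. Passing tests therefore demonstrate the
correctness of the statistical machinery under known truth, not the
accuracy of any particular real-world extraction.

## Case-finding and linkage

Sources share one anonymised identifier, so linkage is an exact merge.
"≥ k records" counts events, not distinct sources: two hospital rows
satisfy k = 2. Rationale: claims legitimately repeat (refund lines), and
an event-count rule is the stricter-to-looser monotone family users expect;
an exact-duplicate filter is available but off by default. Residence
filtering happens after linkage so the number of removed non-residents is
reportable.

## Validation statistics

The algorithm is a binary rule, so its ROC is the two-segment polygon with
area (sensitivity + specificity)/2. Binomial intervals are exact
Clopper–Pearson (beta quantiles). The evaluation frame is always an
explicit argument: with a single-centre registry as reference, specificity
and predictive values measure agreement with that registry, not with true
disease status — most algorithm positives are genuine cases simply not
enrolled at that centre. The pipeline's default frame is the union of
algorithm positives and registry members plus an equal-sized sample of
unflagged residents; sensitivity is frame-robust, the other margins are
reported with this caveat attached.

## Imputation

Chained equations with m = 10 copies and 10 cycles (defaults). Birth year:
predictive mean matching, k = 5 donors, type-1 matching with coefficients
drawn from the normal–inverse-chi-square posterior; PMM keeps imputations
on the observed discrete year support. Area: multinomial-logit draw from
fitted category probabilities on standardised predictors; with thousands of
observed rows per category the omitted coefficient-draw variance is
negligible. Predictors: sex, total record count, and the three per-source
usage indicators. Downstream, stratum case counts are computed per copy
and pooled by Rubin's rules, with the within-imputation variance of a count
taken as the count itself (Poisson); rates use the pooled mean counts. A
diagnostic logistic regression of each missingness indicator on the
predictors is available (`missingness_report`).

## Rates, standardisation, confidence intervals

Five-year age bands 0–4 … 85+; age on the prevalence day is computed as
prevalence_year − birth_year − 1 (only birth years are retained in the
data, so ages are accurate to ±1 year). Direct standardisation uses the
2013 European Standard Population by default — shipped in-code and labelled
in output metadata; any weight table can be supplied, and weights equal to
the study population's own age shares reproduce the crude rate to machine
precision. SMRs apply regional (age band × sex) rates to provincial
populations.

Count intervals use Byar's cube-root normal approximation to the Poisson
limits; against the exact chi-square-quantile bounds the relative error is
below 1% for counts above 10 (swept in tests). For a directly standardised
rate, the weighted sum of independent Poisson counts is approximated by a
scaled Poisson with matching mean and variance (equivalent count
d* = rate²/var) and Byar limits are applied to d*.

## Prevalence-ratio regression

Aggregated (age band, sex, province) strata, log-link Poisson with
log-population offset — identical to the person-level fit for this link.
Age enters as categorical 5-year bands, matching the standardisation
strata. Variance is the HC0 sandwich A⁻¹BA⁻¹ (A the Fisher information, B
the outer product of scores); cell counts here are large, so no
small-sample scaling is applied by default (HC1 available via the
covariance flag). Adjuster levels with zero cases overall sit at the −∞
boundary, are fitted exactly at zero, and carry no information about the
province contrasts; their strata are dropped to keep the fit interior.

## Capture–recapture

The 7 observed cells of the three-source inclusion table are fitted by
Poisson maximum likelihood under each hierarchical log-linear model with
main effects and a subset of pairwise interactions (8 models; the
three-way term is structurally inestimable with one unobserved cell and is
excluded). Fitting is Newton–Raphson with step halving, tolerance 1e-10,
500 iterations. A source with a zero margin is dropped together with its
cells and interactions — the fit then reduces exactly to the two-source
(Lincoln–Petersen) problem. Zero cells that push a parameter to the
boundary are flagged, not continuity-corrected (an optional 0.5 correction
is deliberately absent from the default path).

Model criteria are reported in two conventions: deviance-relative
(AIC = G² − 2·df, BIC = G² − df·log n_obs) and absolute
(−2ℓ + penalty·p). Selection in the pipeline defaults to BIC. The reason
is consistency: on tables generated under a smaller model, AIC retains a
spurious pairwise term whenever that term's drop-in-deviance (a χ²₁
variable under the null) exceeds 2 — probability ≈ 0.16 per pair — so the
selected model, and with it the extrapolated μ̂(0,0,0), fluctuates across
replications (observed range ≈ 1.9–3.0% undercount on identical study
conditions). BIC's log(n) penalty removes this and recovers the generating
model essentially always at study scale; AIC remains available and both
criteria are printed for every fit.

Confidence intervals for N follow the goodness-of-fit profile: the model is
refitted with the empty cell pinned at x₀₀₀ = N − n_obs, and the interval
is the set of N whose deviance stays within the χ²₁ quantile of the
minimum; endpoints are located by bisection to 0.5 cases. Coverage of the
95% interval, checked by simulation at study scale (N = 5500,
n_obs ≈ 5360, all-pairwise truth), is ≈ 96%.

## Problem sizes used in the shipped checks

The test suite and the acceptance script choose sizes that make the
statistical assertions sharp while keeping runs quick: the acceptance
script runs the generator at the full documented scale (5,826,860 persons);
the end-to-end recovery test uses 50 replicates of 150,000 persons
(~135 cases each); profile-CI coverage uses 500 simulated tables; the
imputation-recovery check uses 40 replicates of 600 rows with m = 5. These
are the package's own choices and can be scaled up via the same APIs.

## Known limitations

- Capture heterogeneity across persons (e.g. severity-dependent drug use)
  is not modelled; log-linear capture–recapture absorbs it only insofar as
  it looks like pairwise source dependence.
- The directly standardised rate of *detected* cases underestimates true
  standardised prevalence by the undetected fraction (~2.6% under the
  default configuration); the capture–recapture stage quantifies, but the
  rate stage does not add back, that undercount.
- Specificity/PPV against a partial registry are frame-dependent by
  construction and should not be read as population operating
  characteristics.
- Rubin pooling of stratum counts treats the per-copy count as Poisson for
  the within-imputation variance — adequate for rare-disease counts, crude
  for common outcomes.
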