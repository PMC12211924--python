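# Methods

This note documents the models implemented in `airses`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about behaviour on real cohorts.

## Synthetic cohort generator

The generator is first-class code, not a fixture: it defines the study
conditions every other module is validated under.

**Pollutant panel.** Concentrations of PM₂.₅, PM₁₀, PM₂.₅–₁₀, NO₂ and NOₓ
are drawn from a multivariate log-normal. Marginals are moment-matched so
the *natural-scale* means and SDs converge to the configured targets
(defaults 9.96 (1.05), 16.20 (1.90), 6.42 (0.90), 26.38 (7.57),
43.55 (15.46) µg/m³ — typical UK annual averages for a middle-aged
cohort): with target mean m and SD s, the log-scale parameters are
σ² = log(1 + s²/m²), µ = log m − σ²/2. The covariance argument is read as
natural-scale variances on the diagonal and *log-scale* correlations off
the diagonal; the induced natural-scale correlation is the usual
log-normal attenuation (e.g. a log correlation of 0.9 between NO₂ and NOₓ
induces ≈0.895 on the natural scale). Published pollutant correlation
magnitudes for such cohorts were not available to calibrate against, so
the default structure (0.7–0.85 within the particulate block, 0.9 between
NO₂ and NOₓ, ≈0.5 across blocks) is a configurable choice reflecting how
these pollutants co-vary in practice, not a fitted quantity.

**SES indicators.** Three latent classes (default prevalences
0.31/0.47/0.22, matching the observed individual-SES split of the
motivating cohort) emit education (4 levels), income (5) and employment
(2) independently given class. Default item-response rows were chosen so
class separation is realistic rather than clean: the Bayes-optimal
assignment accuracy is ≈69%, which is what makes downstream attenuation
visible in the examples.

**Event histories.** Competing transitions out of each state are latent
exponential clocks on the study-time scale; the earliest clock wins.
Default baseline intensities (0.00097, 0.0060, 0.28, 0.012, 0.012 per
year for transitions 1–5) are calibrated so a 12.5-year administratively
censored follow-up yields ≈1.2% incident AMD, ≈7.3% deaths, and ≈75% of
AMD cases progressing to an ocular comorbidity — the event mix the
analysis is designed around. Group-specific log hazard ratios multiply
the clocks per transition. Calendar dates are entry + floor(years × 
365.25) days, which makes same-day ties possible; an additional
`tie_fraction` (default 2%) of AMD→OCMD pairs is coerced onto the same
day to exercise the half-day rule. Censoring is a single administrative
cutoff; random loss to follow-up is not modelled.

A cohort-table validator enforces the design's structural rules: entry
age ≥ 45, no comorbidity without prior disease, no comorbidity dated
before the disease, and all event dates within follow-up. Same-day
disease/comorbidity dates are deliberately *allowed* (the generator
produces them and the half-day rule resolves them); only strictly
reversed sequencing is rejected.

## Exposure scores

**APS1.** PCA runs on the correlation matrix (pollutants have
incommensurate scales, and correlation-based PCA makes the score
invariant to rescaling any pollutant). Components with eigenvalue > 1
are retained by default (`n_components` overrides, including the
single-component mode); loadings are varimax-rotated with Kaiser row
normalization (toggleable), each rotated component is oriented so its
loading sum is positive (removing eigenvector sign ambiguity), and the
score is the explained-variance-share-weighted sum of the rotated
standardized component scores. With one retained component this reduces
to that component's score. The weighting choice is documented rather
than canonical: a composite built from several rotated components has no
single standard definition, and the variance-weighted sum keeps the
score's range behaviour similar to a summed construction. Whether the
weighted-score betas are per-µg/m³ or per-SD is likewise left to the
caller (the function is agnostic; the pipeline estimates per-µg/m³
coefficients).

**Varimax.** The SVD-update iteration maximizes the varimax criterion
(summed variance of squared loadings per factor); the criterion is
non-decreasing across iterations, k = 1 returns the input, and
non-convergence at `max_iter` returns the best iterate flagged
unconverged. Tests pin the k = 2 optimum against an exhaustive
grid-search over the planar rotation angle.

**Tertiles.** Empirical 1/3 and 2/3 quantiles (type-7, the numpy
default), left-closed intervals. Ties at a cut necessarily share a label,
so group sizes can be unequal under heavy ties; this is the reproducible
behaviour the rule is stated for.

## Latent-class SES

Standard conditional-independence latent class likelihood, fitted by EM
over distinct response patterns (cost scales with patterns, not
subjects). LCA likelihoods are multimodal, so the default is the best of
20 random Dirichlet starts, tolerance 1e-8 on relative log-likelihood
change, 1000 iterations cap; the log-likelihood trace of every start is
retained and asserted monotone in tests. Globally empty categories are
dropped with a warning; requesting more classes than distinct patterns is
an error.

Classes are ordered high/medium/low by descending probability of the
most-advantaged education category (ties: income's top category, then
prevalence) — an explicit, testable version of labelling classes by their
item-response profiles. Hard assignment is the posterior mode, because
the downstream Cox models need categories; the full posterior is returned
for anyone preferring probabilistic weighting.

## Joint hazard analysis

The 9-level joint factor crosses the score tertile with the SES level;
the reference is tertile 1 × most favourable SES. Partial-likelihood
maximization is delegated to lifelines' `CoxPHFitter` (Efron tie
handling — day-resolution dates make ties common — and `entry_col` for
left truncation); the module's contract is the returned
coefficient/covariance/log-likelihood triple, and the design matrix is
checked for exact collinearity before fitting. Likelihood-ratio
interaction tests compare the cross-classified model against the
main-effects model (χ² on the parameter difference; identical models
return statistic 0, p 1; a full-model likelihood below the reduced one
beyond tolerance is surfaced as an optimizer failure).

Additive interaction uses the delta method on the fit covariance for
RERI and AP, and the conventional log-scale delta method for the synergy
index S. S is undefined when (HR₁₀−1)+(HR₀₁−1) ≤ 0 (protective
components) — the measure's own domain restriction — and is returned as
such with a reason rather than a number. A Monte-Carlo check in the tests
confirms the delta-method RERI standard error against 10⁵ draws from the
coefficient sampling distribution. Multiplicative interaction is the
exponentiated product-term coefficient of a two-binary-factor model (each
factor dichotomized at its highest-risk level), with its own LR test.

The restricted cubic spline basis is Harrell's truncated-power natural
spline (linear beyond the boundary knots), knots at the
5th/35th/65th/95th percentiles, curve referenced to the score median
(log-HR exactly 0 there) with pointwise Wald bands. Proportionality
diagnostics correlate scaled Schoenfeld residuals (scaled by
d·Var(β̂), d = event count) with event-time rank; degenerate covariates
are excluded from the test. Rubin's rules pool estimates across
imputations (pooled mean; total variance W + (1+1/m)B); the imputation
step itself is out of scope — synthetic cohorts are complete, and a
missing-as-category switch covers the sensitivity-analysis style of
handling.

## Multistate model

Five transitions: baseline→AMD, baseline→death, AMD→OCMD, AMD→death,
OCMD→death. Time runs on the study clock (years since entry) with left
truncation at state entry rather than clock reset — the standard
framework for illness-death models reported as one HR per transition —
and baseline-to-death risk is censored at disease onset (the illness-death
reading of the transition diagram). Baseline hazards are stratified by
transition with transition-specific coefficients (no sharing), matching
separate per-transition reporting.

The half-day rule untangles same-day state entries by backdating the
theoretically prior state 0.5 day, applied from the latest occupied state
backwards so chains stay ordered (AMD = OCMD = death = day 1000 becomes
999 / 999.5 / 1000). The administrative censor date participates in the
untying so censored windows also stay strictly positive. On the year
scale half a day is 0.5/365.25, keeping every window positive. Expansion
invariants — rows = 2n + 2·#AMD + #OCMD, event conservation per
transition, max exit = death-or-censor time — are asserted in tests.
Transitions with too few events return an explicit not-estimable record
(sparse late transitions are expected, not exceptional).

## Life expectancy

Population central mortality rates m(a), single year of age 50–100 per
sex, are partitioned across joint groups with prevalences p_g and
all-cause-mortality hazard ratios HR_g by
m_ref(a) = m(a)/Σ p_g·HR_g, m_g(a) = HR_g·m_ref(a) — the normalization
guarantees the prevalence-weighted group rates reproduce the population
schedule exactly at every age. Applying HRs directly to the population
rate (m_g = HR_g·m) is available as `mode="direct"`; it inflates the
implied population mortality whenever any HR exceeds 1, which is why the
normalized partition is the default.

Life tables use the actuarial a(x) = 0.5 approximation
(q = m/(1+0.5m)), radix 100,000, and an open terminal interval at 100
(q = 1, L = l/m). HRs are treated as age-constant over 50–100, mirroring
one sex-specific HR per group. Confidence intervals come from a
parametric bootstrap: each run redraws every non-reference log HR from
Normal(log ĤR, SE), recomputes partition → life tables → Δe(50), and the
interval is the 2.5th/97.5th percentile over runs (default 10,000,
vectorized across runs so the full bootstrap takes well under a second).
Prevalences are held fixed — only the hazard ratios are treated as
stochastic — which understates total uncertainty slightly and is noted as
a deliberate limitation. Zero-SE inputs give zero-width intervals;
identical seeds give identical output.

The bundled reference mortality is a synthetic Gompertz schedule
(m(x) = a·e^{bx}, b = 0.095, sex-specific a giving e(50) ≈ 29.0 years for
men and 33.7 for women) — realistic magnitudes, explicitly not calibrated
to any national register, and shipped both as code
(`lifetable.synthetic_reference`) and as a small clearly-labelled CSV for
the CLI.

## Pipeline

A single root seed spawns per-stage seeds through `SeedSequence`, so the
full run is deterministic and partial reruns from persisted intermediates
reproduce the manifest. Intermediates are plain CSV for inspectability;
the manifest records per-artifact row counts and SHA-256 checksums. The
pipeline estimates the weighted-score betas from its own cohort (an
age/sex-adjusted multipollutant hazard fit on incident disease),
mirroring how a coefficient-weighted score is constructed in practice.

## Problem sizes and what the tests show

Simulation-based checks run at sizes chosen to make the asymptotic claims
they test hold with comfortable Monte-Carlo margins: hazard-recovery and
coverage experiments use 200 replicates of n = 10,000 cohorts with a
raised disease incidence (≈250 events per replicate), the end-to-end null
uses 10 replicates at n = 20,000, the latent-class recovery uses
n = 20,000 with 20 starts, and the bootstrap reproducibility check runs
the full 10,000 draws. Passing these establishes internal correctness —
estimators recover the generator's truth at the stated nominal rates —
under the generator's assumptions: exponential (constant) baseline
hazards, exactly proportional group effects, conditionally independent
SES indicators, log-normal exposures, complete data, and purely
administrative censoring. Real cohorts violate all of these to varying
degrees (age-increasing hazards, exposure measurement error,
informative dropout, missing covariates), so the suite validates the
machinery, not the epidemiology.

## Known limitations

- No Fine–Gray subdistribution modelling; competing risks are handled
  only through the cause-specific multistate structure.
- No transition-probability prediction (Aalen–Johansen) from the
  multistate fits.
- Multiple imputation generation is out of scope; only Rubin pooling is
  implemented.
- The synergy index is undefined for protective component effects, and
  its log-scale CI requires HR₁₁ > 1.
- Life-table prevalences are fixed in the bootstrap; group prevalence
  uncertainty is not propagated.
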