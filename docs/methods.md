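# Methods

This note records the models the package implements, the defaults it
ships, the numerical choices behind the estimators, and what the synthetic
data does and does not establish.

## Measurement models

Depression is measured by four ordered 0–3 items, neuroticism by twelve
yes/no items. Both are scored with logistic IRT models sharing one code
path: the graded response model's cumulative curves
P(X ≥ k | θ) = logistic(a(θ − b_k)) with strictly ordered thresholds, of
which the two-parameter logistic is the two-category case.

*Calibration.* EM marginal maximum likelihood. The latent scale is
identified by fixing the prior to N(0, 1) rather than anchoring an item —
standard for MML, and it makes scores directly interpretable as SD units
with most respondents between −3 and +3. The E-step integrates over a
fixed grid of 61 equally spaced nodes on [−6, 6] weighted by the normal
density (configurable; a 201-node grid changes EAP scores by < 1e−4). The
M-step maximizes each item's expected complete-data likelihood with an
analytic gradient under an unconstrained reparameterization (log
discrimination, first threshold, log threshold gaps), which enforces
ordering by construction. EM stops when the relative marginal
log-likelihood change falls below 1e−6 (or 500 iterations); the
log-likelihood trace is returned and is non-decreasing. Items whose
estimated discrimination falls below 0.2 are flagged weakly identified;
items with a single observed category raise an error naming the item.

*Scoring.* EAP means and posterior SDs on the same grid; deterministic
given parameters. In longitudinal runs item parameters are calibrated on
the baseline wave and held fixed when scoring later waves, so both waves
sit on a common metric. Refusal responses are never imputed — participants
carrying them are excluded upstream, mirroring the case-wise handling of
the cohort this emulates.

*Scale shrinkage.* EAP scores are shrunken toward zero by roughly the
scale reliability, so regression coefficients with an EAP outcome are
attenuated by a common factor relative to the latent truth. The
compensating fraction τ depends only on the *ratio* β_AC/β_lnY and is
therefore invariant to that common factor — this is why end-to-end
recovery is asserted on τ rather than on raw coefficients. A related
caveat: the posterior *mean* is not pattern-wise closer to zero than the
ML estimate (skewness can nudge it past a near-zero MLE by ~0.01); the
shrinkage that holds is in magnitude away from zero and in overall
dispersion.

## Panel estimator

The within-between random model regresses Θ on demeaned (x − x̄) and
person-mean (x̄) components of each time-varying exposure plus
time-invariant covariates, with a random person intercept:
per-person covariance σ_ε²I + σ_v²11ᵀ. Because the demeaned columns are
orthogonal to every person-level column under this covariance, β^w equals
the fixed-effects (demeaned least squares) estimate identically, and the
coefficient covariance is block-diagonal between within- and
between-components.

*Estimation.* Maximum likelihood (not REML). The likelihood is profiled:
for a given variance ratio λ = σ_v²/σ_ε², GLS coefficients and σ_ε² have
closed forms via the rank-one Woodbury identity, leaving a 1-D
maximization over log λ (bounded search on [−12, 8], absolute tolerance
1e−10, with the λ = 0 boundary evaluated explicitly and flagged when it
wins). This is the same estimator as direct maximization over
(β, log σ_v², log σ_ε²) but with two of the three directions solved
analytically; the marginal log-likelihood agrees with an independent
mixed-model implementation to better than 1e−6. Coefficient covariance is
σ̂_ε²(XᵀŴ⁻¹X)⁻¹ — the information-matrix block for β, exact here because β
and the variance parameters are orthogonal in Gaussian models. Standard
errors are model-based; no robust/clustered correction is applied.

Unbalanced panels are supported (person means over available waves);
singleton-cluster data degenerate to pooled least squares with
between-labelled coefficients, which is how the cross-sectional design is
fit. Rank-deficient designs raise an error naming the collinear columns
found by pivoted QR.

*Wald test.* H0: β^b = β^w per variable or jointly, quadratic form in
(β̂^b − β̂^w) against chi-square with one df per variable. Its size was
verified by simulation (rejection rate 0.058 in 1000 null panels of 500
clusters × 2 waves at α = 0.05).

## Shadow pricing

τ = exp(−β_AC/β_lnY) − 1, gradient (−e/β_lnY, e·β_AC/β_lnY²) with
e = exp(−β_AC/β_lnY), variance by first-order propagation through the
2×2 coefficient covariance. The 95% interval is normal-theory on the τ
scale (matching the propagated variance), not a back-transformed
coefficient interval. Monetization multiplies τ by the weighted mean net
income Σ p_i(income_i − tax_i) over eight five-year age bands (35–39 …
70–74). The shipped income/tax table is a clearly marked synthetic
placeholder with a weighted net income near the cohort-typical £30,500;
substantive use requires supplying official figures via configuration.
Currency is rounded half-even to 2 d.p. at the reporting layer only.

*Pooling.* The four per-equation prices are combined by an equal-weight
mean with a t(n−1) interval. That construction was chosen because it
exactly reproduces the published pooled summary from its published
components, and the `PooledCIV.method` field records the assumption.

*Delta-method validity.* The propagated SE matches the Monte-Carlo SD of
τ within 5% in the small-covariance regime. When the income coefficient's
sampling noise is a sizable fraction of its value (fewer than ~1000
clusters at the default effect sizes), the ratio leaves the linear regime
and normal-theory τ intervals under-cover (measured 0.86 at 300
clusters vs 0.94 at 3000) — small-panel prices should be read with that
caveat; the coverage test runs at 3000 clusters × 2 waves.

## Synthetic cohort

The generator produces the analysis-facing table (one row per participant
per wave) plus a ground-truth side-car that never enters the CSV.

What it emulates: band-censored household income (latent log-normal,
mean log 26,000, SD 0.5, wave-level SD 0.2, censored to the five survey
bands); alcohol intake composed from per-beverage Poisson counts with
person-level consumption scales and Dirichlet beverage preferences,
reported weekly or monthly by frequency group and converted to grams/day
(weekly totals ÷ 7, monthly ÷ 30.44); affect driven by the within-between
equation above; IRT item responses from the shipped banks; MCAR refusal
codes (0.5% per item — higher rates would delete most of a two-wave panel
through the any-refusal filter); independent participant-level exclusion
flags (non-drinker 14%, neurological 2%, dependence 0.5%); and follow-up
subsampling — everyone appears at baseline, later waves only for a
retained subset (default 30%), because the emulated study's repeat
assessment covered a small fraction of baseline and the pooled interval's
coverage depends on the cross-sectional and longitudinal estimates being
quasi-independent.

Two choices matter for testability. First, the affect equation uses the
*encoded* exposures the analysis observes (grams/day from counts, ln of
the band value), so estimator-recovery tests are exact; the latent income
is retained so band-censoring error can be quantified separately. Second,
the default cluster-mean/intercept correlation is zero: a nonzero value
genuinely confounds the between effect (no estimator recovers the
generative between-coefficient — the within-between model's protection
covers β^w only), and the emulated study's own equal-effects test for
alcohol is consistent with no such correlation. Bias-demonstration
studies set the correlation to 0.6 explicitly and assert only the within
effect's robustness.

Default truths are β_AC = 0.02 affect-SD per gram/day and β_lnY = −0.15
per log-pound (both components), σ_v = σ_ε = 0.5 — effect sizes
detectable at the desk scales the test suite runs (1,200–5,000
participants; the published-scale β_AC = 0.001 needs a six-figure cohort
and remains available through configuration). The implied generative
compensating fraction is exp(0.02/0.15) − 1 = 14.26% of income per
gram/day. There is no secular drift between waves: wave spacing and time
trends are not part of the emulated design.

What passing tests do *not* show about real data: the generator's
marginals are census-like but not calibrated to any cohort's Table-1
distributions; missingness is MCAR whereas real refusals are not;
exclusion flags are independent of affect; and frequency group is fixed
per participant. Results on synthetic data validate the estimators, not
any substantive claim about drinkers.

## Eligibility filtering

Participant-level rules in a fixed, documented order: any item refusal
(baseline only in cross-sectional mode, any wave in longitudinal mode) →
neurological condition → non-drinker (frequency "never") → alcohol
dependence history → case-wise deletion on any missing covariate, refused
income band or refused frequency → (longitudinal) incomplete panel. The
per-rule counts depend on this order; the final eligible set does not.
The exclusion log conserves participants (eligible + excluded = raw) and
filtering is idempotent. Income refusals are treated as case-wise
deletions; "special occasions only" drinkers are treated as monthly
reporters. Beverage ethanol content defaults: beer 20.45 g/pint, wine
12.5 g per 125 ml glass, fortified wine 8 g, spirits 11 g per 35 ml,
other 12 g — explicit configuration, as are the band pound values (9,000;
24,500; 41,500; 76,000; 125,000).

## Problem sizes

The suites run at: IRT recovery n = 5,000 (errors pooled over three
replicate calibrations to stabilize the 4-item RMSE); estimator recovery
200 panels of 2,000 clusters × 2 waves; bias demonstration 200 panels of
1,000 clusters; Wald size 1,000 panels of 500 clusters; τ-interval
coverage 1,000 panels of 3,000 clusters; end-to-end null control 100
pipeline runs of 2,000 participants. These are the package's chosen desk
scales; all are configurable.

## Known limitations

- Estimates are associations; the within-between model removes
  time-invariant confounding from β^w but neither coefficient is causal.
- The between-effect price inherits any person-level confounding
  correlated with exposure means (see the correlation discussion above).
- Delta-method intervals for τ are unreliable when β̂_lnY is imprecise
  relative to its magnitude.
- Only random intercepts: no random slopes, serial correlation, or
  non-identity links — the affect equations are linear in Θ.
- The two open-ended income bands have no data-driven pound value; the
  encoded log income is a step function of five values, so β_lnY is a
  band-contrast slope, not a continuous income elasticity.
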