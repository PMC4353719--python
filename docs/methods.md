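# Methods

## The problem

`mgcfa` asks whether a multi-item questionnaire measures the same
constructs in every group of a cohort — here, whether a 240-item,
30-facet personality inventory means the same thing to 12 adult age
groups.  If it does not (if the measurement model lacks *invariance*),
group differences in scale scores confound real differences in the latent
traits with differences in how the items express those traits.  The
package estimates constrained multi-group factor models, walks the
standard invariance ladder, calibrates its decision criterion by
permutation, searches for partial invariance, and quantifies what
non-invariance means at the level of item and facet scores.

## The model

Each facet is a one-factor model.  For person i in group g and item j:

    x_ij = tau_jg + lambda_jg * eta_i + eps_ij,
    eta_i ~ N(alpha_g, psi_g),   eps_i ~ N(0, Theta_g)

Identification fixes `psi_g = 1` in every group at every ladder level, so
loadings are comparable across groups and latent means are in standard
score units.  Latent means are fixed at 0 everywhere until the strong
level, where all but the reference (youngest) group's means are freed.
`Theta_g` is diagonal plus a small number of residual-covariance pairs
found by the baseline search.

Estimation is normal-theory maximum likelihood from per-group sufficient
statistics (n_g, mean vector, ML covariance with divisor n).  The fitted
discrepancy is

    F = sum_g (n_g/N) [ ln|Sigma_g| - ln|S_g| + tr(S_g Sigma_g^-1) - p
                        + (xbar_g - mu_g)' Sigma_g^-1 (xbar_g - mu_g) ]

with `chisq = N * F`, which is exactly the raw-data likelihood-ratio
statistic against the saturated model.  Robust (scaled) test statistics
are not implemented: they need raw fourth moments, and every pipeline
stage here is defined on sufficient statistics.  Fit indices therefore
differ somewhat from what robust estimators would print on heavy-tailed
real data; on the generator's normal data they are exact.

Cross-group equality constraints are implemented by parameter sharing
(one free scalar mapped into several groups), never by penalties.
Optimization is L-BFGS-B with the analytic gradient; start values are
loadings 0.5, residual variances half the observed variance, intercepts at
the reference-group means, latent means 0; on failure up to 5 jittered
restarts run from a fixed documented seed.  Convergence requires the
optimizer's relative-F criterion (1e-12) or a projected-gradient norm
below 1e-5.  Residual variances are bounded below at 1e-6; a bound hit is
flagged as a Heywood case rather than raised.  Residual covariances are
unbounded, with positive-definiteness of the implied covariance enforced
by a penalty during line search; a non-PSD 2x2 residual block at the
optimum would surface as a penalty/convergence flag.

### Fit indices

CFI uses the per-group independence baseline (free variances and means,
zero covariances), available in closed form.  RMSEA carries the sqrt(G)
multi-group multiplier — conventions differ across software; this follows
the convention in which a fixed per-group misfit yields the same RMSEA
regardless of G.  The 90% interval inverts the noncentral chi-square
distribution by root finding (`P(X2_df(ncp) <= chisq) = .95 / .05`).
With df = 0 the RMSEA is reported as 0 with an `undefined` flag.

### Modification indices

Univariate score (Lagrange-multiplier) statistics: with `s` the gradient
and `H` the expected information of the chi-square surface at the
constrained optimum, the index for one candidate constraint is
`MI = s_c_adj^2 / (2 * schur)` with the usual Schur-complement adjustment
for the free parameters, and the expected parameter change is
`-s_c_adj / schur`.  The residual free-parameter gradient is retained in
the adjustment rather than assumed zero, which makes the indices robust
to slightly inexact convergence.  Score and likelihood-ratio statistics
are first-order equivalent; for large violations the two can drift apart
by more than the ~5% seen in the validation toys, which is a property of
the statistics, not of the implementation.

## The ladder

Levels, in order, all with latent variance fixed at 1:

1. **single-group** — the baseline model on the pooled full sample;
2. **configural** — all parameters free per group, latent means fixed 0;
3. **weak** — loadings constrained equal across groups;
4. **strong** — intercepts also equal; latent means freed except the
   reference group;
5. **strict** — residual variances also equal.

Before the ladder, residual covariances are constrained equal across
groups once, retained if the configural delta-CFI is at most .01 and the
RMSEA intervals overlap.  The decision statistic at each level is
`delta-CFI = CFI(previous) - CFI(current)`; the configural level is
compared against the single-group model.  Default limits are .03
(configural) and .01 (weak/strong/strict) — the values a permutation
calibration supports at this design's group sizes.  RMSEA-interval
overlap is reported alongside but never gates a decision, because RMSEA
rewards the parsimony of more constrained models and is therefore the
more liberal criterion.

**Calibration** shuffles the age column across persons (pseudo groups of
exactly the original sizes), reruns the ladder per shuffle, and reports
the null delta-CFI distributions per level plus the smallest threshold in
{.01, .02, .03, .05} with zero observed exceedances.  Fresh permutations
are drawn per run.  The zero-exceedance rule is an explicit artifact
choice where the underlying reasoning is informal.

**Partial invariance search** (weak level: loadings; strong level:
intercepts; strict is never partialized because group comparisons use
latent means, which strict invariance does not affect): for every
still-constrained item the modification index is averaged over all
groups; the item with the highest average is released *simultaneously in
all groups*; the model is refitted and the delta-CFI recomputed against
the previous-level model; repeat until the level passes.  Averaging over
groups and releasing in all groups resists capitalizing on chance and
admits systematic (e.g. roughly linear-in-age) parameter drift.  Ties
break deterministically on the lowest item index.  If more than half the
items would need release the search stops with an "unattainable" flag.
Latent group means are always read from the (partial) strong model.

## Factor scores and score-level analyses

Facet and domain scores are ordinary-least-squares (minimum-residual)
single-factor extractions from the correlation matrix — minimizing the
off-diagonal squared residuals — with regression-method (linear
projection) scores, restandardized to mean 0 / SD 1.  The scoring method
(regression rather than Bartlett) is an artifact choice; factors are
oriented so the sum of loadings is positive, and subset factors are
additionally sign-aligned to their full-pool factor so quantile summaries
are not corrupted by arbitrary orientation.

*Residual-age correlations*: each component (item of a facet, or facet
score of a domain) is regressed on its unit's factor score; the residual
is exactly orthogonal to the score, and its Pearson correlation with age
isolates component-specific age variance.  Significance uses the critical
value `r* = t*/sqrt(t*^2 + n - 2)` at Bonferroni-adjusted two-sided
alphas (items: .05/240; facets: .05/30, with a descriptive p < .01 flag),
with the full-sample n.  Age is continuous here, not the group index.

*Random-subset sensitivity*: B = 1000 draws of k = 12 of a domain's 48
items; each subset is scored as above and correlated with age; the mean
and the 2.5%/97.5% quantiles summarize how much the domain-age
association depends on which quarter of its indicators defines it.

*Reliability*: coefficient omega per group from the configural model,
`omega_g = (sum lambda)^2 / ((sum lambda)^2 + sum theta_jj + 2 sum
theta_jk)`.

## The synthetic cohort

The generator's defaults are the emulated study's conditions: 240 items,
30 facets, 5 domains; 12 age groups with sizes
(310, 299, 253, 269, 254, 208, 211, 191, 188, 193, 185, 150), total
2711; brackets 18-24, 25-29, ..., 70-74, 75-91.  Ages are uniform within
brackets (the real within-group age distribution is unknown; uniform is
an explicit assumption), integer-labelled brackets cover [lo, hi+1) with
the last bin closed at 91.  Facet loadings are evenly spaced over
[0.3, 0.8] (deterministic; only the range is prescribed), intercepts 0,
residual variances `1 - lambda^2`, latent variance 1.  Facet latents
within a domain share a domain factor with correlation 0.4 — a
mid-range value typical of facet intercorrelations — so domain-level
scoring and subset analyses see realistically correlated facets.  Latent
age trajectories are linear in standardized group mid-age with a
configurable slope (default 0), pinned to 0 in the youngest group.

Non-invariance directives perturb one item's loading or intercept by a
step (listed groups) or a linear-in-group-index drift.  One global seed
drives three documented substreams (ages, latents, residuals), so adding
items never perturbs ages; the same spec and seed reproduce the same
table bitwise.

What the generator does **not** emulate: item skew and category
sparseness (items are continuous normal; a fixed-threshold 5-category
discretization exists but is off by default), missing data, informant
reports, cohort-vs-age confounding, and any age-latent dependence within
a group beyond the group mean.  Passing tests therefore demonstrate the
statistical machinery under the model's own assumptions, not robustness
to the distributional pathologies of real questionnaire data.

## Validation design and problem sizes

The test suite validates against independent oracles: a derivative-free
optimizer (Powell) on the same discrepancy for small instances;
refit chi-square drops for modification indices (with a moderate
injected effect, where the score and LR statistics are first-order
equivalent); bisection on the noncentral chi-square CDF for RMSEA
intervals; closed-form loadings for just-identified models; per-person
normal log-densities for the moment-based likelihood; and Monte-Carlo
null calibration for the critical correlation.

Stochastic suites use problem sizes chosen to estimate their targets
stably at desk scale: 100 facet-runs for the null calibration of the
delta-CFI criterion, 40 replicates for injected-drift power and
release-recovery, 20 replicates for latent-mean recovery (whose
per-replicate RMSE is dominated by the reference group's realized latent
mean, sd ~ 1/sqrt(n_ref)), and 200-1000 subset draws per arm in the
sensitivity contrast.

## Known limitations

- Normal-theory ML only; no robust scaled statistics, no ordinal
  (threshold) estimation, no standard errors for parameters (point
  estimates and test statistics suffice for the pipeline).
- One factor per scale; hierarchical item-facet-domain models are out of
  scope (domains are modelled through facet factor scores instead).
- Deposited moment files must state whether covariances use divisor n or
  n-1; the reader rescales on request (`divisor="n-1"`) but cannot detect
  the convention itself.
- The partial-invariance search is greedy and its release order is only
  guaranteed deterministic, not globally optimal.
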