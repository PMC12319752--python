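# Methods

## The model

`brainnorm` fits, independently for each region × hemisphere × metric, a
four-parameter distributional regression of the log10-transformed
measure on age, sex and scanning site. All morphometric values
(thickness, volume, areas) are log10-transformed first so that measures
of different dimensionality can be treated identically; the folding
components K, I and S are linear combinations of logs already and pass
through untransformed.

The response distribution is the sinh–arcsinh (SHASH) location–scale
family: with `r = (y − μ)/σ`,

    z = sinh(τ·asinh(r) − ν)  ~  N(0, 1),

so ν controls skew (0 = symmetric), τ tail weight (1 = Gaussian; the
family reduces *exactly* to the normal at ν = 0, τ = 1), and centiles
and quantile residuals come in closed form through the normal CDF. A
Box–Cox power-exponential family is provided behind the same interface
to keep the family pluggable; the Gaussian reduction (`family =
"gaussian"`) freezes ν and τ.

Each parameter has its own additive predictor:

| parameter | link | terms |
|---|---|---|
| μ (location) | identity | intercept + spline(age) + sex + site |
| σ (scale) | log | intercept + spline(age) + sex + site |
| ν (skew) | identity | intercept + spline(age) + sex |
| τ (kurtosis) | log | intercept + spline(age) |

The age smooth is a cubic B-spline with 10 interior knots at age
quantiles and a second-order difference penalty; the smoothing
parameter per submodel is chosen by generalised AIC (k = 2) over a log
grid at the submodel's first update and then frozen. Site enters μ and
σ as a normal random intercept, realised as ridge-penalised site
dummies; the shrinkage variance is initialised by method of moments on
residual site means, refined by one EM-type step, then frozen. With
fewer than ~10 sites a warning recommends fixed site effects
(`site_random=False`).

Estimation is penalised maximum likelihood by cyclic
(Rigby–Stasinopoulos-style) updating: each submodel is refreshed by a
penalised weighted least-squares step on working responses built from
numerically differentiated per-observation score and curvature, with
step-halving against the penalised log-likelihood. Once the penalties
are frozen the objective is non-decreasing by construction (asserted in
tests). Convergence: relative penalised-deviance change < 1e-6, at most
200 outer cycles; non-convergence is reported honestly via the
`converged` flag and a warning, never silently.

Curvature weights are floored *relative to the median observed
curvature* (not at a tiny absolute constant): a hard floor lets the
working response of low-curvature observations destroy their score
contribution and stalls the scale update short of its optimum.

Coefficient uncertainties come from the **joint** observed information
across all four submodels. This matters: on near-Gaussian data μ- and
ν-terms jointly shift the location, so per-submodel (block-diagonal)
covariances understate e.g. the sex-effect SE and break nominal ±2 SE
coverage.

## Harmonising unseen sites and scoring

A new site/batch must bring healthy controls (HCs). Residuals of those
HCs against the reference-site prediction (the training site with the
most subjects, configurable) give the site offset (their mean). The
scoring SD is the HC residual SD when the site has ≥ 30 HCs, else the
unweighted mean of the per-site residual SDs stored in the model. The
30 cut-off reflects the sampling accuracy of a sample SD — at n = 30
the probability of being within 10 % of the true SD is ≈ 55 % and
within 25 % ≈ 95 % (`sd_rule_probability` returns both the Monte-Carlo
estimate and the chi-square closed form).

z-scores are `(y − μ_ref − offset)/SD`. Centiles use the full family
CDF with skew and kurtosis evaluated at each subject's age and sex, but
with location and scale chosen by **moment matching**: the family's
mean and SD are set equal to the harmonised site mean and SD. The scale
parameter of a SHASH is not its standard deviation once ν/τ leave their
neutral values, so plugging the site SD in as raw σ would mis-scale the
tails whenever the fitted τ wobbles off 1; moment matching removes that
inconsistency and is what makes the centile coverage tests calibrate.
Patients never contribute to offset or SD estimation; multiple unseen
sites in one table are harmonised independently.

## QC

Residual outliers are flagged at more than 5 median absolute deviations
from the median residual (MAD scaled by 1.4826 for normal consistency;
the raw-MAD reading is one `consistency=1.0` switch away). A subject
flagged in any single model is excluded from all models (listwise
deletion) so every fit shares one reference set. A zero MAD flags
nothing and warns. One fit → flag → refit pass is the default.

## Group statistics and lateralisation

`case_control` mode is the two-sample Cohen's d (pooled SD) between
patient and control z-scores. `normative` mode — for cohorts without a
matched control group — is the one-sample standardised mean of patient
z-scores against the reference population (mean 0 by construction);
this statistic is deliberately swappable, and it is defined as 0 for
the degenerate all-zero case. Lateralisation uses Δz = z_left − z_right
(left-minus-right convention throughout); the predicted side is the
more abnormal hemisphere given the metric's abnormal direction (atrophy
metrics: lower), and subjects are flagged when Δz falls outside 2 SDs
of the control Δz distribution (control-based, not the theoretical
√2). No multiple-comparison correction is applied to d maps.

## The synthetic generator

`synthetic_cohorts` draws, on the log10 scale,

    y = base + f(age) + β_sex·1[male] + site_offset + subject_offset
        + site_scale · SHASH-noise(σ, ν, τ),

with uniform ages in [5, 95], balanced sex, equal-probability site
assignment, normal site intercepts (SD 0.01, shared across a subject's
regions, as a scanner shift would be), log-normal multiplicative site
scale factors (SD 0.10) acting on the measurement noise, and a
per-subject biological offset (SD 0.015) shared across all of a
subject's measures. Defaults: measurement σ = 0.015 log10 units, ν = 0,
τ = 1; sex effect −0.004 (males thinner); the age curve is a monotone
decreasing piecewise cubic through (5, +0.012), (20, 0), (65, −0.012),
(95, −0.045) — steeper decline in early and late life, ~13 % total for
a thickness-like metric, with knots at 20 and 65.

The subject-level offset is the one deliberate addition beyond the
model's own covariate structure: it makes the two hemispheres (and all
regions) of one subject correlated, as they are in any real cohort.
Without it, Δz lateralisation would be tested against an unrealistically
noisy Δz (independent hemispheres double the Δz variance), and with it
the injected 1.5-SD one-sided effects are classified correctly >90 % of
the time, as a method that works on real data should achieve.

Disease injection shifts targeted region × hemisphere values by a
stated number of control SDs, where the control SD is each patient's
*own site's* total residual SD — the scale their z-score will be in.
Lateralised specs shift one hemisphere only.

What the generator does **not** emulate: spatially structured
region-to-region covariance beyond the single shared subject factor,
FreeSurfer measurement-error structure, realistic demographic
imbalances, multi-session data, or non-uniform age distributions.
Passing tests therefore certify the statistical machinery under the
model's own assumptions plus mild site/subject heterogeneity — not
robustness to everything real MRI data does.

## Numerical choices

- Numeric score/curvature: central differences in predictor space,
  h = 1e-4·(1+|η|); exact for the Gaussian μ-update.
- Conditioning ridge 1e-7 on all coefficients (the centred spline basis
  and the intercept share a constant direction; the penalty null space
  makes the split immaterial for predictions).
- Age outside the training range is clamped to the spline boundary with
  an extrapolation warning (constant extrapolation, growth-chart
  practice).
- Centiles are clipped to [0.01, 99.99] with a `clipped` flag.
- Standardised-family moments for moment matching via 101-node
  Gauss–Hermite quadrature through the quantile function (probabilities
  clipped away from 0/1 at the extreme nodes, whose weights are ~1e-38).
- Degenerate designs degrade with warnings: one sex drops the sex term,
  a single site drops the site block.

## Problem sizes used in validation

The validation experiments run at the sizes the pipeline targets in
practice scaled to a desktop: training cohorts of n = 2000 over 5
sites, held-out unseen sites of n = 2000, 50 replicates for coverage of
±2 SE intervals, 100 000 Monte-Carlo replicates for the SD rule, and
patient groups of n = 200 (disease recovery) and 2 × 100 (laterality).
Coverage-type quantities are averaged over a handful of seeded
replicates of the same-size experiment, because a single n = 2000
closure measures a 50 % coverage with ±1.1pp binomial noise — the
averaging reduces estimator noise, not the claimed sample size.

## Known limitations

- No Bayesian hierarchical fitting, no vertex-wise models, no
  longitudinal (multi-session) modelling; first session kept, warned.
- K/I/S at hemisphere level only; regional folding components deferred.
- Scoring requires HCs from every unseen site; there is no
  prior-based fallback for HC-free uploads.
- The sigma submodel's site scale enters scoring only through the
  per-site SD rule, not as a refitted parameter.
- R² is in-sample on the training cohort unless held-out data are
  passed explicitly.
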