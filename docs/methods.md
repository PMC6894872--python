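# Methods

## The problem

A regression model fitted to available data is routinely asked to predict at
new locations. When a new location's covariates lie outside the range of the
fitting data — or form a novel *combination* of otherwise unremarkable values —
the prediction is an extrapolation and may be unreliable. For a univariate
response this is classically diagnosed with the independent variable hull
(IVH): a point `x0` is inside the hull when

```
x0' (X'X)^(-1) x0  <=  h,      h = max_i h_ii,
```

where `h_ii = x_i'(X'X)^(-1) x_i` are the leverages of the design `X`
(l rows, p columns including an intercept). Leverage and the squared
Mahalanobis distance of the covariate part of a row are monotonically related
when an intercept is present:

```
h_ii = 1/l + MD_i^2 / (l - 1),
```

so hull membership is a covariate-space outlyingness test. An equivalent
formulation replaces the quadratic form by the predictive variance of the
mean, which generalizes beyond the linear model: a prediction location is an
interpolation when its predictive-mean variance does not exceed the maximum
over the locations used to fit the model.

With a *multivariate* response the predictive variance at a location is an
`n x n` covariance matrix `V_i`, not a scalar, and the "does not exceed the
maximum" rule needs a scalarization. This package implements that multivariate
extension.

## Model

Responses are modelled jointly as a multivariate-normal linear regression

```
y_i = B x_i + eps_i,      eps_i ~ iid N(0, Sigma),
```

with `y_i` the length-n response vector of location i (in the motivating
water-quality setting: log TN, log TP, log chlorophyll a, log Secchi depth),
`x_i` the covariate vector (intercept + q covariates), `B` the n x p
coefficient matrix and `Sigma` the n x n residual covariance capturing the
dependence among responses left after regression. Priors are vague and
conjugate: independent `N(0, 100)` on each entry of `B` (100 is a variance)
and inverse-Wishart `IW(I, n + 1)` on `Sigma` — the smallest integer degrees
of freedom giving a proper prior on an n x n covariance. The df is
configurable (`Priors.iw_df`) because conventions tying it to the predictor
count also appear in practice.

A location's response vector may be fully observed, partially observed, or
fully missing. Estimation is by Gibbs sampling with data augmentation:

* `vec(B) | Sigma, Y` — multivariate normal; precision
  `Sigma^(-1) (x) X'X + I/100` (Kronecker, row-major stacking), solved by
  Cholesky each sweep (np <= ~40 in the shipped configurations, so the dense
  solve is trivial);
* `Sigma | B, Y` — inverse-Wishart with scale `I + E'E` and df `n + 1 + l`;
* missing entries of partially observed rows — drawn from the conditional
  MVN of the missing block given the row's observed block and current
  `(B, Sigma)`, vectorized over rows sharing a missingness pattern.

Fully missing rows carry no likelihood information; augmenting them would
only replay the current draw of `(B, Sigma)` plus noise, so they are held out
of the fit entirely and treated as prediction locations.

Defaults are 20,000 iterations with the first half discarded as burn-in and no
thinning; convergence is summarized by effective sample size (initial
positive-sequence autocorrelation estimator) and split-chain potential scale
reduction, with a warning (not a failure) above 1.05. Tests and the
acceptance script use 400–3,000 iterations at their smaller problem sizes;
posterior summaries there are stable at far fewer draws than the default,
which is sized for the full application scale.

## Predictive variance and its scalarizations

At a covariate vector `x`, each retained draw gives a predictive mean
`mu^(a) = B^(a) x`; the predictive-mean covariance is the sample covariance of
these across draws,

```
V_i = var(B x_i | Y),
```

deliberately *excluding* the residual `Sigma` — the hull is defined from the
variance of the mean, and adding a constant `Sigma` to every location would
not change any comparison against a cutoff computed the same way. Two
scalarizations are provided, named after their optimal-design analogues:

* `MVPV(tr)_i = tr(V_i)` — A-optimality style; ignores response correlations
  and is not scale-invariant, so it is mainly useful when all responses share
  a scale (e.g. all log-transformed);
* `MVPV(D)_i = |V_i|` — D-optimality style; accounts for correlations.
  Rescaling every response by fixed positive constants multiplies *every*
  determinant (observed and predicted) by the same factor, so max- and
  quantile-based identification is unchanged; the determinant itself is not
  invariant, only the identification it induces.

Determinants of 4 x 4 covariance matrices of small variances underflow
easily; they are computed from the symmetric eigendecomposition with
eigenvalues clipped at zero (a matrix indefinite beyond an 1e-8 relative
tolerance is rejected), and comparisons are monotone, so working on the
natural scale with doubles is safe at these dimensions.

### Conditional single-variable measure (CMVPV)

Often one response (TN in the motivating application) is the prediction
target, and the location's *other* observed responses should sharpen the
prediction. Per retained draw the joint `(mu^(a), Sigma^(a))` is partitioned
on target vs observed companions; the conditional MVN gives

```
mu_bar^(a)    = mu_t^(a) + S12 S22^(-1) (a_obs - mu_c^(a))
sigma_bar^(a) = S11 - S12 S22^(-1) S21     (Schur complement)
```

and the measure is `Var_a(mu_bar^(a)) + mean_a(sigma_bar^(a))`. For a
location with no observed companions the measure is
`Var_a(mu_t^(a)) + mean_a(Sigma_tt^(a))`: the second term is the residual
variance the conditioning would have reduced, added so that values are
comparable across locations with different observation status. Without it, a
location with rich companion data would look *worse* than one with no data at
all purely because the unconditioned value omits a variance term.

For this measure the observed/prediction split is target-driven: locations
where the target was sampled form the cutoff pool (each conditioned on its
own other observed variables), and every location missing the target —
partially observed or fully unobserved — is classified. Fully unobserved
locations carry the full residual variance and are therefore flagged at a
much higher rate than partially observed ones; that asymmetry is real, not an
artifact: with no response data at all, a single-variable prediction leans
entirely on the regression.

## Cutoffs and the extrapolation index

Cutoffs are always computed from observed-split values `v_o` only:

* `k_max = max(v_o)` — the classical hull boundary; very conservative when
  the fitting data contain their own outliers;
* `k_lev` — the maximum after removing locations whose leverage exceeds
  `2 p / l` (classical rule of thumb; multiplier configurable), so one
  influential fitting point cannot dictate the boundary;
* `k_r` — the empirical quantile at level r (0.99 and 0.95 by default),
  linear interpolation at plotting position `h = (l - 1) r + 1` (the default
  convention of mainstream statistical environments; configurable in the
  sense that any quantile level may be requested).

The binary extrapolation index is `e = 1` iff `v_p > k` (strict: a location
exactly on the boundary is an interpolation), and the relative measure
`R = v_p / k` grades how far beyond the hull a location lies; `e = 1` iff
`R > 1`. Decreasing cutoffs produce nested, non-shrinking extrapolation sets;
the run log prints counts in decreasing-cutoff order so the monotone pattern
is visible. Note the four rules above need not be monotone as a group — the
leverage-informed maximum can fall below the 0.99 quantile when the high-
leverage fitting points carry the entire upper tail of the measure — so the
log orders by realized value, not by rule name.

## When not to use predictive variance

Under bounded-mean models the predictive variance can *mask* extrapolation:
for Bernoulli data with a logit link, `var(y|p) = p(1-p) -> 0` as the linear
predictor grows, so a wildly out-of-range covariate point can carry a tiny
delta-method variance `(dg^{-1}/deta)^2 var(eta_hat)`. The
`glm_masking` module demonstrates this and pairs it with the design-based
hull test, which is immune (it never sees the response); for binomial, beta
or similar bounded supports the hull test is the recommended diagnostic.
Only the logit/Bernoulli case is shipped; the `GlmSpec` container admits
other links.

## Characterizing extrapolation regions

A binary classification tree fitted with the extrapolation index as the
response turns a list of flagged locations into interpretable covariate
regions ("shoreline above t1 and elevation above t2"). The tree is plain
greedy CART: Gini impurity, numeric covariates, midpoint thresholds, ties
broken by column order then smaller threshold, strict `<` routes left.
Defaults `max_depth = 4`, `min_leaf = 5`, no pruning — deep enough to read,
shallow enough not to memorize a rare class; optional inverse-frequency class
weights (off by default) counteract the strong imbalance typical of
extrapolation indices. These control choices are this package's defaults, not
inferred from any reference analysis.

## Synthetic data

The generator emulates the structure of a large multi-lake water-quality
compilation so every stage is testable with known truth:

* covariates: correlated MVN (exchangeable correlation 0.3 by default) —
  landscape covariates are mutually correlated but not collinear;
* responses: the generative model above; the default 4-response residual
  covariance uses log-scale SDs (0.65, 0.75, 0.95, 0.60) with strong positive
  TP–chlorophyll coupling (0.7) and negative Secchi correlations, the
  qualitative pattern of lake nutrient–productivity–clarity data;
* missingness: completely at random with per-variable probabilities
  (0.5, 0.2, 0.25, 0.15) — the first response (TN analogue) undersampled, as
  nitrogen is in real monitoring data. MCAR keeps parameter-recovery tests
  clean; an optional covariate-dependent mode mimics geographically
  informative undersampling for demonstration only;
* planted extrapolations: prediction-split points placed along random
  directions from the observed covariate mean, scaled to hit target squared
  Mahalanobis distances (60–150 in the `lagos-like` fixture, far beyond the
  ~35 maximum a 2,000-point 9-covariate Gaussian cloud attains).

What passing tests do **not** show about real data: the generator has no
spatial autocorrelation, no temporal averaging, no informative missingness
(in its default mode), exactly Gaussian tails, and a correctly specified mean
model. Detection rates on real compilations will differ; the tests establish
that the machinery is correct, not that any particular flag rate will be
observed in the field.

## Problem sizes and numerics

* Shipped fixtures: `tiny` (30 + 6 locations, 2 covariates, 2 responses),
  `small` (300 + 60, 4, 3), `lagos-like` (2,000 observed + 500 prediction +
  5 planted, 9 covariates, 4 responses). The acceptance script runs the
  lagos-like configuration with 2,000 Gibbs iterations and a 50-replicate
  interval-calibration study at smaller size; these are the package's default
  simulation scales.
* Quadratic forms and conditional moments use Cholesky/QR solves throughout;
  explicit matrix inversion appears only inside test oracles.
* Rank deficiency is declared at a relative singular-value threshold of
  1e-10, and the offending (linearly dependent) columns are named via pivoted
  QR.
* Mahalanobis distances use the intercept-excluded covariate columns with the
  l - 1 covariance denominator; they are computed only when the design has an
  intercept, since the leverage identity above presupposes one.
* Cook's distance uses the leverage/studentized-residual form with `p` the
  full coefficient count (so `trace(H) = p` is consistent); a location with
  leverage 1 is reported with infinite distance rather than an error.
* The conditional-MVN mean uses the standard `+` sign on the regression
  term; the Monte-Carlo rejection oracle in the test suite confirms the sign
  convention.
* Degenerate inputs: empty conditioning sets return marginal moments;
  all-one-class tree inputs return a single leaf; a chain of identical draws
  yields an exactly zero predictive variance.

## Known limitations

* No spatial or temporal structure in model or generator.
* Gaussian responses only; the GLM module demonstrates the masking hazard but
  does not fit GLMs.
* The leverage-informed cutoff's influence rule (leverage > 2p/l) is a
  covariate-only heuristic; response-space outliers in the fitting data still
  inflate `k_max`.
* Tree characterization handles numeric covariates only; no pruning or
  surrogate splits.
* E-optimality (maximum-eigenvalue) scalarization is not provided.
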