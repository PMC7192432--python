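# Methods

## Model

`dfakit` fits dynamic factor analysis (DFA) models to panels of z-scored
time series. DFA is a state-space dimension-reduction method: a small
number *m* of latent "common trends" evolve as random walks and each
observed series is a linear combination of them plus noise,

```
x_t = x_{t-1} + w_t,          w_t ~ MVN(0, Q)
y_t = Z x_t + a + D d_t + v_t, v_t ~ MVN(0, R)
```

with `y_t` the n-vector of observed anomalies in year t, `Z` the n × m
loading matrix, `d_t` an optional complete covariate series and `D` its
effect. Three conventions make the model identifiable and are fixed, not
estimated: the level `a = 0` (the data are z-scored), the state covariance
`Q = I`, and the loading cells `z_ij = 0` for column j > row i. The free
parameter count of a specification is therefore
`n·m − m(m−1)/2 + (R parameters) + (D parameters)`.

The observation covariance `R` encodes the scientific hypothesis about
unexplained variance and can be: one shared variance (`diagonal-equal`),
one variance per series (`diagonal-unequal`), shared variance plus one
shared covariance (`equal-variance-covariance`, i.e. compound symmetry),
or one variance per series group (`grouped-by-class`,
`grouped-by-station`). `m = 0` with a covariate is the trend-free
multiple-regression model.

## Estimation

The marginal likelihood is maximized by EM:

- **E-step.** An exact Kalman filter/smoother. Rows of `Z`/`R` belonging
  to missing observations are dropped from each update and the
  log-likelihood accumulates the prediction-error decomposition over
  non-missing cells only. The initial state is `x_0 ~ MVN(0, κI)` with
  `κ = 5` by default (configurable) — a vague but proper prior appropriate
  for z-scored data — so the filter starts from `Var(x_1) = (κ+1) I`.
  Because the model is time-invariant, the filter gain reaches a steady
  state within runs of a constant missing pattern; once the filtered
  covariance changes by < 1e-12 the gain is reused and only means are
  propagated, which is exact to rounding and dominates the speed of long
  panels. For the M-step, missing observations are treated as latent:
  their conditional first and second moments given the observed rows and
  the smoothed state are reconstructed exactly, including the
  `R_mo R_oo^{-1}` coupling needed for non-diagonal `R`.

- **M-step.** Closed form. The free cells of `Z` and the covariate
  effects solve a constrained weighted least-squares system (weighted by
  the current `R^{-1}`; a shared covariate effect is one tied parameter).
  `R` is then updated under its structure: group-averaged diagonals for
  the diagonal/grouped structures, and for compound symmetry the exact
  MLE obtained from its fixed eigenstructure
  `R = c1·J/n + c2·(I − J/n)`. Because `Z, D` are updated given the old
  `R` and `R` given the new `Z, D` (ECM), every iteration weakly
  increases the log-likelihood; the suite asserts this to 1e-8.

- **Acceleration.** Plain EM converges slowly along the nearly flat
  rotational directions of the loading space. `fit_dfa` therefore
  over-relaxes along the EM direction with an adaptive step (grown 1.4×
  per accepted step, capped at 16, reset on rejection) and keeps an
  extrapolated iterate only when the next likelihood evaluation confirms
  it did not decrease; otherwise it falls back to the plain EM iterate.
  The accepted log-likelihood sequence is still monotone.

- **Starts.** Free loadings are initialized U(−1, 1) and R variances
  U(0.1, 1), each start from an independent seeded stream. All starts get
  a short screening run (`screen_iter`, default 100 iterations) and only
  the best is iterated to convergence — the usual strategy for EM factor
  models. Convergence: absolute log-likelihood improvement < 1e-6
  (configurable) or `max_iter` (default 5000).

Reported trends are varimax-rotated (via statsmodels' rotation
machinery), with each rotated trend sign-flipped so its loading sum is
non-negative; the rotation is a presentation convention that leaves
fitted values unchanged, and the unrotated solution is also written.
Trend order carries no meaning.

## Model selection and diagnostics

Specifications are compared by AICc,
`−2ℓ + 2k + 2k(k+1)/(n−k−1)`, with `n` the number of non-missing
observation cells across all series — the only counting consistent with
the printed bookkeeping of the reference design (68 series with 472
station-years gives N = 1888). Differences ≤ 2 are labelled strong
support, > 10 very little. Failed fits are kept in the table with
infinite AICc rather than dropped.

Goodness of fit is `r² = 1 − SSE/SST` per series (SST about the series
mean of the z-scored data) and pooled across cells for the overall value.
Negative values are possible for badly fitting series and are reported
as-is rather than clamped, since the convention cannot be resolved from
printed values alone; the squared-correlation alternative can be computed
from the residual matrix if wanted. Loadings with |z| > 0.2 (strict) are
flagged as interpretable.

Correlations between trends (or residuals) and environmental series use
Spearman's rho with average ranks, and a t-test whose degrees of freedom
come from the autocorrelation-adjusted effective sample size
`1/N* = 1/N + (2/N)·r_x(1)·r_y(1)` (the modified Chelton correction
restricted to lag 1, matching how such series are usually handled;
summing higher lags is a straightforward extension but lag 1 is the
default and the only mode exposed). `N*` is capped at `N` when the
autocorrelation product is negative and floored at 3. No multiple-testing
correction is applied across the correlation tables; consumers should
treat the p-values as descriptive screening.

Residual diagnostics per series: D'Agostino–Pearson omnibus normality
(requires ≥ 8 residuals), lag-1 autocorrelation over consecutively
observed pairs flagged against ±1.96/√N, and a descriptive homogeneity
summary (Spearman correlation of |residual| with fitted value) — no
formal heteroscedasticity test is imposed.

## Preprocessing

From a long-format sample table (station, date, class, value): same-day
replicates are averaged first, then all sampled July–August dates are
averaged with equal weight (not calendar-weighted) into one summer mean
per station/class/year. Within one sample, taxa can be filtered to the
dominant set reaching 90% of total biovolume; the threshold is read
inclusively (the shortest descending-dominance prefix whose cumulative
share is ≥ 0.90, ties kept in input order), a deterministic reading of an
"approximately 90%" rule. Class-level zero means are replaced by a seeded
uniform draw on (0, half the series' smallest positive value] so the
series can be log-transformed. Every series is then ln-transformed and
z-scored with the sample SD (denominator n−1). Total-biomass series sum
the classes configured as consistently measured per station. The panel
carries a transform-state flag and refuses to z-score twice.

Sensitivity masking sets the given years to missing in every series and
re-z-scores over the remaining cells, then the model grid is refit and
the selected specifications compared.

## Synthetic data

The generator draws panels from the DFA generative model itself so every
downstream stage can be tested against known truth. Its defaults emulate
a Baltic-style monitoring panel: 17 stations (ordered southwest to
northeast) × 4 classes (cyanobacteria, dinoflagellates, diatoms,
cryptophytes) over 34 years from 1979, each station observed in 20–33
years (station-years are masked jointly across classes, as when a
station-year is simply not sampled). Latent anomalies are scaled to
log-biomass (`log_mean = 4`, `log_sd = 1`, arbitrary but realistic
magnitudes for wet-weight units) and exponentiated; each observed
station-year gets 1–3 July/August sampling dates with lognormal
within-year scatter (SD 0.1), so the averaging pipeline is exercised.
Zero inflation (default probability 0.03 per class-cell) and whole-year
class-wide absence events enter the *raw* table as zero biomass, so the
zero-replacement rule is exercised exactly where it matters. A
regime-shifting AR(1) climate index (coefficient 0.3, mean step −1 at
year index 16 — a mid-series shift) and station temperature/salinity
series with a latitudinal gradient round out the covariates.

What the generator does not emulate: species composition, nutrient
dynamics, observation error that is non-Gaussian on the log scale, or
spatial autocorrelation beyond the block loading structure. Passing
recovery tests therefore demonstrates correctness of the estimator under
its own assumptions, not robustness to the full messiness of field data.

## Problem sizes used in the test suite

The validation experiments run at reduced scale chosen to make their
statistical behaviour clear while keeping the suite practical to run
routinely: trend recovery uses 20 replicates of n=12 series over T=300
years (block loadings 0.6, R = 0.25·I, 3 starts, ≤ 2000 iterations);
selection consistency 10 replicates of n=12, T=150 over a 1–3 trend
grid; the sensitivity harness 10 replicates of a 6-station × 2-class,
34-year panel with two injected whole-year class absences. Exact-inference
checks run on 100 random instances with n ≤ 3, m ≤ 2, T ≤ 5 against a
brute-force joint-Gaussian oracle.

## Known limitations

- EM (even accelerated) can need thousands of iterations on weakly
  identified panels; fits report `converged=False` honestly when the
  tolerance was not reached.
- The m=0 regression path requires a non-degenerate covariate; an
  all-zero covariate makes the M-step singular.
- Totals containing zeros cannot be log-transformed; zero replacement is
  deliberately restricted to class-level series.
- Standard errors of loadings are not computed; inference about trends
  is by model comparison and post-hoc correlation, not Wald tests.
- Covariates are used as provided (not re-standardized); pre-scale them
  if effect sizes should be comparable.
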