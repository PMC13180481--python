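# Methods

This note documents the statistical machinery, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices a maintainer would want to know about.

## Trend models

Each population's annual counts are treated as independent draws
`y_t ~ NB(mu_t, theta)` with log link and NB2 variance `mu + mu^2/theta`.
Years are centered on the first observed year internally, so fits are
invariant to calendar shifts; gaps are simply absent rows (no imputation).

**Eligibility and routing.** Populations need at least 6 distinct observed
years (consecutive or not). 6–9 years route to a log-linear GLM; 10 or
more to a penalized-spline GAM. The thresholds are configurable
(`min_years`, `gam_threshold`).

**GLM.** `log mu = a + b·(t − t_first)`. `theta` is profiled by outer
maximum likelihood (bounded search on `log theta` in `[log 1e-2, log 1e7]`,
tolerance 0.05); the inner problem is IRLS with step halving on the
penalized log-likelihood. The omnibus test is the likelihood-ratio
statistic against the intercept-only NB fit, referred to an `F(1, n−2)`
distribution rather than `chi2(1)`: at 6–9 observations with estimated
dispersion the chi-squared reference rejects ~9–10% at nominal 5%, while
the F reference measured 5.0% in simulation (300 stable series, theta=5,
n=9).

**GAM.** `log mu = f(t)` with `f` a cubic B-spline of dimension
`k = min(10, n_obs − 2)`, interior knots at quantiles of the observed
years, and an integrated-squared-second-derivative penalty `lambda·S`
(computed exactly by 3-point Gauss–Legendre per knot span). The penalty
null space is the linear functions, so the smooth may legitimately shrink
to a straight line (`edf → 2`); that is not an error. `lambda` is chosen
by a Laplace-approximate restricted marginal likelihood (REML) evaluated
at the converged penalized fit, and `theta` is profiled on the *same* REML
criterion. This matters: profiling `theta` on the unpenalized likelihood
lets excess dispersion be re-explained as spurious wiggliness, which in
simulation inflated the omnibus rejection rate under constant trends to
~35%; the shared REML criterion removes the trade-off.

**Omnibus test for the smooth.** The statistic is
`2·(penalized loglik of the smooth − loglik of the intercept-only fit)`,
referred to `chi2` with `df = tr(2F − FF) − 1`, where
`F = (X'WX + lambda·S)^{-1} X'WX`. Two deliberate choices:

- the *penalized* log-likelihood charges the fit for its wiggliness, and
- `tr(2F − FF)` is the smoothing-bias-corrected effective degrees of
  freedom, larger than `tr(F)`, which accounts for the smoothing parameter
  having been estimated.

The naive combination (unpenalized statistic, `tr(F) − 1` df) rejected
10.5% under the null at nominal 5%; the implemented combination measured
7% (200 stable series, theta=5, n=15). The reference distribution remains
approximate — penalized LRTs have non-standard nulls — and the residual
anti-conservatism is inherited by downstream screening, where it is
absorbed by the FDR margin (measured directional error 0.5%).

**Coefficient covariance** is the Bayesian posterior
`(X'WX + lambda·S)^{-1}` (the frequentist sandwich is not used), with
`theta` treated as fixed at its profiled value, as is conventional.

## Contrasts and classification

`begin_end = [f(t_last) − f(t_first)] / (t_last − t_first)` on the linear
predictor (log) scale, making GLM and GAM values commensurable and
size-independent; the divisor is the elapsed span, not the number of
observations. `avg_slope` is the mean first derivative over a uniform grid
of 201 points, by central finite differences with step `1e-4 × span`; for
the linear basis the exact derivative (the slope itself) is used, so
`begin_end == avg_slope == b` holds to machine precision for GLMs.

Uncertainty comes from parametric simulation: 10,000 coefficient draws
from `N(beta, V)` (fixed seed; Cholesky with a `1e-12`-scaled jitter, a
singular covariance raises "unstable fit"), the SE is the draw standard
deviation and the two-sided p-value uses a normal reference. A pure
draw-counting p-value would be floored at `2/n_sim`, too coarse for BH
screening across hundreds of sites.

Classification is stage-wise per model family (GLM and GAM corrected
separately, mirroring their separate reporting): BH screening on omnibus
p-values at `alpha = 0.05` selects `R` of `m` sites; screened sites are
confirmed when the begin–end p-value is at most `alpha·R/m`. Labels follow
the contract: not screened → `non_significant`; confirmed → `increasing`
or `decreasing` by sign; screened but unconfirmed → `flexible`. For the
GLM family the begin–end contrast *is* the omnibus hypothesis, so
screening alone decides and `flexible` is unreachable by construction.
Only the begin–end contrast is ever used for labels; the average slope is
reported alongside. A population is `disappeared` when it is labelled
`decreasing` and its last two observed counts are zero — an operational
rule chosen because monitoring typically stops only after repeated empty
years.

## Landscape metrics

Buffers use the center-in-circle rule on cell centers. Patches are maximal
4-connected (rook) same-class regions; edge length is the count of
rook-adjacent unlike-class cell pairs times the cell size, so it is the
exact class-boundary length at cell resolution; the buffer rim and masked
cells contribute nothing. Patches clipped by the buffer count as whole
patches (no boundary correction) — a documented limitation. Shannon
diversity uses natural log over the six merged classes; nodata cells are
excluded from every denominator and a buffer over 50% nodata logs a
warning. Metrics are computed on the 6-class (merged) map. The 11→6
merging ships as an editable `ReclassTable` (CSV-loadable) — it is
configuration, not inference. Raster I/O is plain-text ESRI ASCII grid;
inputs must share one projected metric CRS (no reprojection engine).

## Association testing

The design per radius is `[identity proportions except the reference |
shannon | n_patches | edge_length | bray_curtis_change]`. Identity
proportions stay on their natural [0, 1] scale so the intercept keeps its
interpretation (expected trend in a landscape made entirely of the
reference class, agricultural land by default) and each identity
coefficient is a replacement effect; structure and change columns are
z-scored, which stabilizes the design and leaves all F-statistics
invariant to affine rescaling of those predictors. Rank is verified with a
greedy QR-style scan that names the aliased columns; entering all six
identities is the canonical failure.

The interaction test augments the design with all pairwise products of the
non-reference identity columns (up to 10), dropping any product aliased
with columns already present and reporting the realized numerator df
transparently. The main-effects omnibus is the standard F against
intercept-only. Post-hoc per-term tests (BH across terms within a radius)
are populated only when an omnibus rejects. Moran's I uses
inverse-Euclidean-distance weights, zero diagonal, row-standardized;
expectation `−1/(n−1)` exactly, variance under the normality assumption,
two-sided p; duplicate coordinates are jittered by 0.5 m with a logged
warning. By default only GAM-family populations enter the association
model (`population_subset="gam_only"`), switchable to all labelled sites.
In orchestrated runs too few sites for the interaction model degrades to
"interaction test skipped" rather than aborting the workflow; calling
`test_interactions` directly still raises.

## Synthetic data

The generator produces what the analysis assumes, with ground-truth
labels:

- **Counts**: NB draws around four latent log-mean shapes — `constant`,
  `linear` (slope per year), `step` (mid-series jump sized so its
  begin–end per-year change matches the linear shape), and `hump` (a
  parabola with equal endpoints and peak `amplitude_log`). Shapes are
  parameterised on the observed span so hump endpoints coincide with the
  series endpoints regardless of gapping. Defaults: mean 100 at baseline,
  `theta = 5` (a harness choice — no dispersion estimate exists for real
  patrol data), 15 observed years within 1981–2022, and gaps in 60% of
  series (gapped series spread over the full range with endpoints always
  retained; ungapped series are consecutive blocks). Endpoints are always
  retained because the begin–end contrast needs both.
- **Rasters**: Gaussian-smoothed white noise thresholded at class-weight
  quantiles (composition exact to one cell per class, patch size set by
  `patch_scale`), chosen over patch-growing for determinism and O(cells)
  cost; the second date reassigns exactly `round(change_fraction·n_cells)`
  random cells.

What the generator does **not** emulate: within-season phenology (the
analysis consumes annual sums), observation-effort variation, temporal
autocorrelation of counts, real land-cover frequencies or spatial
layouts of any particular region, and spatially correlated trends across
sites. Passing tests therefore demonstrate the statistical machinery's
operating characteristics under the stated generative model, not field
performance on real monitoring data.

## Simulation sizes and tolerances

The test suite and `scripts/acceptance.py` use: 200 stable series for the
directional type-I check (bound 7.5% = 5% FDR + Monte-Carlo margin), 100
decline series for power (bound 90%), 40 hump series for the flexible
rule, 100 monotone series for contrast concordance (Spearman ≥ 0.9), 100
random 20×20 grids for exact oracle equivalence, 200 replicates for
replacement-effect recovery (within 2 SE in ≥ 90%), 500 replicates for
F-test calibration ([3%, 8%] at nominal 5%), and 100 trials × 1000
permutations for Moran's I null coverage (≥ 93%). Optimizer tolerances:
0.05 on `log theta`, 0.1 on `log lambda`, IRLS relative tolerance 1e-9
with at most 200 iterations and 30 step-halvings; a warm start that fails
is retried cold before a series is excluded as non-convergent (excluded
sites are logged with reasons, never silently coerced).

## Known limitations

- The GAM omnibus reference distribution is approximate (measured 7%
  rejection at nominal 5% under the null); FDR control of the final labels
  is the property that holds tightly.
- Begin–end contrasts at the series endpoints inherit smoothing bias when
  the trend bends sharply right at an endpoint.
- Buffer metrics have no boundary correction for clipped patches, and
  small landscape elements below cell resolution are invisible.
- No spatial pooling across populations, no spatial regression (SAR/CAR),
  and no connectivity/resistance modelling.
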