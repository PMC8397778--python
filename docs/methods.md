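# Methods

## Model

Each OTU's read count at site *s* is modelled as a rate times exposure:

    count_s ~ F(mu_s),   log mu_s = o_s + beta_0 + sum_v f_v(x_sv)

with offset `o_s = log L_s` (the site's raw total sequence count, taken
*before* any filtering, so filters never change the exposure), nine
predictor effects `f_v`, and response family `F` either Poisson or negative
binomial (NB2: `Var = mu + alpha mu^2`). Because the offset enters the link
additively, predictions are exactly linear in the exposure: doubling the
offset's library size doubles every predicted count. Projections onto new
sites use a common fixed offset, the log of the median training library
size, so projected abundances are comparable across sites.

### GAM engine

`f_v` are penalized cubic B-splines (basis size 10 per predictor, built by
statsmodels' `GLMGam`/`BSplines`). Predictors are standardized internally so
one shared penalty weight is meaningful across variables; the weight is
chosen by generalized cross-validation, `n·Deviance/(n − edf)²`, over the
grid {0.1, 1, 10, 100, 1000} under the Poisson working family. For the NB
family the dispersion `alpha` is then estimated by an outer profile
likelihood: a method-of-moments start from the Poisson fit's residuals,
refined over a multiplicative grid {0.25, 0.5, 1, 2, 4}× with the additive
model refit at each candidate and the NB log-likelihood as the criterion.

Degenerate inputs: all-zero counts are rejected; if the penalized IRLS
terminates with an exact fit (statsmodels' perfect-separation guard, e.g.
constant counts at a common offset) the fit falls back to the intercept-only
model, which reproduces the constant exactly. Predicted means are floored at
1e-10 so deviances stay finite.

The spline basis is only defined over the training range; prediction clamps
each predictor to that range, i.e. the smooths extrapolate as constants
beyond it. This is deliberate: projection sites beyond the training envelope
are flagged non-analogous anyway, and constant extrapolation avoids the
unbounded excursions a polynomial tail would produce there.

### GBM engine

Stagewise Poisson-deviance boosting: the baseline is the maximum-likelihood
constant rate `f0 = log(sum y / sum exp(o))`; each of the 2000 stages fits a
least-squares regression tree (depth ≤ 3) to the current gradient residuals
`y − mu` on a seeded 50 % subsample, then replaces each terminal node's
value with the Poisson line-search update `log(sum y / sum mu)` over the
in-bag samples in that node (clipped to ±4), scaled by the shrinkage 0.01.
With the bagging fraction at 1 this construction descends the training
deviance monotonically; the default 0.5 matches common boosting practice.
Trees are stored as plain arrays, so serialization and re-loaded prediction
are bit-exact.

Friedman relative influence is accumulated as each tree's unnormalized
squared-error split improvements per predictor, normalized to sum to 100.
Note a caveat established during development: on heteroscedastic counts
(library sizes spanning 10×, NB noise) these unweighted squared-error
attributions systematically dilute the dominant smooth driver relative to
hessian-weighted attributions (cross-checked against xgboost's total gain on
identical data). The permutation measure below does not suffer from this and
is the engine-agnostic ranking used in the recovery experiments.

## Assessment protocol

* `cor_expl`: Pearson correlation of observed and fitted counts on the
  response scale (Spearman available via a flag). A constant vector makes
  the correlation undefined; it is returned as NaN and treated as failing
  the retention threshold rather than silently zero.
* Split plan: ten independent partitions with exactly `round(0.8 n)`
  calibration sites, so over the plan each site is used on average 8× for
  calibration and 2× for evaluation. `cor_pred` refits the model per
  calibration set, averages each site's held-out predictions over the
  repeats that evaluated it, and correlates observed counts with those
  averages; sites never evaluated under a plan are dropped (logged). For GAM
  refits the smoothing weight and NB dispersion estimated on the full data
  are held fixed — only the coefficients are re-estimated — which keeps the
  ten refits cheap and avoids split-to-split tuning noise.
* Exclusion: an OTU is dropped from projections only when *both*
  `cor_expl < 0.2` and `cor_pred < 0.2` (strict; NaN counts as weak).
* Permutation importance: each predictor column is shuffled across sites
  (10 permutations by default) on the *fitted* model — no refitting — and
  the raw importance is the drop in observed-vs-predicted correlation,
  floored at 0 and normalized to percentages. All shuffled designs are
  stacked into a single prediction call so tree ensembles remain affordable.

## Scenario engine

Mean per-pair slopes `(value_new − value_old)/(year_new − year_old)` from
paired resurvey records are extrapolated from the base year (default 2013)
to 2060; "increase" applies the extrapolated shift, "decrease" its negation,
"now" zero. The packaged default magnitudes are 0.3 pH units and 3.2 TOC
percentage points. TOC shifts act on the raw percentage scale and the
modelling column `TOC_log` is recomputed afterwards, with TOC floored at
0.01 % so the log stays defined under the decrease scenario. Shifts are
spatially constant. The nine combinations all carry the future climate
columns; radiation, topography and clay never change. Non-analog flags mark
values strictly outside the training min–max (the closed interval is
analog); a warning is emitted if a shifted pH leaves [2, 10].

## Community summaries

Response curves run each predictor over 100 equally spaced points between
its training min and max, others held at training medians, offset at the
median library. "Proportion above median" compares each OTU to its own
median across the evaluation points of the same summary (grid points for
curves, projection sites for maps). Shannon uses natural log on relative
abundances of expected counts at the common offset (equivalently rates), so
it is invariant to rescaling all abundances. Change classification uses a
relative threshold of 1e-6: with continuous predictions ties are essentially
impossible, so the three percentages partition the OTUs. Summaries are
emitted for all sites and restricted to analog sites.

## Synthetic generator

The generator emulates the study design, not any particular dataset: 255
training and 229 projection sites; predictors sampled independently and
uniformly within realistic mountain-region ranges (pH 3–8.5, TOC 0.5–60 % on
a log scale, coldest-quarter temperature −14–1 °C, …), with an optional
copula knob for pH–temperature covariance (off by default); library sizes
log-uniform over [5·10⁴, 5·10⁵]; 60 OTUs with Gaussian log-rate niches and
NB dispersion 1 (strong overdispersion, as preliminary fits to real
sequence counts typically show).

Niche defaults are set once, on ecological grounds. pH is the dominant axis:
optima U(6.8, 8.2) and breadths U(0.6, 1.0), reflecting a calcareous-bedrock
region whose community diversity increases along the sampled pH gradient;
the other eight predictors get a maximal log-rate drop across their gradient
of U(0.5, 1.5) — several-fold weaker than pH's. Baseline relative abundance
at the niche centre is U(1e-4, 1e-3). The parameter-recovery experiments use
interior pH optima, U(5.5, 7.5): a peak within about two breadths of the
sampled boundary is statistically unidentifiable (the true-model
maximum-likelihood oracle fails there too), so recovery is evaluated where
the data can, in principle, answer. The recovery check compares the response
curve's argmax to the true optimum on a 20-point grid (step ≈ 0.29 pH);
this resolution matches the information actually present — the oracle's
median peak-location error at these sample sizes is ≈ 0.1 pH units, so a
100-point grid step would be far below the attainable precision for any
estimator.

What the generator does *not* emulate: spatial autocorrelation, predictor
multicollinearity (beyond the optional copula), zero-inflation beyond the
NB's own zeros, relic DNA, chimeras, or read-level artefacts. Passing tests
therefore demonstrate the correctness and statistical behaviour of the
pipeline under its stated model, not performance on raw field data.

Sequence fixtures are substitution-mutated copies of random ancestors scored
with a simple global match/mismatch alignment (+5/−4, gaps −10/−1); with
equal-length substitution-only variants the self-score is maximal by
construction. They exist to exercise the distance/clustering path, not to
model real amplicon evolution.

## Problem sizes

The packaged experiments run the full study scale for the statistics that
need it (60 OTUs × 255 sites for recovery, overdispersion and
scenario-direction experiments; 229 projection sites) and small fixtures
elsewhere. The overfitting comparison uses one seeded 80/20 split per OTU
(gap = calibration minus evaluation correlation); the ten-repeat protocol is
exercised separately where `cor_pred` itself is the quantity of interest.
The pipeline driver's demo configuration scales everything down (60 sites, 5
OTUs) since it tests plumbing, not statistics.

## Known limitations

* GAM smoothing is a single shared penalty on standardized inputs, selected
  on a coarse grid — adequate for ranking and recovery, coarser than a
  per-term REML optimization.
* NB dispersion is a single per-OTU constant; zero-inflated families are out
  of scope.
* The GBM's Friedman influence inherits the least-squares attribution bias
  described above; prefer permutation importance when ranking predictors
  across engines.
* Scenario shifts are spatially constant; no soil-buffering dynamics.
* Offsets make projected *absolute* changes conditional on the chosen
  reference library size; directions and rankings are unaffected.
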