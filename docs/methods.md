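# Methods

This note documents the models, the simulation design, the synthetic
population and the numerical choices behind `arvarsim`, in enough detail to
judge what the package's results do and do not show.

## Processes and estimators

The data-generating process is a zero-mean, stationary VAR(1),
x_t = Φ x_{t−1} + ε_t with independent Gaussian innovations and a diagonal
innovation covariance diag(σ²_1…σ²_p). Gaussianity is the standard VAR
assumption and the one under which the OLS estimators used here are maximum
likelihood. Series start from the zero state and a burn-in (default 100
steps) is discarded so samples come from the stationary distribution; for
the default coefficient scales (spectral radius mostly below 0.7) the
transient decays well within that window.

Both model classes are estimated by per-equation ordinary least squares of
x_t on x_{t−1} with no intercept: the processes are simulated zero-mean and
the error measures concern Φ only, so an intercept would add a parameter
that never enters any reported quantity. An `intercept=True` switch exists
on both fitters for non-centred data; the intercept is excluded from
estimation error. The VAR fit solves the normal equations; a design with
condition number above 1e12 raises a singular-design error by default
(`on_singular="pinv"` opts into a pseudo-inverse fallback instead — an
explicit opt-in, because a silent fallback would hide that the reported
coefficients are not a unique least-squares solution). The AR fit is the
univariate slope per coordinate with off-diagonals structurally zero.

Estimation error averages squared coefficient deviations over all p²
entries for both model classes, so the AR fit pays (1/p²) Σ_{i≠j} Φ²_ij for
its structural zeros. This convention is what produces the AR bias floor —
the quantity the whole bias–variance story rests on. The alternative
(averaging AR error over the p diagonal entries only) would make EE_AR and
EE_VAR averages over different parameter sets and their crossing
uninterpretable. Prediction error is the grand mean of squared one-step
errors over test time points and coordinates, a single scalar per fit. Its
floor is mean(σ²_i); estimation noise adds to it, which is what makes
PE curves cross at a different n than EE curves.

## Replication design

Per true model and replicate, one training series of length max(n_grid)
and one independent test series of length n_test = 2000 are simulated.
Both model classes are then fitted on the *prefix* of the first n
observations for every n on the grid — the same series grows, as it would
for a researcher collecting more data, so curves are smooth in n within a
replicate. Means and SDs across replicates give the four error curves.
Defaults: n_grid = {8, 10, …, 500}, 20 replications at desk scale
(100 at full scale).

Fits below the minimum-n rule (n ≥ p + 2 for VAR, n ≥ 3 for AR) or with a
numerically singular design are flagged unfittable and excluded from that
grid point's mean rather than imputed — imputation would bias the curves
exactly where they are least reliable.

Crossover points use the replicate-averaged curves: n_e is the first grid
point with EE_AR > EE_VAR strictly, n_p likewise for prediction error, and
n_gap = n_e − n_p. First-crossing needs no extra parameter; noisy curves
can cross repeatedly, and a persistence window (`persistence=w`, requiring
the inequality to hold for w consecutive valid grid points) is exposed for
sensitivity analysis but off by default. A pair of curves that never
crosses on the grid is reported as censored — all that is known is that
the crossover lies beyond max(n_grid) — and censored models are excluded,
with counts, from distribution summaries. A per-replicate crossing mode
(locate the crossing in each replicate, take the median) is available via
`crossing_summary(..., use_replicates=True)` but is not the default: the
question posed is about expected error, and replicate-level EE curves at
small n are dominated by sampling noise.

Seeds are hierarchical (master seed → model index → replicate →
train/test substream) via `numpy.random.SeedSequence`, so every replicate
is reproducible in isolation and models are embarrassingly parallel
(`threads` uses joblib). All outputs are bit-reproducible from
(config, master seed).

For speed, prefix fits reuse cumulative Gram matrices (running sums of
x_{t−1}x_{t−1}ᵀ and x_{t−1}x_tᵀ), making the whole n-grid one pass over
the series plus a p × p solve per grid point; test-set prediction error is
evaluated from the test Gram matrices. Equality with the direct
fit-and-predict route is asserted by tests to ~1e−9 relative.

## Synthetic population

The population stands in for a multilevel VAR fitted to experience-sampling
data: a fixed-effects matrix with person-level deviations. Each draw is

Φ = fixed_phi + S ∘ re_sd ∘ Z,  Z entrywise standard normal,

where S applies two per-draw lognormal scale factors (one for the diagonal
block, one for the off-diagonal block) to the entrywise random-effect SDs.
The scale mixture makes person-level effects heavy-tailed: with purely
Gaussian entrywise effects the *mean* of 30 absolute off-diagonals has a
cross-person max/min ratio of only ~2.6, and the sampled models would
collapse onto a sliver of the D–O plane instead of populating a 15 × 15
grid. `scale_log_sd=(0, 0)` switches the mixture off. Draws are
rejection-sampled to stationarity; innovation variances are lognormal
(log-mean 0, log-sd 0.3, i.e. unit-scale variances varying by a factor of
~2 across variables).

Default parameters (p = 6) were calibrated once, against the behaviour
reported for person-specific VAR fits to affect data, and then frozen:

- fixed diagonal 0.12 with random-effect SD 0.18 and diagonal scale
  log-sd 0.8, so D spans at least [0.05, 0.5] across 1000 draws;
- fixed off-diagonals ±0.07 with alternating signs (positive and negative
  lagged influences mix in affect networks), random-effect SD 0.06 and
  off-diagonal scale log-sd 0.5, giving O typically near 0.08 and ranging
  ~[0.05, 0.2].

The nonzero fixed cross-lags matter: they bound O away from zero across
persons, which is what keeps crossovers observable — published full-scale
results show only ~0.4% of models failing to cross by n = 500, and the
package's default study reproduces that near-total crossing. A population
with zero fixed cross-lags and only random off-diagonal effects
(an earlier calibration attempt) leaves a fringe of near-diagonal models
whose crossover lies far beyond any realistic grid.

Stratification: a pilot sample (default 2000 draws; 10000 at full scale)
sets equal-width grid edges over the observed D and O ranges (15 bins per
axis, half-open intervals with the last closed); only cells containing at
least one pilot point are retained, and sampling continues until every
retained cell holds `per_cell` models, discarding overflow so cell counts
stay exactly equal and results are comparable across cells.

Weights: stratification deliberately distorts the population, so summary
statistics re-weight each model by the pilot fraction of its cell, shared
equally within the cell (`weight_mode="cell"`, the default). A per-entry
Gaussian-density product over Φ − fixed_phi (`"density"`, with the scale
factors integrated out by Gauss–Hermite quadrature) is implemented and is
the right object for small unstratified collections, but for a stratified
collection a 36-dimensional density ratio is so peaked that the normalized
weights degenerate onto the single model nearest the fixed effects;
`"uniform"` is available as a robustness check. Weighted medians and
quantiles use lower interpolation on the weighted empirical CDF (n_e is
integer-valued, so the convention must be fixed to be testable); the n_gap
histogram uses width-10 bins centred on zero so "mode at zero" is
well-defined.

## Selection rules

At each (model, n): min-PE takes the model with the lower replicate-mean
prediction error (AR on an exact tie — parsimony); the 1SER takes AR
whenever PE_AR ≤ PE_VAR + SE, boundary inclusive. The SE is the replicate
SD of PE_VAR across training sets — the across-training-set SD *is* the
standard error of a single-training-set PE, so no √reps division applies.
The rule's reference model is VAR by default; `mode="best"` uses the SD of
whichever model currently has the lower PE (the classic
statistical-learning formulation). Both rules are scored by
EE_diff = EE_best − EE_sel ≤ 0, and EE_comp = EE_diff(1SER) −
EE_diff(min-PE); the disagreement analysis restricts to cases where the
rules differ (everywhere else EE_comp = 0 identically), weighting each
case by its model's weight, uniform over n within model.

## What the synthetic study does and does not show

The generator emulates the *structure* of a fitted multilevel VAR —
person-level heterogeneity in both effect blocks, diagonal innovation
covariance, stationarity — and is calibrated to the published D–O scales,
but it is not a fit to any real data set. Reproduced qualitative findings
(the crossover n_e falling as O grows; a right-skewed n_gap distribution
with mode at zero; EE_comp positive at small-to-moderate n and vanishing
at the top of the grid) are therefore statements about this population
family, not about any particular empirical panel; exact headline values
(e.g. the weighted median n_e) shift with the population's O level.
Real experience-sampling data also violate assumptions held fixed here:
non-Gaussian and non-stationary innovations, measurement error, unequal
sampling intervals, day/night structure, and correlated random effects
across entries. None of these enter the simulation, by design — the
package isolates the sample-size question under the model's own
assumptions.

Other limitations: only lag 1 and diagonal innovation covariance are
supported (higher lags, regularized estimators and mixed-effects
estimation are out of scope); prediction error is an out-of-sample test-set
quantity, not a cross-validation estimate from a single observed series,
so the selection-rule results describe the rules' *potential*, with the
cross-validated practitioner setting left as future work.

## Numerical conventions collected

- Stationarity: strict spectral-radius test, |λ|max < 1 via eigvals.
- Singularity: condition number > 1e12 → error (direct fits) or
  unfittable flag (experiment grid); AR additionally rejects constant
  lagged columns (zero lagged variance).
- Replicate SDs use ddof = 1; grid points with < 2 valid replicates report
  NaN SD.
- Weighted skewness is m₃/m₂^{3/2} with weighted central moments and is
  defined as 0 for a degenerate (zero-variance) distribution; weighted
  correlations with a zero-variance margin are reported as missing.
- Matrix CSV I/O uses %.17g, exact round-trip; pipeline CSVs are re-read
  with round-trip float parsing so staged and end-to-end runs are
  byte-identical.
- Desk-scale defaults (pilot 2000, per_cell 2 → ~150–220 models, reps 20,
  n_grid {8, 10, …, 500}, n_test 2000) complete in a few minutes on one
  CPU; the full-scale design is exposed as `paper_scale_config()`.
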