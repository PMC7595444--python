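# arvarsim

**When does a VAR(1) model beat an AR(1) model on a short multivariate time
series — and how should you choose between them in practice?**

Researchers working with intensive longitudinal data (experience sampling,
ecological momentary assessment, ambulatory physiology) routinely fit
first-order autoregressive models to person-level time series of p ≈ 6
variables and n ≈ 30–200 time points. The scientific payoff of the full
vector-autoregressive model — the cross-lagged effects that make up a
dynamic network — comes at the price of p² parameters instead of p, and at
typical sample sizes the simpler diagonal AR model can have *lower*
estimation error even though it is misspecified: the classic bias–variance
trade-off. `arvarsim` is a simulation laboratory for exactly this question.

## The models and the quantities computed

A zero-mean VAR(1) process on p variables evolves as

```
x_t = Φ x_{t-1} + ε_t,     ε_t ~ N(0, diag(σ²_1 … σ²_p)),
```

with a p × p lag-1 coefficient matrix Φ (stationary iff every eigenvalue
satisfies |λ| < 1). The AR(1) model is the special case with diagonal Φ.
Two scalars summarise a coefficient matrix:

- **D** = (1/p) Σᵢ |Φᵢᵢ| — mean absolute autoregressive effect,
- **O** = (1/(p(p−1))) Σᵢ Σ_{j≠i} |Φᵢⱼ| — mean absolute cross-lagged effect.

Both model classes are fitted by per-equation ordinary least squares of
x_t on x_{t−1}. For a fit Φ̂ against a known truth Φ the package measures

- **estimation error** EE = (1/p²) Σᵢⱼ (Φ̂ᵢⱼ − Φᵢⱼ)² (AR's structural zeros
  are counted, which is what gives AR its bias floor), and
- **prediction error** PE = mean squared one-step-ahead error on an
  independent test series.

Monte-Carlo replication over a grid of sample sizes n yields four curves
EE_AR(n), EE_VAR(n), PE_AR(n), PE_VAR(n) per true model, and from them

- **n_e** — smallest n at which EE_AR > EE_VAR (VAR starts winning in
  estimation), **n_p** — the same for prediction error, and
  **n_gap = n_e − n_p**, whose sign says which model deserves the benefit
  of the doubt when prediction errors tie;
- a head-to-head comparison of two selection rules: *min-PE* (take the
  model with lower prediction error) and the *1 Standard Error Rule*
  (prefer AR unless its PE exceeds VAR's by more than one standard error),
  scored by the estimation-error regret difference **EE_comp** (> 0 when
  the 1SER picked the better model).

True models are drawn from a synthetic multilevel population (fixed-effects
Φ plus heavy-tailed person-level random effects, rejection-sampled to
stationarity), stratified over a 15 × 15 grid of the D–O plane so that
rare corners of parameter space are represented, then re-weighted by the
population probability of each grid cell.

## Worked example

Fit both models to one short series from a known truth:

```python
import numpy as np
from arvarsim import (VARModel, simulate_var, fit_var, fit_ar,
                      estimation_error, prediction_error)

phi = np.array([[0.30, 0.10], [0.05, 0.25]])
truth = VARModel(phi=phi, noise_vars=[1.0, 1.0], model_id="demo")
train = simulate_var(truth, n=60, burn_in=100, seed=7)
test = simulate_var(truth, n=2000, burn_in=100, seed=8)

var_fit, ar_fit = fit_var(train), fit_ar(train)
for name, fit in [("VAR", var_fit), ("AR", ar_fit)]:
    print(f"{name}: EE = {estimation_error(fit, truth):.4f}   "
          f"PE = {prediction_error(fit, test):.4f}")
```

```
VAR: EE = 0.0029   PE = 1.0390
AR: EE = 0.0032   PE = 1.0296
```

At n = 60 this truth (O = 0.075) sits right at the crossover: the
misspecified AR fit is still slightly ahead on prediction error while the
VAR fit has just pulled ahead in estimation error — a single replicate of
the phenomenon the full study quantifies.

Run a small version of the whole study (about ten seconds):

```python
from arvarsim import Study, StudyConfig

cfg = StudyConfig(pilot=500, per_cell=1, n_grid=tuple(range(8, 201, 4)),
                  reps=10, master_seed=42)
res = Study(cfg).run()
print(res.summary())
```

```
AR(1) vs VAR(1) crossover study
==================================
models: 73   retained D-O cells: 73
censored: n_e 2, n_p 1
n_e weighted median [IQR]: 116 [56, 152]
n_gap weighted median: 12   skewness: 1.25   mode bin: (5.0, 15.0)
1SER better in 60.2% of 280 weighted disagreement cases
mean EE_comp > 0 for n in [8, 192]
```

Reading the output: across this small stratified collection the VAR model
needs a weighted-median n_e = 116 observations before it beats AR in
estimation error; the n_gap distribution is right-skewed with its mass
near zero; and in the (model, n) cases where the two selection rules
disagree, the 1SER picks the better model more often than not, with its
advantage concentrated at small n.

The same pipeline is scriptable from the shell
(`arvarsim all --seed 7 --out-dir study_out`, with per-stage subcommands
`sample-models`, `run-curves`, `crossings`, `compare-rules`, `report`), and
`arvarsim.pipeline.paper_scale_config()` returns the full-scale design
(100 models per retained cell, n up to 500, 100 replications) for those
with cluster-style patience.

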