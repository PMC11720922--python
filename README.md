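# cbnn — case-base sampling for survival analysis with logistic and neural hazards

`cbnn` estimates **full hazard and risk functions** for single-event,
right-censored survival data. It is aimed at biostatisticians and
epidemiologists who want absolute-risk predictions — `F(t|X)`, the
probability of the event by time `t` given covariates — rather than hazard
ratios, and who suspect their data contain a complicated baseline hazard or
covariate effects that change over follow-up (non-proportional hazards).

## The method

**Case-base sampling** converts follow-up time into a binary-outcome
problem. Each observed event contributes one *case* person-moment at its
event time; `b` *base* person-moments are drawn uniformly over the study
base `B = Σᵢ Tᵢ` (total person-time), an individual being picked with
probability proportional to its follow-up. Because the base series is
uniform over person-time, the odds that a sampled moment is a case satisfy

    P(Y=1 | X, t) / P(Y=0 | X, t) = h(t|X) / (b/B),

so a probabilistic classifier with a **fixed offset** `log(B/b)` added
before the sigmoid estimates the log-hazard directly:

    P(Y=1 | X, t) = sigmoid( f(X, t) + log(B/b) ),      h(t|X) = exp f(X, t).

Censoring is handled by the sampling itself — censored individuals
contribute person-time but no case — and no custom loss is needed: the model
is trained with ordinary binary cross-entropy.

Two model families implement `f`:

* **CBLR** — logistic regression on user-chosen design terms over covariates
  and time (optionally a natural cubic spline basis of log-time), fitted by
  IRLS; deterministic.
* **CBNN** — a feed-forward network (two hidden layers, ReLU or linear,
  dropout, Adam) that takes **time as an input feature**, so the baseline
  hazard and any time-varying interactions are learned from data.

The risk function follows by a left-endpoint Riemann sum,
`F(t|X) = 1 − exp(−Σ_{u≤t} h(u|X) Δu)`. Predictions are evaluated under
censoring with IPCW metrics: the Brier score `BS(t)` (Kaplan–Meier censoring
weights `1/Ĝ(Tᵢ⁻)` and `1/Ĝ(t)`), its time-averaged integral IBS, the index
of prediction accuracy `IPA(t) = 1 − BS_model/BS_null` against a
Kaplan–Meier null, and the IPCW-weighted cumulative/dynamic time-dependent
AUC. A spline-hazard simulator with a time-varying interaction generates
benchmark cohorts, and a harness reproduces the full protocol: fixed 15%
test split, 3-fold cross-validated grid search by IBS, bootstrap bands.

## Worked example

```python
import numpy as np, pandas as pd
from cbnn import SurvivalDataset, case_base_sample, fit_cblr, CBLRSpec

rng = np.random.default_rng(3)
x = rng.normal(size=4000)
times = rng.exponential(np.exp(-(-1 + 0.5 * x)))   # true log h = -1 + 0.5 x
data = SurvivalDataset(times, np.ones(4000), pd.DataFrame({"x": x}))

moments, spec = case_base_sample(data, ratio=50, rng=4)
model = fit_cblr(moments, CBLRSpec(terms=("x",)))
print(np.round(model.coef_, 3))          # [-1.    0.52]  ~ truth [-1, 0.5]

risk = model.predict_risk(pd.DataFrame({"x": [1.0]}), np.linspace(0, 3, 200))
print(round(float(risk.values[0, -1]), 4))   # 0.8424 vs closed form 0.8364
```

The fitted coefficients recover the generating log-hazard and the
Riemann-sum risk curve tracks the exponential closed form
`F(t|x) = 1 − exp(−t·e^{−1+0.5x})`. The scripts in `examples/` walk through
each capability — sampling, the logistic and network hazards, the
simulator, and the benchmark harness — each printing the numbers it
computes and what they mean:

```bash
python examples/03_neural_hazard.py
# fraction of follow-up   CBLR IPA   CBNN IPA
#                  0.25      0.564      0.740
#                   0.5      0.299      0.420
#                  0.75     -0.410      0.096
```

(the network keeps beating the Kaplan–Meier null late in follow-up, where
the linear model's proportional-hazards-style fit collapses).

There is also a thin CLI: `cbnn simulate|sample|fit|predict|evaluate|benchmark --help`.

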