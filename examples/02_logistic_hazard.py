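"""Logistic hazard model (CBLR): fit, coefficient recovery, risk curves.

Simulates data whose true log-hazard is -1 + 0.5*x (exponential conditional
on x), fits the offset logistic model on sampled person-moments, and shows
that the coefficients recover the truth and that the risk curve matches the
closed form F(t|x) = 1 - exp(-t * exp(-1 + 0.5 x)).
"""

import numpy as np
import pandas as pd

from cbnn import CBLRSpec, SurvivalDataset, case_base_sample, fit_cblr

rng = np.random.default_rng(3)
n = 4000
x = rng.normal(size=n)
times = rng.exponential(np.exp(-(-1 + 0.5 * x)))
data = SurvivalDataset(
    time=times, event=np.ones(n), covariates=pd.DataFrame({"x": x})
)

moments, _ = case_base_sample(data, ratio=50, rng=4)
model = fit_cblr(moments, CBLRSpec(terms=("x",)))

print("design columns:", model.column_names_)
print("coefficients:  ", np.round(model.coef_, 3), "(truth: [-1, 0.5])")

grid = np.linspace(0, 3, 200)
profile = pd.DataFrame({"x": [1.0]})
risk = model.predict_risk(profile, grid)
closed_form = 1 - np.exp(-grid * np.exp(-1 + 0.5 * 1.0))
print()
for t in (0.5, 1.5, 3.0):
    j = np.searchsorted(grid, t) - 1
    print(
        f"F({grid[j]:.2f} | x=1): model {risk.values[0, j]:.4f}"
        f"   closed form {closed_form[j]:.4f}"
    )
print()
print(
    "The fitted intercept and slope match the generating log-hazard, and the\n"
    "Riemann-sum risk curve tracks the exponential CDF."
)
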