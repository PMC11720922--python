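"""Case-base sampling: turn a survival dataset into person-moments.

Simulates a small exponential cohort, samples the case and base series at
a 20:1 ratio, and prints the bookkeeping that the downstream models rely
on.  The offset log(B/b) is what lets a logistic model estimate the hazard.
"""

import numpy as np
import pandas as pd

from cbnn import SurvivalDataset, case_base_sample, total_person_time

rng = np.random.default_rng(0)
n = 500
x = rng.normal(size=n)
times = rng.exponential(np.exp(-0.5 * x))  # hazard increases with x
event = (rng.uniform(size=n) > 0.2).astype(float)  # ~20% censored
data = SurvivalDataset(time=times, event=event, covariates=pd.DataFrame({"x": x}))

moments, spec = case_base_sample(data, ratio=20, rng=1)

print(f"individuals:        {data.n}")
print(f"events (c):         {spec.c}")
print(f"person-time (B):    {total_person_time(data):.1f}")
print(f"base series (b):    {spec.b}  (= 20 x c)")
print(f"offset log(B/b):    {spec.offset:.4f}")
print()
print(moments.data.head())
print()
print(
    "Every event contributes one case row at its event time; base rows are\n"
    "person-moments drawn uniformly over the cohort's total follow-up, so\n"
    "the odds of a row being a case at time t estimate h(t|x) * B/b."
)
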