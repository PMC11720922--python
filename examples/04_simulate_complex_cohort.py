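"""The spline-hazard simulator: covariates, event times, censoring.

Draws the default breast-cancer-like cohort — a flexible spline baseline
hazard on log-time, strong direct effects, a covariate interaction and a
time-varying effect — and prints cohort-level facts a survival analyst
would sanity-check first.
"""

import numpy as np

from cbnn import SimulationConfig, simulate_dataset, true_log_hazard, draw_covariates

cfg = SimulationConfig(n=5000)
data = simulate_dataset(cfg, rng=11)

print(f"individuals:         {data.n}")
print(f"event fraction:      {data.event.mean():.3f}  (10% random censoring)")
print(f"median follow-up:    {np.median(data.time):.0f} days")
print(f"max follow-up:       {data.time.max():.0f} days (horizon {cfg.t_admin:.0f})")

z = data.covariates
by_group = {
    "z1=0": np.median(data.time[z["z1"] == 0]),
    "z1=1": np.median(data.time[z["z1"] == 1]),
}
print(f"median time by z1:   {by_group['z1=0']:.0f} vs {by_group['z1=1']:.0f} days")

profile = draw_covariates(1, rng=12)
for t in (30.0, 300.0, 2000.0):
    lh = true_log_hazard(t, profile, cfg)[0]
    print(f"log h({t:>6.0f} d | z): {lh:8.3f}")
print()
print(
    "The z1=1 group is strongly protected early (beta1 = -5) but its hazard\n"
    "grows with follow-up (tau1 * z1 * t), so the groups' event times\n"
    "overlap late — the non-proportional signal the network models exploit."
)
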