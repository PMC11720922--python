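"""Network hazard model (CBNN): time as a feature, offset-adjusted sigmoid.

Fits a small feed-forward network on case-base sampled moments from the
built-in spline-hazard simulator and compares its test-set IPA with the
plain logistic model.  The generator contains a time-varying effect the
linear model cannot represent, which the network learns from (x, t) inputs.
"""

import numpy as np

import cbnn

cfg = cbnn.SimulationConfig(n=1200)
rng = np.random.default_rng(7)
data = cbnn.simulate_dataset(cfg, rng=rng)
train, val, test = cbnn.split_data(data, rng=rng)

moments, _ = cbnn.case_base_sample(train, ratio=50, rng=rng)

linear = cbnn.fit_cblr(moments, cbnn.CBLRSpec(terms=("z1", "z2", "z3")))
net = cbnn.build_cbnn(
    cbnn.CBNNSpec(layer1_nodes=30, layer2_nodes=15, max_epochs=60, n_batches=50),
    p=3,
    rng=8,
)
net.fit(moments, rng=9)
print(f"network parameters: {net.n_parameters}, epochs run:",
      len(net.history_["train_loss"]))

t_max = float(test.time.max())
grid = np.linspace(t_max / 60, t_max, 60)
print(f"\n{'fraction of follow-up':>22}  {'CBLR IPA':>9}  {'CBNN IPA':>9}")
for name, model in [("CBLR", linear), ("CBNN", net)]:
    risks = model.predict_risk(test.covariates, grid)
    long = cbnn.evaluate_risks(risks.values, grid, test)
    summary = cbnn.summarize_at_fractions(long)
    vals = summary[summary["metric"] == "IPA"].set_index("fraction")["value"]
    if name == "CBLR":
        cblr_vals = vals
    else:
        for frac in (0.25, 0.5, 0.75):
            print(f"{frac:>22}  {cblr_vals[frac]:>9.3f}  {vals[frac]:>9.3f}")
print()
print(
    "Positive IPA means the model beats the Kaplan-Meier null; the network\n"
    "keeps its advantage late in follow-up where the linear model's\n"
    "proportional-hazards-style fit degrades."
)
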