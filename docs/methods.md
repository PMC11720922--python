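# Methods

This note documents the statistical model behind `cbnn`, the conventions the
implementation commits to, the simulator's parametrization, and the places
where the design was genuinely open.

## Case-base sampling

Follow-up of each individual `i` (time `Tᵢ > 0`, event `δᵢ ∈ {0,1}`,
covariates `Xᵢ`) is decomposed into person-moments. The **case series**
holds one row per observed event, at its event time. The **base series**
holds `b = ratio × c` rows (default ratio 100, `c` the number of events)
drawn uniformly over the study base `B = Σ Tᵢ` by a two-stage scheme: pick
an individual with probability `Tᵢ/B` **with replacement**, then a moment
uniform on `(0, Tᵢ]`. This is exactly uniform over person-time at `O(b)`
cost, with no discretization grid. Base moments may coincide with an event
time (a measure-zero event in theory); they keep label 0. At ratio 100 the
two-sample information factor `(1/c + 1/b)/(1/c)` equals 1.01, i.e. at most
a one-percent inflation relative to using the entire study base.

Because the base series is uniform, the sampling process has constant
"hazard" `b/B`, and the case/base odds at a moment equal `h(t|X)/(b/B)`.
Models therefore add the **offset** `log(B/b)` — stored once per table, not
per row — to the linear predictor during fitting, and replace it by zero at
prediction time, so `h(t|X) = exp f(X,t)` directly.

## Hazard models

**CBLR.** `f` is linear in user-specified design terms: any covariate, the
special term `time`, products (`"z1*time"`, `"z2*z3"`), and optionally a
natural cubic spline basis of `log(time/time_scale)`. The fit is a binomial
GLM (statsmodels IRLS) with the offset as a fixed unit-coefficient term;
it is deterministic and affine-invariant, so covariates enter unscaled. The
default design is intercept + each covariate + time linearly; the
benchmark's plain-CBLR comparator deliberately drops the time term (see
"Open choices").

**CBNN.** `f` is a dense feed-forward network on `(X_scaled, t/t_max)`:
two hidden layers (defaults 75 and 50 nodes — the combination selected by
the reference grid search), ReLU or identity activations, inverted dropout
(default 0.01), a single linear output unit, then the fixed offset and a
sigmoid. Covariates are standardized by the **training** mean/SD and time
divided by the **training** maximum; the scaling is frozen into the model.
Training minimizes binary cross-entropy by Adam (β = 0.9/0.999, ε = 1e-7)
over `n_batches` minibatches per epoch (batch size = rows/n_batches,
default 100 batches), with Glorot-uniform seeded initialization. Arithmetic
is float32 internally. The epoch budget is not part of the estimator's
definition, so the default is max_epochs 200 with early stopping (patience
10): either on an explicitly supplied validation moment table — sampled
independently from a validation split and scored with the *training*
offset — or, absent one, on a random 20% of the training moments. Best
weights are restored. A non-finite loss aborts with a diagnostic rather
than returning a silently broken model.

**Risk curves.** `F(t|X) = 1 − exp(−∫₀ᵗ h)` is approximated by a
left-endpoint Riemann sum on the user grid (default 100 points per
horizon). The first interval's left endpoint would be `t = 0`, where
log-time designs are undefined; its midpoint is used instead. The sum is
monotone by construction, so every risk curve is nondecreasing in `[0,1]`
regardless of the fitted hazard. Error decreases first-order in the grid
step; tests verify halving against adaptive quadrature.

## Evaluation under censoring

`Ĝ(t) = P(C > t)` is the reverse Kaplan–Meier estimate (lifelines, event
indicator reversed). Individuals with an event by the horizon `t` are
weighted `1/Ĝ(Tᵢ⁻)` — the left limit, the usual IPCW convention — and
individuals still at risk `1/Ĝ(t)`; individuals censored before `t` drop
out through the weights. A weight that would divide by `Ĝ = 0` raises an
error naming the offending time instead of silently dropping the subject
(reachable when `Ĝ` estimated on one sample is applied to another with
longer follow-up).

* **BS(t)**: mean of `(1−F̂)²` over events by `t` plus `F̂²` over the
  at-risk, each IPCW-weighted. With no censoring it reduces exactly to the
  mean squared error against `I(Tᵢ ≤ t)`.
* **IBS**: trapezoidal time-average of `BS(t)` over the evaluation grid
  (the weight `dw = dt/t_max` makes it an average).
* **IPA(t)** `= 1 − BS_model/BS_null`, the null being the training
  Kaplan–Meier risk assigned to everyone; undefined (NaN) if `BS_null = 0`.
* **AUC(t)**: IPCW-weighted probability that a case (`Tᵢ ≤ t, δᵢ=1`)
  outranks a control (`Tⱼ > t`), pair weight `Wᵢ(t)Wⱼ(t)`. **Ties count
  1/2** by default — the standard concordance convention, which keeps a
  constant predictor at 0.5 — with the strict indicator available via
  `ties="strict"`. With zero censoring this reduces to the plain
  cumulative/dynamic time-dependent AUC.

Metric curves are computed on a uniform grid of 100 points on
`(0, t_max]` with `t_max` the maximum follow-up in the evaluation split;
summary tables read values at 25/50/75/100% of `t_max` by
stepwise-previous interpolation, falling back to the last *defined* grid
value at or before the horizon (at `t_max` itself the at-risk set can be
empty, leaving AUC undefined there). Values at the extreme end of
follow-up are intrinsically unstable — a handful of subjects carry very
large weights — which is why the reference summaries average five seeds.

## The simulator

The generator emulates a breast-cancer-like cohort. Covariates:
`z1 ~ Bernoulli(0.5)`, `z2 ~ N(z1, 0.5)`, `z3 ~ N(1, 0.5)`. Log-hazard:

    log h(t|z) = Σₖ γₖ ψₖ(log(t/s)) + β₁z1 + β₂z2 + β₃z3 + τ₁ z1·t + τ₂ z2·z3

with `ψ` the restricted (natural) cubic spline basis — intercept, log-time,
one basis function per internal knot, linear beyond the boundary knots —
the basis used by flexible-parametric survival models. Defaults:
`β = (−5, −1, 1)`, `τ = (0.001, −1)`, `γ = (3.9, 3, −0.43, 1.33, −0.86)`.

The γ and knots come from an intercept-only three-knot spline model fitted
to the German Breast Cancer Study Group cohort (686 women, follow-up in
days, maximum 2659). The package refits that model (flexsurv's spline
routine) to fix what is otherwise under-determined: internal knots sit at
the quartiles of observed log event times and boundary knots at their
extremes — `(4.2767, 6.0544, 6.4708, 7.0026, 7.8063)` on log-days — and the
intercept is quoted on the max-rescaled time axis `s = 2659` days
(equivalently, an intercept of −19.75 on raw log-days: the two differ by
`γ₂·log 2659`). The fit determines the sign of the second internal-knot
coefficient as +1.33; with −1.33 the hazard shape degenerates (all events
collapse into a short early window and the late follow-up structure the
benchmark probes disappears). Time is measured in days throughout, which is
what makes `τ₁ z1·t` a genuine time-varying effect: the z1 = 1 group is
strongly protected at entry (`β₁ = −5`) but its log-hazard gains
`τ₁·t ≈ 2.7` by the end of follow-up — a proportional-hazards violation no
time-free linear model can represent.

Event times invert the cumulative hazard: `T = H⁻¹(−log U)`. `H` factorizes
as `exp(linear predictor)` times a z1-dependent time profile, so two
accumulated tables (trapezoid on a 4096-point log-spaced grid) bracket each
individual's solution; a closed-form inversion of the within-cell
exponential-linear interpolant warm-starts a bracketed Newton iteration
with composite-Simpson evaluation of the exact hazard (tolerance 1e-8 on
the time step; verified to ~1e-6 absolute against closed-form Weibull and
exponential inversions). Individuals unresolved by the administrative
horizon are censored there. The horizon defaults to 2659 days — the source
cohort's maximum follow-up — rather than a marginal-survival cutoff,
because the protected group's tail makes any such cutoff enormous; the cap
binds for ~0.2% of individuals. "10% random censoring" is implemented by
censoring a 10% random subset at `Uniform(0, Tᵢ)`; an independent
exponential mechanism with the rate calibrated to the same expected
fraction is available (`mechanism="exponential"`), since nothing pins down
the mechanism and the choice is consequential mainly for late-time weights.

What the generator does **not** emulate: competing risks, left truncation
or delayed entry, covariate measurement error, informative censoring, tied
event times from coarse recording. Tests passing on this generator show the
estimators recover a known smooth hazard under light independent censoring;
they do not certify behavior under heavy or informative censoring or
discrete time scales.

## Benchmark protocol

15% of individuals form a fixed test set before any tuning; 15% of the
remainder form a validation split. The network's hyperparameters come from
a three-fold cross-validated grid search over learning rate {0.001, 0.01},
dropout {0.01, 0.05, 0.1}, first layer {50, 75, 100}, second layer
{10, 25, 50}, batches {100, 500}, activation {ReLU, linear} (216
combinations; the reference runs use the selected combination directly),
scored by the mean held-out-fold IBS; a diverging combination scores
infinity rather than aborting the search. Logistic models, being
deterministic, train on training+validation combined; the network trains on
the training split with early stopping on validation moments. Bootstrap
bands are pointwise 2.5/97.5 percentiles over (default 100) refits on
training resamples, evaluated on the unchanged test set; resamples without
events are redrawn with a warning. Reported CV IBS is the cross-validation
mean for the selected combination, not a refit value.

The reference runs (`scripts/acceptance.py`, `tests/test_acceptance.py`)
use n = 5000, ratio 100, a 100-point metric grid, and five seeds; the
parameter-recovery check uses 20 seeds of an exponential
proportional-hazards configuration of the same generator. These sizes keep
a full run in the ten-minute range on a single CPU while holding the
Monte-Carlo error of the summary means near ±0.01–0.03.

## Known limitations

* Summary magnitudes at 75% and especially 100% of follow-up have heavy
  seed-to-seed noise (thin at-risk sets under IPCW); compare means over
  seeds, not single runs.
* The spline knots and γ parametrization are reconstructed, not copied;
  quantities that depend on the exact baseline-hazard shape (e.g. absolute
  IBS levels) shift with knot placement even when model *orderings* are
  stable.
* The network trainer is a minimal numpy implementation: single-threaded,
  dense layers only, no learning-rate schedules; it is adequate for the
  cohort sizes here but not a general-purpose DL stack.
* CBLR inference (`bse`) is taken from the binomial GLM on sampled moments
  and ignores sampling-induced dependence between moments from the same
  individual; it is used only for coarse recovery checks, not reported
  confidence intervals (the benchmark bootstraps instead).
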