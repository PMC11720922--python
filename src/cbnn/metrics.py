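"""Time-dependent evaluation of risk predictions under right censoring.

All metrics weight individuals by the inverse probability of remaining
uncensored (IPCW), using the reverse Kaplan-Meier estimate ``G(t) = P(C > t)``
of the censoring distribution:

* Brier score  BS(t) — mean weighted squared error of ``F(t|X)`` against the
  observed event status at ``t``;
* IBS — the time-average of BS(t) over the follow-up grid (weight dw = dt/t_max);
* IPA(t) = 1 - BS_model(t)/BS_null(t), the gain over a Kaplan-Meier null that
  assigns every individual the marginal risk;
* AUC_IPCW(t) — weighted probability that a case's predicted risk exceeds a
  control's (cumulative/dynamic time-dependent AUC).

Individuals who experienced the event by ``t`` are weighted by ``1/G(T_i-)``
(left limit, the usual IPCW convention); individuals still at risk by
``1/G(t)``; individuals censored before ``t`` drop out through the weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .sampling import SurvivalDataset

__all__ = [
    "CensoringEstimate",
    "MetricCurve",
    "censoring_survival",
    "brier_score",
    "integrated_brier_score",
    "null_model_risks",
    "ipa",
    "auc_ipcw",
    "evaluate_risks",
    "summarize_at_fractions",
]


@dataclass(frozen=True)
class _StepSurvival:
    """Right-continuous step survival function with left limits."""

    times: np.ndarray  # ascending jump times
    values: np.ndarray  # S(times[k]) just after the jump

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        vals = np.where(idx >= 0, self.values[np.maximum(idx, 0)], 1.0)
        return float(vals) if np.isscalar(t) else vals

    def left_limit(self, t: np.ndarray | float) -> np.ndarray | float:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="left") - 1
        vals = np.where(idx >= 0, self.values[np.maximum(idx, 0)], 1.0)
        return float(vals) if np.isscalar(t) else vals


def _km_step(time: np.ndarray, event: np.ndarray) -> _StepSurvival:
    km = KaplanMeierFitter().fit(time, event)
    sf = km.survival_function_
    return _StepSurvival(
        times=sf.index.to_numpy(float), values=sf.iloc[:, 0].to_numpy(float)
    )


@dataclass(frozen=True)
class CensoringEstimate:
    """Reverse Kaplan-Meier estimate of the censoring survival ``G``."""

    step: _StepSurvival

    def __call__(self, t):
        return self.step(t)

    def left_limit(self, t):
        return self.step.left_limit(t)


@dataclass
class MetricCurve:
    """A metric evaluated on an ascending time grid."""

    times: np.ndarray
    values: np.ndarray
    name: str = ""

    def at_fraction(self, frac: float) -> float:
        """Value at ``frac * max(times)``, stepwise-previous interpolation."""
        t = frac * self.times[-1]
        j = int(np.searchsorted(self.times, t * (1 + 1e-12), side="right")) - 1
        return float(self.values[max(j, 0)])


def censoring_survival(data: SurvivalDataset) -> CensoringEstimate:
    """Kaplan-Meier with the event indicator reversed (censoring as event)."""
    return CensoringEstimate(_km_step(data.time, 1.0 - data.event))


def km_survival(data: SurvivalDataset) -> _StepSurvival:
    """Marginal Kaplan-Meier survival estimate (the null model)."""
    return _km_step(data.time, data.event)


def _weights(
    data: SurvivalDataset, t: float, G: CensoringEstimate
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event/at-risk indicators and IPCW weights at horizon ``t``."""
    had_event = (data.time <= t) & (data.event == 1)
    at_risk = data.time > t
    G_T = np.asarray(G.left_limit(data.time))
    G_t = float(G(t))
    if np.any(had_event & (G_T <= 0)):
        bad = float(data.time[had_event & (G_T <= 0)][0])
        raise ValueError(f"censoring survival is zero at event time {bad:g}")
    w = np.zeros(data.n)
    w[had_event] = 1.0 / G_T[had_event]
    if np.any(at_risk):
        if G_t <= 0:
            raise ValueError(
                f"censoring survival is zero at evaluation time {t:g}"
            )
        w[at_risk] = 1.0 / G_t
    return had_event, at_risk, w


def brier_score(
    risks_at_t: np.ndarray,
    data: SurvivalDataset,
    t: float,
    G: CensoringEstimate,
) -> float:
    """IPCW Brier score of predicted risks ``F(t|X_i)`` at horizon ``t``."""
    F = np.asarray(risks_at_t, dtype=float)
    if F.shape != (data.n,):
        raise ValueError("risks_at_t must have one entry per individual")
    if np.any((F < 0) | (F > 1)):
        raise ValueError("risks must lie in [0, 1]")
    had_event, at_risk, w = _weights(data, t, G)
    terms = (1.0 - F) ** 2 * had_event * w + F**2 * at_risk * w
    return float(terms.mean())


def integrated_brier_score(bs: MetricCurve, t_max: float | None = None) -> float:
    """Trapezoidal time-average of the Brier score over the follow-up grid."""
    if bs.times.size == 0:
        raise ValueError("empty Brier score curve")
    if bs.times.size == 1:
        return float(bs.values[0])
    t = bs.times
    if t_max is not None:
        keep = t <= t_max + 1e-12
        t, vals = t[keep], bs.values[keep]
    else:
        vals = bs.values
    return float(np.trapezoid(vals, t) / (t[-1] - t[0]))


def null_model_risks(train: SurvivalDataset, t: float) -> np.ndarray:
    """KM-null prediction: every individual gets the marginal risk at ``t``."""
    S = km_survival(train)
    return np.full(train.n, 1.0 - float(S(t)))


def ipa(bs_model: float, bs_null: float) -> float:
    """Index of prediction accuracy ``1 - BS_model/BS_null`` (nan if null=0)."""
    if bs_null == 0:
        return float("nan")
    return 1.0 - bs_model / bs_null


def auc_ipcw(
    risks_at_t: np.ndarray,
    data: SurvivalDataset,
    t: float,
    G: CensoringEstimate,
    ties: str = "half",
) -> float:
    """IPCW-weighted cumulative/dynamic time-dependent AUC at horizon ``t``.

    Cases are individuals with an observed event by ``t``; controls are those
    still at risk.  Each ordered pair contributes ``W_i(t) * W_j(t)`` with the
    IPCW weights; with ``ties='half'`` equal predicted risks count 1/2
    (concordance convention), with ``ties='strict'`` they count 0.

    Returns nan when there is no case or no control.
    """
    if ties not in ("half", "strict"):
        raise ValueError("ties must be 'half' or 'strict'")
    F = np.asarray(risks_at_t, dtype=float)
    had_event, at_risk, w = _weights(data, t, G)
    if not had_event.any() or not at_risk.any():
        return float("nan")
    Fi, wi = F[had_event], w[had_event]
    Fj, wj = F[at_risk], w[at_risk]
    greater = (Fi[:, None] > Fj[None, :]).astype(float)
    if ties == "half":
        greater += 0.5 * (Fi[:, None] == Fj[None, :])
    pair_w = wi[:, None] * wj[None, :]
    return float((greater * pair_w).sum() / pair_w.sum())


def evaluate_risks(
    risk_values: np.ndarray,
    grid: np.ndarray,
    data: SurvivalDataset,
    G: CensoringEstimate | None = None,
    null_train: SurvivalDataset | None = None,
) -> pd.DataFrame:
    """Compute BS, BS_null, IPA and AUC on a grid of horizons.

    ``risk_values`` has one row per individual of ``data`` and one column per
    grid time.  ``G`` defaults to the reverse KM of ``data``; the KM null is
    estimated on ``null_train`` (default: ``data``).  Times where a metric is
    undefined yield nan.  Returns a long-format frame (time, metric, value).
    """
    grid = np.asarray(grid, dtype=float)
    risk_values = np.atleast_2d(np.asarray(risk_values, dtype=float))
    if risk_values.shape != (data.n, grid.size):
        raise ValueError("risk_values must be (n individuals, n grid times)")
    if G is None:
        G = censoring_survival(data)
    S_null = km_survival(null_train if null_train is not None else data)
    rows = []
    for k, t in enumerate(grid):
        F = risk_values[:, k]
        try:
            bs = brier_score(F, data, t, G)
            bs_null = brier_score(
                np.full(data.n, 1.0 - float(S_null(t))), data, t, G
            )
            ipa_t = ipa(bs, bs_null)
        except ValueError:
            bs = bs_null = ipa_t = float("nan")
        try:
            auc_t = auc_ipcw(F, data, t, G)
        except ValueError:
            auc_t = float("nan")
        rows += [
            {"time": t, "metric": "BS", "value": bs},
            {"time": t, "metric": "BS_null", "value": bs_null},
            {"time": t, "metric": "IPA", "value": ipa_t},
            {"time": t, "metric": "AUC", "value": auc_t},
        ]
    return pd.DataFrame(rows)


def summarize_at_fractions(
    long: pd.DataFrame, fractions: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
) -> pd.DataFrame:
    """Read metric values at fractions of the last grid time (step-previous)."""
    out = []
    tmax = long["time"].max()
    for metric, sub in long.groupby("metric"):
        curve = MetricCurve(
            sub["time"].to_numpy(float), sub["value"].to_numpy(float), metric
        )
        for frac in fractions:
            finite = np.isfinite(curve.values) & (curve.times <= frac * tmax * (1 + 1e-12))
            val = (
                curve.values[finite][-1] if finite.any() else float("nan")
            )  # last defined point at or before the horizon
            out.append({"metric": metric, "fraction": frac, "value": val})
    return pd.DataFrame(out)
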