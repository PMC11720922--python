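"""IPCW metrics against brute-force oracles and closed-form limits."""

import numpy as np
import pandas as pd
import pytest

from cbnn import (
    MetricCurve,
    SurvivalDataset,
    auc_ipcw,
    brier_score,
    censoring_survival,
    integrated_brier_score,
    ipa,
    null_model_risks,
)
from cbnn.metrics import km_survival

from conftest import make_exponential_data, random_toy_dataset


def _dataset(times, events):
    times = np.asarray(times, dtype=float)
    return SurvivalDataset(
        time=times,
        event=np.asarray(events, dtype=float),
        covariates=pd.DataFrame({"x": np.zeros(times.size)}),
    )


# ---------------------------------------------------------------------------
# brute-force oracles (straight transcriptions of the definitions)


def _km_by_hand(times, events, t):
    """Product-limit estimate at t via an explicit loop."""
    surv = 1.0
    for u in sorted(set(times[events == 1])):
        if u > t:
            break
        at_risk = np.sum(times >= u)
        d = np.sum((times == u) & (events == 1))
        surv *= 1 - d / at_risk
    return surv


def _brier_by_hand(F, data, t, G):
    total = 0.0
    for i in range(data.n):
        Ti, di, Fi = data.time[i], data.event[i], F[i]
        if Ti <= t and di == 1:
            total += (1 - Fi) ** 2 / G.left_limit(Ti)
        elif Ti > t:
            total += Fi**2 / G(t)
    return total / data.n


def _auc_by_hand(F, data, t, G):
    num = den = 0.0
    for i in range(data.n):
        if not (data.time[i] <= t and data.event[i] == 1):
            continue
        wi = 1.0 / G.left_limit(data.time[i])
        for j in range(data.n):
            if not data.time[j] > t:
                continue
            wj = 1.0 / G(t)
            w = wi * wj
            den += w
            if F[i] > F[j]:
                num += w
            elif F[i] == F[j]:
                num += 0.5 * w
    return num / den if den > 0 else float("nan")


# ---------------------------------------------------------------------------


class TestCensoringSurvival:
    def test_no_censoring_gives_unit_curve(self):
        data = _dataset([1, 2, 3, 4], [1, 1, 1, 1])
        G = censoring_survival(data)
        assert G(0.0) == 1.0
        assert G(3.9) == 1.0

    def test_single_censored_individual_steps_to_zero(self):
        data = _dataset([5.0], [0])
        G = censoring_survival(data)
        assert G(4.99) == 1.0
        assert G(5.0) == 0.0
        assert G.left_limit(5.0) == 1.0

    def test_matches_hand_computed_product_limit(self):
        times = np.array([1.0, 2.0, 2.5, 3.0, 4.0, 6.0])
        events = np.array([1, 0, 1, 0, 0, 1.0])
        data = _dataset(times, events)
        G = censoring_survival(data)
        for t in (0.5, 1.5, 2.2, 2.7, 3.5, 5.0):
            assert G(t) == pytest.approx(
                _km_by_hand(times, 1 - events, t), abs=1e-12
            )

    def test_monotone_nonincreasing_in_unit_interval(self, rng):
        data = make_exponential_data(100, censor_frac=0.4, rng=rng)
        G = censoring_survival(data)
        grid = np.linspace(0, data.time.max(), 200)
        vals = np.asarray(G(grid))
        assert np.all(np.diff(vals) <= 1e-12)
        assert np.all((vals >= 0) & (vals <= 1))


class TestBrierScore:
    def test_equals_mse_without_censoring(self, rng):
        data = make_exponential_data(200, rng=rng)
        G = censoring_survival(data)
        t = float(np.median(data.time))
        F = rng.uniform(size=data.n)
        mse = np.mean((F - (data.time <= t)) ** 2)
        assert brier_score(F, data, t, G) == pytest.approx(mse, abs=1e-12)

    def test_perfect_predictions_score_zero(self):
        data = _dataset([1, 2, 3, 4], [1, 1, 1, 1])
        G = censoring_survival(data)
        t = 2.5
        F = (data.time <= t).astype(float)
        assert brier_score(F, data, t, G) == 0.0

    def test_toy_set_with_censoring_matches_term_by_term(self):
        data = _dataset([1, 2, 3, 4, 5.0], [1, 0, 1, 1, 1])
        G = censoring_survival(data)
        F = np.array([0.9, 0.5, 0.6, 0.2, 0.1])
        t = 3.5
        assert brier_score(F, data, t, G) == pytest.approx(
            _brier_by_hand(F, data, t, G), abs=1e-12
        )

    def test_invariant_to_permuting_individuals(self, rng):
        data = make_exponential_data(50, censor_frac=0.3, rng=rng)
        G = censoring_survival(data)
        F = rng.uniform(size=data.n)
        t = float(np.median(data.time))
        perm = rng.permutation(data.n)
        permuted = SurvivalDataset(
            time=data.time[perm],
            event=data.event[perm],
            covariates=data.covariates.iloc[perm].reset_index(drop=True),
        )
        assert brier_score(F[perm], permuted, t, G) == pytest.approx(
            brier_score(F, data, t, G), rel=1e-12
        )

    def test_zero_censoring_weight_raises_with_time_in_message(self):
        # G estimated on one sample can vanish before another sample's
        # follow-up ends; affected weights must raise, not drop silently
        train = _dataset([1.0, 2.0, 3.0], [1, 1, 0])  # G = 0 from t = 3
        G = censoring_survival(train)
        test = _dataset([1.0, 4.0], [1, 1])
        with pytest.raises(ValueError, match="4"):
            brier_score(np.array([0.5, 0.5]), test, 4.5, G)
        with pytest.raises(ValueError, match="3.5"):
            brier_score(np.array([0.5, 0.5]), test, 3.5, G)


class TestIntegratedBrierScore:
    def test_constant_curve_integrates_to_itself(self):
        curve = MetricCurve(np.linspace(0.1, 5, 60), np.full(60, 0.17))
        assert integrated_brier_score(curve) == pytest.approx(0.17, abs=1e-12)

    def test_linear_curve_integrates_to_half(self):
        t = np.linspace(0, 4, 100)
        curve = MetricCurve(t, t / 4)
        assert integrated_brier_score(curve) == pytest.approx(0.5, abs=1e-9)

    def test_matches_quadrature_of_interpolant(self, rng):
        t = np.sort(rng.uniform(0.1, 10, size=50))
        v = rng.uniform(0, 0.3, size=50)
        curve = MetricCurve(t, v)
        dense = np.linspace(t[0], t[-1], 200_001)  # high-resolution quadrature
        exact = np.trapezoid(np.interp(dense, t, v), dense)
        assert integrated_brier_score(curve) == pytest.approx(
            exact / (t[-1] - t[0]), abs=1e-6
        )

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            integrated_brier_score(MetricCurve(np.array([]), np.array([])))


class TestNullModel:
    def test_no_events_give_zero_risk(self):
        data = _dataset([1, 2, 3], [0, 0, 0])
        np.testing.assert_array_equal(null_model_risks(data, 2.5), 0.0)

    def test_all_events_before_t_give_unit_risk(self):
        data = _dataset([1, 2, 3], [1, 1, 1])
        np.testing.assert_array_equal(null_model_risks(data, 3.5), 1.0)

    def test_matches_hand_computed_km(self):
        times = np.array([1.0, 2.0, 2.5, 3.0, 4.0, 6.0])
        events = np.array([1, 0, 1, 0, 0, 1.0])
        data = _dataset(times, events)
        for t in (0.5, 2.2, 3.5, 6.0):
            expected = 1 - _km_by_hand(times, events, t)
            np.testing.assert_allclose(null_model_risks(data, t), expected)


class TestIPA:
    @pytest.mark.parametrize(
        "bs_model, bs_null, expected",
        [(0.2, 0.2, 0.0), (0.0, 0.3, 1.0), (0.4, 0.2, -1.0)],
    )
    def test_arithmetic(self, bs_model, bs_null, expected):
        assert ipa(bs_model, bs_null) == pytest.approx(expected, abs=1e-12)

    def test_zero_null_flagged_missing(self):
        assert np.isnan(ipa(0.1, 0.0))

    def test_null_against_itself_is_exactly_zero(self, rng):
        data = make_exponential_data(100, censor_frac=0.2, rng=rng)
        G = censoring_survival(data)
        t = float(np.median(data.time))
        F = null_model_risks(data, t)
        bs = brier_score(F, data, t, G)
        assert ipa(bs, bs) == 0.0


class TestAUC:
    def test_perfectly_ordered_risks_score_one(self):
        data = _dataset([1, 2, 3, 4], [1, 1, 1, 1])
        G = censoring_survival(data)
        F = np.array([0.9, 0.8, 0.2, 0.1])
        assert auc_ipcw(F, data, 2.5, G) == 1.0

    def test_anti_ordered_risks_score_zero(self):
        data = _dataset([1, 2, 3, 4], [1, 1, 1, 1])
        G = censoring_survival(data)
        F = np.array([0.1, 0.2, 0.8, 0.9])
        assert auc_ipcw(F, data, 2.5, G) == 0.0

    def test_constant_predictor_half_vs_strict_zero(self):
        data = _dataset([1, 2, 3, 4], [1, 1, 1, 1])
        G = censoring_survival(data)
        F = np.full(4, 0.5)
        assert auc_ipcw(F, data, 2.5, G, ties="half") == 0.5
        assert auc_ipcw(F, data, 2.5, G, ties="strict") == 0.0

    def test_toy_set_with_censoring_matches_double_loop(self, rng):
        data = _dataset(
            [0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0],
            [1, 0, 1, 1, 0, 1, 0, 1],
        )
        G = censoring_survival(data)
        F = rng.uniform(size=8)
        t = 2.2
        assert auc_ipcw(F, data, t, G) == pytest.approx(
            _auc_by_hand(F, data, t, G), abs=1e-12
        )

    def test_no_cases_or_controls_flagged_missing(self):
        data = _dataset([1, 2], [1, 1])
        G = censoring_survival(data)
        assert np.isnan(auc_ipcw(np.array([0.1, 0.2]), data, 0.5, G))
        assert np.isnan(auc_ipcw(np.array([0.1, 0.2]), data, 2.5, G))

    def test_equals_unweighted_auc_without_censoring(self, rng):
        """Zero censoring: reduces to the plain cumulative/dynamic AUC."""
        data = make_exponential_data(60, rng=rng)
        G = censoring_survival(data)
        F = rng.uniform(size=data.n)
        for t in np.quantile(data.time, [0.2, 0.5, 0.8]):
            cases = (data.time <= t) & (data.event == 1)
            controls = data.time > t
            num = den = 0.0
            for i in np.flatnonzero(cases):
                for j in np.flatnonzero(controls):
                    den += 1
                    num += (F[i] > F[j]) + 0.5 * (F[i] == F[j])
            assert auc_ipcw(F, data, t, G) == pytest.approx(num / den, abs=1e-12)

    def test_uninformative_risks_concentrate_at_half(self):
        """Risks independent of outcomes: mean AUC ~ 0.5 over replicates."""
        master = np.random.default_rng(99)
        aucs = []
        for _ in range(200):
            rng = np.random.default_rng(master.integers(2**31))
            data = make_exponential_data(80, censor_frac=0.2, rng=rng)
            G = censoring_survival(data)
            t = float(np.median(data.time))
            aucs.append(auc_ipcw(rng.uniform(size=data.n), data, t, G))
        aucs = np.asarray(aucs)
        se = aucs.std(ddof=1) / np.sqrt(len(aucs))
        assert abs(aucs.mean() - 0.5) < 3 * se


class TestOracleEquivalenceOnRandomToys:
    def test_brier_and_auc_match_brute_force_on_100_datasets(self):
        """Both metrics agree with O(n^2)/term-by-term oracles to 1e-10."""
        master = np.random.default_rng(7)
        checked_auc = 0
        for _ in range(100):
            rng = np.random.default_rng(master.integers(2**31))
            data = random_toy_dataset(rng)
            G = censoring_survival(data)
            F = rng.uniform(size=data.n)
            t = float(rng.uniform(0.3, data.time.max() * 0.95))
            had_event = (data.time <= t) & (data.event == 1)
            if np.any(had_event & (np.asarray(G.left_limit(data.time)) <= 0)):
                continue  # weight undefined; the implementation raises
            assert brier_score(F, data, t, G) == pytest.approx(
                _brier_by_hand(F, data, t, G), abs=1e-10
            )
            expected_auc = _auc_by_hand(F, data, t, G)
            got_auc = auc_ipcw(F, data, t, G)
            if np.isnan(expected_auc):
                assert np.isnan(got_auc)
            else:
                assert got_auc == pytest.approx(expected_auc, abs=1e-10)
                checked_auc += 1
        assert checked_auc >= 50


class TestAgainstScikitSurvival:
    """Independent cross-checks against scikit-survival's IPCW metrics."""

    @staticmethod
    def _sksurv_arrays(data):
        from sksurv.util import Surv

        return Surv.from_arrays(event=data.event.astype(bool), time=data.time)

    def test_brier_score_matches_sksurv(self, rng):
        from sksurv.metrics import brier_score as sks_brier

        data = make_exponential_data(150, censor_frac=0.3, rng=rng)
        G = censoring_survival(data)
        y = self._sksurv_arrays(data)
        t = float(np.quantile(data.time, 0.5))
        F = rng.uniform(size=data.n)
        _, bs = sks_brier(y, y, 1 - F, [t])
        assert brier_score(F, data, t, G) == pytest.approx(bs[0], abs=1e-10)

    def test_auc_matches_sksurv(self, rng):
        from sksurv.metrics import cumulative_dynamic_auc

        data = make_exponential_data(150, censor_frac=0.3, rng=rng)
        G = censoring_survival(data)
        y = self._sksurv_arrays(data)
        t = float(np.quantile(data.time, 0.5))
        F = rng.uniform(size=data.n)  # continuous: no ties
        auc, _ = cumulative_dynamic_auc(y, y, F, [t])
        assert auc_ipcw(F, data, t, G) == pytest.approx(auc[0], abs=1e-10)


def test_km_survival_matches_lifelines_step_convention(rng):
    data = make_exponential_data(50, censor_frac=0.3, rng=rng)
    S = km_survival(data)
    assert S(0.0) <= 1.0
    assert float(S(data.time.max() + 1)) == pytest.approx(
        _km_by_hand(data.time, data.event, data.time.max() + 1), abs=1e-12
    )
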