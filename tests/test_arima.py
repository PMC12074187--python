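"""Grid-search cells, criterion selection, medians and residual whiteness."""

import numpy as np
import pandas as pd
import pytest

from cvrarima.arima import (ArimaFitRecord, ArimaSpec, fit_arima,
                            grid_search, population_median_models,
                            residual_diagnostics, select_optimal)
from cvrarima.synthetic import simulate_arima_series


def _record(p, d, q, aic=0.0, bic=0.0, ll=0.0, converged=True):
    return ArimaFitRecord("p", "s", 1, ArimaSpec(p=p, d=d, q=q, pre_diff=1),
                          aic, bic, ll, converged, 0.0)


class TestFitArima:
    def test_white_noise_ar_coefficient_near_zero(self, rng):
        x = rng.normal(size=2000)
        rec = fit_arima(x, 1, 0, 0)
        assert rec.converged
        assert abs(rec.spec.phi[0]) < 0.1

    def test_criteria_identity(self, rng):
        x = rng.normal(size=400)
        rec = fit_arima(x, 2, 0, 1)
        k = 2 + 1 + 1 + 1     # p + q + constant + variance
        assert rec.aic - rec.bic == pytest.approx(k * (2 - np.log(rec.n_eff)))
        assert rec.aic == pytest.approx(2 * k - 2 * rec.ll)

    def test_ar_coefficient_recovery(self):
        x = simulate_arima_series(1, 0, 0, (0.8,), (), 1.0, 5000, seed=1)
        rec = fit_arima(x, 1, 0, 0)
        assert rec.spec.phi[0] == pytest.approx(0.8, abs=0.05)

    def test_degenerate_series_returns_nonconverged(self):
        rec = fit_arima(np.zeros(100), 2, 1, 2)
        assert not rec.converged
        assert rec.aic == np.inf and rec.ll == -np.inf

    def test_constant_policy_follows_differencing(self, rng):
        x = rng.normal(size=300)
        with_c = fit_arima(x, 1, 0, 0)
        without_c = fit_arima(x, 1, 1, 0)
        # d=0 fit estimates a constant; d=1 fit does not
        assert with_c.spec.constant != 0.0
        assert without_c.spec.constant == 0.0


class TestGridSearch:
    def test_reduced_grid_cell_count(self, rng):
        x = rng.normal(size=80)
        records = grid_search(x, range(1, 4), (0,), range(0, 3))
        assert len(records) == 9

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            grid_search(rng.normal(size=50), [], (0,), [])

    def test_optimum_reproducible_by_single_refit(self, rng):
        x = rng.normal(size=150)
        records = grid_search(x, range(1, 3), (0,), range(0, 3))
        best = select_optimal(records, "aic")
        refit = fit_arima(x, best.spec.p, best.spec.d, best.spec.q,
                          pre_diff=1)
        assert refit.aic == pytest.approx(best.aic, abs=1e-8)

    def test_total_d_accounts_for_predifferencing(self, rng):
        records = grid_search(rng.normal(size=80), range(1, 2), (0, 1),
                              range(0, 1), pre_diff=1)
        assert sorted(r.spec.total_d for r in records) == [1, 2]


class TestSelectOptimal:
    def test_argmin_aic(self):
        recs = [_record(1, 0, 0, aic=10), _record(2, 0, 0, aic=8),
                _record(3, 0, 0, aic=9)]
        assert select_optimal(recs, "aic").aic == 8

    def test_tie_broken_toward_simpler_model(self):
        recs = [_record(3, 0, 2, aic=8), _record(2, 0, 2, aic=8)]
        assert select_optimal(recs, "aic").spec.p == 2

    def test_ll_is_argmax(self):
        recs = [_record(1, 0, 0, ll=-50), _record(2, 0, 0, ll=-40)]
        assert select_optimal(recs, "ll").ll == -40

    def test_no_converged_record_gives_none(self):
        recs = [_record(1, 0, 0, converged=False)]
        assert select_optimal(recs, "aic") is None

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            select_optimal([_record(1, 0, 0)], "r2")


class TestPopulationMedians:
    def _frame(self, triples):
        return pd.DataFrame([
            {"patient_id": f"p{i}", "signal": "ICP", "resolution": 1,
             "p": p, "total_d": d, "q": q, "aic": 100.0 + i}
            for i, (p, d, q) in enumerate(triples)
        ])

    def test_componentwise_median(self):
        out = population_median_models(self._frame([(4, 1, 5), (4, 1, 4), (3, 1, 6)]))
        row = out.iloc[0]
        assert (row["median_p"], row["median_d"], row["median_q"]) == (4, 1, 5)

    def test_even_cohort_half_points_floored(self):
        out = population_median_models(self._frame([(2, 1, 1), (4, 1, 3)]))
        row = out.iloc[0]
        assert (row["median_p"], row["median_d"], row["median_q"]) == (3, 1, 2)
        # half-point medians round down to the simpler order
        out2 = population_median_models(self._frame([(2, 1, 1), (3, 1, 2)]))
        assert (out2.iloc[0]["median_p"], out2.iloc[0]["median_q"]) == (2, 1)

    def test_median_criterion_value_reported(self):
        out = population_median_models(self._frame([(1, 1, 1)] * 3))
        assert out.iloc[0]["median_criterion_value"] == pytest.approx(101.0)
        assert out.iloc[0]["n_patients"] == 3


class TestResidualDiagnostics:
    def test_band_width(self, rng):
        x = rng.normal(size=400)
        diag = residual_diagnostics(x, ArimaSpec(p=1, d=0, q=0), n_lags=20)
        assert diag.band == pytest.approx(1.96 / np.sqrt(400))

    def test_correct_order_fit_whitens_residuals(self):
        x = simulate_arima_series(2, 0, 2, (0.5, -0.3), (0.4, 0.2), 1.0,
                                  3000, seed=11)
        diag = residual_diagnostics(x, ArimaSpec(p=2, d=0, q=2))
        assert diag.prop_significant_post <= 0.10

    def test_raw_ar1_has_many_significant_lags(self):
        x = simulate_arima_series(1, 0, 0, (0.8,), (), 1.0, 2000, seed=5)
        diag = residual_diagnostics(x, ArimaSpec(p=1, d=0, q=0), n_lags=10)
        # analytic ACF 0.8^k stays above the +-1.96/sqrt(n) band early on
        assert diag.prop_significant_pre > 0.5
        assert diag.prop_significant_post < diag.prop_significant_pre

    def test_excessive_lags_truncated_with_warning(self, rng):
        x = rng.normal(size=60)
        with pytest.warns(UserWarning, match="truncating"):
            diag = residual_diagnostics(x, ArimaSpec(p=1, d=0, q=0), n_lags=80)
        assert diag.n_lags < 60


def test_spec_validation():
    with pytest.raises(ValueError):
        ArimaSpec(p=-1, d=0, q=0)
    with pytest.raises(ValueError):
        ArimaSpec(p=1, d=0, q=0, phi=(0.5, 0.2))
    assert ArimaSpec(p=1, d=1, q=0, pre_diff=1).total_d == 2
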