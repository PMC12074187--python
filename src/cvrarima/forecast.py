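"""One-step-ahead forecasting with fixed per-patient ARIMA orders.

A model with the previously selected (p, d, q) orders is fitted once on
an initial training window; the fitted coefficients are then frozen and
the Kalman filter is advanced through the held-out portion, emitting each
one-step-ahead prediction before the corresponding observation enters the
state. (Re-estimating the coefficients at every step is available by
flag, at a substantial cost.)

Agreement between predictions and observations is summarized by the
Pearson correlation and by Bland-Altman statistics of the paired
differences ``forecast - observed``: mean difference (systematic bias)
and limits of agreement ``mean +- 1.96 * SD`` (sample SD, n-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa.arima.model import ARIMA

from .arima import ArimaSpec

__all__ = [
    "ForecastEvaluation",
    "rolling_one_step",
    "pearson_agreement",
    "bland_altman",
    "evaluate_forecasts",
    "correlation_vs_spread",
]


@dataclass(frozen=True)
class ForecastEvaluation:
    """Per patient x signal forecast agreement summary."""

    patient_id: str
    signal: str
    spec: ArimaSpec
    pearson_r: float
    ba_mean: float
    ba_lower: float
    ba_upper: float
    n_forecasts: int

    @property
    def loa_spread(self) -> float:
        return self.ba_upper - self.ba_lower


def rolling_one_step(series, spec: ArimaSpec, train_fraction: float = 0.5,
                     refit_each_step: bool = False
                     ) -> tuple[np.ndarray, np.ndarray]:
    """One-step-ahead predictions over the held-out tail of ``series``.

    The model is estimated on the leading ``train_fraction`` of the data.
    In the default fixed-coefficient mode the remaining observations are
    filtered through the fitted model one at a time, each prediction
    emitted before its observation is revealed. Returns
    ``(predictions, observations)`` of equal length.
    """
    x = np.asarray(series, dtype=float)
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(x)
    n_train = int(n * train_fraction)
    k = spec.p + spec.q + 2
    if n_train < k + 10:
        raise ValueError("training window shorter than k + 10")
    order = (spec.p, spec.d, spec.q)
    trend = "c" if spec.d == 0 else "n"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if refit_each_step:
            preds = np.empty(n - n_train)
            for i, t in enumerate(range(n_train, n)):
                res = ARIMA(x[:t], order=order, trend=trend).fit()
                preds[i] = res.forecast(1)[0]
        else:
            res = ARIMA(x[:n_train], order=order, trend=trend).fit()
            # freeze coefficients, run the filter over the full series
            full = res.apply(x)
            preds = np.asarray(
                full.get_prediction(start=n_train, end=n - 1,
                                    dynamic=False).predicted_mean)
    return preds, x[n_train:]


def pearson_agreement(predictions, observations) -> float:
    """Pearson r between predictions and observations; NaN if degenerate."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predictions and observations differ in length")
    if len(p) < 3 or np.ptp(p) == 0 or np.ptp(o) == 0:
        return float("nan")
    return float(np.corrcoef(p, o)[0, 1])


def bland_altman(predictions, observations) -> tuple[float, float, float]:
    """Bland-Altman bias and limits of agreement of ``forecast - observed``.

    Returns ``(mean_diff, lower_loa, upper_loa)`` with the limits at
    ``mean +- 1.96 * SD`` using the sample (n-1) standard deviation.
    """
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predictions and observations differ in length")
    d = p - o
    if len(d) < 2:
        return float("nan"), float("nan"), float("nan")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def evaluate_forecasts(series, spec: ArimaSpec, patient_id: str = "",
                       signal: str = "ICP", train_fraction: float = 0.5,
                       refit_each_step: bool = False) -> ForecastEvaluation:
    """Run the rolling scheme and summarize agreement for one series."""
    preds, obs = rolling_one_step(series, spec, train_fraction,
                                  refit_each_step)
    r = pearson_agreement(preds, obs)
    mean, lower, upper = bland_altman(preds, obs)
    return ForecastEvaluation(patient_id, signal, spec, r, mean, lower,
                              upper, len(preds))


def correlation_vs_spread(evaluations) -> pd.DataFrame:
    """Scatter table of Pearson r against limits-of-agreement spread."""
    return pd.DataFrame([
        {
            "patient_id": ev.patient_id,
            "signal": ev.signal,
            "pearson_r": ev.pearson_r,
            "loa_spread": ev.loa_spread,
        }
        for ev in evaluations
    ])


def evaluations_frame(evaluations) -> pd.DataFrame:
    """Per-patient agreement table in the reporting column order."""
    return pd.DataFrame([
        {
            "patient_id": ev.patient_id,
            "signal": ev.signal,
            "p": ev.spec.p,
            "d": ev.spec.total_d,
            "q": ev.spec.q,
            "pearson_r": ev.pearson_r,
            "ba_mean": ev.ba_mean,
            "ba_lower_loa": ev.ba_lower,
            "ba_upper_loa": ev.ba_upper,
            "n_forecasts": ev.n_forecasts,
        }
        for ev in evaluations
    ])
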