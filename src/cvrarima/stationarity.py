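"""ADF/KPSS stationarity classification per patient x signal x resolution.

The ADF test has a unit-root null (rejection suggests stationarity); the
KPSS test has a level-stationarity null (rejection suggests
non-stationarity). Cohort tables are labelled by the KPSS outcome alone,
while the two-test agreement flag (ADF failed to reject AND KPSS
rejected) is recorded separately as the trigger that motivated
first-order differencing. Series failing the minimum-length rule are
labelled NA.

Both tests run with conventional defaults for physiologic means: ADF
regression with constant only, lag order by AIC; KPSS level-stationarity
with automatic Newey-West bandwidth. KPSS p-values come from
interpolation in the standard critical-value table and are therefore
bracketed to [0.01, 0.10].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tools.sm_exceptions import InterpolationWarning
from statsmodels.tsa.stattools import adfuller, kpss

from .resolution import MIN_POINTS_TEST, sufficiency_check

__all__ = [
    "TestResult",
    "StationarityResult",
    "adf_test",
    "kpss_test",
    "classify",
    "difference",
    "evaluate_series",
    "cohort_stationarity_table",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    stat: float
    p: float
    reject: bool
    usable: bool


_NA_TEST = TestResult(np.nan, np.nan, False, False)


@dataclass(frozen=True)
class StationarityResult:
    """Outcome for one patient x signal x resolution cell at one stage."""

    patient_id: str
    signal: str
    resolution: int
    differencing_applied: int          # 0 = raw, 1 = first difference
    adf: TestResult
    kpss: TestResult
    label: str                         # stationary / non-stationary / NA
    needs_differencing: bool           # agreement flag: ADF retain & KPSS reject


def _clean(series) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    return x[~np.isnan(x)]


def adf_test(series, alpha: float = ALPHA,
             min_points: int = MIN_POINTS_TEST) -> TestResult:
    """Augmented Dickey-Fuller test (unit-root null).

    Constant-only regression; lag order chosen by AIC up to the usual
    ``12 * (n/100)**0.25`` ceiling (statsmodels default). Rejection at
    ``alpha`` favours stationarity.
    """
    x = _clean(series)
    if not sufficiency_check(x, min_points):
        return _NA_TEST
    try:
        stat, p, *_ = adfuller(x, regression="c", autolag="AIC")
    except (ValueError, np.linalg.LinAlgError):
        return _NA_TEST
    return TestResult(float(stat), float(p), bool(p < alpha), True)


def kpss_test(series, alpha: float = ALPHA,
              min_points: int = MIN_POINTS_TEST) -> TestResult:
    """KPSS test (level-stationarity null), automatic Newey-West bandwidth.

    The rejection flag compares the statistic against the 5% critical
    value directly, so it is exact even where the p-value is bracketed.
    """
    x = _clean(series)
    if not sufficiency_check(x, min_points):
        return _NA_TEST
    if np.ptp(x) == 0:
        # constant series: zero partial-sum variance, trivially stationary
        return TestResult(0.0, 0.10, False, True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", InterpolationWarning)
            stat, p, _, crit = kpss(x, regression="c", nlags="auto")
    except (ValueError, OverflowError):
        return _NA_TEST
    return TestResult(float(stat), float(p), bool(stat > crit["5%"]), True)


def classify(adf_reject: bool, kpss_reject: bool, usable: bool = True
             ) -> tuple[str, bool]:
    """Label a cell and report the differencing-trigger agreement flag.

    The cohort label follows the KPSS outcome alone (reject ->
    non-stationary, retain -> stationary); the agreement flag fires when
    ADF fails to reject (unit root plausible) AND KPSS rejects
    (stationarity implausible).
    """
    if not usable:
        return "NA", False
    label = "non-stationary" if kpss_reject else "stationary"
    return label, (not adf_reject) and kpss_reject


def difference(series, order: int = 1):
    """Repeated first differencing: ``x_t - x_{t-1}``, applied ``order`` times.

    Output length is ``n - order``; a NaN input propagates to every
    difference that touches it.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    x = np.asarray(series, dtype=float)
    if len(x) <= order:
        raise ValueError("series too short to difference")
    out = np.diff(x, n=order)
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index[order:])
    return out


def evaluate_series(series, patient_id: str, signal: str, resolution: int,
                    stage: int = 0, alpha: float = ALPHA,
                    min_points: int = MIN_POINTS_TEST) -> StationarityResult:
    """Run both tests on one cell and classify it."""
    adf = adf_test(series, alpha, min_points)
    kp = kpss_test(series, alpha, min_points)
    usable = adf.usable and kp.usable
    label, flag = classify(adf.reject, kp.reject, usable)
    return StationarityResult(patient_id, signal, resolution, stage,
                              adf, kp, label, flag)


def results_frame(results) -> pd.DataFrame:
    """Long-format table of stationarity results."""
    rows = [
        {
            "patient_id": r.patient_id,
            "signal": r.signal,
            "resolution": r.resolution,
            "stage": "raw" if r.differencing_applied == 0 else "differenced",
            "adf_stat": r.adf.stat,
            "adf_p": r.adf.p,
            "adf_reject": r.adf.reject,
            "kpss_stat": r.kpss.stat,
            "kpss_p": r.kpss.p,
            "kpss_reject": r.kpss.reject,
            "label": r.label,
            "needs_differencing": r.needs_differencing,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def cohort_stationarity_table(results: pd.DataFrame) -> pd.DataFrame:
    """Percentages of {stationary, non-stationary, NA} per signal x resolution.

    The denominator is the full cohort, so the three percentages sum to
    100 up to the 0.1 rounding applied to each entry.
    """
    if results.empty:
        return pd.DataFrame(
            columns=["signal", "resolution", "stationary", "non-stationary", "NA"])
    rows = []
    for (signal, resolution), grp in results.groupby(
            ["signal", "resolution"], sort=True):
        n = len(grp)
        counts = grp["label"].value_counts()
        rows.append({
            "signal": signal,
            "resolution": resolution,
            "stationary": round(100.0 * counts.get("stationary", 0) / n, 1),
            "non-stationary": round(100.0 * counts.get("non-stationary", 0) / n, 1),
            "NA": round(100.0 * counts.get("NA", 0) / n, 1),
        })
    return pd.DataFrame(rows)
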