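"""ARIMA grid search, criterion-based selection and residual diagnostics.

Every (p, d, q) cell of a configurable grid is fitted by maximum
likelihood to a series that has already been first-differenced once (the
universal pre-differencing step), so a within-fit ``d`` of 0 or 1
corresponds to a total integration order of 1 or 2. Fits are scored by
AIC, BIC and log-likelihood; per-patient optima are aggregated into
population median models per signal x resolution.

Conventions:

* ``p`` starts at 1 by default (pure-MA cells are unreachable unless the
  caller widens the range);
* a constant term is estimated only when the within-fit ``d`` is 0 — a
  constant under differencing would encode a deterministic drift;
* cells whose optimizer fails or raises are kept as non-converged records
  carrying infinite criteria, so grid completeness stays auditable;
* parallel execution across cells (joblib) preserves the serial ordering
  of records and is numerically identical to serial execution.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from math import floor
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from statsmodels.tsa.arima.model import ARIMA
from statsmodels.tsa.stattools import acf, pacf

__all__ = [
    "ArimaSpec",
    "ArimaFitRecord",
    "fit_arima",
    "grid_search",
    "select_optimal",
    "population_median_models",
    "residual_diagnostics",
    "records_frame",
]

DEFAULT_P_RANGE = range(1, 11)
DEFAULT_D_GRID = (0, 1)
DEFAULT_Q_RANGE = range(0, 11)


@dataclass(frozen=True)
class ArimaSpec:
    """Orders and estimated coefficients of one ARIMA model."""

    p: int
    d: int                      # differencing inside the fit
    q: int
    pre_diff: int = 0           # differencing applied before the fit
    constant: float = 0.0
    phi: tuple[float, ...] = ()
    theta: tuple[float, ...] = ()
    sigma2: float = float("nan")

    @property
    def total_d(self) -> int:
        return self.pre_diff + self.d

    def __post_init__(self) -> None:
        if min(self.p, self.d, self.q, self.pre_diff) < 0:
            raise ValueError("orders must be nonnegative")
        if len(self.phi) not in (0, self.p) or len(self.theta) not in (0, self.q):
            raise ValueError("coefficient vectors must have lengths p and q")


@dataclass
class ArimaFitRecord:
    """One grid-search cell: orders, criteria, convergence, wall time."""

    patient_id: str
    signal: str
    resolution: int
    spec: ArimaSpec
    aic: float
    bic: float
    ll: float
    converged: bool
    fit_seconds: float
    n_eff: int = 0


def fit_arima(series, p: int, d: int, q: int,
              with_constant: bool | None = None, pre_diff: int = 0,
              patient_id: str = "", signal: str = "",
              resolution: int = 1) -> ArimaFitRecord:
    """Maximum-likelihood fit of one ARIMA(p, d, q) cell.

    ``with_constant=None`` applies the default policy: estimate a constant
    iff ``d == 0``. A failed optimization never raises; it returns a
    non-converged record with infinite criteria.
    """
    x = np.asarray(series, dtype=float)
    trend = "c" if (with_constant if with_constant is not None else d == 0) else "n"
    n_eff = len(x) - d
    t0 = time.perf_counter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # the innovation variance is profiled out of the optimization
            # (faster, same maximum); it still counts toward k below
            res = ARIMA(x, order=(p, d, q), trend=trend,
                        concentrate_scale=True).fit()
        converged = bool(res.mle_retvals.get("converged", True))
        k_trend = 1 if trend == "c" else 0
        spec = ArimaSpec(
            p=p, d=d, q=q, pre_diff=pre_diff,
            constant=float(res.params[0]) if k_trend else 0.0,
            phi=tuple(float(v) for v in res.arparams),
            theta=tuple(float(v) for v in res.maparams),
            sigma2=float(res.scale),
        )
        elapsed = time.perf_counter() - t0
        if converged and np.isfinite(res.llf):
            k = p + q + k_trend + 1          # +1 for the innovation variance
            ll = float(res.llf)
            return ArimaFitRecord(patient_id, signal, resolution, spec,
                                  2 * k - 2 * ll,
                                  k * np.log(n_eff) - 2 * ll,
                                  ll, True, elapsed, n_eff=n_eff)
        return ArimaFitRecord(patient_id, signal, resolution, spec,
                              float("inf"), float("inf"), float("-inf"),
                              False, elapsed, n_eff=n_eff)
    except (ValueError, np.linalg.LinAlgError, IndexError):
        spec = ArimaSpec(p=p, d=d, q=q, pre_diff=pre_diff)
        return ArimaFitRecord(patient_id, signal, resolution, spec,
                              float("inf"), float("inf"), float("-inf"),
                              False, time.perf_counter() - t0, n_eff=n_eff)


def grid_search(series, p_range: Iterable[int] = DEFAULT_P_RANGE,
                d_grid: Iterable[int] = DEFAULT_D_GRID,
                q_range: Iterable[int] = DEFAULT_Q_RANGE,
                pre_diff: int = 1, workers: int = 1,
                **meta) -> list[ArimaFitRecord]:
    """Fit every cell of the (p, d, q) grid on an (already differenced) series.

    The default grid is p in 1..10, d in {0, 1} and q in 0..10 — 220
    cells. One record is returned per cell, in deterministic
    (p, d, q)-lexicographic order regardless of ``workers``.
    """
    cells = [(p, d, q) for p in p_range for d in d_grid for q in q_range]
    if not cells:
        raise ValueError("empty grid")
    if workers > 1:
        return Parallel(n_jobs=workers)(
            delayed(fit_arima)(series, p, d, q, pre_diff=pre_diff, **meta)
            for p, d, q in cells)
    return [fit_arima(series, p, d, q, pre_diff=pre_diff, **meta)
            for p, d, q in cells]


def select_optimal(records: Sequence[ArimaFitRecord],
                   criterion: str = "aic") -> ArimaFitRecord | None:
    """Best record by AIC/BIC (minimum) or log-likelihood (maximum).

    Ties are broken toward the simpler model: smaller p + q, then smaller
    p. Returns None when no cell converged.
    """
    criterion = criterion.lower()
    if criterion not in {"aic", "bic", "ll"}:
        raise ValueError("criterion must be one of aic, bic, ll")
    usable = [r for r in records if r.converged]
    if not usable:
        return None
    if criterion == "ll":
        key = lambda r: (-r.ll, r.spec.p + r.spec.q, r.spec.p)  # noqa: E731
    else:
        key = lambda r: (getattr(r, criterion), r.spec.p + r.spec.q, r.spec.p)  # noqa: E731
    return min(usable, key=key)


def _floor_median(values) -> int:
    """Median with half-point values rounded down to the simpler order."""
    return int(floor(float(np.median(values))))


def population_median_models(optima: pd.DataFrame,
                             criterion: str = "aic") -> pd.DataFrame:
    """Component-wise median optimal orders per signal x resolution.

    ``optima`` needs columns patient_id, signal, resolution, p, total_d,
    q and the criterion value column. Component-wise medians of the
    orders are reported (half-point medians floored), alongside the
    median criterion value and the number of contributing patients.
    """
    col = criterion.lower()
    rows = []
    for (signal, resolution), grp in optima.groupby(
            ["signal", "resolution"], sort=True):
        grp = grp.dropna(subset=["p", "total_d", "q", col])
        if grp.empty:
            continue
        rows.append({
            "signal": signal,
            "resolution": resolution,
            "criterion": col.upper(),
            "median_p": _floor_median(grp["p"]),
            "median_d": _floor_median(grp["total_d"]),
            "median_q": _floor_median(grp["q"]),
            "median_criterion_value": float(np.median(grp[col])),
            "n_patients": int(len(grp)),
        })
    return pd.DataFrame(rows)


@dataclass
class ResidualDiagnostics:
    residuals: np.ndarray
    acf_raw: np.ndarray
    pacf_raw: np.ndarray
    acf_resid: np.ndarray
    pacf_resid: np.ndarray
    band: float
    prop_significant_pre: float
    prop_significant_post: float
    n_lags: int = field(default=40)


def residual_diagnostics(series, spec: ArimaSpec,
                         n_lags: int = 40) -> ResidualDiagnostics:
    """Whiteness check: ACF/PACF of the raw series vs the fit residuals.

    The 95% band is ``+-1.96 / sqrt(n_eff)``; the proportions count lags
    1..n_lags whose ACF falls outside the band, before and after
    modelling. An adequate model shows a pronounced reduction.
    """
    x = np.asarray(series, dtype=float)
    n_eff = len(x) - spec.d
    max_lags = n_eff // 2 - 1   # PACF estimable only up to half the sample
    if n_lags > max_lags:
        warnings.warn("n_lags too large for series length; truncating",
                      stacklevel=2)
        n_lags = max(1, max_lags)
    trend = "c" if spec.d == 0 else "n"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = ARIMA(x, order=(spec.p, spec.d, spec.q), trend=trend).fit()
        resid = np.asarray(res.resid[spec.d:], dtype=float)
        acf_raw = acf(x, nlags=n_lags, fft=True)
        pacf_raw = pacf(x, nlags=n_lags)
        acf_res = acf(resid, nlags=n_lags, fft=True)
        pacf_res = pacf(resid, nlags=n_lags)
    band = 1.96 / np.sqrt(n_eff)
    pre = float(np.mean(np.abs(acf_raw[1:]) > band))
    post = float(np.mean(np.abs(acf_res[1:]) > band))
    return ResidualDiagnostics(resid, acf_raw, pacf_raw, acf_res, pacf_res,
                               band, pre, post, n_lags)


def plot_diagnostics(diag: ResidualDiagnostics, path) -> None:
    """Write the residual/ACF/PACF diagnostic panel to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 6))
    axes[0, 0].plot(diag.residuals, lw=0.6)
    axes[0, 0].set_title("residuals")
    lags = np.arange(diag.n_lags + 1)
    for ax, vals, title in (
            (axes[0, 1], diag.acf_raw, "ACF (raw)"),
            (axes[1, 0], diag.acf_resid, "ACF (residuals)"),
            (axes[1, 1], diag.pacf_resid, "PACF (residuals)")):
        ax.stem(lags, vals[: diag.n_lags + 1])
        ax.axhspan(-diag.band, diag.band, alpha=0.2)
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def records_frame(records: Sequence[ArimaFitRecord]) -> pd.DataFrame:
    """Flatten grid records into the per-cell CSV layout."""
    rows = [
        {
            "patient_id": r.patient_id,
            "signal": r.signal,
            "resolution": r.resolution,
            "p": r.spec.p,
            "d": r.spec.d,
            "q": r.spec.q,
            "total_d": r.spec.total_d,
            "aic": r.aic,
            "bic": r.bic,
            "ll": r.ll,
            "converged": r.converged,
            "fit_seconds": r.fit_seconds,
        }
        for r in records
    ]
    return pd.DataFrame(rows)
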