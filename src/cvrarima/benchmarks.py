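"""Seeded validation experiments with known ground truth.

Each routine here builds its own synthetic inputs from a seed, runs the
relevant part of the pipeline, and measures how well the known structure
is recovered: ARIMA order recovery, ADF/KPSS calibration, index ground
truth, subgroup-test size and power, and forecast agreement coverage.
They back both the test suite and the reproduction script.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .arima import fit_arima, grid_search, residual_diagnostics, select_optimal
from .forecast import bland_altman, rolling_one_step
from .arima import ArimaSpec
from .signals import compute_amp, derive_indices, ten_second_means
from .stationarity import adf_test, difference, kpss_test
from .subgroups import subgroup_analysis
from .synthetic import (SimulationConfig, _patient_config, metadata_frame,
                        simulate_arima_series, simulate_metadata,
                        simulate_waveforms)

__all__ = [
    "order_recovery",
    "stationarity_calibration",
    "index_ground_truth",
    "subgroup_null_calibration",
    "marshall_effect_power",
    "forecast_loa_coverage",
]

# Reference generating process for order recovery: ARIMA(2,1,2) with
# phi = (0.5, -0.3), theta = (0.4, 0.2), unit innovation SD.
RECOVERY_AR = (0.5, -0.3)
RECOVERY_MA = (0.4, 0.2)


def order_recovery(n_series: int = 20, n: int = 3000, seed: int = 0,
                   p_max: int = 5, q_max: int = 5) -> dict:
    """Grid-search AIC optima on seeded ARIMA(2,1,2) series.

    Each replicate is pre-differenced once and searched over p in
    1..p_max, d in {0, 1}, q in 0..q_max, so the true model sits at the
    within-fit cell (2, 0, 2) with total d = 1. Reports how often the
    optimum lands on total_d = 1 and within +-1 of (p, q) = (2, 2).
    """
    ss = np.random.SeedSequence(seed)
    d1_hits = pq_hits = bic_le_aic = aic_le_ll = 0
    optima = []
    post_props = []
    for child in ss.spawn(n_series):
        x = simulate_arima_series(2, 1, 2, RECOVERY_AR, RECOVERY_MA, 1.0, n,
                                  seed=np.random.default_rng(child))
        pre = difference(x, 1)
        records = grid_search(pre, range(1, p_max + 1), (0, 1),
                              range(0, q_max + 1), pre_diff=1)
        best = select_optimal(records, "aic")
        optima.append(best.spec)
        if best.spec.total_d == 1:
            d1_hits += 1
        if abs(best.spec.p - 2) <= 1 and abs(best.spec.q - 2) <= 1:
            pq_hits += 1
        by = {c: select_optimal(records, c).spec for c in ("bic", "ll")}
        if by["bic"].p + by["bic"].q <= best.spec.p + best.spec.q:
            bic_le_aic += 1
        if best.spec.p + best.spec.q <= by["ll"].p + by["ll"].q:
            aic_le_ll += 1
        diag = residual_diagnostics(pre, best.spec)
        post_props.append(diag.prop_significant_post)
    return {
        "n_series": n_series,
        "total_d1": d1_hits,
        "pq_within_1": pq_hits,
        "bic_le_aic": bic_le_aic,
        "aic_le_ll": aic_le_ll,
        "median_prop_significant_post": float(np.median(post_props)),
        "optima": optima,
    }


def stationarity_calibration(n_reps: int = 100, n: int = 1000,
                             seed: int = 0) -> dict:
    """Size and power of the two-test ladder on known processes.

    Random walks should fire the non-stationarity agreement flag (ADF
    retains AND KPSS rejects) and stop firing after first differencing;
    iid Gaussian series should retain the KPSS null.
    """
    ss = np.random.SeedSequence(seed)
    rw_flag = rw_diff_flag = gauss_kpss_retain = gauss_adf_reject = 0
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        walk = np.cumsum(rng.normal(size=n))
        gauss = rng.normal(size=n)
        adf, kp = adf_test(walk), kpss_test(walk)
        if (not adf.reject) and kp.reject:
            rw_flag += 1
        dwalk = difference(walk, 1)
        adf_d, kp_d = adf_test(dwalk), kpss_test(dwalk)
        if (not adf_d.reject) and kp_d.reject:
            rw_diff_flag += 1
        if not kpss_test(gauss).reject:
            gauss_kpss_retain += 1
        if adf_test(gauss).reject:
            gauss_adf_reject += 1
    return {
        "n_reps": n_reps,
        "rw_agreement_flag": rw_flag,
        "rw_diff_agreement_flag": rw_diff_flag,
        "gauss_kpss_retain": gauss_kpss_retain,
        "gauss_adf_reject": gauss_adf_reject,
    }


def index_ground_truth(seed: int = 3, duration_min: float = 60.0) -> dict:
    """Index derivation on passive (g=+1) and counter-regulating (g=-1)
    patients with slow waves far above the noise floor, plus the pure-tone
    pulse-amplitude check."""
    base = SimulationConfig(
        seed=seed, duration_min=duration_min, autoregulation_gain=1.0,
        noise_sd={"ABP": 0.05, "ICP": 0.02, "rSO2": 0.1, "PbtO2": 0.1})
    passive = derive_indices(ten_second_means(simulate_waveforms(base)))
    counter_cfg = dataclasses.replace(base, autoregulation_gain=-1.0)
    counter = derive_indices(ten_second_means(simulate_waveforms(counter_cfg)))
    t = np.arange(int(60 * 50)) / 50.0
    amp = compute_amp(10 + 2 * np.sin(2 * np.pi * 1.2 * t), 50.0)
    cpp_residual = float(np.nanmax(np.abs(
        passive["CPP"] + passive["ICP"] - passive["MAP"])))
    return {
        "prx_median_passive": float(np.nanmedian(passive["PRx"])),
        "prx_median_counter": float(np.nanmedian(counter["PRx"])),
        "amp_pure_tone": float(np.nanmean(amp)),
        "cpp_identity_residual": cpp_residual,
    }


def _metric_cohort(rng: np.random.Generator, n_patients: int,
                   noise_scales: np.ndarray, n_minutes: int = 240
                   ) -> np.ndarray:
    """Per-patient AIC of a fixed-order fit to minute-scale series whose
    innovation SD carries the subgroup effect."""
    aics = np.empty(n_patients)
    for i in range(n_patients):
        x = simulate_arima_series(1, 1, 0, (0.5,), (), float(noise_scales[i]),
                                  n_minutes, seed=rng)
        pre = difference(x, 1)
        aics[i] = fit_arima(pre, 1, 0, 1, pre_diff=1).aic
    return aics


def subgroup_null_calibration(n_cohorts: int = 200, n_patients: int = 40,
                              seed: int = 0) -> dict:
    """Empirical type-I rate of the gated ladder under a global null.

    Each cohort draws covariates from the simulator and model metrics
    from a common distribution (no injected effect); every
    signal x grouping x metric cell is tested at alpha = 0.05.
    """
    ss = np.random.SeedSequence(seed)
    rejected = total = 0
    for child in ss.spawn(n_cohorts):
        rng = np.random.default_rng(child)
        cfg = SimulationConfig(seed=int(child.generate_state(1)[0] % 2**31),
                               n_patients=n_patients, duration_min=1)
        meta = metadata_frame(simulate_metadata(cfg, rng))
        optima = pd.DataFrame({
            "patient_id": meta["patient_id"],
            "signal": "ICP",
            "aic": rng.normal(size=n_patients),
            "bic": rng.normal(size=n_patients),
            "ll": rng.normal(size=n_patients),
        })
        out = subgroup_analysis(optima, meta)
        rejected += int(out["significant"].sum())
        total += len(out)
    return {"n_cohorts": n_cohorts, "n_tests": total,
            "rejection_rate": rejected / total if total else float("nan")}


def marshall_effect_power(n_reps: int = 10, n_per_group: int = 20,
                          seed: int = 0, noise_scale: float = 1.5) -> dict:
    """Power to detect an injected Marshall-group noise effect.

    Patients with Marshall >= 5 receive a ``noise_scale`` multiplier on
    their innovation SD (the subgroup-effect mechanism of the simulator);
    the per-patient metric is the AIC of a fixed-order fit, and the gated
    two-group comparison is run on each replicate cohort.
    """
    effects = {"marshall_group=>=5": {"noise_sd_scale": noise_scale}}
    n_patients = 2 * n_per_group
    ss = np.random.SeedSequence(seed)
    detected = 0
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        cfg = SimulationConfig(seed=0, n_patients=n_patients, duration_min=1,
                               subgroup_effects=effects)
        metas = simulate_metadata(cfg, rng)
        # balanced design: first half Marshall II, second half Marshall V
        metas = [dataclasses.replace(m, marshall=2 if i < n_per_group else 5)
                 for i, m in enumerate(metas)]
        meta = metadata_frame(metas)
        scales = np.array([
            _patient_config(cfg, m).noise_sd["ABP"] for m in metas])
        aics = _metric_cohort(rng, n_patients, scales)
        optima = pd.DataFrame({
            "patient_id": meta["patient_id"], "signal": "MAP",
            "aic": aics, "bic": aics, "ll": -aics,
        })
        out = subgroup_analysis(optima, meta)
        cell = out[(out["grouping"] == "marshall_group")
                   & (out["metric"] == "AIC")]
        if not cell.empty and bool(cell["significant"].iloc[0]):
            detected += 1
    return {"n_reps": n_reps, "detected": detected,
            "power": detected / n_reps}


def forecast_loa_coverage(n: int = 1000, seed: int = 0) -> dict:
    """Fraction of one-step forecast differences inside the limits of
    agreement for a Gaussian-innovation AR process."""
    x = simulate_arima_series(1, 1, 0, (0.5,), (), 1.0, n, seed=seed)
    preds, obs = rolling_one_step(x, ArimaSpec(p=1, d=1, q=0))
    d = preds - obs
    _, lo, hi = bland_altman(preds, obs)
    coverage = float(np.mean((d >= lo) & (d <= hi)))
    return {"n_forecasts": len(d), "coverage": coverage}
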