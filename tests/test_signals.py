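"""Frame means, pulse amplitude, CPP and moving-correlation indices."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cvrarima.signals import (compute_amp, compute_cpp, derive_indices,
                              moving_correlation, ten_second_means)
from cvrarima.synthetic import SimulationConfig, WaveformRecord, simulate_waveforms


def _record(channels, fs=50.0):
    return WaveformRecord("t", {k: np.asarray(v, float) for k, v in channels.items()},
                          sampling_rate=fs)


class TestTenSecondMeans:
    def test_constant_signal_means_are_constant(self):
        rec = _record({"ABP": np.full(3000, 80.0)})
        out = ten_second_means(rec)
        assert np.allclose(out["MAP"], 80.0)
        assert len(out) == 6

    def test_full_cycle_sinusoid_averages_to_zero(self):
        # 1.2 Hz has 12 full cycles per 10-s frame
        t = np.arange(3000) / 50.0
        rec = _record({"ABP": np.sin(2 * np.pi * 1.2 * t)})
        assert np.allclose(ten_second_means(rec)["MAP"], 0.0, atol=1e-12)

    def test_ramp_first_frame_mean(self):
        rec = _record({"ABP": np.arange(600.0)}, fs=1.0)
        assert ten_second_means(rec)["MAP"].iloc[0] == pytest.approx(4.5)

    def test_frames_with_missing_samples_are_nan(self):
        x = np.ones(1500)
        x[520] = np.nan
        out = ten_second_means(_record({"ABP": x}))
        assert np.isnan(out["MAP"].iloc[1])
        assert np.isfinite(out["MAP"].drop(out.index[1])).all()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=st.floats(-5, 5, allow_nan=False),
           b=st.floats(-50, 50, allow_nan=False))
    def test_commutes_with_affine_rescaling(self, a, b):
        rng = np.random.default_rng(7)
        x = rng.normal(80, 5, 1500)
        base = ten_second_means(_record({"ABP": x}))["MAP"]
        scaled = ten_second_means(_record({"ABP": a * x + b}))["MAP"]
        np.testing.assert_allclose(scaled, a * base + b, rtol=1e-9, atol=1e-7)


class TestComputeAmp:
    def test_pure_tone_amplitude_recovered(self):
        t = np.arange(0, 60 * 50) / 50.0
        amp = compute_amp(10 + 2 * np.sin(2 * np.pi * 1.2 * t), 50.0)
        np.testing.assert_allclose(amp, 2.0, rtol=0.02)

    def test_constant_signal_zero_amplitude(self):
        assert np.allclose(compute_amp(np.full(1500, 10.0), 50.0), 0.0)

    def test_slow_tone_outside_band_ignored(self):
        t = np.arange(0, 120 * 50) / 50.0
        x = 2 * np.sin(2 * np.pi * 1.2 * t) + 1 * np.sin(2 * np.pi * 0.02 * t)
        amp = compute_amp(x, 50.0)
        # oracle: per-frame DFT magnitudes by direct summation
        frame = 500
        f0 = x[:frame] - x[:frame].mean()
        k = np.arange(frame)
        direct = [2 * abs(np.sum(f0 * np.exp(-2j * np.pi * kk * k / frame))) / frame
                  for kk in range(1, frame // 2)]
        freqs = np.arange(1, frame // 2) * 50.0 / frame
        in_band = (freqs >= 0.66) & (freqs <= 3.0)
        assert amp[0] == pytest.approx(max(np.asarray(direct)[in_band]), rel=1e-9)
        np.testing.assert_allclose(amp, 2.0, rtol=0.05)

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1500)
        np.testing.assert_allclose(compute_amp(x, 50.0),
                                   compute_amp(x + 123.4, 50.0), atol=1e-12)

    def test_missing_samples_propagate(self):
        x = np.ones(1000)
        x[5] = np.nan
        amp = compute_amp(x, 50.0)
        assert np.isnan(amp[0]) and np.isfinite(amp[1])

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            compute_amp(np.ones(1000), 50.0, cardiac_band=(30.0, 20.0))


class TestComputeCpp:
    def test_cohort_mean_values(self):
        # cohort-typical means: MAP 86.9, ICP 11.9 -> CPP 75.0
        assert compute_cpp(np.array([86.9]), np.array([11.9]))[0] == pytest.approx(75.0)

    def test_identity_and_nan_propagation(self):
        out = compute_cpp(np.array([80.0, 80.0]), np.array([80.0, np.nan]))
        assert out[0] == 0.0 and np.isnan(out[1])

    def test_misaligned_grids_rejected(self):
        idx_a = pd.date_range("2024-01-01", periods=3, freq="10s")
        idx_b = pd.date_range("2024-01-01 00:00:10", periods=3, freq="10s")
        with pytest.raises(ValueError, match="misaligned"):
            compute_cpp(pd.Series([1.0] * 3, index=idx_a),
                        pd.Series([1.0] * 3, index=idx_b))


class TestMovingCorrelation:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=120)
        assert np.allclose(moving_correlation(x, x), 1.0)

    def test_sign_reversal(self, rng):
        x = rng.normal(size=120)
        assert np.allclose(moving_correlation(x, -x), -1.0)

    def test_constant_window_is_nan(self, rng):
        x = np.ones(60)
        y = rng.normal(size=60)
        assert np.isnan(moving_correlation(x, y)).all()

    def test_independent_series_mean_near_zero(self, rng):
        n = 30 + 6 * 200
        r = moving_correlation(rng.normal(size=n), rng.normal(size=n))
        assert abs(np.nanmean(r)) < 0.05

    def test_nan_in_window_gives_nan(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        x[10] = np.nan
        r = moving_correlation(x, y)
        assert np.isnan(r[0])   # first window covers samples 0..29

    def test_output_bounded(self, rng):
        r = moving_correlation(rng.normal(size=300), rng.normal(size=300))
        ok = r[~np.isnan(r)]
        assert ((-1 <= ok) & (ok <= 1)).all()

    def test_bad_update_rejected(self):
        with pytest.raises(ValueError):
            moving_correlation(np.ones(40), np.ones(40), update_samples=0)


class TestDeriveIndices:
    def test_passive_patient_has_high_prx(self, passive_record):
        mt = derive_indices(ten_second_means(passive_record))
        assert np.nanmedian(mt["PRx"]) > 0.8

    def test_counter_regulating_patient_has_negative_prx(self, passive_config):
        cfg = dataclasses.replace(passive_config, autoregulation_gain=-1.0)
        mt = derive_indices(ten_second_means(simulate_waveforms(cfg)))
        assert np.nanmedian(mt["PRx"]) < -0.5

    def test_cpp_plus_icp_equals_map(self, passive_record):
        mt = derive_indices(ten_second_means(passive_record))
        resid = (mt["CPP"] + mt["ICP"] - mt["MAP"]).dropna()
        assert np.abs(resid).max() < 1e-9

    def test_missing_rso2_leaves_cox_na_and_prx_unaffected(self, passive_record):
        channels = {k: v for k, v in passive_record.channels.items()
                    if not k.startswith("rSO2")}
        partial = WaveformRecord("p", channels, passive_record.sampling_rate)
        mt_full = derive_indices(ten_second_means(passive_record))
        mt_part = derive_indices(ten_second_means(partial))
        for col in ("COx_L", "COx_R", "COx-a_L", "COx-a_R", "rSO2_L", "rSO2_R"):
            assert mt_part[col].isna().all()
        pd.testing.assert_series_equal(mt_part["PRx"], mt_full["PRx"])

    def test_minute_grid_spacing(self, passive_record):
        mt = derive_indices(ten_second_means(passive_record))
        steps = np.diff(mt.index.view("int64"))
        assert (steps == 60 * 10**9).all()

    def test_index_columns_bounded(self, passive_record):
        mt = derive_indices(ten_second_means(passive_record))
        for col in ("PRx", "PAx", "RAC", "RAP", "COx_L", "COx_R"):
            vals = mt[col].dropna()
            assert ((vals >= -1) & (vals <= 1)).all()
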