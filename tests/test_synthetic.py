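"""Simulator contracts: determinism, spectral placement, coupling sign,
covariate marginals and ARIMA ground-truth series."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cvrarima.synthetic import (SimulationConfig, inject_gaps,
                                metadata_frame, simulate_arima_series,
                                simulate_cohort, simulate_waveforms)


class TestSimulateWaveforms:
    def test_same_config_same_seed_is_bit_identical(self):
        cfg = SimulationConfig(seed=11, duration_min=5)
        a = simulate_waveforms(cfg)
        b = simulate_waveforms(cfg)
        for ch in a.channels:
            np.testing.assert_array_equal(a.channels[ch], b.channels[ch])

    def test_noise_free_flat_abp_is_baseline_plus_sinusoid(self):
        cfg = SimulationConfig(seed=1, duration_min=2, slow_wave_amp=0.0,
                               noise_sd={})
        rec = simulate_waveforms(cfg)
        t = np.arange(rec.n_samples) / cfg.sampling_rate
        resid = rec.channels["ABP"] - cfg.map_baseline
        # residual is a pure sinusoid at the cardiac frequency
        corr = np.ptp(resid)
        assert corr == pytest.approx(2 * cfg.cardiac_amp_abp, rel=1e-3)
        # removing the best-fit cardiac sinusoid leaves the constant baseline
        design = np.column_stack([np.sin(2 * np.pi * cfg.cardiac_freq * t),
                                  np.cos(2 * np.pi * cfg.cardiac_freq * t)])
        coef, *_ = np.linalg.lstsq(design, resid, rcond=None)
        assert np.allclose(resid - design @ coef, 0.0, atol=1e-8)

    def test_spectral_peaks_confined_to_cardiac_and_slow_band(self):
        cfg = SimulationConfig(seed=5, duration_min=30, noise_sd={})
        rec = simulate_waveforms(cfg)
        x = rec.channels["ABP"] - rec.channels["ABP"].mean()
        # Hann window keeps finite-record leakage well below the peaks
        x = x * np.hanning(len(x))
        freqs = np.fft.rfftfreq(len(x), 1 / cfg.sampling_rate)
        power = np.abs(np.fft.rfft(x)) ** 2
        significant = freqs[power > power.max() * 1e-4]
        lo, hi = cfg.slow_wave_band
        in_slow = significant <= 2 * hi
        near_cardiac = np.abs(significant - cfg.cardiac_freq) < 0.05
        assert np.all(in_slow | near_cardiac)
        # both regions actually carry power
        assert np.any(significant <= hi) and np.any(near_cardiac)

    @pytest.mark.parametrize("g", [1.0, -1.0, 0.5])
    def test_coupling_sign_matches_gain(self, g):
        cfg = SimulationConfig(seed=8, duration_min=30,
                               autoregulation_gain=g, noise_sd={})
        rec = simulate_waveforms(cfg)
        frame = int(cfg.sampling_rate * 10)
        n = rec.n_samples // frame * frame
        abp = rec.channels["ABP"][:n].reshape(-1, frame).mean(axis=1)
        icp = rec.channels["ICP"][:n].reshape(-1, frame).mean(axis=1)
        r = np.corrcoef(abp, icp)[0, 1]
        assert np.sign(r) == np.sign(g)
        assert abs(r) > 0.9

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(duration_min=-1).validate()
        with pytest.raises(ValueError):
            SimulationConfig(sampling_rate=0).validate()
        with pytest.raises(ValueError):
            SimulationConfig(slow_wave_band=(0.005, 2.0)).validate()
        with pytest.raises(ValueError):
            SimulationConfig(autoregulation_gain=1.5).validate()

    def test_declared_gaps_written_as_missing(self):
        cfg = SimulationConfig(seed=2, duration_min=10,
                               gap_spec=((3, 2),))
        rec = simulate_waveforms(cfg)
        fs = cfg.sampling_rate
        sl = slice(int(3 * 60 * fs), int(5 * 60 * fs))
        for ch in rec.channels.values():
            assert np.isnan(ch[sl]).all()
            assert not np.isnan(np.delete(ch, np.arange(sl.start, sl.stop))).any()


class TestSimulateArimaSeries:
    def test_white_noise_variance_approaches_sigma_squared(self):
        x = simulate_arima_series(0, 0, 0, (), (), 2.0, 20000, seed=4)
        assert np.var(x) == pytest.approx(4.0, rel=0.05)

    def test_random_walk_first_difference_is_iid(self):
        x = simulate_arima_series(0, 1, 0, (), (), 1.0, 5000, seed=4)
        dx = np.diff(x)
        from statsmodels.tsa.stattools import acf
        assert abs(acf(dx, nlags=1)[1]) < 0.05

    def test_ar1_lag_one_autocorrelation_recovers_phi(self):
        x = simulate_arima_series(1, 0, 0, (0.8,), (), 1.0, 5000, seed=1)
        from statsmodels.tsa.stattools import acf
        assert acf(x, nlags=1)[1] == pytest.approx(0.8, abs=0.05)

    def test_nonstationary_ar_rejected(self):
        with pytest.raises(ValueError, match="non-stationary"):
            simulate_arima_series(1, 0, 0, (1.01,), (), 1.0, 100, seed=0)

    def test_noninvertible_ma_rejected(self):
        with pytest.raises(ValueError, match="non-invertible"):
            simulate_arima_series(0, 0, 1, (), (1.5,), 1.0, 100, seed=0)


class TestSimulateCohort:
    def test_male_fraction_within_binomial_bounds(self):
        cfg = SimulationConfig(seed=42, n_patients=100, duration_min=1)
        _, metas = simulate_cohort(cfg)
        male = sum(m.sex == "M" for m in metas)
        # binomial 95% bounds around 0.78 at n = 100
        lo, hi = stats.binom.ppf([0.025, 0.975], 100, 0.78)
        assert lo <= male <= hi

    def test_null_construction_gives_identical_parameters(self):
        cfg = SimulationConfig(seed=1, n_patients=4, duration_min=1)
        assert cfg.subgroup_effects == {}
        # no effects: patient config equals cohort config for everyone
        from cvrarima.synthetic import _patient_config, simulate_metadata
        for meta in simulate_metadata(cfg):
            assert _patient_config(cfg, meta) == cfg

    def test_subgroup_effect_applies_only_to_matching_level(self):
        cfg = SimulationConfig(
            seed=1, n_patients=30, duration_min=1,
            subgroup_effects={"marshall_group=>=5": {"noise_sd_scale": 1.5}})
        from cvrarima.synthetic import _patient_config, simulate_metadata
        for meta in simulate_metadata(cfg):
            pc = _patient_config(cfg, meta)
            factor = 1.5 if meta.marshall >= 5 else 1.0
            assert pc.noise_sd["ICP"] == pytest.approx(
                cfg.noise_sd["ICP"] * factor)

    def test_unknown_effect_level_rejected(self):
        with pytest.raises(ValueError, match="unknown covariate"):
            SimulationConfig(
                subgroup_effects={"marshall_group=7": {"slow_wave_amp": 1}}
            ).validate()

    def test_metadata_frame_has_dichotomized_groupings(self):
        cfg = SimulationConfig(seed=9, n_patients=20, duration_min=1)
        _, metas = simulate_cohort(cfg)
        df = metadata_frame(metas)
        assert set(df["marshall_group"]) <= {"<5", ">=5"}
        assert set(df["age_group"]) <= {"<40", ">=40"}
        assert ((df["marshall"] >= 5) == (df["marshall_group"] == ">=5")).all()


class TestInjectGaps:
    def test_single_run_count(self):
        out = inject_gaps(np.arange(20.0), [(10, 3)])
        assert np.isnan(out).sum() == 3
        assert np.isnan(out[10:13]).all()

    def test_empty_spec_is_identity(self):
        x = pd.Series(np.arange(5.0))
        pd.testing.assert_series_equal(inject_gaps(x, []), x)

    def test_total_missing_adds_up(self):
        out = inject_gaps(np.arange(30.0), [(2, 2), (10, 7)])
        assert np.isnan(out).sum() == 9

    def test_overlapping_runs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            inject_gaps(np.arange(20.0), [(2, 5), (4, 3)])

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            inject_gaps(np.arange(10.0), [(8, 5)])
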