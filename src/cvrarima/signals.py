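"""Waveform-to-index derivation.

Turns high-frequency waveform records into the canonical minute-by-minute
table of raw means and cerebrovascular-reactivity (CVR) indices:

* 10-s non-overlapping frame means of ABP (-> MAP), ICP, rSO2 and PbtO2,
  emphasizing the slow vasogenic oscillations tied to autoregulation;
* AMP, the cardiac pulse amplitude of ICP, from a discrete Fourier
  transform of each 10-s frame (amplitude of the dominant component in a
  configurable cardiac band, 0.66-3 Hz ~ 40-180 bpm by default);
* CPP = MAP - ICP;
* moving Pearson correlations over 30 consecutive 10-s means, updated
  every minute: PRx (ICP~MAP), PAx (AMP~MAP), RAC (AMP~CPP), RAP
  (AMP~ICP), COx (rSO2~CPP) and COx-a (rSO2~ABP) per hemisphere.

Conventions: half-open frames [t, t+10); index windows are right-aligned
(the value stamped at minute t uses the 300 s ending at t); any NaN inside
a frame or window propagates to NaN rather than shrinking the effective n.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import WaveformRecord

__all__ = [
    "ten_second_means",
    "compute_amp",
    "compute_cpp",
    "moving_correlation",
    "derive_indices",
    "MINUTE_COLUMNS",
    "INDEX_PAIRS",
    "CARDIAC_BAND",
]

FRAME_SECONDS = 10
FRAMES_PER_MINUTE = 6
WINDOW_FRAMES = 30          # 30 x 10 s = 5 min correlation window
CARDIAC_BAND = (0.66, 3.0)  # Hz

#: Canonical column order of the minute table.
MINUTE_COLUMNS = [
    "MAP", "ICP", "CPP", "AMP",
    "PRx", "PAx", "RAC", "RAP",
    "COx_L", "COx_R", "COx-a_L", "COx-a_R",
    "rSO2_L", "rSO2_R", "PbtO2",
]

#: index name -> (x channel, y channel) of the moving correlation, both on
#: the 10-s grid.
INDEX_PAIRS = {
    "PRx": ("ICP", "MAP"),
    "PAx": ("AMP", "MAP"),
    "RAC": ("AMP", "CPP"),
    "RAP": ("AMP", "ICP"),
    "COx_L": ("rSO2_L", "CPP"),
    "COx_R": ("rSO2_R", "CPP"),
    "COx-a_L": ("rSO2_L", "MAP"),
    "COx-a_R": ("rSO2_R", "MAP"),
}

# 10-s mean column produced from each waveform channel
_MEAN_NAMES = {"ABP": "MAP", "ICP": "ICP", "rSO2_L": "rSO2_L",
               "rSO2_R": "rSO2_R", "PbtO2": "PbtO2"}


def _frame_view(x: np.ndarray, frame: int) -> np.ndarray:
    n_frames = len(x) // frame
    return x[: n_frames * frame].reshape(n_frames, frame)


def ten_second_means(waveform: WaveformRecord) -> pd.DataFrame:
    """Non-overlapping 10-s frame means of every channel, plus AMP and CPP.

    Each output value is the arithmetic mean of the samples in its
    half-open frame [t, t+10); a frame containing any missing sample is
    NaN. The trailing partial frame is dropped.
    """
    frame = int(round(waveform.sampling_rate * FRAME_SECONDS))
    if frame < 1:
        raise ValueError("sampling_rate too low: fewer than 1 sample per 10-s frame")
    out: dict[str, np.ndarray] = {}
    for ch, samples in waveform.channels.items():
        name = _MEAN_NAMES.get(ch, ch)
        out[name] = _frame_view(np.asarray(samples, float), frame).mean(axis=1)
    if "ICP" in waveform.channels:
        out["AMP"] = compute_amp(waveform.channels["ICP"], waveform.sampling_rate)
    if "MAP" in out and "ICP" in out:
        out["CPP"] = compute_cpp(out["MAP"], out["ICP"])
    n_frames = min(len(v) for v in out.values()) if out else 0
    index = waveform.t0 + pd.to_timedelta(
        np.arange(n_frames) * FRAME_SECONDS, unit="s")
    return pd.DataFrame({k: v[:n_frames] for k, v in out.items()}, index=index)


def compute_amp(icp_waveform: np.ndarray, sampling_rate: float,
                cardiac_band: tuple[float, float] = CARDIAC_BAND) -> np.ndarray:
    """Cardiac pulse amplitude of ICP per 10-s frame.

    Each frame is demeaned and Fourier transformed; AMP is the sinusoidal
    amplitude ``2 |X_k| / N`` of the largest spectral component inside
    ``cardiac_band``, so a pure sinusoid of amplitude A yields AMP = A.
    Frames with missing samples give NaN.
    """
    fs = float(sampling_rate)
    frame = int(round(fs * FRAME_SECONDS))
    lo, hi = cardiac_band
    if not (0 < lo < hi <= fs / 2):
        raise ValueError("cardiac_band must lie within (0, Nyquist]")
    freqs = np.fft.rfftfreq(frame, d=1.0 / fs)
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any():
        raise ValueError("cardiac_band contains no DFT bins at this frame length")
    frames = _frame_view(np.asarray(icp_waveform, float), frame)
    amp = np.full(len(frames), np.nan)
    ok = ~np.isnan(frames).any(axis=1)
    if ok.any():
        demeaned = frames[ok] - frames[ok].mean(axis=1, keepdims=True)
        spectra = np.abs(np.fft.rfft(demeaned, axis=1))
        amp[ok] = 2.0 * spectra[:, band].max(axis=1) / frame
    return amp


def compute_cpp(map_series, icp_series):
    """Cerebral perfusion pressure: CPP = MAP - ICP, NaN-propagating."""
    if isinstance(map_series, pd.Series) and isinstance(icp_series, pd.Series):
        if not map_series.index.equals(icp_series.index):
            raise ValueError("MAP and ICP grids are misaligned")
        return map_series - icp_series
    map_a, icp_a = np.asarray(map_series, float), np.asarray(icp_series, float)
    if map_a.shape != icp_a.shape:
        raise ValueError("MAP and ICP grids are misaligned")
    return map_a - icp_a


def moving_correlation(x, y, window_samples: int = WINDOW_FRAMES,
                       update_samples: int = FRAMES_PER_MINUTE) -> np.ndarray:
    """Right-aligned moving Pearson correlation on the 10-s grid.

    Emits one value per ``update_samples`` step, each the correlation of
    the most recent ``window_samples`` paired values. Windows containing
    any NaN, or with zero variance in either input, give NaN. Output is
    clipped to [-1, 1] against floating-point overshoot.
    """
    if update_samples <= 0:
        raise ValueError("update_samples must be positive")
    if window_samples < 3:
        raise ValueError("window_samples must be >= 3")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y grids are misaligned")
    n = len(x)
    if n < window_samples:
        return np.empty(0)
    xv = np.lib.stride_tricks.sliding_window_view(x, window_samples)
    yv = np.lib.stride_tricks.sliding_window_view(y, window_samples)
    # right-aligned windows ending at sample (window-1), (window-1+step), ...
    ends = np.arange(window_samples - 1, n, update_samples)
    xv = xv[ends - window_samples + 1]
    yv = yv[ends - window_samples + 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        xm = xv - xv.mean(axis=1, keepdims=True)
        ym = yv - yv.mean(axis=1, keepdims=True)
        denom = np.sqrt((xm ** 2).sum(axis=1) * (ym ** 2).sum(axis=1))
        r = (xm * ym).sum(axis=1) / denom
    r[denom == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def derive_indices(tens: pd.DataFrame) -> pd.DataFrame:
    """Reduce a 10-s table to the minute-by-minute table of means and indices.

    Raw signals (MAP, ICP, CPP, AMP, rSO2, PbtO2) become the mean of the
    six 10-s means in each minute. Each CVR index is the moving Pearson
    correlation of its channel pair over 30 consecutive 10-s means,
    stamped at the end of each minute (so the first four minutes are NaN).
    An index is emitted only when both channels of its pair exist; with
    partial monitoring (e.g. no rSO2) the corresponding columns are NaN.
    """
    n_frames = len(tens)
    n_min = n_frames // FRAMES_PER_MINUTE
    index = tens.index[0] + pd.to_timedelta(
        (np.arange(n_min) + 1) * 60, unit="s")
    out = pd.DataFrame(index=index, columns=MINUTE_COLUMNS, dtype=float)

    for col in tens.columns:
        vals = tens[col].to_numpy()[: n_min * FRAMES_PER_MINUTE]
        out[col] = vals.reshape(n_min, FRAMES_PER_MINUTE).mean(axis=1)

    for name, (xc, yc) in INDEX_PAIRS.items():
        if xc not in tens.columns or yc not in tens.columns:
            continue
        r = moving_correlation(tens[xc].to_numpy(), tens[yc].to_numpy())
        # window of 30 frames first completes at the end of minute 5
        first_minute = WINDOW_FRAMES // FRAMES_PER_MINUTE
        col = np.full(n_min, np.nan)
        n_fit = min(len(r), n_min - (first_minute - 1))
        col[first_minute - 1: first_minute - 1 + n_fit] = r[:n_fit]
        out[name] = col
    return out
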