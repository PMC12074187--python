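"""Seeded synthetic cohort generator.

Produces pulsatile arterial/intracranial pressure waveforms with slow
vasogenic oscillations, NIRS and brain-tissue-oxygen channels, per-patient
clinical covariates, and pure ARIMA test series with known ground truth.
The generator is the stand-in dataset for a multi-centre TBI neuromonitoring
cohort whose real recordings are not publicly available: every downstream
operator in this package is validated against the known structure injected
here.

The waveform model is deliberately a sum-of-sinusoids-plus-noise
abstraction, not a hemodynamic ODE. The quantity of interest downstream is
statistical structure (moving correlations, autocorrelation, stationarity),
and that structure is fully controlled by three ingredients:

* a cardiac sinusoid at ``cardiac_freq`` (pulse pressure),
* a band-limited slow-wave process ``s(t)`` confined to
  ``slow_wave_band`` (vasogenic oscillations, 0.005-0.05 Hz by default),
* an autoregulation coupling gain ``g`` in [-1, 1] that transmits the
  arterial slow wave into ICP: ``+1`` is fully pressure-passive
  (PRx -> +1 downstream), ``-1`` is active counter-regulation
  (PRx -> -1), ``0`` decouples the two.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.tsa.arima_process import ArmaProcess

__all__ = [
    "SimulationConfig",
    "PatientMeta",
    "WaveformRecord",
    "simulate_waveforms",
    "simulate_arima_series",
    "simulate_cohort",
    "simulate_metadata",
    "inject_gaps",
    "metadata_frame",
    "COVARIATE_LEVELS",
]

#: Default marginal covariate frequencies, mirroring the demographics of a
#: large multi-centre moderate-to-severe TBI cohort (78% male, ~50%
#: bilateral reactive pupils, ~30% Marshall V-VI, ...).
DEFAULT_MARGINALS = {
    "male": 0.78,
    "hypoxia": 0.265,
    "hypotension": 0.151,
    # bilateral reactive / unilateral unreactive / bilateral unreactive
    "pupils": (0.515, 0.176, 0.309),
    # Marshall CT class II..VI
    "marshall": (0.294, 0.126, 0.250, 0.165, 0.165),
}

PUPIL_LEVELS = (
    "bilateral reactive",
    "unilateral unreactive",
    "bilateral unreactive",
)

COVARIATE_LEVELS = {
    "sex": ("M", "F"),
    "age_group": ("<40", ">=40"),
    "hypoxia": ("yes", "no"),
    "hypotension": ("yes", "no"),
    "pupils": PUPIL_LEVELS,
    "marshall_group": ("<5", ">=5"),
}

#: Config fields that subgroup effects may offset additively.
_OFFSETTABLE = {
    "map_baseline",
    "icp_baseline",
    "cardiac_amp_abp",
    "cardiac_amp_icp",
    "slow_wave_amp",
    "autoregulation_gain",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic cohort.

    Identical configs (including ``seed``) produce bit-identical output.
    """

    seed: int = 0
    n_patients: int = 1
    duration_min: float = 180.0
    sampling_rate: float = 50.0          # Hz
    map_baseline: float = 86.9           # mmHg, cohort-typical mean MAP
    icp_baseline: float = 11.9           # mmHg, cohort-typical mean ICP
    cardiac_freq: float = 1.2            # Hz (72 bpm)
    cardiac_amp_abp: float = 20.0        # mmHg (half the pulse pressure)
    cardiac_amp_icp: float = 2.0         # mmHg
    slow_wave_band: tuple[float, float] = (0.005, 0.05)  # Hz
    slow_wave_amp: float = 5.0           # mmHg
    autoregulation_gain: float = 0.3     # g in [-1, 1]
    icp_attenuation: float = 0.5         # kappa: slow-wave transmission into ICP
    rso2_baseline: float = 70.0          # %
    rso2_gain: float = 0.1               # |h|; sign follows sign(g)
    pbto2_baseline: float = 25.0         # mmHg
    pbto2_drift_sd: float = 0.02         # mmHg per sqrt(s) random drift
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"ABP": 1.0, "ICP": 0.5, "rSO2": 0.3, "PbtO2": 0.5}
    )
    n_slow_components: int = 8
    gap_spec: tuple[tuple[int, int], ...] = ()   # (start minute, run minutes)
    subgroup_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.duration_min <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration_min and sampling_rate must be positive")
        if self.sampling_rate < 4 * self.cardiac_freq:
            raise ValueError(
                "sampling_rate must be >= 4 x cardiac_freq to resolve the "
                "cardiac harmonic"
            )
        lo, hi = self.slow_wave_band
        if not (0 < lo < hi < self.cardiac_freq):
            raise ValueError("slow_wave_band must lie inside (0, cardiac_freq)")
        if abs(self.autoregulation_gain) > 1:
            raise ValueError("autoregulation_gain must be in [-1, 1]")
        for name in ("cardiac_amp_abp", "cardiac_amp_icp", "slow_wave_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise_sd values must be >= 0")
        for key, offsets in self.subgroup_effects.items():
            cov, _, level = key.partition("=")
            if cov not in COVARIATE_LEVELS or level not in COVARIATE_LEVELS[cov]:
                raise ValueError(f"unknown covariate level in subgroup_effects: {key!r}")
            for pname in offsets:
                if pname != "noise_sd_scale" and pname not in _OFFSETTABLE:
                    raise ValueError(f"unknown parameter in subgroup_effects: {pname!r}")

    def with_offsets(self, offsets: Mapping[str, float]) -> "SimulationConfig":
        """Return a copy with additive offsets (and ``noise_sd_scale``) applied."""
        changes: dict = {}
        for pname, value in offsets.items():
            if pname == "noise_sd_scale":
                changes["noise_sd"] = {
                    k: v * value for k, v in self.noise_sd.items()
                }
            else:
                changes[pname] = getattr(self, pname) + value
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class PatientMeta:
    """Clinical covariates for one synthetic patient."""

    patient_id: str
    age: float
    sex: str                 # M / F
    hypoxia: str             # yes / no
    hypotension: str         # yes / no
    pupils: str              # one of PUPIL_LEVELS
    marshall: int            # Marshall CT class, 2..6

    @property
    def age_group(self) -> str:
        return ">=40" if self.age >= 40 else "<40"

    @property
    def marshall_group(self) -> str:
        return ">=5" if self.marshall >= 5 else "<5"

    def level(self, covariate: str) -> str:
        if covariate == "sex":
            return self.sex
        if covariate == "age_group":
            return self.age_group
        if covariate == "marshall_group":
            return self.marshall_group
        return getattr(self, covariate)


@dataclass
class WaveformRecord:
    """High-frequency multichannel samples for one patient.

    All present channels share one sampling grid; NaN appears only inside
    declared gap runs.
    """

    patient_id: str
    channels: dict[str, np.ndarray]
    sampling_rate: float
    t0: pd.Timestamp = pd.Timestamp("2024-01-01T00:00:00")

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    def times(self) -> pd.DatetimeIndex:
        secs = np.arange(self.n_samples) / self.sampling_rate
        return self.t0 + pd.to_timedelta(secs, unit="s")


def _slow_wave(rng: np.random.Generator, t: np.ndarray,
               band: tuple[float, float], amp: float, k: int) -> np.ndarray:
    """Random-phase sum of k sinusoids with frequencies inside ``band``.

    Component amplitudes are ``amp / sqrt(k)`` so the process RMS matches a
    single sinusoid of amplitude ``amp``.
    """
    freqs = rng.uniform(band[0], band[1], size=k)
    phases = rng.uniform(0, 2 * np.pi, size=k)
    a = amp / np.sqrt(k)
    s = np.zeros_like(t)
    for f, ph in zip(freqs, phases):
        s += a * np.sin(2 * np.pi * f * t + ph)
    return s


def simulate_waveforms(config: SimulationConfig,
                       patient_id: str = "sim-001",
                       rng: np.random.Generator | None = None) -> WaveformRecord:
    """Simulate one patient's multichannel waveform record.

    ABP = map_baseline + s(t) + cardiac sinusoid + noise, with s(t) the
    band-limited slow wave; ICP receives ``g * kappa * s(t)`` plus its own
    (independently phased) cardiac sinusoid; rSO2 channels follow the
    slow-wave component of CPP with gain ``rso2_gain * sign(g)``; PbtO2 is
    a slow random drift. Declared gap runs are written as NaN in every
    channel.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    fs = config.sampling_rate
    n = int(round(config.duration_min * 60 * fs))
    t = np.arange(n) / fs
    g = config.autoregulation_gain

    s = _slow_wave(rng, t, config.slow_wave_band, config.slow_wave_amp,
                   config.n_slow_components)
    phase_abp, phase_icp = rng.uniform(0, 2 * np.pi, size=2)

    sd = dict(config.noise_sd)
    noise = lambda key, size: (  # noqa: E731 - local shorthand
        rng.normal(0.0, sd.get(key, 0.0), size) if sd.get(key, 0.0) > 0
        else np.zeros(size)
    )

    abp = (config.map_baseline + s
           + config.cardiac_amp_abp * np.sin(2 * np.pi * config.cardiac_freq * t + phase_abp)
           + noise("ABP", n))
    icp_slow = g * config.icp_attenuation * s
    icp = (config.icp_baseline + icp_slow
           + config.cardiac_amp_icp * np.sin(2 * np.pi * config.cardiac_freq * t + phase_icp)
           + noise("ICP", n))

    h = config.rso2_gain * np.sign(g)
    cpp_slow = s - icp_slow
    rso2_l = config.rso2_baseline + h * cpp_slow + noise("rSO2", n)
    rso2_r = config.rso2_baseline + h * cpp_slow + noise("rSO2", n)

    drift = np.cumsum(rng.normal(0.0, config.pbto2_drift_sd / np.sqrt(fs), n))
    pbto2 = config.pbto2_baseline + drift + noise("PbtO2", n)

    channels = {
        "ABP": abp, "ICP": icp,
        "rSO2_L": rso2_l, "rSO2_R": rso2_r,
        "PbtO2": pbto2,
    }
    for start_min, run_min in config.gap_spec:
        i0 = int(round(start_min * 60 * fs))
        i1 = int(round((start_min + run_min) * 60 * fs))
        if i0 < 0 or i1 > n:
            raise ValueError(f"gap run ({start_min}, {run_min}) outside record")
        for arr in channels.values():
            arr[i0:i1] = np.nan

    return WaveformRecord(patient_id=patient_id, channels=channels,
                          sampling_rate=fs)


def simulate_arima_series(p: int, d: int, q: int,
                          ar_coeffs: Sequence[float] = (),
                          ma_coeffs: Sequence[float] = (),
                          innovation_sd: float = 1.0,
                          n: int = 1000,
                          seed: int | np.random.Generator = 0) -> np.ndarray:
    """Generate a series whose d-th difference follows the given ARMA model.

    ``ar_coeffs`` / ``ma_coeffs`` are the phi / theta coefficients of the
    recursion (not the sign-flipped polynomial convention). A burn-in of
    ``max(20, 10 * (p + q))`` samples is discarded before integrating.
    """
    ar_coeffs = tuple(ar_coeffs)
    ma_coeffs = tuple(ma_coeffs)
    if len(ar_coeffs) != p or len(ma_coeffs) != q:
        raise ValueError("coefficient vectors must have lengths p and q")
    if n <= p + q + d:
        raise ValueError("n must exceed p + q + d")
    proc = ArmaProcess(np.r_[1, -np.asarray(ar_coeffs)],
                       np.r_[1, np.asarray(ma_coeffs)])
    if not proc.isstationary:
        raise ValueError("AR coefficients define a non-stationary polynomial")
    if not proc.isinvertible:
        raise ValueError("MA coefficients define a non-invertible polynomial")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    burn = max(20, 10 * (p + q))
    x = proc.generate_sample(nsample=n + burn, scale=innovation_sd,
                             distrvs=rng.standard_normal)[burn:]
    for _ in range(d):
        x = np.cumsum(x)
    return x


def simulate_metadata(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> list[PatientMeta]:
    """Draw per-patient covariates from the default marginal frequencies."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    metas = []
    for i in range(config.n_patients):
        pid = f"patient_{i + 1:03d}"
        sex = "M" if rng.random() < DEFAULT_MARGINALS["male"] else "F"
        # log-normal age: median ~38 y, IQR ~ (26, 55)
        age = float(np.clip(np.exp(rng.normal(np.log(38.0), 0.55)), 16, 90))
        hypoxia = "yes" if rng.random() < DEFAULT_MARGINALS["hypoxia"] else "no"
        hypotension = "yes" if rng.random() < DEFAULT_MARGINALS["hypotension"] else "no"
        pupils = PUPIL_LEVELS[rng.choice(3, p=np.asarray(DEFAULT_MARGINALS["pupils"]))]
        marshall = int(2 + rng.choice(5, p=np.asarray(DEFAULT_MARGINALS["marshall"])))
        metas.append(PatientMeta(pid, age, sex, hypoxia, hypotension, pupils, marshall))
    return metas


def _patient_config(config: SimulationConfig, meta: PatientMeta) -> SimulationConfig:
    cfg = config
    for key, offsets in config.subgroup_effects.items():
        cov, _, level = key.partition("=")
        if meta.level(cov) == level:
            cfg = cfg.with_offsets(offsets)
    return cfg


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[list[WaveformRecord], list[PatientMeta]]:
    """Simulate a full cohort: covariates first, then one record per patient.

    When ``subgroup_effects`` is given, patients whose covariate level
    matches receive the stated parameter offsets, so downstream subgroup
    tests have a known ground truth.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.n_patients + 1)
    metas = simulate_metadata(config, np.random.default_rng(child_seeds[0]))
    records = []
    for meta, child in zip(metas, child_seeds[1:]):
        cfg = _patient_config(config, meta)
        records.append(
            simulate_waveforms(cfg, meta.patient_id, np.random.default_rng(child))
        )
    return records, metas


def inject_gaps(series: pd.Series | np.ndarray,
                gap_spec: Sequence[tuple[int, int]]):
    """Set the requested runs (start index, run length) to NaN.

    Runs must lie within bounds and must not overlap; all other values are
    returned untouched.
    """
    values = pd.Series(series, dtype=float, copy=True)
    seen: set[int] = set()
    for start, length in gap_spec:
        if start < 0 or start + length > len(values):
            raise ValueError(f"gap run ({start}, {length}) out of bounds")
        idx = set(range(start, start + length))
        if idx & seen:
            raise ValueError("overlapping gap runs")
        seen |= idx
    positions = sorted(seen)
    values.iloc[positions] = np.nan
    if isinstance(series, np.ndarray):
        return values.to_numpy()
    return values


def metadata_frame(metas: Sequence[PatientMeta]) -> pd.DataFrame:
    """Tabulate metadata, including the derived dichotomized groupings."""
    rows = [
        {
            "patient_id": m.patient_id,
            "age": m.age,
            "sex": m.sex,
            "age_group": m.age_group,
            "hypoxia": m.hypoxia,
            "hypotension": m.hypotension,
            "pupils": m.pupils,
            "marshall": m.marshall,
            "marshall_group": m.marshall_group,
        }
        for m in metas
    ]
    return pd.DataFrame(rows)
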