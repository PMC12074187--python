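"""End-to-end pipeline: simulate -> derive -> reduce -> stationarity ->
grid search -> summarize -> subgroup -> forecast.

Each stage writes its tables into a stage-named subdirectory of the
output tree; a ``manifest.json`` records the config, its hash, the seed,
the package version and a SHA-256 per deterministic output file, so a
rerun under the same manifest can be verified byte-for-byte. Wall-time
measurements (inherently non-deterministic) go to ``*_timings.csv``
sidecars that are excluded from the manifest hash set.

Failures in a single patient x signal x resolution cell are logged and
skipped; they never abort the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .arima import (ArimaSpec, grid_search, population_median_models,
                    records_frame, select_optimal)
from .forecast import evaluate_forecasts, evaluations_frame, correlation_vs_spread
from .io import (config_hash, read_minute_csv, sha256_file, write_minute_csv,
                 write_table, write_waveform_csv)
from .resolution import (MIN_POINTS_FIT, MIN_POINTS_TEST, downsample,
                         fill_gaps, segments_of, sufficiency_check)
from .signals import INDEX_PAIRS, derive_indices, ten_second_means
from .stationarity import (cohort_stationarity_table, difference,
                           evaluate_series, results_frame)
from .subgroups import significant_table, subgroup_analysis
from .synthetic import SimulationConfig, metadata_frame, simulate_cohort

log = logging.getLogger("cvrarima")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Run-level configuration and reproducibility contract."""

    mode: str = "simulate"                     # simulate | load
    out_dir: str = "cvrarima_out"
    input_dir: str | None = None               # minute CSVs for load mode
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    resolutions: tuple[int, ...] = (1, 60, 1440)
    p_min: int = 1
    p_max: int = 10
    d_grid: tuple[int, ...] = (0, 1)
    q_max: int = 10
    criterion: str = "aic"
    alpha: float = 0.05
    min_n_test: int = MIN_POINTS_TEST
    min_n_fit: int = MIN_POINTS_FIT
    train_fraction: float = 0.5
    refit_each_step: bool = False
    forecast_signal: str = "ICP"
    workers: int = 1
    save_waveforms: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["noise_sd"] = dict(self.sim.noise_sd)
        d["sim"]["subgroup_effects"] = {
            k: dict(v) for k, v in self.sim.subgroup_effects.items()}
        return d

    @property
    def hash(self) -> str:
        # out_dir and workers cannot change any computed value, so they
        # stay outside the reproducibility fingerprint
        d = self.to_dict()
        d.pop("out_dir")
        d.pop("workers")
        return config_hash(d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        for key in ("slow_wave_band", "gap_spec"):
            if key in sim_raw:
                sim_raw[key] = tuple(
                    tuple(v) if isinstance(v, (list, tuple)) else v
                    for v in sim_raw[key]) if key == "gap_spec" else tuple(sim_raw[key])
        for key in ("resolutions", "d_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sim=SimulationConfig(**sim_raw), **raw)


def _reduce_signal(series_1min: pd.Series, resolution: int,
                   ) -> list[pd.Series]:
    """Gap rule at 1 min, then per-segment non-overlapping block means."""
    segs = segments_of(fill_gaps(series_1min))
    if resolution == 1:
        return segs
    out = []
    for seg in segs:
        ds = downsample(seg, resolution, source_resolution=1)
        if len(ds):
            out.append(ds)
    return out


def _longest(segments: list[pd.Series]) -> pd.Series:
    if not segments:
        return pd.Series(dtype=float)
    return max(segments, key=len)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash, seed = config.hash, config.sim.seed
    tracked: list[Path] = []
    untracked: list[Path] = []

    # -- simulate / load ---------------------------------------------------
    if config.mode == "simulate":
        records, metas = simulate_cohort(config.sim)
        meta_df = metadata_frame(metas)
        tracked.append(write_table(meta_df, out / "simulate" / "metadata.csv",
                                   "simulate", chash, seed))
        if config.save_waveforms:
            for rec in records:
                tracked.append(write_waveform_csv(
                    rec, out / "simulate" / f"{rec.patient_id}_waveform.csv",
                    chash, seed))
        minute_tables = {
            rec.patient_id: derive_indices(ten_second_means(rec))
            for rec in records
        }
    elif config.mode == "load":
        if not config.input_dir:
            raise ValueError("load mode requires input_dir")
        in_dir = Path(config.input_dir)
        if not in_dir.is_dir():
            raise ValueError(f"unreadable input directory: {in_dir}")
        minute_tables = {}
        for path in sorted(in_dir.glob("*.csv")):
            if path.name == "metadata.csv":
                continue
            minute_tables[path.stem] = read_minute_csv(path)
        if not minute_tables:
            raise ValueError(f"no minute CSVs found in {in_dir}")
        meta_path = in_dir / "metadata.csv"
        meta_df = (pd.read_csv(meta_path, comment="#")
                   if meta_path.exists() else pd.DataFrame())
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    # -- derive ------------------------------------------------------------
    for pid, table in minute_tables.items():
        missing = [c for c in table.columns if table[c].isna().all()]
        for name, (xc, yc) in INDEX_PAIRS.items():
            if name in missing:
                log.info("patient %s: index %s unavailable (needs %s/%s)",
                         pid, name, xc, yc)
        tracked.append(write_minute_csv(
            table, out / "derive" / f"{pid}.csv", "derive", chash, seed))

    # -- reduce ------------------------------------------------------------
    # reduced[(pid, resolution)][signal] -> list of segment Series
    reduced: dict[tuple[str, int], dict[str, list[pd.Series]]] = {}
    for pid, table in minute_tables.items():
        for res in config.resolutions:
            by_signal = {}
            rows = []
            for signal in table.columns:
                try:
                    segs = _reduce_signal(table[signal], res)
                except Exception:           # pragma: no cover - cell isolation
                    log.exception("reduce failed: %s %s %s", pid, signal, res)
                    segs = []
                by_signal[signal] = segs
                for sid, seg in enumerate(segs):
                    for ts, val in seg.items():
                        rows.append({"timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S"),
                                     "signal": signal, "value": val,
                                     "segment_id": sid})
            reduced[(pid, res)] = by_signal
            tracked.append(write_table(
                pd.DataFrame(rows), out / "reduce" / f"res_{res:04d}" / f"{pid}.csv",
                "reduce", chash, seed))

    # -- stationarity ------------------------------------------------------
    stat_results = []
    for (pid, res), by_signal in reduced.items():
        for signal, segs in by_signal.items():
            series = _longest(segs)
            try:
                raw = evaluate_series(series, pid, signal, res, stage=0,
                                      alpha=config.alpha,
                                      min_points=config.min_n_test)
                stat_results.append(raw)
                if len(series) > 1:
                    diff = difference(series, 1)
                    stat_results.append(
                        evaluate_series(diff, pid, signal, res, stage=1,
                                        alpha=config.alpha,
                                        min_points=config.min_n_test))
            except Exception:               # pragma: no cover - cell isolation
                log.exception("stationarity failed: %s %s %s", pid, signal, res)
    stat_df = results_frame(stat_results)
    tracked.append(write_table(stat_df, out / "stationarity" / "results.csv",
                               "stationarity", chash, seed))
    for stage_name in ("raw", "differenced"):
        sub = stat_df[stat_df["stage"] == stage_name] if not stat_df.empty else stat_df
        tracked.append(write_table(
            cohort_stationarity_table(sub),
            out / "stationarity" / f"cohort_{stage_name}.csv",
            "stationarity", chash, seed))

    # -- grid search -------------------------------------------------------
    grid_frames = []
    for (pid, res), by_signal in reduced.items():
        for signal, segs in by_signal.items():
            series = _longest(segs)
            if not sufficiency_check(series, config.min_n_fit):
                continue
            try:
                pre = difference(series.to_numpy(), 1)
                recs = grid_search(
                    pre, range(config.p_min, config.p_max + 1),
                    config.d_grid, range(0, config.q_max + 1),
                    pre_diff=1, workers=config.workers,
                    patient_id=pid, signal=signal, resolution=res)
                grid_frames.append(records_frame(recs))
            except Exception:               # pragma: no cover - cell isolation
                log.exception("grid search failed: %s %s %s", pid, signal, res)
    grid_df = (pd.concat(grid_frames, ignore_index=True)
               if grid_frames else records_frame([]))
    for (pid, res), grp in (grid_df.groupby(["patient_id", "resolution"])
                            if not grid_df.empty else []):
        base = out / "gridsearch" / f"res_{res:04d}"
        tracked.append(write_table(
            grp.drop(columns=["fit_seconds"]), base / f"{pid}.csv",
            "gridsearch", chash, seed))
        untracked.append(write_table(
            grp[["signal", "p", "d", "q", "fit_seconds"]],
            base / f"{pid}_timings.csv", "gridsearch", chash, seed))

    # -- summarize ---------------------------------------------------------
    optima_rows = []
    if not grid_df.empty:
        for (pid, signal, res), grp in grid_df.groupby(
                ["patient_id", "signal", "resolution"], sort=True):
            row = {"patient_id": pid, "signal": signal, "resolution": res}
            ok = grp[grp["converged"]]
            if ok.empty:
                continue
            for crit in ("aic", "bic", "ll"):
                best = (ok.assign(pq=ok["p"] + ok["q"])
                          .sort_values([crit, "pq", "p"],
                                       ascending=[crit != "ll", True, True])
                          .iloc[0])
                row[crit] = best[crit]
                row[f"{crit}_p"] = int(best["p"])
                row[f"{crit}_total_d"] = int(best["total_d"])
                row[f"{crit}_q"] = int(best["q"])
            row["p"] = row[f"{config.criterion}_p"]
            row["total_d"] = row[f"{config.criterion}_total_d"]
            row["q"] = row[f"{config.criterion}_q"]
            optima_rows.append(row)
    optima_df = pd.DataFrame(optima_rows)
    tracked.append(write_table(optima_df, out / "summarize" / "optima.csv",
                               "summarize", chash, seed))
    if not optima_df.empty:
        tracked.append(write_table(
            population_median_models(optima_df, config.criterion),
            out / "summarize" / "median_models.csv", "summarize", chash, seed))

    # -- subgroup ----------------------------------------------------------
    if not optima_df.empty and not meta_df.empty:
        sub_frames = []
        for res in config.resolutions:
            res_opt = optima_df[optima_df["resolution"] == res]
            if res_opt.empty:
                continue
            frame = subgroup_analysis(res_opt, meta_df, alpha=config.alpha)
            if not frame.empty:
                frame.insert(0, "resolution", res)
                sub_frames.append(frame)
        if sub_frames:
            sub_df = pd.concat(sub_frames, ignore_index=True)
            tracked.append(write_table(sub_df, out / "subgroup" / "results.csv",
                                       "subgroup", chash, seed))
            tracked.append(write_table(
                significant_table(sub_df.drop(columns=["resolution"])),
                out / "subgroup" / "significant.csv", "subgroup", chash, seed))

    # -- forecast ----------------------------------------------------------
    evaluations = []
    if not optima_df.empty:
        res1 = optima_df[(optima_df["resolution"] == 1)
                         & (optima_df["signal"] == config.forecast_signal)]
        for _, row in res1.iterrows():
            pid = row["patient_id"]
            series = _longest(reduced[(pid, 1)].get(config.forecast_signal, []))
            spec = ArimaSpec(p=int(row["p"]), d=int(row["total_d"]),
                             q=int(row["q"]))
            try:
                evaluations.append(evaluate_forecasts(
                    series.to_numpy(), spec, patient_id=pid,
                    signal=config.forecast_signal,
                    train_fraction=config.train_fraction,
                    refit_each_step=config.refit_each_step))
            except Exception:               # pragma: no cover - cell isolation
                log.exception("forecast failed: %s", pid)
    if evaluations:
        tracked.append(write_table(
            evaluations_frame(evaluations), out / "forecast" / "agreement.csv",
            "forecast", chash, seed))
        tracked.append(write_table(
            correlation_vs_spread(evaluations),
            out / "forecast" / "correlation_vs_spread.csv",
            "forecast", chash, seed))

    # -- manifest ----------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "config_hash": chash,
        "seed": seed,
        "version": __version__,
        "outputs": {
            str(p.relative_to(out)): sha256_file(p) for p in sorted(tracked)
        },
        "non_deterministic_outputs": sorted(
            str(p.relative_to(out)) for p in untracked),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return manifest
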