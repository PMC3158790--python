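"""Readers, writers, run configuration and the full-night pipeline.

Tabular formats are header-first delimited text (comma or tab,
auto-detected on read).  Times in files are seconds or percent as labelled
by the column name; the core works in percent-of-episode units.  Missing
values are empty cells and survive a write/read round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import spectral
from .cascade import TransitionProbabilities, Trajectory
from .cohort import SubjectEpisodeTable
from .fitting import FitConfig, FitResult, PowerTimeCourse, fit_episode, rebin_normalize
from .flipflop import ActivityTrace, AlignmentReport
from .spectral import EEGRecord, Hypnogram

__all__ = [
    "read_power_timecourse", "write_power_timecourse",
    "read_epoch_power", "write_epoch_power",
    "read_hypnogram", "write_hypnogram",
    "read_activity_trace", "write_activity_trace",
    "read_subject_table", "write_subject_table",
    "write_fit_result", "write_alignment_report",
    "write_trajectory", "read_eeg_text",
    "RunConfig", "PipelineError", "pipeline",
]


def _read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - message formatting only
        raise ValueError(f"malformed table {path}: {exc}") from exc


def read_power_timecourse(path) -> PowerTimeCourse:
    """Read binned band powers: columns time_pct, delta, sigma, beta."""
    frame = _read_table(path)
    required = {"time_pct", "delta", "sigma", "beta"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bands = {band: frame[band].to_numpy(dtype=float)
             for band in ("delta", "sigma", "beta")}
    return PowerTimeCourse(time=frame["time_pct"].to_numpy(dtype=float),
                           bands=bands)


def write_power_timecourse(tc: PowerTimeCourse, path) -> None:
    tc.to_frame().to_csv(path, index=False)


def read_epoch_power(path) -> pd.DataFrame:
    """Read a 4-s epoch power table: columns time_s plus one per band."""
    frame = _read_table(path)
    if "time_s" not in frame.columns:
        raise ValueError(f"{path}: missing time_s column")
    return frame


def write_epoch_power(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def write_hypnogram(hyp: Hypnogram, path) -> None:
    lines = [f"# epoch_s={hyp.epoch_s:g}", f"# lights_off={hyp.lights_off}"]
    if hyp.lights_on is not None:
        lines.append(f"# lights_on={hyp.lights_on}")
    lines.extend(hyp.stages)
    Path(path).write_text("\n".join(lines) + "\n")


def read_hypnogram(path) -> Hypnogram:
    """One stage code per line; header comments carry lights-off/on markers."""
    meta = {"epoch_s": 20.0, "lights_off": 0, "lights_on": None}
    stages: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("#").strip().partition("=")
            key = key.strip()
            if key in meta:
                meta[key] = float(value) if key == "epoch_s" else int(value)
            continue
        if line not in spectral.STAGE_CODES:
            raise ValueError(f"{path}:{lineno}: unknown stage code {line!r}")
        stages.append(line)
    return Hypnogram(stages=tuple(stages), lights_off=int(meta["lights_off"]),
                     lights_on=meta["lights_on"], epoch_s=meta["epoch_s"])


def read_activity_trace(path, bin_width: float | None = None) -> ActivityTrace:
    """Two-column trace (time_s, value); bin width inferred if not given."""
    frame = _read_table(path)
    if not {"time_s", "value"} <= set(frame.columns):
        raise ValueError(f"{path}: need columns time_s, value")
    times = frame["time_s"].to_numpy(dtype=float)
    if bin_width is None:
        if times.size < 2:
            raise ValueError(f"{path}: cannot infer bin width from one row")
        bin_width = float(times[1] - times[0])
    return ActivityTrace(times=times, values=frame["value"].to_numpy(dtype=float),
                         bin_width=bin_width)


def write_activity_trace(trace: ActivityTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "value": trace.values}).to_csv(
        path, index=False)


def read_subject_table(path) -> SubjectEpisodeTable:
    return SubjectEpisodeTable(_read_table(path))


def write_subject_table(table: SubjectEpisodeTable, path) -> None:
    table.frame.to_csv(path, index=False)


def write_fit_result(result: FitResult, path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")


def write_alignment_report(report: AlignmentReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def write_trajectory(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False)


def read_eeg_text(path, label: str = "EEG") -> EEGRecord:
    """Single-column EEG samples with a '# rate=<Hz>' header line."""
    rate = None
    samples: list[float] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("#").strip().partition("=")
            if key.strip() == "rate":
                rate = float(value)
            continue
        try:
            samples.append(float(line))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: not a number: {line!r}") from exc
    if rate is None:
        raise ValueError(f"{path}: missing '# rate=<Hz>' header")
    return EEGRecord(samples=np.asarray(samples), rate=rate, label=label)


_CONFIG_KEYS = {
    "eeg_path", "hypnogram_path", "out_dir", "band_edges",
    "probabilities", "beta_bias", "seed", "log_level", "max_episodes",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full-night pipeline run."""

    eeg_path: str
    hypnogram_path: str
    out_dir: str = "."
    band_edges: dict[str, tuple[float, float]] | None = None
    probabilities: TransitionProbabilities = TransitionProbabilities()
    beta_bias: float = 2.0
    seed: int = 0
    log_level: str = "INFO"
    max_episodes: int = 4

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "probabilities" in raw:
            raw["probabilities"] = TransitionProbabilities.from_vector(
                raw["probabilities"])
        if "band_edges" in raw and raw["band_edges"] is not None:
            raw["band_edges"] = {k: tuple(v) for k, v in raw["band_edges"].items()}
        return cls(**raw)


class PipelineError(RuntimeError):
    """Stage failure with the failing stage's name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def pipeline(config: RunConfig) -> dict:
    """Full-night analysis: spectra -> segmentation -> per-episode fits.

    Returns a machine-readable summary (also written to
    ``<out_dir>/summary.json``) with sleep statistics and one fit per NREM
    episode found.
    """
    import logging

    log = logging.getLogger("ntpsleep.pipeline")
    log.setLevel(config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        record = read_eeg_text(config.eeg_path)
        hyp = read_hypnogram(config.hypnogram_path)
    except Exception as exc:
        raise PipelineError("input", exc) from exc

    try:
        mask = spectral.artefact_mask(record)
        powers = spectral.epoch_band_power(record, bands=config.band_edges,
                                           valid_seconds=mask)
        write_epoch_power(powers, out_dir / "epoch_power.csv")
    except Exception as exc:
        raise PipelineError("spectra", exc) from exc

    try:
        stats = spectral.sleep_statistics(hyp)
        boundaries = spectral.segment_episodes(hyp, config.max_episodes)
    except Exception as exc:
        raise PipelineError("segmentation", exc) from exc

    fits = []
    fit_config = FitConfig(probabilities=config.probabilities,
                           beta_bias=config.beta_bias, seed=config.seed)
    for index, (start_ep, end_ep) in enumerate(boundaries, start=1):
        try:
            t0 = start_ep * hyp.epoch_s
            t1 = (end_ep + 1) * hyp.epoch_s
            sel = (powers["time_s"] >= t0) & (powers["time_s"] < t1)
            sub = powers[sel]
            tc = rebin_normalize(
                sub["time_s"].to_numpy(),
                {band: sub[band].to_numpy() for band in ("delta", "sigma", "beta")},
                episode_start=t0, episode_end=t1)
            result = fit_episode(tc, fit_config)
            write_fit_result(result, out_dir / f"fit_nrem{index}.json")
            fits.append({"nrem": index, **result.to_dict()})
            log.info("NREM %d: overall R^2 = %.1f%% (%s), TA = %d", index,
                     result.r2_overall, result.quality, result.ta_count)
        except Exception as exc:
            raise PipelineError(f"fit_nrem{index}", exc) from exc

    summary = {"sleep_statistics": stats,
               "episodes": [{"nrem": i + 1, "start_epoch": a, "end_epoch": b}
                            for i, (a, b) in enumerate(boundaries)],
               "fits": fits, "seed": config.seed}
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
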