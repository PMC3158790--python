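"""Raw EEG to per-episode band-power series, plus standard sleep statistics.

Power spectra are computed by FFT with a Hanning window on consecutive 4-s
epochs (0.25 Hz resolution at 256 Hz), summed into the delta (1-4 Hz),
sigma (12-15 Hz) and beta (18-25 Hz) bands.  Artefact-containing seconds
are masked and become missing data downstream, preserving time continuity.
NREM episodes are delimited on the hypnogram with the 15-min combining rule
for the end of a REM episode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram

__all__ = [
    "EEGRecord",
    "Hypnogram",
    "EpisodeBoundaries",
    "DEFAULT_BANDS",
    "STAGE_CODES",
    "epoch_band_power",
    "artefact_mask",
    "segment_episodes",
    "sleep_statistics",
]

#: Band edges in Hz.  The beta lower edge is subject-dependent in practice
#: and configurable; 18 Hz is the default.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "sigma": (12.0, 15.0),
    "beta": (18.0, 25.0),
}

STAGE_CODES = frozenset({"W", "R", "1", "2", "3", "4", "M", "U"})
SLEEP_STAGES = frozenset({"1", "2", "3", "4", "R"})

EPOCH_S = 20          # hypnogram scoring epoch, seconds
POWER_EPOCH_S = 4     # spectral analysis epoch, seconds
REM_COMBINING_MIN = 15.0  # gap (min) without REM that ends a REM episode


@dataclass(frozen=True)
class EEGRecord:
    """Single-channel EEG samples in microvolts."""

    samples: np.ndarray
    rate: float = 256.0
    label: str = "EEG"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class Hypnogram:
    """Visually scored sleep stages, one code per 20-s epoch."""

    stages: tuple[str, ...]
    lights_off: int = 0
    lights_on: int | None = None
    epoch_s: float = EPOCH_S

    def __post_init__(self) -> None:
        stages = tuple(str(s) for s in self.stages)
        object.__setattr__(self, "stages", stages)
        unknown = set(stages) - STAGE_CODES
        if unknown:
            raise ValueError(f"unknown stage codes: {sorted(unknown)}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    def sleep_onset(self) -> int:
        """Index of the first stage-2 epoch (sleep onset)."""
        for i, s in enumerate(self.stages):
            if s == "2" and i >= self.lights_off:
                return i
        raise ValueError("no stage 2 sleep found; sleep onset undefined")


@dataclass(frozen=True)
class EpisodeBoundaries:
    """Start/end hypnogram epochs (inclusive) of consecutive NREM episodes."""

    episodes: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        eps = tuple((int(a), int(b)) for a, b in self.episodes)
        object.__setattr__(self, "episodes", eps)
        for (a, b) in eps:
            if b < a:
                raise ValueError("episode end before start")
        for (_, b), (a2, _) in zip(eps, eps[1:]):
            if a2 <= b:
                raise ValueError("episodes must be ordered and non-overlapping")

    def __len__(self) -> int:
        return len(self.episodes)

    def __iter__(self):
        return iter(self.episodes)


def epoch_band_power(record: EEGRecord,
                     bands: dict[str, tuple[float, float]] | None = None,
                     epoch_s: float = POWER_EPOCH_S,
                     valid_seconds: np.ndarray | None = None):
    """Band power per consecutive 4-s epoch by Hanning-windowed FFT.

    Power (uV^2) is the one-sided periodogram summed over the 0.25 Hz bins
    whose frequency lies within the band edges (inclusive).  Epochs that
    overlap any artefact-masked second are reported missing.  Returns a
    DataFrame with columns time_s (epoch start) and one column per band.
    """
    import pandas as pd

    bands = dict(DEFAULT_BANDS if bands is None else bands)
    top = max(hi for _, hi in bands.values())
    if record.rate / 2.0 < top:
        raise ValueError(
            f"Nyquist frequency {record.rate / 2:.1f} Hz below the top band edge {top} Hz")
    n = int(round(epoch_s * record.rate))
    if record.samples.size < n:
        raise ValueError("record shorter than one spectral epoch")
    n_epochs = record.samples.size // n

    rows = {band: np.empty(n_epochs) for band in bands}
    times = np.arange(n_epochs) * epoch_s + record.start_time
    for k in range(n_epochs):
        segment = record.samples[k * n:(k + 1) * n]
        freqs, pxx = periodogram(segment, fs=record.rate, window="hann",
                                 detrend=False, scaling="density")
        df = freqs[1] - freqs[0]
        for band, (lo, hi) in bands.items():
            sel = (freqs >= lo) & (freqs <= hi)
            rows[band][k] = float(np.sum(pxx[sel]) * df)

    if valid_seconds is not None:
        valid_seconds = np.asarray(valid_seconds, dtype=bool)
        sec_per_epoch = int(round(epoch_s))
        for k in range(n_epochs):
            sl = valid_seconds[k * sec_per_epoch:(k + 1) * sec_per_epoch]
            if sl.size and not sl.all():
                for band in bands:
                    rows[band][k] = np.nan
    out = pd.DataFrame({"time_s": times})
    for band in bands:
        out[band] = rows[band]
    return out


def artefact_mask(record: EEGRecord, background_s: float = 180.0,
                  k: float = 4.0) -> np.ndarray:
    """Per-second validity flags from a background-dependent RMS filter.

    A second is invalid when its RMS amplitude exceeds ``k`` times the
    rolling median RMS over a centered ``background_s`` window.  Flagged
    seconds become missing data downstream so time continuity is preserved.
    """
    import pandas as pd

    n = int(record.samples.size // record.rate)
    if n < 1:
        raise ValueError("record shorter than one second")
    samples = record.samples[: int(n * record.rate)].reshape(n, -1)
    rms = np.sqrt(np.mean(samples ** 2, axis=1))
    window = max(int(round(background_s)), 3)
    background = (pd.Series(rms)
                  .rolling(window, center=True, min_periods=1)
                  .median()
                  .to_numpy())
    background = np.where(background > 0, background, np.nan)
    with np.errstate(invalid="ignore"):
        invalid = rms > k * background
    return ~np.where(np.isnan(background), False, invalid)


def _rem_episodes(stages: tuple[str, ...], onset: int,
                  epoch_s: float) -> list[tuple[int, int]]:
    """Group REM epochs into episodes with the 15-min combining rule."""
    gap_epochs = int(round(REM_COMBINING_MIN * 60.0 / epoch_s))
    rem = [i for i in range(onset, len(stages)) if stages[i] == "R"]
    episodes: list[tuple[int, int]] = []
    for i in rem:
        if episodes and i - episodes[-1][1] < gap_epochs:
            episodes[-1] = (episodes[-1][0], i)
        else:
            episodes.append((i, i))
    return episodes


def segment_episodes(hyp: Hypnogram, max_episodes: int = 4) -> EpisodeBoundaries:
    """Delimit consecutive NREM episodes on the hypnogram.

    NREM episode 1 starts at sleep onset (first stage-2 epoch).  REM bouts
    separated by less than 15 min without REM belong to one REM episode
    (no minimum REM duration is required); a REM episode ends at its last
    REM epoch.  Each subsequent NREM episode starts at the epoch
    immediately following the previous REM episode's end and runs to the
    epoch before the next REM episode (or the last sleep epoch).
    """
    onset = hyp.sleep_onset()
    rem = _rem_episodes(hyp.stages, onset, hyp.epoch_s)

    last_sleep = max((i for i, s in enumerate(hyp.stages) if s in SLEEP_STAGES),
                     default=onset)
    nrem: list[tuple[int, int]] = []
    start = onset
    for rem_start, rem_end in rem:
        if rem_start > start:
            nrem.append((start, rem_start - 1))
        start = rem_end + 1
        if len(nrem) >= max_episodes:
            break
    if len(nrem) < max_episodes and start <= last_sleep:
        nrem.append((start, last_sleep))
    if len(nrem) < max_episodes:
        warnings.warn(f"only {len(nrem)} NREM episodes found", stacklevel=2)
    return EpisodeBoundaries(tuple(nrem[:max_episodes]))


def sleep_statistics(hyp: Hypnogram) -> dict[str, float]:
    """Sleep latency (min) and sleep efficiency index.

    Latency is the interval between lights-off and the first stage-2 epoch.
    Efficiency is total sleep time (excluding wake) over the total sleep
    period (sleep onset through the last sleep epoch, wake included).
    """
    onset = hyp.sleep_onset()
    latency_min = (onset - hyp.lights_off) * hyp.epoch_s / 60.0

    last_sleep = max(i for i, s in enumerate(hyp.stages) if s in SLEEP_STAGES)
    period = hyp.stages[onset:last_sleep + 1]
    total_sleep = sum(1 for s in period if s in SLEEP_STAGES)
    efficiency = total_sleep / len(period)
    return {"latency_min": latency_min, "efficiency": efficiency}
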