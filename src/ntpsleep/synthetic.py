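"""Seeded generators for every input the analysis pipeline consumes.

These generators emulate the statistical structure the analysis assumes —
cascade-generated band-power curves with multiplicative noise and missing
bins, cohorts whose TA-cycle counts rise across the night, paired
SCN-activity/slow-wave-activity traces driven by a known flip-flop
schedule, and band-limited synthetic EEG whose spectral envelopes follow a
known episode model.  They do not emulate real-EEG features such as
transient arousals, spindles as discrete events, or non-stationary
artefacts; passing recovery tests on this data demonstrates correctness of
the pipeline, not performance on real recordings.

All generators are pure functions of their arguments and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cascade import (
    DEFAULT_PROBABILITIES,
    EpisodeModel,
    ModeOccupancy,
    PhasePlan,
    TransitionProbabilities,
    occupancy_to_power,
    simulate_episode,
)
from .fitting import N_BINS, PowerTimeCourse
from .flipflop import ActivityTrace, bin_trace
from .spectral import EEGRecord, Hypnogram

__all__ = [
    "NoiseModel",
    "CohortSpec",
    "SyntheticEpisode",
    "generate_plan",
    "generate_episode_data",
    "generate_cohort",
    "generate_scn_swa",
    "generate_synthetic_eeg",
]

#: Typical absolute band powers (uV^2) used as default vertical scales.
DEFAULT_BAND_SCALES = {"delta": 120.0, "sigma": 12.0, "beta": 5.0}


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise plus random missing bins.

    Band power is positive with roughly scale-proportional variability, so
    each bin is multiplied by exp(sigma * Z); sigma = 0.1 corresponds to
    about 10% multiplicative noise.
    """

    sigma: float = 0.1
    missing_p: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if not (0.0 <= self.missing_p < 1.0):
            raise ValueError("missing probability must lie in [0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition defaults for a synthetic cohort.

    TA-cycle counts per episode are drawn as shifted Poisson variates
    (1 + Poisson(mean - 1)) centered near the observed cohort means for
    NREM 1-4, so the built-in rising trend across the night matches the
    reference cohort's.
    """

    n_subjects: int = 30
    ta_means: tuple[float, float, float, float] = (5.2, 6.7, 6.8, 7.1)
    durations_min: tuple[float, float, float, float] = (70.0, 60.0, 55.0, 50.0)
    probabilities: TransitionProbabilities = DEFAULT_PROBABILITIES
    noise: NoiseModel = NoiseModel(sigma=0.1, missing_p=0.02)
    band_scales: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_SCALES))
    beta_bias: float = 2.0
    min_phase_bins: int = 2   # stick-breaking floor per phase, in 2% bins
    max_ta: int = 12

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if any(d <= 0 for d in self.durations_min):
            raise ValueError("durations must be positive")
        if any(m < 1 for m in self.ta_means):
            raise ValueError("TA means must be >= 1")


def generate_plan(ta_count: int, rng: np.random.Generator,
                  min_phase_pct: float = 4.0) -> PhasePlan:
    """Random alternating plan with the given TA-cycle count.

    2*ta_count phase lengths are drawn by stick-breaking over [0, 100]
    with a minimum phase length, then cumulated into switchover times.
    """
    n_phases = 2 * ta_count
    slack = 100.0 - n_phases * min_phase_pct
    if slack <= 0:
        raise ValueError(f"TA count {ta_count} infeasible with "
                         f"{min_phase_pct}% minimum phases")
    extra = rng.dirichlet(np.ones(n_phases)) * slack
    lengths = min_phase_pct + extra
    edges = np.cumsum(lengths)[:-1]
    return PhasePlan(switchover_times=tuple(edges), first_phase="towards")


def _bin_centers(n_bins: int = N_BINS) -> np.ndarray:
    return (np.arange(n_bins) + 0.5) * (100.0 / n_bins)


def generate_episode_data(model: EpisodeModel, noise: NoiseModel = NoiseModel(),
                          seed: int | np.random.Generator = 0,
                          n_bins: int = N_BINS) -> PowerTimeCourse:
    """Noisy binned band-power curves generated by an episode model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = _bin_centers(n_bins)
    traj = simulate_episode(model, centers)
    powers = occupancy_to_power(traj, model.band_scales, model.beta_bias)
    bands: dict[str, np.ndarray] = {}
    for band in ("delta", "sigma", "beta"):
        values = powers[band].copy()
        if noise.sigma > 0:
            values = values * np.exp(noise.sigma * rng.standard_normal(n_bins))
        if noise.missing_p > 0:
            values[rng.random(n_bins) < noise.missing_p] = np.nan
        bands[band] = values
    return PowerTimeCourse(time=centers, bands=bands)


@dataclass(frozen=True)
class SyntheticEpisode:
    subject: int
    nrem: int
    model: EpisodeModel
    data: PowerTimeCourse
    duration_min: float


def generate_cohort(spec: CohortSpec = CohortSpec(), seed: int = 0,
                    ) -> tuple[list[SyntheticEpisode], pd.DataFrame]:
    """Synthetic cohort of per-subject episodes plus its ground-truth table.

    Returns the episode datasets and a long-format DataFrame with columns
    subject, nrem, ta (true cycle count) for recovery tests.
    """
    rng = np.random.default_rng(seed)
    episodes: list[SyntheticEpisode] = []
    truth_rows = []
    min_phase_pct = spec.min_phase_bins * (100.0 / N_BINS)
    for subject in range(1, spec.n_subjects + 1):
        # per-subject vertical scales vary lognormally around the defaults
        scales = {band: value * float(np.exp(0.3 * rng.standard_normal()))
                  for band, value in spec.band_scales.items()}
        for ep_index, ta_mean in enumerate(spec.ta_means, start=1):
            ta = 1 + int(rng.poisson(ta_mean - 1.0))
            ta = min(ta, spec.max_ta)
            plan = generate_plan(ta, rng, min_phase_pct=min_phase_pct)
            model = EpisodeModel(probabilities=spec.probabilities, plan=plan,
                                 initial_occupancy=ModeOccupancy(1.0, 0.0, 0.0),
                                 band_scales=scales, beta_bias=spec.beta_bias)
            data = generate_episode_data(model, spec.noise, rng)
            episodes.append(SyntheticEpisode(
                subject=subject, nrem=ep_index, model=model, data=data,
                duration_min=spec.durations_min[ep_index - 1]))
            truth_rows.append({"subject": subject, "nrem": ep_index, "ta": ta})
    return episodes, pd.DataFrame(truth_rows)


def generate_scn_swa(switch_times: Sequence[float], t_end: float,
                     noise_sigma: float = 2.0,
                     seed: int | np.random.Generator = 0,
                     bin_width: float = 60.0, sample_dt: float = 10.0,
                     scn_low: float = 50.0, scn_high: float = 90.0,
                     swa_slope: float = 0.15,
                     swa_range: tuple[float, float] = (10.0, 150.0),
                     ) -> tuple[ActivityTrace, ActivityTrace, float]:
    """Paired SCN/SWA traces driven by a known flip-flop schedule.

    The SCN trace alternates between a low level (below threshold: the
    sleep-deepening *towards* state) and a high level, switching at the
    given times (seconds), plus Gaussian noise.  SWA responds
    anti-correlated: it ramps upward at ``swa_slope`` (%/s) while the SCN
    is below threshold and downward while above, clipped to ``swa_range``,
    so its turning points fall exactly on the switch times.  Both traces
    are binned at ``bin_width`` (values in % of mean NREM activity).
    Returns (scn_trace, swa_trace, true_threshold).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    switch_times = np.asarray(sorted(switch_times), dtype=float)
    if switch_times.size and (switch_times[0] <= 0 or switch_times[-1] >= t_end):
        raise ValueError("switch times must lie strictly inside (0, t_end)")
    t = np.arange(0.0, t_end, sample_dt)
    # state 0 = towards (SCN low) first, alternating at each switch time
    state = np.searchsorted(switch_times, t, side="right") % 2
    scn_clean = np.where(state == 0, scn_low, scn_high)
    threshold = (scn_low + scn_high) / 2.0
    scn = scn_clean + noise_sigma * rng.standard_normal(t.size)

    swa = np.empty_like(t)
    level = swa_range[0]
    for i, s in enumerate(state):
        level += (swa_slope if s == 0 else -swa_slope) * sample_dt
        level = min(max(level, swa_range[0]), swa_range[1])
        swa[i] = level
    swa = swa + noise_sigma * rng.standard_normal(t.size)

    return (bin_trace(t, scn, bin_width), bin_trace(t, swa, bin_width),
            float(threshold))


def generate_synthetic_eeg(model: EpisodeModel, fs: float = 128.0,
                           episode_min: float = 25.0,
                           seed: int | np.random.Generator = 0,
                           latency_min: float = 10.0, rem_min: float = 16.0,
                           band_edges: dict[str, tuple[float, float]] | None = None,
                           ) -> tuple[EEGRecord, Hypnogram]:
    """Synthetic single-channel EEG whose band envelopes follow the model.

    The NREM section is a sum of band-limited Gaussian noise carriers
    (delta 1-4, sigma 12-15, beta 18-25 Hz) whose amplitude envelopes are
    the square roots of the model's band-power time courses.  A leading
    wake section and a trailing REM section (both low-amplitude broadband)
    come with a matching hypnogram so episode segmentation is exercised.
    """
    from scipy.signal import butter, sosfiltfilt

    if fs < 64.0:
        raise ValueError("sampling rate must be >= 64 Hz (Nyquist above beta)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bands = dict({"delta": (1.0, 4.0), "sigma": (12.0, 15.0), "beta": (18.0, 25.0)}
                 if band_edges is None else band_edges)

    n_ep = int(episode_min * 60 * fs)
    grid = np.linspace(0.0, 100.0, n_ep)
    traj = simulate_episode(model, grid)
    powers = occupancy_to_power(traj, model.band_scales, model.beta_bias)

    def carrier(lo: float, hi: float, n: int) -> np.ndarray:
        sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        x = sosfiltfilt(sos, rng.standard_normal(n))
        return x / x.std()

    nrem = np.zeros(n_ep)
    for band, (lo, hi) in bands.items():
        nrem += carrier(lo, hi, n_ep) * np.sqrt(np.maximum(powers[band], 0.0))

    n_wake = int(latency_min * 60 * fs)
    n_rem = int(rem_min * 60 * fs)
    wake = 2.0 * rng.standard_normal(n_wake)
    rem = 2.0 * rng.standard_normal(n_rem)
    samples = np.concatenate([wake, nrem, rem])
    record = EEGRecord(samples=samples, rate=fs, label="synthetic")

    def n_epochs(minutes: float) -> int:
        return int(round(minutes * 60 / 20))

    stages = (["W"] * n_epochs(latency_min) + ["2"] * n_epochs(episode_min)
              + ["R"] * n_epochs(rem_min))
    hyp = Hypnogram(stages=tuple(stages), lights_off=0)
    return record, hyp
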