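"""Fitting the three-mode cascade model to observed band-power time courses.

The procedure mirrors how the model is taken to the data: the episode is
normalized to 100% duration and averaged into 2% bins; switchover times are
initialized by peak/trough detection on the three-point-smoothed delta
curve; delta is fitted first (vertical scale by closed-form least squares,
switchover times by coordinate search on the bin grid); then, with the plan
frozen, the sigma and beta vertical scales are fitted — beta after
subtracting a constant background bias (about 2 uV^2).  Goodness of fit is
the coefficient of determination R^2 per band, combined across bands on the
Fisher-z scale (z = atanh of r = sqrt(R^2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .cascade import (
    DEFAULT_PROBABILITIES,
    EpisodeModel,
    ModeOccupancy,
    PhasePlan,
    TransitionProbabilities,
    occupancy_to_power,
    simulate_episode,
)

__all__ = [
    "PowerTimeCourse",
    "FitConfig",
    "FitResult",
    "BANDS",
    "N_BINS",
    "rebin_normalize",
    "smooth3",
    "detect_switchovers",
    "alternating_extrema",
    "fit_episode",
    "coefficient_of_determination",
    "overall_r2",
    "classify_fit",
]

BANDS = ("delta", "sigma", "beta")
N_BINS = 50  # 2% bins over the normalized episode


@dataclass(frozen=True)
class PowerTimeCourse:
    """Binned band-power series over a normalized NREM episode.

    ``bands`` maps band name to an array of per-bin mean powers (uV^2) on
    the common grid of bin centers ``time`` (% of episode duration).
    Missing bins are NaN.
    """

    time: np.ndarray
    bands: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        object.__setattr__(self, "time", time)
        bands = {k: np.asarray(v, dtype=float) for k, v in self.bands.items()}
        object.__setattr__(self, "bands", bands)
        widths = np.diff(time)
        if time.size >= 2 and not np.allclose(widths, widths[0]):
            raise ValueError("bins must be equally spaced")
        for name, values in bands.items():
            if values.shape != time.shape:
                raise ValueError(f"band {name!r} length mismatch")

    @property
    def n_bins(self) -> int:
        return self.time.size

    @property
    def bin_width(self) -> float:
        return float(self.time[1] - self.time[0]) if self.n_bins > 1 else float("nan")

    def valid_mask(self, band: str) -> np.ndarray:
        return ~np.isnan(self.bands[band])

    def to_frame(self):
        import pandas as pd

        data = {"time_pct": self.time}
        data.update({band: self.bands[band] for band in self.bands})
        return pd.DataFrame(data)


def rebin_normalize(times: Sequence[float],
                    band_powers: dict[str, Sequence[float]],
                    episode_start: float, episode_end: float,
                    n_bins: int = N_BINS) -> PowerTimeCourse:
    """Normalize an episode to 100% duration and average into equal bins.

    ``times`` are sample times (any unit) within [episode_start,
    episode_end); bin value is the mean of contained valid samples; bins
    with no valid samples are flagged missing (NaN).
    """
    duration = episode_end - episode_start
    if duration <= 0:
        raise ValueError("episode duration must be positive")
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty input series")
    if np.any(times < episode_start) or np.any(times > episode_end):
        raise ValueError("sample times outside episode bounds")
    pct = (times - episode_start) / duration * 100.0
    idx = np.clip((pct / (100.0 / n_bins)).astype(int), 0, n_bins - 1)
    centers = (np.arange(n_bins) + 0.5) * (100.0 / n_bins)

    binned: dict[str, np.ndarray] = {}
    for band, values in band_powers.items():
        values = np.asarray(values, dtype=float)
        if values.shape != times.shape:
            raise ValueError(f"band {band!r} length mismatch with times")
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins)
        valid = ~np.isnan(values)
        np.add.at(sums, idx[valid], values[valid])
        np.add.at(counts, idx[valid], 1.0)
        with np.errstate(invalid="ignore"):
            binned[band] = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
        if not np.any(counts > 0):
            raise ValueError(f"band {band!r} has no valid samples")
    return PowerTimeCourse(time=centers, bands=binned)


def smooth3(series: Sequence[float]) -> np.ndarray:
    """Three-point moving average, excluding missing values from local means.

    Interior points are replaced by the mean of the available values among
    (i-1, i, i+1); endpoints use their two available neighbors.  Missing
    positions stay missing.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError("series must have length >= 3")
    out = np.full_like(x, np.nan)
    for i in range(x.size):
        if np.isnan(x[i]):
            continue
        window = x[max(i - 1, 0):i + 2]
        out[i] = np.nanmean(window)
    return out


def alternating_extrema(values: Sequence[float]) -> list[tuple[int, str]]:
    """Indices of alternating local maxima/minima of a (possibly gappy) series.

    Operates on the non-missing values in order; plateaus are collapsed to
    their first index.  Consecutive extrema of the same kind keep the more
    extreme one, so the result strictly alternates 'max', 'min'.
    """
    x = np.asarray(values, dtype=float)
    idx = np.flatnonzero(~np.isnan(x))
    v = x[idx]
    if v.size < 3:
        return []
    raw: list[tuple[int, str]] = []
    direction = 0  # sign of the last nonzero step
    for k in range(1, v.size):
        step = np.sign(v[k] - v[k - 1])
        if step == 0:
            continue
        if direction > 0 and step < 0:
            raw.append((int(idx[k - 1]), "max"))
        elif direction < 0 and step > 0:
            raw.append((int(idx[k - 1]), "min"))
        direction = step
    # enforce strict alternation, keeping the more extreme of same-kind runs
    out: list[tuple[int, str]] = []
    for i, kind in raw:
        if out and out[-1][1] == kind:
            j, _ = out[-1]
            better = x[i] > x[j] if kind == "max" else x[i] < x[j]
            if better:
                out[-1] = (i, kind)
        else:
            out.append((i, kind))
    return out


def detect_switchovers(delta: Sequence[float],
                       time: Sequence[float] | None = None) -> PhasePlan:
    """Initial towards/away switchover plan from a smoothed delta series.

    Local maxima of the (already smoothed) delta curve mark towards->away
    switches and minima mark away->towards switches.  The plan begins with
    a towards phase at t=0, so a leading minimum (delta falling from the
    episode start) is dropped.  A monotone series yields a single-phase
    plan.
    """
    x = np.asarray(delta, dtype=float)
    if np.count_nonzero(~np.isnan(x)) < 5:
        raise ValueError("need at least 5 non-missing bins")
    if time is None:
        time = (np.arange(x.size) + 0.5) * (100.0 / x.size)
    time = np.asarray(time, dtype=float)

    extrema = alternating_extrema(x)
    while extrema and extrema[0][1] == "min":
        extrema.pop(0)
    # re-collapse any same-kind neighbors introduced by the drop
    cleaned: list[tuple[int, str]] = []
    for i, kind in extrema:
        if cleaned and cleaned[-1][1] == kind:
            j, _ = cleaned[-1]
            if (kind == "max" and x[i] > x[j]) or (kind == "min" and x[i] < x[j]):
                cleaned[-1] = (i, kind)
        else:
            cleaned.append((i, kind))
    times = tuple(float(time[i]) for i, _ in cleaned)
    return PhasePlan(switchover_times=times, first_phase="towards")


def coefficient_of_determination(observed: Sequence[float],
                                 predicted: Sequence[float]) -> float:
    """R^2 in percent: 100 * (1 - SS_res / SS_tot), SS_tot about the mean.

    Pairs with a missing observation or prediction are excluded.  May be
    negative for fits worse than the mean.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    mask = ~np.isnan(obs) & ~np.isnan(pred)
    obs, pred = obs[mask], pred[mask]
    if obs.size < 2:
        raise ValueError("need at least 2 paired non-missing values")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed series has zero variance; R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 100.0 * (1.0 - ss_res / ss_tot)


def overall_r2(r2_delta: float, r2_sigma: float, r2_beta: float) -> float:
    """Combine three per-band R^2 (%) into one overall R^2 (%) via Fisher z.

    Each R^2 is converted to r = sqrt(R^2/100), z = atanh(r) averaged over
    the three bands, and the mean back-transformed (tanh, squared, percent).
    This reproduces the printed overall values, e.g. (97.8, 82.0, 90.3)
    -> 92.6 and (88.6, 63.6, 84.7) -> 81.2.
    """
    values = (r2_delta, r2_sigma, r2_beta)
    if any(not (0.0 < v < 100.0) for v in values):
        raise ValueError("per-band R^2 values must lie in (0, 100)")
    z = [math.atanh(math.sqrt(v / 100.0)) for v in values]
    return math.tanh(sum(z) / 3.0) ** 2 * 100.0


#: Quality-of-fit class thresholds on overall R^2 (%).
QUALITY_THRESHOLDS = (("VG", 60.0), ("G", 40.0), ("F", 19.0))


def classify_fit(r2_overall: float) -> str:
    """Quality class: VG (>=60), G (40-60), F (19-40), BF below 19."""
    for label, threshold in QUALITY_THRESHOLDS:
        if r2_overall >= threshold:
            return label
    return "BF"  # below-fair: outside the observed range of the classes


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the staged episode fit."""

    probabilities: TransitionProbabilities = DEFAULT_PROBABILITIES
    free_probabilities: bool = False
    beta_bias: float = 2.0          # uV^2, constant background beta component
    max_sweeps: int = 30            # coordinate-search sweeps over switchovers
    max_shift_bins: int = 3         # search radius per sweep, in bins
    min_phase_bins: int = 1         # phases may not collapse below this
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta_bias < 0:
            raise ValueError("beta bias must be non-negative")
        if self.max_sweeps < 1:
            raise ValueError("iteration cap must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one episode."""

    model: EpisodeModel
    r2: dict[str, float]
    r2_overall: float
    quality: str
    residuals: dict[str, np.ndarray]
    ta_count: int
    converged: bool
    runs_test_p: float | None = None
    delta_normalization: float = 1.0

    def to_dict(self) -> dict:
        return {
            "probabilities": self.model.probabilities.as_dict(),
            "switchover_times": list(self.model.plan.switchover_times),
            "band_scales": dict(self.model.band_scales),
            "beta_bias": self.model.beta_bias,
            "r2": {k: float(v) for k, v in self.r2.items()},
            "r2_overall": float(self.r2_overall),
            "quality": self.quality,
            "ta_count": self.ta_count,
            "converged": self.converged,
            "runs_test_p": self.runs_test_p,
        }


def _shape(probabilities: TransitionProbabilities, plan: PhasePlan,
           occ0: ModeOccupancy, time: np.ndarray) -> dict[str, np.ndarray]:
    traj = simulate_episode(
        EpisodeModel(probabilities=probabilities, plan=plan, initial_occupancy=occ0),
        time)
    return {band: traj.component(band) for band in BANDS}


def _ls_scale(obs: np.ndarray, shape: np.ndarray) -> float:
    """Closed-form least-squares vertical scale for power = scale * shape."""
    mask = ~np.isnan(obs)
    denom = float(np.sum(shape[mask] ** 2))
    if denom == 0:
        return 1.0
    return max(float(np.sum(obs[mask] * shape[mask])) / denom, 1e-12)


def _delta_r2(obs: np.ndarray, shape: np.ndarray) -> float:
    scale = _ls_scale(obs, shape)
    try:
        return coefficient_of_determination(obs, scale * shape)
    except ValueError:
        return -np.inf


def _refine_plan(plan: PhasePlan, obs_delta: np.ndarray, time: np.ndarray,
                 probabilities: TransitionProbabilities, occ0: ModeOccupancy,
                 config: FitConfig) -> tuple[PhasePlan, bool]:
    """Coordinate search over switchover times on the bin grid.

    One switchover moves at a time by up to ``max_shift_bins`` bin widths,
    keeping times strictly increasing and at least ``min_phase_bins`` bins
    apart; moves that improve the delta R^2 are kept.  Returns the refined
    plan and a convergence flag (False if the sweep cap was reached).
    """
    width = float(time[1] - time[0])
    min_gap = config.min_phase_bins * width

    def score(p: PhasePlan) -> float:
        return _delta_r2(obs_delta, _shape(probabilities, p, occ0, time)["delta"])

    best = score(plan)
    times = list(plan.switchover_times)
    converged = False
    for _ in range(config.max_sweeps):
        improved = False
        for j in range(len(times)):
            lo = times[j - 1] + min_gap if j > 0 else min_gap
            hi = times[j + 1] - min_gap if j < len(times) - 1 else plan.t_end - min_gap
            for shift in range(-config.max_shift_bins, config.max_shift_bins + 1):
                if shift == 0:
                    continue
                candidate = times[j] + shift * width
                if not (lo <= candidate <= hi):
                    continue
                trial = times.copy()
                trial[j] = candidate
                trial_plan = PhasePlan(tuple(trial), plan.first_phase, plan.t_end)
                s = score(trial_plan)
                if s > best + 1e-12:
                    best, times, improved = s, trial, True
                    break
        if not improved:
            converged = True
            break
    return PhasePlan(tuple(times), plan.first_phase, plan.t_end), converged


def _runs_test_p(residuals: np.ndarray) -> float | None:
    """Two-sided runs test on residual signs (randomness about zero)."""
    signs = np.sign(residuals[~np.isnan(residuals)])
    signs = signs[signs != 0]
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    if n_pos == 0 or n_neg == 0:
        return None
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n_pos + n_neg
    mean = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n ** 2 * (n - 1.0))
    if var <= 0:
        return None
    from scipy.stats import norm

    z = (runs - mean) / math.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def fit_episode(data: PowerTimeCourse, config: FitConfig = FitConfig()) -> FitResult:
    """Staged fit of the cascade model to one episode's band-power curves.

    Stage 1 fits delta: the switchover plan is initialized from peak/trough
    detection on the smoothed delta curve and refined by coordinate search,
    with the delta vertical scale at its closed-form optimum throughout.
    Stage 2 freezes the plan and fits the sigma and beta vertical scales
    (beta after subtracting the constant background bias).  Missing bins
    are excluded from every residual sum.
    """
    if "delta" not in data.bands:
        raise ValueError("delta band is required for fitting")
    obs_delta_raw = data.bands["delta"]
    if np.count_nonzero(~np.isnan(obs_delta_raw)) < 5:
        raise ValueError("need at least 5 non-missing delta bins")
    time = data.time

    # initial delta normalization to the maximum data value
    delta_max = float(np.nanmax(obs_delta_raw))
    if delta_max <= 0:
        raise ValueError("delta power must be positive somewhere")
    obs_delta = obs_delta_raw / delta_max

    occ0 = ModeOccupancy(1.0, 0.0, 0.0)
    probabilities = config.probabilities
    plan0 = detect_switchovers(smooth3(obs_delta), time)
    plan, converged = _refine_plan(plan0, obs_delta, time, probabilities,
                                   occ0, config)

    if config.free_probabilities:
        from scipy.optimize import minimize

        def negloss(logp: np.ndarray) -> float:
            try:
                p = TransitionProbabilities.from_vector(np.exp(logp))
            except ValueError:
                return np.inf
            r2s = []
            shapes = _shape(p, plan, occ0, time)
            for band in BANDS:
                obs = data.bands.get(band)
                if obs is None:
                    continue
                obs = obs / max(float(np.nanmax(obs)), 1e-12)
                scale = _ls_scale(obs, shapes[band])
                try:
                    r2s.append(coefficient_of_determination(obs, scale * shapes[band]))
                except ValueError:
                    return np.inf
            # maximize the Fisher-z mean of clamped per-band R^2
            z = [math.atanh(math.sqrt(min(max(r, 0.01), 99.99) / 100.0)) for r in r2s]
            return -sum(z) / len(z)

        res = minimize(negloss, np.log(np.array(probabilities.as_vector())),
                       method="Nelder-Mead",
                       options={"maxiter": 400, "xatol": 1e-4, "fatol": 1e-7})
        probabilities = TransitionProbabilities.from_vector(np.exp(res.x))
        plan, converged = _refine_plan(plan, obs_delta, time, probabilities,
                                       occ0, config)

    shapes = _shape(probabilities, plan, occ0, time)

    scales: dict[str, float] = {}
    r2: dict[str, float] = {}
    residuals: dict[str, np.ndarray] = {}
    # stage 1 result: delta scale in original units
    scale_delta_norm = _ls_scale(obs_delta, shapes["delta"])
    scales["delta"] = scale_delta_norm * delta_max
    pred = scales["delta"] * shapes["delta"]
    r2["delta"] = coefficient_of_determination(obs_delta_raw, pred)
    residuals["delta"] = obs_delta_raw - pred

    # stage 2: sigma and beta vertical scales with the plan frozen
    for band in ("sigma", "beta"):
        obs = data.bands.get(band)
        if obs is None:
            continue
        target = obs - config.beta_bias if band == "beta" else obs
        scales[band] = _ls_scale(target, shapes[band])
        offset = config.beta_bias if band == "beta" else 0.0
        pred = scales[band] * shapes[band] + offset
        r2[band] = coefficient_of_determination(obs, pred)
        residuals[band] = obs - pred

    overall = overall_r2(
        min(max(r2.get("delta", 50.0), 1e-6), 100 - 1e-9),
        min(max(r2.get("sigma", 50.0), 1e-6), 100 - 1e-9),
        min(max(r2.get("beta", 50.0), 1e-6), 100 - 1e-9),
    )
    model = EpisodeModel(probabilities=probabilities, plan=plan,
                         initial_occupancy=occ0, band_scales=scales,
                         beta_bias=config.beta_bias if "beta" in scales else 0.0)
    return FitResult(model=model, r2=r2, r2_overall=overall,
                     quality=classify_fit(overall), residuals=residuals,
                     ta_count=plan.n_towards, converged=converged,
                     runs_test_p=_runs_test_p(residuals["delta"]),
                     delta_normalization=delta_max)


def predicted_power(result: FitResult, time: np.ndarray) -> dict[str, np.ndarray]:
    """Fitted band-power curves of a fit result on an arbitrary grid."""
    traj = simulate_episode(result.model, time)
    return occupancy_to_power(traj, result.model.band_scales,
                              result.model.beta_bias)
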