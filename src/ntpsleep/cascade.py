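"""Two-phase three-mode neuronal cascade underlying the NREM power pattern.

A fixed-size generating population of brainstem activating neurons occupies
one of three firing-rate modes (beta, sigma, delta).  During a *towards*
(sleep-deepening) phase neurons cascade beta -> sigma -> delta; during an
*away* (sleep-lightening) phase the cascade reverses, delta -> sigma -> beta.
Within a phase the occupancies follow the closed-form solution of a linear
serial decay chain (Bateman-type kinetics): the first mode declines
exponentially, the middle mode rises to a maximum and declines, and the last
mode rises in an S-curve.  Phases alternate at switchover times; each phase
starts from the end values of the previous one.

Time is measured in percent of the NREM episode duration throughout; the
transition probabilities are per 1% of episode duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "TransitionProbabilities",
    "ModeOccupancy",
    "PhasePlan",
    "EpisodeModel",
    "Trajectory",
    "DEFAULT_PROBABILITIES",
    "phase_occupancy",
    "sigma_peak_time",
    "simulate_episode",
    "occupancy_to_power",
    "monte_carlo_phase",
]

# Relative rate difference below which the equal-rate limit form is used.
# The default rates (0.13 vs 0.131) sit near the singular denominator of the
# two-exponential solution, so the difference of exponentials is always
# evaluated through expm1 and the true limit form only at near-degeneracy.
_EQUAL_RATE_RTOL = 1e-9

PhaseKind = Literal["towards", "away"]


@dataclass(frozen=True)
class TransitionProbabilities:
    """Four-element transition probability vector P.

    Each entry is a transition probability per unit time, with the unit time
    equal to 1% of the NREM episode duration.  Order: beta->sigma and
    sigma->delta drive the *towards* cascade; delta->sigma and sigma->beta
    drive the *away* cascade.
    """

    p_beta_sigma: float = 0.13
    p_sigma_delta: float = 0.131
    p_delta_sigma: float = 0.2
    p_sigma_beta: float = 0.6

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if not (0.0 < value < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {value}")

    def as_dict(self) -> dict[str, float]:
        return {
            "p_beta_sigma": self.p_beta_sigma,
            "p_sigma_delta": self.p_sigma_delta,
            "p_delta_sigma": self.p_delta_sigma,
            "p_sigma_beta": self.p_sigma_beta,
        }

    def as_vector(self) -> tuple[float, float, float, float]:
        return (self.p_beta_sigma, self.p_sigma_delta,
                self.p_delta_sigma, self.p_sigma_beta)

    @classmethod
    def from_vector(cls, vector: Sequence[float]) -> "TransitionProbabilities":
        if len(vector) != 4:
            raise ValueError("probability vector must have four elements")
        return cls(*map(float, vector))

    def rates(self, phase: PhaseKind) -> tuple[float, float]:
        """(first, second) cascade rates for the given phase kind."""
        if phase == "towards":
            return self.p_beta_sigma, self.p_sigma_delta
        if phase == "away":
            return self.p_delta_sigma, self.p_sigma_beta
        raise ValueError(f"unknown phase kind {phase!r}")


#: The common probability set used for all episodes and subjects.
DEFAULT_PROBABILITIES = TransitionProbabilities()


@dataclass(frozen=True)
class ModeOccupancy:
    """Population occupancy of the three firing modes at one time point.

    Counts (or fractions of the fixed generating population N0) are
    non-negative and conserved: the population is closed.
    """

    n_beta: float
    n_sigma: float
    n_delta: float
    time: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_beta", "n_sigma", "n_delta"):
            value = getattr(self, name)
            if value < -1e-12 or not math.isfinite(value):
                raise ValueError(f"{name} must be finite and >= 0, got {value}")

    @property
    def total(self) -> float:
        return self.n_beta + self.n_sigma + self.n_delta

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.n_beta, self.n_sigma, self.n_delta)


@dataclass(frozen=True)
class PhasePlan:
    """Alternating towards/away phase schedule over [0, 100]% of an episode.

    ``switchover_times`` are the interior instants at which the cascade
    direction flips; phases alternate starting with ``first_phase`` at t=0.
    """

    switchover_times: tuple[float, ...] = ()
    first_phase: PhaseKind = "towards"
    t_end: float = 100.0

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.switchover_times)
        object.__setattr__(self, "switchover_times", times)
        if self.first_phase not in ("towards", "away"):
            raise ValueError(f"unknown phase kind {self.first_phase!r}")
        if any(not (0.0 < t < self.t_end) for t in times):
            raise ValueError("switchover times must lie strictly inside (0, t_end)")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("switchover times must be strictly increasing")

    @property
    def phases(self) -> list[tuple[float, float, PhaseKind]]:
        """List of (start, end, kind) intervals covering [0, t_end]."""
        edges = (0.0, *self.switchover_times, self.t_end)
        kinds: list[PhaseKind] = ["towards", "away"] if self.first_phase == "towards" else ["away", "towards"]
        return [(edges[i], edges[i + 1], kinds[i % 2]) for i in range(len(edges) - 1)]

    @property
    def n_towards(self) -> int:
        """Number of towards phases = the episode's TA cycle count."""
        return sum(1 for _, _, kind in self.phases if kind == "towards")


@dataclass(frozen=True)
class EpisodeModel:
    """Complete generative model of one NREM episode's band-power curves."""

    probabilities: TransitionProbabilities = DEFAULT_PROBABILITIES
    plan: PhasePlan = PhasePlan()
    initial_occupancy: ModeOccupancy = ModeOccupancy(1.0, 0.0, 0.0)
    band_scales: dict[str, float] = field(
        default_factory=lambda: {"delta": 1.0, "sigma": 1.0, "beta": 1.0})
    beta_bias: float = 0.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.band_scales.values()):
            raise ValueError("band scales must be positive")
        if self.beta_bias < 0:
            raise ValueError("beta bias must be non-negative")

    def with_scales(self, scales: dict[str, float], beta_bias: float | None = None) -> "EpisodeModel":
        return replace(self, band_scales=dict(scales),
                       beta_bias=self.beta_bias if beta_bias is None else beta_bias)


def _serial_decay(n1: float, n2: float, n3: float,
                  p1: float, p2: float,
                  t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form serial decay chain 1 -> 2 -> 3 from arbitrary start values.

    Vectorized over t.  Uses expm1 to keep the two-exponential difference
    accurate for nearly equal rates, and the analytic limit form when the
    rates are numerically degenerate.
    """
    e1 = np.exp(-p1 * t)
    out1 = n1 * e1
    if abs(p2 - p1) < _EQUAL_RATE_RTOL * p1:
        # limit p2 -> p1: n2(t) = (n2 + n1*p1*t) e^{-p t}
        out2 = (n2 + n1 * p1 * t) * e1
    else:
        # e^{-p1 t} - e^{-p2 t} = -e^{-p1 t} * expm1(-(p2-p1) t)
        diff = -e1 * np.expm1(-(p2 - p1) * t)
        out2 = n2 * np.exp(-p2 * t) + n1 * p1 / (p2 - p1) * diff
    out3 = (n1 + n2 + n3) - out1 - out2
    return out1, out2, out3


def _phase_components(occ: ModeOccupancy, phase: PhaseKind) -> tuple[float, float, float]:
    """Occupancy in cascade order (first, middle, last) for the phase kind."""
    if phase == "towards":
        return occ.n_beta, occ.n_sigma, occ.n_delta
    return occ.n_delta, occ.n_sigma, occ.n_beta


def _occupancy_from_components(first: float, middle: float, last: float,
                               phase: PhaseKind, time: float) -> ModeOccupancy:
    first, middle, last = (max(v, 0.0) for v in (first, middle, last))
    if phase == "towards":
        return ModeOccupancy(first, middle, last, time=time)
    return ModeOccupancy(last, middle, first, time=time)


def phase_occupancy(occ0: ModeOccupancy, p_first: float, p_second: float,
                    t: float, phase: PhaseKind = "towards") -> ModeOccupancy:
    """Occupancy after time ``t`` of uninterrupted cascading within one phase.

    For a towards phase the cascade order is beta -> sigma -> delta with
    rates (p_first, p_second) = (p_beta_sigma, p_sigma_delta); for an away
    phase the roles of beta and delta are swapped.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if p_first <= 0 or p_second <= 0:
        raise ValueError("rates must be positive")
    n1, n2, n3 = _phase_components(occ0, phase)
    o1, o2, o3 = _serial_decay(n1, n2, n3, p_first, p_second, np.asarray(float(t)))
    return _occupancy_from_components(float(o1), float(o2), float(o3),
                                      phase, occ0.time + t)


def sigma_peak_time(occ0: ModeOccupancy, p_first: float, p_second: float,
                    phase: PhaseKind = "towards") -> float | None:
    """Interior time at which the middle-mode occupancy is maximal.

    Returns None when the middle mode declines from the start (no interior
    maximum).  With the whole population initially in the first mode this is
    the classical ln(p2/p1)/(p2-p1), reducing to 1/p for equal rates.
    """
    if p_first <= 0 or p_second <= 0:
        raise ValueError("rates must be positive")
    n1, n2, _ = _phase_components(occ0, phase)
    # middle-mode rate of change at t: p1*n1(t) - p2*n2(t)
    if p_first * n1 <= p_second * n2:
        return None
    if n2 == 0.0:
        if abs(p_second - p_first) < _EQUAL_RATE_RTOL * p_first:
            return 1.0 / p_first
        return math.log(p_second / p_first) / (p_second - p_first)

    from scipy.optimize import brentq

    def growth(t: float) -> float:
        o1, o2, _ = _serial_decay(n1, n2, 0.0, p_first, p_second, np.asarray(t))
        return p_first * float(o1) - p_second * float(o2)

    hi = 1.0 / min(p_first, p_second)
    while growth(hi) > 0:
        hi *= 2.0
    return float(brentq(growth, 0.0, hi, xtol=1e-12))


@dataclass(frozen=True)
class Trajectory:
    """Mode occupancies sampled on a time grid (percent of episode)."""

    time: np.ndarray
    n_beta: np.ndarray
    n_sigma: np.ndarray
    n_delta: np.ndarray

    def component(self, band: str) -> np.ndarray:
        return {"beta": self.n_beta, "sigma": self.n_sigma,
                "delta": self.n_delta}[band]

    @property
    def total(self) -> np.ndarray:
        return self.n_beta + self.n_sigma + self.n_delta

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_pct": self.time, "n_beta": self.n_beta,
                             "n_sigma": self.n_sigma, "n_delta": self.n_delta})


def simulate_episode(model: EpisodeModel, grid: Iterable[float]) -> Trajectory:
    """Evaluate the piecewise cascade over a sorted time grid in [0, t_end].

    Each phase starts from the end values of the previous phase, making the
    trajectory continuous at every switchover.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty time grid")
    if np.any(np.diff(grid) < 0):
        raise ValueError("time grid must be sorted")
    plan = model.plan
    if grid[0] < 0 or grid[-1] > plan.t_end:
        raise ValueError(f"grid must lie within [0, {plan.t_end}]")

    out = {b: np.empty_like(grid) for b in ("beta", "sigma", "delta")}
    occ = model.initial_occupancy
    phases = plan.phases
    for i, (start, end, kind) in enumerate(phases):
        p1, p2 = model.probabilities.rates(kind)
        last = i == len(phases) - 1
        mask = (grid >= start) & ((grid <= end) if last else (grid < end))
        n1, n2, n3 = _phase_components(occ, kind)
        if mask.any():
            o1, o2, o3 = _serial_decay(n1, n2, n3, p1, p2, grid[mask] - start)
            if kind == "towards":
                out["beta"][mask], out["sigma"][mask], out["delta"][mask] = o1, o2, o3
            else:
                out["delta"][mask], out["sigma"][mask], out["beta"][mask] = o1, o2, o3
        occ = phase_occupancy(occ, p1, p2, end - start, phase=kind)
    return Trajectory(time=grid, n_beta=out["beta"], n_sigma=out["sigma"],
                      n_delta=out["delta"])


def occupancy_to_power(traj: Trajectory, band_scales: dict[str, float],
                       beta_bias: float = 0.0) -> dict[str, np.ndarray]:
    """Map mode occupancies to band powers in microvolt-squared.

    power_band(t) = scale_band * n_band(t), with the constant background
    beta component added to the beta band only.
    """
    if any(s <= 0 for s in band_scales.values()):
        raise ValueError("band scales must be positive")
    if beta_bias < 0:
        raise ValueError("beta bias must be non-negative")
    powers = {band: band_scales[band] * traj.component(band)
              for band in ("delta", "sigma", "beta")}
    powers["beta"] = powers["beta"] + beta_bias
    return powers


def monte_carlo_phase(counts0: Sequence[int], p_first: float, p_second: float,
                      dt: float, t_end: float,
                      seed: int | np.random.Generator = 0,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Stochastic cascade of an integer population by per-step thinning.

    Each neuron independently moves first -> middle with probability
    p_first*dt and middle -> last with probability p_second*dt per step.
    The total count is conserved exactly and seeded runs are reproducible.
    Returns (times, counts) with counts of shape (n_steps + 1, 3).
    """
    if p_first * dt >= 1 or p_second * dt >= 1:
        raise ValueError("p*dt must be < 1; reduce dt")
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    counts = [int(c) for c in counts0]
    if len(counts) != 3 or any(c < 0 for c in counts):
        raise ValueError("counts0 must be three non-negative integers")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    history = np.empty((n_steps + 1, 3), dtype=np.int64)
    history[0] = counts
    n1, n2, n3 = counts
    for step in range(1, n_steps + 1):
        leave1 = rng.binomial(n1, p_first * dt) if n1 else 0
        leave2 = rng.binomial(n2, p_second * dt) if n2 else 0
        n1 -= leave1
        n2 += leave1 - leave2
        n3 += leave2
        history[step] = (n1, n2, n3)
    return times, history
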