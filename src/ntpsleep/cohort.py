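"""Cohort-level aggregation and inference over per-episode fit results.

Works on a complete subjects x NREM-episodes design holding, per cell, the
overall goodness of fit R^2 (%) and the number of towards-and-away (TA)
cycles.  Provides the Fisher-z mean used to average R^2 across subjects,
one-way repeated-measures ANOVA with the Huynh-Feldt sphericity
adjustment, single-degree-of-freedom polynomial trend contrasts across the
night, and the quality-class breakdown per episode.

A reference cohort (30 healthy young adults, NREM episodes 1-4, fitted
with the common probability set) ships with the package; see
``load_reference_table``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .fitting import classify_fit

__all__ = [
    "SubjectEpisodeTable",
    "RMAnovaResult",
    "TrendResult",
    "load_reference_table",
    "fisher_z_mean",
    "rm_anova",
    "polynomial_trends",
    "quality_table",
]

#: Orthogonal polynomial contrast coefficients for 4 equally spaced levels.
POLY_CONTRASTS: dict[str, tuple[int, ...]] = {
    "linear": (-3, -1, 1, 3),
    "quadratic": (1, -1, -1, 1),
    "cubic": (-1, 3, -3, 1),
}


@dataclass(frozen=True)
class SubjectEpisodeTable:
    """Long-format table with columns subject, nrem, r2, ta."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject", "nrem", "r2", "ta"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if self.frame.duplicated(["subject", "nrem"]).any():
            raise ValueError("duplicate subject/episode cells")

    @property
    def episodes(self) -> list[int]:
        return sorted(self.frame["nrem"].unique())

    def matrix(self, measure: str) -> np.ndarray:
        """Subjects x episodes matrix of the given measure; errors if incomplete."""
        wide = self.frame.pivot(index="subject", columns="nrem", values=measure)
        if wide.isna().any().any():
            raise ValueError("incomplete design: every subject needs every episode")
        return wide.sort_index(axis=1).to_numpy(dtype=float)

    @property
    def n_subjects(self) -> int:
        return self.frame["subject"].nunique()


def load_reference_table() -> SubjectEpisodeTable:
    """The packaged reference cohort: 30 subjects x NREM episodes 1-4."""
    with resources.files("ntpsleep.data").joinpath("reference_cohort.csv").open() as fh:
        frame = pd.read_csv(fh)
    return SubjectEpisodeTable(frame)


def fisher_z_mean(values) -> float:
    """Mean R^2 (%) on the Fisher-z scale.

    Each R^2 is converted to r = sqrt(R^2/100); the Fisher transform
    z = atanh(r) is averaged arithmetically and the mean back-transformed,
    r = tanh(z), R^2 = 100 r^2.  Averaging on the variance-stabilized z
    scale is the standard way to combine coefficients of determination.
    """
    arr = np.asarray(values, dtype=float)
    if np.any((arr <= 0) | (arr >= 100)):
        raise ValueError("R^2 values must lie in (0, 100)")
    z = np.arctanh(np.sqrt(arr / 100.0))
    return float(np.tanh(z.mean()) ** 2 * 100.0)


@dataclass(frozen=True)
class RMAnovaResult:
    f: float
    df_effect: int
    df_error: int
    p_uncorrected: float
    epsilon_hf: float
    p_hf: float
    ss_effect: float
    ss_error: float


def _huynh_feldt_epsilon(data: np.ndarray) -> float:
    """Huynh-Feldt sphericity epsilon from the within-subject covariance."""
    n, k = data.shape
    cov = np.cov(data, rowvar=False, ddof=1)
    # double-center the covariance matrix
    row = cov.mean(axis=0, keepdims=True)
    centered = cov - row - row.T + cov.mean()
    denom = (k - 1) * np.sum(centered ** 2)
    if denom == 0:  # no within-subject variance: sphericity trivially holds
        return 1.0
    eps_gg = np.trace(centered) ** 2 / denom
    num = n * (k - 1) * eps_gg - 2.0
    den = (k - 1) * (n - 1 - (k - 1) * eps_gg)
    return float(min(num / den, 1.0)) if den > 0 else 1.0


def rm_anova(data: np.ndarray | SubjectEpisodeTable,
             measure: str = "r2") -> RMAnovaResult:
    """One-way within-subject ANOVA on a complete subjects x episodes design.

    F = MS_episode / MS_(subject x episode).  The Huynh-Feldt epsilon and
    the epsilon-adjusted p value are reported alongside; the F statistic
    itself is never adjusted.
    """
    if isinstance(data, SubjectEpisodeTable):
        data = data.matrix(measure)
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or np.isnan(data).any():
        raise ValueError("need a complete 2-D subjects x episodes matrix")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 episodes")
    grand = data.mean()
    ss_effect = n * float(np.sum((data.mean(axis=0) - grand) ** 2))
    ss_subject = k * float(np.sum((data.mean(axis=1) - grand) ** 2))
    ss_total = float(np.sum((data - grand) ** 2))
    ss_error = ss_total - ss_effect - ss_subject
    df_effect = k - 1
    df_error = (n - 1) * (k - 1)
    if ss_error <= 0:
        f_value = math.inf if ss_effect > 0 else 0.0
    else:
        f_value = (ss_effect / df_effect) / (ss_error / df_error)
    eps = _huynh_feldt_epsilon(data)
    p_unc = float(f_dist.sf(f_value, df_effect, df_error))
    p_hf = float(f_dist.sf(f_value, eps * df_effect, eps * df_error))
    return RMAnovaResult(f=float(f_value), df_effect=df_effect,
                         df_error=df_error, p_uncorrected=p_unc,
                         epsilon_hf=eps, p_hf=p_hf,
                         ss_effect=ss_effect, ss_error=ss_error)


@dataclass(frozen=True)
class TrendResult:
    f: float
    df_error: int
    p: float
    ss: float
    percent_of_effect: float


def polynomial_trends(data: np.ndarray | SubjectEpisodeTable,
                      measure: str = "r2") -> dict[str, TrendResult]:
    """Linear/quadratic/cubic trend contrasts across four episodes.

    Each contrast's per-subject scores are analysed as a one-sample
    problem, giving F(1, n-1) against the contrast-specific error term.
    The contrast sums of squares decompose the within-subject effect SS
    exactly (orthogonality), and each contrast's share of that effect is
    reported in percent.
    """
    if isinstance(data, SubjectEpisodeTable):
        data = data.matrix(measure)
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if k != 4:
        raise ValueError("polynomial contrasts are defined for 4 equally spaced episodes")
    ss_effect = n * float(np.sum((data.mean(axis=0) - data.mean()) ** 2))
    out: dict[str, TrendResult] = {}
    for name, coeffs in POLY_CONTRASTS.items():
        c = np.asarray(coeffs, dtype=float)
        scores = data @ c
        mean = scores.mean()
        var = scores.var(ddof=1)
        ss = n * mean ** 2 / float(c @ c)
        f_value = math.inf if var == 0 else n * mean ** 2 / var
        p = float(f_dist.sf(f_value, 1, n - 1)) if math.isfinite(f_value) else 0.0
        share = 100.0 * ss / ss_effect if ss_effect > 0 else float("nan")
        out[name] = TrendResult(f=float(f_value), df_error=n - 1, p=p,
                                ss=float(ss), percent_of_effect=share)
    return out


def quality_table(table: SubjectEpisodeTable) -> pd.DataFrame:
    """Percent of episodes in each quality class, per NREM episode.

    Classes follow the overall-R^2 thresholds (VG >= 60, G 40-60, F 19-40,
    BF below); percentages in each column sum to 100.
    """
    frame = table.frame.copy()
    frame["quality"] = frame["r2"].map(classify_fit)
    counts = (frame.pivot_table(index="quality", columns="nrem",
                                values="subject", aggfunc="count",
                                fill_value=0))
    order = [q for q in ("VG", "G", "F", "BF") if q in counts.index]
    counts = counts.loc[order]
    return counts / counts.sum(axis=0) * 100.0
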