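"""Closed-form demographic and utility statistics.

Group demographics in studies of this kind are usually published only as
mean ± SEM with ranges and counts, so the Welch t statistic and Satterthwaite
degrees of freedom are computed directly from those summaries.  The gender
comparison is the Yates continuity-corrected chi-square on the 2x2 count
table, and significance of a Pearson correlation is converted to a t statistic
on n - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "welch_t_from_summary",
    "satterthwaite_df",
    "chi2_2x2_yates",
    "pearson_r_t",
    "sigma_to_fwhm",
    "fwhm_to_sigma",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class GroupSummary:
    """Published per-group summary: mean, standard error of the mean, n."""

    mean: float
    sem: float
    n: int

    def __post_init__(self):
        if self.sem < 0:
            raise ValueError("sem must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def welch_t_from_summary(g1: GroupSummary, g2: GroupSummary) -> float:
    """Welch t from group summaries: (m1 - m2) / sqrt(sem1^2 + sem2^2)."""
    denom = np.hypot(g1.sem, g2.sem)
    if denom == 0:
        raise ValueError("both SEMs are zero; t undefined")
    return float((g1.mean - g2.mean) / denom)


def satterthwaite_df(g1: GroupSummary, g2: GroupSummary) -> float:
    """Satterthwaite effective degrees of freedom for the Welch test."""
    v1, v2 = g1.sem**2, g2.sem**2
    if v1 == 0 and v2 == 0:
        raise ValueError("both SEMs are zero; df undefined")
    return float((v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1)))


def chi2_2x2_yates(counts) -> tuple[float, float]:
    """Yates continuity-corrected chi-square on a 2x2 table -> (statistic, p).

    |O - E| is reduced by 0.5 (floored at 0); p from chi-square with 1 df.
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in 2x2 table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(stat), float(p)


def pearson_r_t(r: float, n: int) -> tuple[float, int]:
    """t statistic and df for a Pearson correlation: t = r sqrt(n-2)/sqrt(1-r^2)."""
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    if n < 3:
        raise ValueError("need n >= 3")
    df = n - 2
    return float(r * np.sqrt(df) / np.sqrt(1.0 - r**2)), df


def sigma_to_fwhm(sigma: float) -> float:
    """Gaussian sigma -> full width at half maximum: 2 sqrt(2 ln 2) sigma."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return float(FWHM_PER_SIGMA * sigma)


def fwhm_to_sigma(fwhm: float) -> float:
    """Inverse of :func:`sigma_to_fwhm`."""
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    return float(fwhm / FWHM_PER_SIGMA)
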