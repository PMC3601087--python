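"""Per-cluster trajectory analysis: ROI means, robust trends, crossover points.

For each surviving cluster the mean GM inside the cluster is extracted per
subject.  A Huber robust line is fit to the CD values against the covariate of
interest (optionally with nuisance covariates, reported at their sample means),
and the crossover point is where that line meets the arithmetic mean of the
control ROI values:

    crossover = (control_mean - intercept) / slope

Subjects strictly beyond the crossover are compared to controls with a Welch
unequal-variance t-test, and cross-term specificity is checked by regressing
ROI means from one term's clusters on the other covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .robust_glm import huber_irls

__all__ = [
    "ROISeries",
    "CrossoverResult",
    "TrendFit",
    "WelchResult",
    "extract_roi_means",
    "fit_roi_trend",
    "crossover_point",
    "summarize_crossovers",
    "welch_beyond_crossover",
    "cross_term_check",
]

SLOPE_FLOOR = 1e-12


@dataclass
class ROISeries:
    """Per-subject mean GM inside one cluster, CD and controls separately."""

    cluster_id: int
    cd_values: np.ndarray
    ctrl_values: np.ndarray
    covariates: pd.DataFrame  # CD rows, columns = covariate names

    @property
    def control_mean(self) -> float:
        return float(np.mean(self.ctrl_values))


@dataclass
class TrendFit:
    slope: float
    intercept: float
    slope_se: float
    slope_t: float
    df_resid: int
    covariate: str
    nuisance: tuple[str, ...] = ()
    nuisance_beta: tuple[float, ...] = ()
    converged: bool = True


@dataclass
class CrossoverResult:
    cluster_id: int
    slope: float
    intercept: float
    control_mean: float
    crossover: float
    valid: bool
    in_window: bool = True


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    n_beyond: int
    n_ctrl: int
    testable: bool = True


def extract_roi_means(maps, cohort: pd.DataFrame, labels: np.ndarray, cluster_id: int) -> ROISeries:
    """Unweighted mean of in-cluster voxel values, per subject.

    ``maps`` holds one map per cohort row, same order.
    """
    member = np.asarray(labels) == cluster_id
    if not member.any():
        raise ValueError(f"cluster {cluster_id} is empty")
    means = np.array([np.asarray(getattr(m, "data", m))[member].mean() for m in maps])
    is_cd = (cohort["group"] == "CD").to_numpy()
    return ROISeries(
        cluster_id=int(cluster_id),
        cd_values=means[is_cd],
        ctrl_values=means[~is_cd],
        covariates=cohort.loc[is_cd, ["age", "abstinence_weeks", "years_use"]].reset_index(drop=True),
    )


def fit_roi_trend(series: ROISeries, covariate: str, nuisance: tuple[str, ...] = ()) -> TrendFit:
    """Huber robust line of CD ROI means on one covariate (+ optional nuisances).

    With nuisances present, the reported intercept is re-centered so the line
    is evaluated at the nuisance sample means; slope/intercept stay in natural
    covariate units.
    """
    y = np.asarray(series.cd_values, dtype=float)
    cols = [covariate, *nuisance]
    for c in cols:
        if c not in series.covariates.columns:
            raise ValueError(f"covariate {c!r} not available")
    Xcov = series.covariates[cols].to_numpy(dtype=float)
    n, p = Xcov.shape
    if n < p + 3:
        raise ValueError(f"too few CD subjects ({n}) for {p} covariates")
    X = np.column_stack([np.ones(n), Xcov])
    if np.linalg.cond(X) > 1e10:
        raise ValueError("rank-deficient ROI design (constant or collinear covariate)")
    r = huber_irls(y, X)
    beta = r["beta"]
    intercept = float(beta[0])
    nuis_beta = tuple(float(b) for b in beta[2:])
    if nuisance:
        nuis_means = Xcov[:, 1:].mean(axis=0)
        intercept += float(np.dot(nuis_beta, nuis_means))
    return TrendFit(
        slope=float(beta[1]),
        intercept=intercept,
        slope_se=float(r["se"][1]),
        slope_t=float(r["t"][1]),
        df_resid=r["df_resid"],
        covariate=covariate,
        nuisance=tuple(nuisance),
        nuisance_beta=nuis_beta,
        converged=bool(r["converged"]),
    )


def crossover_point(
    fit: TrendFit,
    control_mean: float,
    cluster_id: int = 0,
    plausible_window: tuple[float, float] | None = None,
) -> CrossoverResult:
    """Covariate value where the CD trend line meets the control mean.

    Zero (or sub-floor) slope yields an invalid result rather than an error;
    a crossover outside ``plausible_window`` is reported but flagged.
    """
    if abs(fit.slope) < SLOPE_FLOOR:
        return CrossoverResult(
            cluster_id=cluster_id,
            slope=fit.slope,
            intercept=fit.intercept,
            control_mean=float(control_mean),
            crossover=float("nan"),
            valid=False,
        )
    x = (float(control_mean) - fit.intercept) / fit.slope
    in_window = True
    if plausible_window is not None:
        in_window = plausible_window[0] <= x <= plausible_window[1]
    return CrossoverResult(
        cluster_id=cluster_id,
        slope=fit.slope,
        intercept=fit.intercept,
        control_mean=float(control_mean),
        crossover=x,
        valid=True,
        in_window=in_window,
    )


def summarize_crossovers(values) -> dict:
    """Mean, sample sd (n-1), and range of a set of crossover points."""
    vals = np.asarray([v for v in values], dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no valid crossover points to summarize")
    return {
        "n": int(len(vals)),
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if len(vals) >= 2 else None,
        "min": float(vals.min()),
        "max": float(vals.max()),
    }


def welch_beyond_crossover(series: ROISeries, crossover: float, covariate: str = "abstinence_weeks") -> WelchResult:
    """Welch t-test: CD subjects strictly beyond the crossover vs controls."""
    cov = series.covariates[covariate].to_numpy(dtype=float)
    beyond = series.cd_values[cov > crossover]
    ctrl = np.asarray(series.ctrl_values, dtype=float)
    if len(beyond) < 2 or len(ctrl) < 2:
        return WelchResult(
            t=float("nan"), df=float("nan"), p=float("nan"),
            n_beyond=int(len(beyond)), n_ctrl=int(len(ctrl)), testable=False,
        )
    res = stats.ttest_ind(beyond, ctrl, equal_var=False)
    return WelchResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        n_beyond=int(len(beyond)),
        n_ctrl=int(len(ctrl)),
    )


def cross_term_check(
    series: ROISeries,
    covariate_b: str,
    nuisance: tuple[str, ...] = ("age",),
    p_threshold: float = 0.05,
) -> dict:
    """Does a cluster found under term A also track covariate B?

    Robust fit of the CD ROI means on covariate B (age nuisance by default);
    two-tailed p from the slope t with n - p df, uncorrected.  Degenerate
    designs (e.g. constant covariate) are reported as not testable.
    """
    try:
        fit = fit_roi_trend(series, covariate_b, nuisance=nuisance)
    except ValueError:
        return {"testable": False, "covariate": covariate_b, "slope": float("nan"),
                "t": float("nan"), "p": float("nan"), "significant": False}
    p = 2.0 * float(stats.t.sf(abs(fit.slope_t), fit.df_resid))
    return {
        "testable": True,
        "covariate": covariate_b,
        "slope": fit.slope,
        "t": fit.slope_t,
        "p": p,
        "significant": bool(p < p_threshold),
    }
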