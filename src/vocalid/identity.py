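"""Per-parameter identity-coding statistics and screening utilities.

PIC (potential of identity coding) for one acoustic parameter is the
small-sample-corrected coefficient of variation of the pooled sample divided
by the mean within-individual corrected CV; values above 1 indicate that the
parameter separates individuals more than calls vary within an individual.
Also provides the KMO factorability statistic, simple OLS age trends, and
Bonferroni thresholds.
"""

from __future__ import annotations

import logging
import math
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "corrected_cv",
    "calc_pic",
    "pic_by_age_class",
    "ols_trend",
    "kmo_overall",
    "bonferroni_threshold",
    "TrendFit",
    "BonferroniThreshold",
]

PIC_CONTEXTS = ["beg", "rest", "touch-affiliative", "touch-aversive"]


def corrected_cv(values: Sequence[float]) -> float:
    """Small-sample-corrected coefficient of variation.

    CV = (SD / |mean|) * (1 + 1/(4n)), with the sample SD (ddof=1). The
    absolute mean keeps the CV positive for negative-valued parameters
    (e.g. spectral slope in dB/kHz).
    """
    v = np.asarray(values, dtype=np.float64)
    n = v.size
    if n < 2:
        raise ValueError("corrected_cv needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("corrected_cv undefined for zero mean")
    if mean < 0:
        logger.debug("corrected_cv: negative mean %.4g, using |mean|", mean)
    return float(v.std(ddof=1) / abs(mean) * (1.0 + 1.0 / (4.0 * n)))


def calc_pic(values: Sequence[float], individuals: Sequence) -> float:
    """PIC of one parameter: pooled corrected CV over mean within-individual
    corrected CV.

    Requires >= 2 individuals with >= 2 calls each. If every individual has
    zero within-variance the ratio is flagged infinite (``math.inf``) with a
    warning rather than failing silently.
    """
    v = np.asarray(values, dtype=np.float64)
    g = np.asarray(individuals)
    if v.shape != g.shape:
        raise ValueError("values and individuals must have equal length")
    groups = pd.unique(g)
    if groups.size < 2:
        raise ValueError("calc_pic needs at least 2 individuals")
    within = []
    for ind in groups:
        vi = v[g == ind]
        if vi.size < 2:
            raise ValueError(f"individual {ind!r} has fewer than 2 calls")
        within.append(corrected_cv(vi))
    mean_within = float(np.mean(within))
    cv_pooled = corrected_cv(v)
    if mean_within == 0:
        logger.warning("calc_pic: zero within-individual variance; PIC is infinite")
        return math.inf
    return cv_pooled / mean_within


class TrendFit(NamedTuple):
    slope: float
    intercept: float
    p: float
    stderr: float = float("nan")
    exact_fit: bool = False


def ols_trend(y: Sequence[float], x: Sequence[float]) -> TrendFit:
    """OLS of y on x; two-sided t-test p-value on the slope.

    An exact fit (zero residual variance) has no finite t statistic; the
    p-value is reported as the smallest positive float and flagged.
    """
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if y.size != x.size:
        raise ValueError("x and y must have equal length")
    if y.size < 3:
        raise ValueError("ols_trend needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; trend undefined")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    if np.allclose(resid, 0, atol=1e-12 * max(1.0, float(np.abs(y).max()))):
        return TrendFit(
            float(fit.slope), float(fit.intercept), np.finfo(float).tiny, 0.0, True
        )
    return TrendFit(
        float(fit.slope), float(fit.intercept), float(fit.pvalue), float(fit.stderr), False
    )


class BonferroniThreshold(NamedTuple):
    raw: float
    rounded: float
    m: int


def bonferroni_threshold(alpha: float, m: int) -> BonferroniThreshold:
    """Per-test threshold alpha/m; ``rounded`` is the 3-decimal report value
    (comparisons should use ``raw``)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    raw = alpha / m
    return BonferroniThreshold(raw=raw, rounded=round(raw, 3), m=m)


def kmo_overall(X: np.ndarray) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, where r are
    Pearson correlations and q are anti-image partial correlations derived
    from the inverse correlation matrix.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 3 rows and >= 2 columns")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("zero-variance column: correlation undefined")
    R = np.corrcoef(X, rowvar=False)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular correlation matrix") from exc
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    Q = -Rinv / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(Q[off] ** 2)
    return float(r2 / (r2 + q2))


def _age_class_midpoint(label: str) -> float:
    lo, hi = label.replace("–", "-").split("-")
    return (int(lo) + int(hi)) / 2.0


def pic_by_age_class(
    calls: pd.DataFrame,
    parameters: Sequence[str] | None = None,
    contexts: Sequence[str] | None = None,
    age_class_column: str = "age_class",
    individual_column: str = "individual",
    context_column: str = "context",
) -> pd.DataFrame:
    """PIC per parameter x age class, pooled across contexts and per context.

    Returns a tidy frame with columns ``context`` ("pooled" or a label),
    ``parameter``, ``age_class``, ``age_mid``, ``pic``, ``n_calls``, plus the
    per-(context, parameter) OLS age trend of PIC against the age-class
    midpoint (``trend_slope``, ``trend_p``). Strata failing the PIC
    preconditions get NaN and a logged reason.
    """
    parameters = list(parameters) if parameters is not None else list(FEATURE_COLUMNS)
    contexts = list(contexts) if contexts is not None else list(PIC_CONTEXTS)
    if age_class_column not in calls.columns:
        raise ValueError(f"calls table lacks {age_class_column!r} column")

    age_classes = sorted(calls[age_class_column].unique(), key=_age_class_midpoint)
    rows = []
    for ctx in ["pooled"] + contexts:
        sub_ctx = calls if ctx == "pooled" else calls[calls[context_column] == ctx]
        for param in parameters:
            for ac in age_classes:
                stratum = sub_ctx[sub_ctx[age_class_column] == ac]
                pic = np.nan
                counts = stratum.groupby(individual_column).size()
                usable = counts[counts >= 2]
                if len(usable) >= 2:
                    keep = stratum[individual_column].isin(usable.index)
                    try:
                        pic = calc_pic(
                            stratum.loc[keep, param].to_numpy(),
                            stratum.loc[keep, individual_column].to_numpy(),
                        )
                    except ValueError as exc:
                        logger.info("PIC missing for %s/%s/%s: %s", ctx, param, ac, exc)
                else:
                    logger.info(
                        "PIC missing for %s/%s/%s: fewer than 2 individuals with >= 2 calls",
                        ctx,
                        param,
                        ac,
                    )
                rows.append(
                    {
                        "context": ctx,
                        "parameter": param,
                        "age_class": ac,
                        "age_mid": _age_class_midpoint(ac),
                        "pic": pic,
                        "n_calls": int(len(stratum)),
                    }
                )
    table = pd.DataFrame(rows)

    # age trend of PIC per (context, parameter), on age-class midpoints
    slopes, ps = {}, {}
    for (ctx, param), grp in table.groupby(["context", "parameter"]):
        ok = grp.dropna(subset=["pic"])
        finite = ok[np.isfinite(ok["pic"])]
        if len(finite) >= 3 and finite["age_mid"].nunique() >= 2:
            fit = ols_trend(finite["pic"].to_numpy(), finite["age_mid"].to_numpy())
            slopes[(ctx, param)], ps[(ctx, param)] = fit.slope, fit.p
        else:
            slopes[(ctx, param)], ps[(ctx, param)] = np.nan, np.nan
            logger.info("PIC trend missing for %s/%s: too few strata", ctx, param)
    keys = list(zip(table["context"], table["parameter"]))
    table["trend_slope"] = [slopes[k] for k in keys]
    table["trend_p"] = [ps[k] for k in keys]
    return table
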