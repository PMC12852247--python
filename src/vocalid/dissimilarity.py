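"""Dyadic vocal dissimilarity across development.

Per individual and day (optionally per behavioural context) the call table
is reduced to a median descriptor profile; every unordered pair of
same-stratum profiles yields a Euclidean dissimilarity score (0 = identical
profiles), and an OLS model of score on age tests whether individuals
diverge vocally as they grow.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import FEATURE_COLUMNS
from .identity import bonferroni_threshold, ols_trend

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_CLASS_BINS",
    "AGE_CLASS_LABELS",
    "assign_age_class",
    "daily_median_profiles",
    "dyadic_dissimilarity",
    "dissimilarity_trend",
    "TrendSummary",
]

#: Seven-day age bins, closed on both ends.
AGE_CLASS_BINS = [(11, 17), (18, 24), (25, 31), (32, 38), (39, 45)]
AGE_CLASS_LABELS = [f"{lo}–{hi}" for lo, hi in AGE_CLASS_BINS]


def assign_age_class(age_days: int) -> str:
    """Label of the seven-day bin containing ``age_days`` (11–45 only)."""
    for (lo, hi), label in zip(AGE_CLASS_BINS, AGE_CLASS_LABELS):
        if lo <= age_days <= hi:
            return label
    raise ValueError(f"age {age_days} outside the covered range 11–45 days")


def daily_median_profiles(
    calls: pd.DataFrame,
    by_context: bool = False,
    parameters: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Median descriptor profile per individual x day (x context if flagged).

    Returns one row per stratum with the median of each parameter and the
    number of contributing calls; empty strata are simply absent.
    """
    parameters = list(parameters) if parameters is not None else list(FEATURE_COLUMNS)
    keys = ["individual", "age_days"] + (["context"] if by_context else [])
    grouped = calls.groupby(keys, sort=True)
    prof = grouped[parameters].median()
    prof["n_calls"] = grouped.size()
    prof = prof.reset_index()
    if not by_context:
        prof.insert(2, "context", "pooled")
    return prof


def dyadic_dissimilarity(
    profiles: pd.DataFrame,
    standardize: bool = False,
    score: str = "distance",
    parameters: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Euclidean dissimilarity for every unordered pair of profiles sharing
    a day (and context).

    ``standardize`` z-scales each parameter globally across the supplied
    profiles before computing distances (off by default, logged when on).
    ``score="max-minus-distance"`` reports the per-stratum maximum distance
    minus each distance instead of the raw distance.

    Returns columns: dyad_a, dyad_b, dyad, age_days, context, score.
    """
    if score not in ("distance", "max-minus-distance"):
        raise ValueError(f"unknown score convention {score!r}")
    parameters = list(parameters) if parameters is not None else list(FEATURE_COLUMNS)
    missing = [p for p in parameters if p not in profiles.columns]
    if missing:
        raise ValueError(f"profiles lack parameter columns: {missing}")

    prof = profiles.copy()
    if standardize:
        logger.info("dyadic_dissimilarity: z-scaling parameters before distance")
        for p in parameters:
            sd = prof[p].std(ddof=1)
            prof[p] = (prof[p] - prof[p].mean()) / (sd if sd > 0 else 1.0)

    if "context" not in prof.columns:
        prof["context"] = "pooled"

    rows = []
    for (ctx, day), grp in prof.groupby(["context", "age_days"], sort=True):
        if len(grp) < 2:
            continue
        vecs = grp[parameters].to_numpy(dtype=np.float64)
        inds = grp["individual"].to_numpy()
        dists = []
        pairs = []
        for i, j in combinations(range(len(grp)), 2):
            a, b = sorted((str(inds[i]), str(inds[j])))
            pairs.append((a, b))
            dists.append(float(np.linalg.norm(vecs[i] - vecs[j])))
        dists = np.asarray(dists)
        if score == "max-minus-distance":
            dists = dists.max() - dists
        for (a, b), d in zip(pairs, dists):
            rows.append(
                {
                    "dyad_a": a,
                    "dyad_b": b,
                    "dyad": f"{a}|{b}",
                    "age_days": day,
                    "context": ctx,
                    "score": d,
                }
            )
    return pd.DataFrame(
        rows, columns=["dyad_a", "dyad_b", "dyad", "age_days", "context", "score"]
    )


class TrendSummary(NamedTuple):
    context: str
    slope: float
    intercept: float
    p: float
    stderr: float
    n: int
    sufficient: bool
    significant: bool


def dissimilarity_trend(
    records: pd.DataFrame,
    context: str = "pooled",
    alpha: float = 0.05,
    bonferroni_m: int = 7,
) -> TrendSummary:
    """OLS of dissimilarity score on age (days) for one context.

    Strata with fewer than 3 records or fewer than 2 distinct ages are
    flagged insufficient (slope/p NaN) rather than raising. Significance is
    judged against the raw Bonferroni threshold ``alpha / bonferroni_m``.
    """
    sub = records[records["context"] == context]
    n = int(len(sub))
    if n < 3 or sub["age_days"].nunique() < 2:
        logger.info("dissimilarity_trend: data for context %r insufficient", context)
        return TrendSummary(context, np.nan, np.nan, np.nan, np.nan, n, False, False)
    fit = ols_trend(sub["score"].to_numpy(), sub["age_days"].to_numpy(dtype=np.float64))
    thr = bonferroni_threshold(alpha, bonferroni_m).raw
    return TrendSummary(
        context, fit.slope, fit.intercept, fit.p, fit.stderr, n, True, bool(fit.p < thr)
    )
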