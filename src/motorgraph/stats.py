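"""Paired nonparametric testing, FDR adjustment, and brain-behavior correlation.

The workhorse is the exact two-sided Wilcoxon signed-rank test: differences
post - pre, zero differences dropped (Wilcoxon's original convention),
absolute differences ranked with midranks for ties, and the two-sided p
obtained from the exact permutation distribution of the positive-rank sum W
over all 2^n sign assignments, conditional on the observed tie pattern.
At the small n of paired rehabilitation cohorts the exact distribution is
cheap and the printed p-values are exact tail probabilities (e.g. seven
positive untied differences give p = 2 / 2^7 = 0.015625).

Multiple comparisons are handled per family of tests with Benjamini-Hochberg
FDR; raw p < trend_cut (default 0.07) that does not survive FDR is flagged
as a trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BehavioralRecord",
    "PairedTestResult",
    "CorrelationResult",
    "UndefinedTestError",
    "load_behavior",
    "wilcoxon_signed_rank_exact",
    "fdr_bh",
    "classify",
    "pearson_with_p",
    "change_scores",
]

ALPHA_DEFAULT = 0.05
TREND_CUT_DEFAULT = 0.07
ENUMERATION_CAP_DEFAULT = 25

ARAT_MAX = 57


class UndefinedTestError(ValueError):
    """The signed-rank test is undefined (all paired differences are zero)."""


@dataclass(frozen=True)
class BehavioralRecord:
    """Per-subject pre/post behavior: ARAT points (0-57, may be missing for
    subjects unable to perform the test) and 9-HPT seconds (mean of two
    trials; lower is better)."""

    subject_id: str
    arat_pre: float | None
    arat_post: float | None
    hpt_pre: float
    hpt_post: float

    def __post_init__(self) -> None:
        for v in (self.arat_pre, self.arat_post):
            if v is not None and not 0 <= v <= ARAT_MAX:
                raise ValueError(f"ARAT score out of [0, {ARAT_MAX}]: {v}")
        if not (self.hpt_pre > 0 and self.hpt_post > 0):
            raise ValueError("9-HPT times must be positive")


@dataclass(frozen=True)
class PairedTestResult:
    n_total: int
    n_effective: int
    statistic: float  # W: sum of positive-difference ranks
    p: float
    q: float | None = None
    flag: str | None = None
    method: str = "exact"


@dataclass(frozen=True)
class CorrelationResult:
    region: str
    metric: str
    behavior: str
    R: float
    n: int
    p: float
    q: float | None = None
    flag: str | None = None


def load_behavior(source: str | Path | None = None) -> list[BehavioralRecord]:
    """Load a behavioral table (CSV with subject_id, arat_pre, arat_post,
    hpt_pre, hpt_post; missing ARAT as empty cell or '-').  With no source,
    the packaged 13-subject study table is returned."""
    if source is None:
        with resources.files("motorgraph.data").joinpath("behavior_scores.csv").open() as fh:
            df = pd.read_csv(fh, na_values=["-", "–"])
    else:
        df = pd.read_csv(source, na_values=["-", "–"])
    records = []
    for row in df.itertuples():
        records.append(
            BehavioralRecord(
                subject_id=str(row.subject_id),
                arat_pre=None if pd.isna(row.arat_pre) else float(row.arat_pre),
                arat_post=None if pd.isna(row.arat_post) else float(row.arat_post),
                hpt_pre=float(row.hpt_pre),
                hpt_post=float(row.hpt_post),
            )
        )
    return records


def _exact_signed_rank_p(ranks: np.ndarray, w: float) -> float:
    """Exact two-sided p for positive-rank sum ``w`` given the midrank vector.

    The null distribution over all 2^n sign assignments is built by
    generating-function convolution: doubling the midranks makes them
    integers, and the polynomial product of (1 + x^r) enumerates every sign
    vector's W.  Identical to literal enumeration, in O(n * sum(r)).
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2 * w))
    lower = counts[: w2 + 1].sum()
    upper = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank_exact(
    pre: Sequence[float],
    post: Sequence[float],
    enumeration_cap: int = ENUMERATION_CAP_DEFAULT,
) -> PairedTestResult:
    """Exact two-sided Wilcoxon signed-rank test on paired pre/post values.

    Pairs with a missing value are deleted, zero differences dropped, and
    the exact two-sided p computed conditional on the tie pattern (midranks).
    Beyond ``enumeration_cap`` effective pairs a tie-corrected normal
    approximation is used instead, with a warning.
    """
    pre_a = np.asarray(pre, dtype=float)
    post_a = np.asarray(post, dtype=float)
    if pre_a.shape != post_a.shape:
        raise ValueError("pre and post must have equal length")
    keep = ~(np.isnan(pre_a) | np.isnan(post_a))
    d = post_a[keep] - pre_a[keep]
    n_total = int(d.size)
    if n_total == 0:
        raise ValueError("no complete pairs")
    d = d[d != 0]
    n_eff = int(d.size)
    if n_eff == 0:
        raise UndefinedTestError("all paired differences are zero")

    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())

    if n_eff <= enumeration_cap:
        p = _exact_signed_rank_p(ranks, w)
        method = "exact"
    else:
        warnings.warn(
            f"n_effective={n_eff} exceeds enumeration cap {enumeration_cap}; "
            "using tie-corrected normal approximation",
            stacklevel=2,
        )
        mean = ranks.sum() / 2.0
        sd = np.sqrt((ranks**2).sum() / 4.0)
        z = (w - mean) / sd
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "normal"
    return PairedTestResult(
        n_total=n_total, n_effective=n_eff, statistic=w, p=p, method=method
    )


def fdr_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    # p = 0.0 can legitimately occur via floating underflow (perfect fits)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify(
    p: float,
    q: float,
    alpha: float = ALPHA_DEFAULT,
    trend_cut: float = TREND_CUT_DEFAULT,
) -> str:
    """'significant' iff q < alpha; else 'trend' iff raw p < trend_cut; else 'null'."""
    if q < alpha:
        return "significant"
    if p < trend_cut:
        return "trend"
    return "null"


def pearson_with_p(
    x: Sequence[float],
    y: Sequence[float],
    region: str = "",
    metric: str = "",
    behavior: str = "",
) -> CorrelationResult:
    """Pearson R with two-sided p (t distribution, n-2 df), pairwise deletion."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    if xa.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("zero variance in correlation input")
    r, p = sps.pearsonr(xa, ya)
    return CorrelationResult(
        region=region, metric=metric, behavior=behavior,
        R=float(r), n=int(xa.size), p=float(p),
    )


def change_scores(records: Sequence[BehavioralRecord]) -> pd.DataFrame:
    """Per-subject post - pre deltas (9-HPT improvement is a negative delta).

    Subjects missing either session of a measure get NaN for that measure.
    """
    rows = []
    for rec in records:
        arat = (
            rec.arat_post - rec.arat_pre
            if rec.arat_pre is not None and rec.arat_post is not None
            else np.nan
        )
        rows.append(
            {
                "subject_id": rec.subject_id,
                "arat_delta": arat,
                "hpt_delta": rec.hpt_post - rec.hpt_pre,
            }
        )
    return pd.DataFrame(rows).set_index("subject_id")
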