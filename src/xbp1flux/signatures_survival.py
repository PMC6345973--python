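"""Signature-activity scoring and survival stratification.

A gene signature (e.g. the 36 XBP1s target genes, or the five-gene
prognostic signature ANLN, CSNK1G3, RRM2, SLC35A2, UBAC2) is summarised
per sample as the mean of per-gene z-scores. Cohorts can be quantile
normalised beforehand to remove cohort-dependent distributional effects.
Samples are split at the median score into high/low activity groups,
compared by Kaplan-Meier estimation and the log-rank test (survival) or
per-gene Welch t-tests (expression stratified by a second activity score,
e.g. AR activity).

Kaplan-Meier and log-rank computations are delegated to lifelines; at
tied times, events are processed before censorings (the standard
convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .io_formats import SurvivalCohort, ValidationError

logger = logging.getLogger("xbp1flux")

__all__ = [
    "KMCurve",
    "LogrankResult",
    "quantile_normalize",
    "signature_score",
    "score_correlation",
    "stratified_expression_test",
    "km_estimate",
    "logrank_test",
    "prognostic_stratification",
]

# prognostic five-gene XBP1 signature
FIVE_GENE_SIGNATURE = ["ANLN", "CSNK1G3", "RRM2", "SLC35A2", "UBAC2"]


@dataclass
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    event_times: np.ndarray  # distinct observed times, ascending
    survival: np.ndarray  # S(t) just after each time
    at_risk: np.ndarray  # number at risk just before each time

    def __post_init__(self) -> None:
        if np.any(np.diff(self.event_times) < 0):
            raise ValidationError("KM event times must be ascending")
        s = self.survival
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12) or np.any(np.diff(s) > 1e-12):
            raise ValidationError("KM survival must be non-increasing within [0, 1]")


@dataclass
class LogrankResult:
    chi_square: float
    p_value: float


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean empirical distribution.

    Each column's sorted values are replaced by the mean of per-rank
    values across columns; ties within a column receive the mean of the
    reference values their rank span covers. Idempotent; a single-column
    matrix is returned unchanged with a warning.
    """
    if expr.isna().any().any():
        raise ValidationError("quantile normalization requires complete data")
    if expr.shape[1] < 2:
        logger.warning("quantile normalization with a single column is a no-op")
        return expr.copy()
    values = expr.to_numpy(dtype=float)
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    cum_ref = np.concatenate([[0.0], np.cumsum(ref)])
    for j in range(values.shape[1]):
        col = values[:, j]
        # tie group spanning ranks i..k (0-based) gets mean(ref[i:k+1])
        rmin = stats.rankdata(col, method="min").astype(int) - 1
        rmax = stats.rankdata(col, method="max").astype(int)
        out[:, j] = (cum_ref[rmax] - cum_ref[rmin]) / (rmax - rmin)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def signature_score(expr: pd.DataFrame, signature: list[str]) -> pd.Series:
    """Per-sample signature activity: mean of per-gene z-scores.

    Genes are centred and scaled across samples (sample standard
    deviation); signature genes absent from the matrix are logged and
    zero-variance genes dropped with a warning. Invariant to the order of
    the signature genes.
    """
    present = [g for g in dict.fromkeys(signature) if g in expr.index]
    absent = sorted(set(signature) - set(present))
    if absent:
        logger.warning("signature genes absent from expression: %s", absent)
    if not present:
        raise ValidationError("no signature gene present in the expression matrix")
    sub = expr.loc[present].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning(
            "dropping %d zero-variance signature gene(s)", int((~keep).sum())
        )
    if not keep.any():
        raise ValidationError("all signature genes have zero variance")
    sub = sub[keep]
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return pd.Series(z.mean(axis=0), index=expr.columns, name="signature_score")


def score_correlation(score_a: pd.Series, score_b: pd.Series) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of two scores on shared samples."""
    shared = score_a.index.intersection(score_b.index)
    if len(shared) < 3:
        raise ValidationError("need at least 3 shared samples")
    a = score_a.loc[shared].to_numpy(dtype=float)
    b = score_b.loc[shared].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("constant score vector; correlation undefined")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def median_split(score: pd.Series) -> pd.Series:
    """Boolean high-activity indicator: score strictly above the median.

    Ties with the median go to the low group.
    """
    return score > score.median()


def stratified_expression_test(
    expr: pd.DataFrame,
    stratifying_score: pd.Series,
    genes: list[str],
) -> pd.DataFrame:
    """Welch t-tests of gene expression between high/low score groups.

    Samples are median-split on ``stratifying_score`` (ties to the low
    group). A gene that is constant in both groups is degenerate and
    reported with t=0, p=1 and a flag.
    """
    stratifying_score = stratifying_score.loc[expr.columns]
    high = median_split(stratifying_score)
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValidationError("each stratum needs at least 2 samples")
    hi_cols = list(expr.columns[high.to_numpy()])
    lo_cols = list(expr.columns[~high.to_numpy()])
    rows = []
    for g in genes:
        if g not in expr.index:
            raise ValidationError(f"gene {g!r} absent from expression")
        x = expr.loc[g, hi_cols].to_numpy(dtype=float)
        y = expr.loc[g, lo_cols].to_numpy(dtype=float)
        if np.std(x) == 0 and np.std(y) == 0:
            rows.append(
                {"gene": g, "t_statistic": 0.0, "p_value": 1.0,
                 "mean_high": float(x.mean()), "mean_low": float(y.mean()),
                 "degenerate": True}
            )
            continue
        t, p = stats.ttest_ind(x, y, equal_var=False)
        rows.append(
            {"gene": g, "t_statistic": float(t), "p_value": float(p),
             "mean_high": float(x.mean()), "mean_low": float(y.mean()),
             "degenerate": False}
        )
    return pd.DataFrame(rows)


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("empty input for KM estimation")
    if (times < 0).any():
        raise ValidationError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    # keep rows at observed times only (drop the t=0 anchor lifelines adds)
    et = kmf.event_table
    mask = et.index > 0 if (times > 0).all() else np.ones(len(et), dtype=bool)
    table = et[mask]
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index).to_numpy()
    return KMCurve(
        event_times=table.index.to_numpy(dtype=float),
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
    )


def logrank_test(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> LogrankResult:
    """Standard 1-df log-rank comparison of two survival samples."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if times_a.size == 0 or times_b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        raise ValidationError("no events in either group; log-rank undefined")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    return LogrankResult(chi_square=chi2, p_value=min(max(p, np.nextafter(0, 1)), 1.0))


def prognostic_stratification(
    cohort: SurvivalCohort,
    signature: list[str],
) -> tuple[KMCurve, KMCurve, LogrankResult, pd.Series]:
    """Median-split a cohort on signature activity and compare survival.

    Returns (KM high, KM low, log-rank result, per-sample score). The
    high group is score > median.
    """
    if cohort.expression is None:
        raise ValidationError("cohort has no expression matrix")
    score = signature_score(cohort.expression, signature)
    score = score.loc[cohort.sample_ids]
    high = median_split(score).to_numpy()
    km_high = km_estimate(cohort.time[high], cohort.event[high])
    km_low = km_estimate(cohort.time[~high], cohort.event[~high])
    lr = logrank_test(
        cohort.time[high], cohort.event[high], cohort.time[~high], cohort.event[~high]
    )
    return km_high, km_low, lr, score
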