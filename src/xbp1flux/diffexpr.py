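"""Simplified negative-binomial differential expression for two groups.

The procedure mirrors the standard count-based workflow: genes are kept
only if, in each of the two groups, at least one sample has more than five
counts; per-sample depth factors come from the median-of-ratios estimator;
each retained gene is fitted with an NB GLM (log link, log size-factor
offset, group indicator) with its own dispersion estimate; the group
coefficient is tested two-sided by Wald and p-values are adjusted by
Benjamini-Hochberg.

Dispersion is estimated per gene with no sharing of information across
genes (no shrinkage, no independent filtering, no outlier handling) — a
deliberate simplification relative to full DESeq2-style machinery, so
results are assessed through distributional properties rather than
numerical equality with that software.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._nbglm import fit_nb_glm
from .io_formats import CountMatrix, ValidationError

logger = logging.getLogger("xbp1flux")

__all__ = [
    "filter_genes",
    "size_factors",
    "nb_wald_de",
    "top_n",
    "benjamini_hochberg",
]

FILTER_THRESHOLD = 5  # strictly more than this in >=1 sample per group


def filter_genes(m: CountMatrix, per_group: bool = True) -> CountMatrix:
    """Keep genes with more than five counts in at least one sample per group.

    With ``per_group=True`` (default) each group must contribute such a
    sample; with ``per_group=False`` a single qualifying sample anywhere
    suffices.
    """
    groups = m.groups
    if len(groups) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {groups}")
    if per_group:
        keep = np.ones(len(m.gene_ids), dtype=bool)
        for g in groups:
            cols = m.samples_in_group(g)
            keep &= (m.counts[cols].to_numpy() > FILTER_THRESHOLD).any(axis=1)
    else:
        keep = (m.counts.to_numpy() > FILTER_THRESHOLD).any(axis=1)
    return CountMatrix(counts=m.counts.loc[keep].copy(), design=m.design.copy())


def size_factors(m: CountMatrix, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios depth factors, rescaled to geometric mean one.

    For each gene with all-positive counts, compute its geometric mean
    across samples; each sample's factor is the median over those genes of
    count / geometric mean. ``pseudo_reference=True`` falls back to using
    genes positive in at least half the samples (zeros excluded from the
    geometric mean) when no gene is positive everywhere.
    """
    counts = m.counts.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        if not pseudo_reference:
            raise ValidationError(
                "no gene with all-positive counts; pass pseudo_reference=True "
                "to fall back to a partial reference"
            )
        usable = (counts > 0).sum(axis=1) >= counts.shape[1] / 2
        if not usable.any():
            raise ValidationError("too many zeros even for the pseudo-reference")
        with np.errstate(divide="ignore"):
            logc = np.where(counts > 0, np.log(counts), np.nan)
        geo = np.exp(np.nanmean(logc[usable], axis=1))
        ratios = np.where(counts[usable] > 0, counts[usable] / geo[:, None], np.nan)
        factors = np.nanmedian(ratios, axis=0)
    else:
        logc = np.log(counts[positive])
        geo = np.exp(logc.mean(axis=1))
        factors = np.median(counts[positive] / geo[:, None], axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.sample_ids, name="size_factor")


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (NaN entries excluded from the family)."""
    p = np.asarray(p, dtype=float)
    adj = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return adj


def nb_wald_de(
    m: CountMatrix,
    sf: pd.Series,
    reference_group: str,
    dispersion: str = "cr",
) -> pd.DataFrame:
    """Per-gene NB Wald differential expression, treatment vs reference.

    Returns a DataFrame indexed like the input genes with columns
    ``gene, baseMean, log2FC, pvalue, padj, rank, converged``; rank is
    ascending in p over converged genes. Genes whose fit fails to converge
    get missing p and are excluded from the BH family.
    """
    groups = m.groups
    if len(groups) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {groups}")
    if reference_group not in groups:
        raise ValidationError(f"reference group {reference_group!r} not in design")
    treatment = next(g for g in groups if g != reference_group)
    sf = sf.loc[m.sample_ids]

    y = m.counts.to_numpy(dtype=float)
    assert (y.sum(axis=1) > 0).all(), "all-zero gene reached nb_wald_de; filter first"
    offset = np.log(sf.to_numpy(dtype=float))
    group_ind = np.array(
        [1.0 if m.design[s] == treatment else 0.0 for s in m.sample_ids]
    )
    X = np.column_stack([np.ones_like(group_ind), group_ind])

    fit = fit_nb_glm(y, X, offset=offset, dispersion=dispersion)
    base_mean = (y / sf.to_numpy()).mean(axis=1)
    log2fc = fit.beta[:, 1] / np.log(2.0)
    wald = fit.beta[:, 1] / fit.se[:, 1]
    # t reference with residual df: the dispersion entering the SE is
    # itself estimated from n - p residual degrees of freedom, and the
    # normal reference is markedly anti-conservative at triplicate scale
    df = y.shape[1] - X.shape[1]
    p = 2.0 * stats.t.sf(np.abs(wald), df)
    p = np.where(fit.converged, p, np.nan)
    n_failed = int((~fit.converged).sum())
    if n_failed:
        logger.warning("%d gene(s) failed to converge; excluded from BH family", n_failed)
    padj = benjamini_hochberg(p)

    res = pd.DataFrame(
        {
            "gene": m.gene_ids,
            "baseMean": base_mean,
            "log2FC": log2fc,
            "pvalue": p,
            "padj": padj,
            "dispersion": fit.alpha,
            "converged": fit.converged,
        }
    )
    order = np.argsort(np.where(np.isfinite(p), p, np.inf), kind="stable")
    rank = np.empty(len(res), dtype=float)
    rank[order] = np.arange(1, len(res) + 1)
    res["rank"] = rank
    return res


def top_n(res: pd.DataFrame, n: int, direction: str = "down") -> list[str]:
    """Top-n genes by ascending p in one fold-change direction.

    Ties in p break by |log2FC| descending, then gene id lexicographic.
    Fewer than ``n`` qualifying genes returns them all with a warning.
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    sub = res[np.isfinite(res["pvalue"])]
    sub = sub[sub["log2FC"] < 0] if direction == "down" else sub[sub["log2FC"] > 0]
    sub = sub.sort_values(
        by=["pvalue", "log2FC", "gene"],
        ascending=[True, True, True],
        key=lambda col: -col.abs() if col.name == "log2FC" else col,
    )
    genes = list(sub["gene"])
    if len(genes) < n:
        logger.warning(
            "only %d %s-regulated genes available for top-%d", len(genes), direction, n
        )
        return genes
    return genes[:n]
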