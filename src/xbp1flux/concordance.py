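"""Concordance and gene-set enrichment statistics for paired contrasts.

Three families of statistics on differential-expression results from two
perturbations (e.g. siRNA knockdown vs small-molecule inhibition of the
same pathway):

* quadrant summaries of paired log2 fold changes, with a Pearson
  correlation among the jointly down-regulated genes;
* an exact upper-tail binomial test on the overlap of two top-n gene
  lists, with success probability n / universe (the number of genes that
  entered differential testing);
* per-set enrichment of the log2 fold-change distribution, either by a
  two-sample Kolmogorov-Smirnov test (set members vs all other tested
  genes) or by a one-sided Fisher's exact test on a selected gene list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .io_formats import GeneSetCollection, ValidationError

logger = logging.getLogger("xbp1flux")

__all__ = [
    "QuadrantSummary",
    "OverlapTest",
    "quadrant_concordance",
    "topn_overlap_test",
    "ks_set_enrichment",
    "fisher_set_enrichment",
]


@dataclass
class QuadrantSummary:
    """Counts of paired-sign quadrants plus Pearson r among (down, down)."""

    down_down: int
    down_up: int
    up_down: int
    up_up: int
    pearson_r_down_down: float  # NaN if fewer than 3 genes in the quadrant
    n_paired: int

    @property
    def counts(self) -> dict[tuple[str, str], int]:
        return {
            ("down", "down"): self.down_down,
            ("down", "up"): self.down_up,
            ("up", "down"): self.up_down,
            ("up", "up"): self.up_up,
        }


@dataclass
class OverlapTest:
    """Exact binomial upper tail for the overlap of two equal-size lists."""

    k: int
    n: int
    universe: int
    p_success: float
    p_value: float


def quadrant_concordance(lfc_a: pd.Series, lfc_b: pd.Series) -> QuadrantSummary:
    """Quadrant counts of paired log2 fold changes on the shared genes.

    Genes with a zero fold change in either series are excluded. Pearson r
    is computed within the (down, down) quadrant and reported as NaN when
    fewer than three genes fall there.
    """
    shared = lfc_a.index.intersection(lfc_b.index)
    a = lfc_a.loc[shared].to_numpy(dtype=float)
    b = lfc_b.loc[shared].to_numpy(dtype=float)
    keep = (a != 0) & (b != 0) & np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    dd = (a < 0) & (b < 0)
    du = (a < 0) & (b > 0)
    ud = (a > 0) & (b < 0)
    uu = (a > 0) & (b > 0)
    if dd.sum() >= 3:
        r = float(stats.pearsonr(a[dd], b[dd]).statistic)
    else:
        r = float("nan")
    return QuadrantSummary(
        down_down=int(dd.sum()),
        down_up=int(du.sum()),
        up_down=int(ud.sum()),
        up_up=int(uu.sum()),
        pearson_r_down_down=r,
        n_paired=int(keep.sum()),
    )


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by log-space term summation."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    j = np.arange(k, n + 1)
    log_terms = (
        gammaln(n + 1)
        - gammaln(j + 1)
        - gammaln(n - j + 1)
        + j * np.log(p)
        + (n - j) * np.log1p(-p)
    )
    return float(np.exp(logsumexp(log_terms)))


def topn_overlap_test(
    list_a: list[str], list_b: list[str], universe: int
) -> OverlapTest:
    """Binomial test for the overlap of two top-n gene lists.

    Under the null that list B is an arbitrary n-subset of the universe,
    each gene of list A lands in B with probability n / universe; the
    p-value is the exact upper tail P(X >= k) at the observed overlap k.
    ``universe`` is the number of genes included in differential testing
    and must be supplied explicitly.
    """
    if len(set(list_a)) != len(list_a):
        raise ValidationError("duplicate genes in list_a")
    if len(set(list_b)) != len(list_b):
        raise ValidationError("duplicate genes in list_b")
    if len(list_a) != len(list_b):
        raise ValidationError("lists must have equal length")
    n = len(list_a)
    if universe <= n:
        raise ValidationError(f"universe ({universe}) must exceed list length ({n})")
    k = len(set(list_a) & set(list_b))
    p_success = n / universe
    p_value = min(1.0, binomial_upper_tail(k, n, p_success))
    return OverlapTest(k=k, n=n, universe=universe, p_success=p_success, p_value=p_value)


def ks_set_enrichment(
    lfc: pd.Series,
    collection: GeneSetCollection,
    min_set_size: int = 15,
) -> pd.DataFrame:
    """Per-set KS test of log2 fold changes: members vs all other genes.

    For each gene set, membership is intersected with the tested genes;
    sets with fewer than ``min_set_size`` tested members are skipped with
    a warning. The two-sided two-sample KS statistic D and its asymptotic
    p-value are reported along with a direction: the sign of the member
    median minus the non-member median fold change.
    """
    lfc = lfc[np.isfinite(lfc)]
    tested = set(lfc.index)
    rows = []
    for name in collection.names():
        members = [g for g in collection.members(name) if g in tested]
        if len(members) < min_set_size:
            logger.warning(
                "set %s: %d tested members < min_set_size=%d; skipped",
                name,
                len(members),
                min_set_size,
            )
            continue
        in_set = lfc.loc[members].to_numpy()
        out_mask = ~lfc.index.isin(members)
        out_set = lfc.to_numpy()[out_mask]
        if out_set.size == 0:
            raise ValidationError(f"set {name} leaves an empty complement")
        ks = stats.ks_2samp(in_set, out_set, alternative="two-sided", method="asymp")
        p = min(max(float(ks.pvalue), np.nextafter(0, 1)), 1.0)
        direction = float(np.sign(np.median(in_set) - np.median(out_set)))
        rows.append(
            {
                "set_name": name,
                "n_in_set": len(members),
                "ks_D": float(ks.statistic),
                "p_value": p,
                "neg_log10_p": -np.log10(p),
                "direction": direction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["set_name", "n_in_set", "ks_D", "p_value", "neg_log10_p", "direction"],
    ).sort_values("p_value", kind="stable", ignore_index=True)


def fisher_set_enrichment(
    selected: list[str],
    collection: GeneSetCollection,
    universe_genes: list[str],
) -> pd.DataFrame:
    """One-sided Fisher's exact enrichment of a selected gene list per set.

    Builds the 2x2 table (in set x selected) over the universe and tests
    for over-representation (alternative='greater'). Sets disjoint from
    the universe are skipped.
    """
    universe = list(dict.fromkeys(universe_genes))
    uset = set(universe)
    sel = set(selected)
    if not sel.issubset(uset):
        raise ValidationError("selected genes must be a subset of the universe")
    rows = []
    for name in collection.names():
        members = set(collection.members(name)) & uset
        if not members:
            logger.warning("set %s disjoint from universe; skipped", name)
            continue
        a = len(members & sel)
        b = len(members - sel)
        c = len(sel - members)
        d = len(uset) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        p = min(max(float(p), np.nextafter(0, 1)), 1.0)
        rows.append(
            {
                "set_name": name,
                "n_in_set": len(members),
                "n_selected_in_set": a,
                "odds_ratio": float(odds),
                "p_value": p,
                "neg_log10_p": -np.log10(p),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "n_in_set",
            "n_selected_in_set",
            "odds_ratio",
            "p_value",
            "neg_log10_p",
        ],
    ).sort_values("p_value", kind="stable", ignore_index=True)
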