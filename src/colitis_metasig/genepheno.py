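"""Rank genes by correlation with a per-animal behavioral metric.

Average rear duration (time spent rearing / number of rears) tracks colonic
state; correlating each gene's normalized expression with this metric across
animals and reporting the top-k positively and negatively correlated genes
links transcriptional perturbation to the behavioral pain surrogate.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationRanking", "correlate_genes"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CorrelationRanking:
    """Per-gene correlation table plus the two disjoint top-k sign lists.

    ``table`` has columns r, n, p indexed by gene; the top lists are sorted
    by |r| descending within their sign, ties broken by gene id. Genes with
    zero expression variance are skipped and recorded in ``skipped``.
    """

    table: pd.DataFrame
    top_positive: pd.DataFrame
    top_negative: pd.DataFrame
    skipped: list[str]
    method: str
    k: int


def correlate_genes(
    expr: pd.DataFrame,
    phenotype: pd.Series,
    gene_subset: Iterable[str] | None = None,
    method: Literal["pearson", "spearman"] = "pearson",
    k: int = 25,
) -> CorrelationRanking:
    """Correlate each gene's expression with a per-animal phenotype.

    ``expr`` is genes x animals (normalized expression); ``phenotype`` is
    indexed by animal id. Animals with missing phenotype are dropped
    (pairwise-complete); at least 3 complete pairs are required. Pearson is
    the default; Spearman ranks both variables first.
    """
    if gene_subset is not None:
        gene_subset = list(gene_subset)
        missing = sorted(set(gene_subset) - set(expr.index))
        if missing:
            raise ValueError(f"genes not in expression matrix: {missing}")
        expr = expr.loc[gene_subset]

    mismatched = sorted(set(phenotype.index) ^ set(expr.columns))
    if mismatched:
        raise ValueError(f"animal ids not shared by matrix and phenotype: {mismatched}")
    phenotype = phenotype.loc[expr.columns]

    complete = phenotype.notna()
    n = int(complete.sum())
    if n < 3:
        raise ValueError(f"only {n} animals with non-missing phenotype (need >= 3)")
    if n < len(phenotype):
        logger.info("dropping %d animals with missing phenotype", len(phenotype) - n)
    x = expr.loc[:, complete.to_numpy()].to_numpy(dtype=float)
    y = phenotype[complete].to_numpy(dtype=float)

    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 1, x)
        y = stats.rankdata(y)

    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = float(np.sqrt((yc**2).sum()))
    ok = (sx > 0) & (sy > 0)
    skipped = expr.index[~ok].tolist()
    if skipped:
        logger.info("skipping %d zero-variance genes", len(skipped))

    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)

    # p from the t-distribution with n-2 df; r = +/-1 gives p = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 0))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2 * stats.t.sf(np.abs(t), n - 2))

    table = pd.DataFrame({"r": r, "n": n, "p": p}, index=expr.index)[ok]
    table = table.copy()
    table["abs_r"] = table["r"].abs()

    def _top(sub: pd.DataFrame) -> pd.DataFrame:
        sub = sub.sort_index(kind="mergesort")  # gene-id tie break
        sub = sub.sort_values("abs_r", ascending=False, kind="mergesort")
        return sub.head(k).drop(columns="abs_r")

    top_positive = _top(table[table["r"] > 0])
    top_negative = _top(table[table["r"] < 0])
    return CorrelationRanking(
        table=table.drop(columns="abs_r"),
        top_positive=top_positive,
        top_negative=top_negative,
        skipped=skipped,
        method=method,
        k=k,
    )
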