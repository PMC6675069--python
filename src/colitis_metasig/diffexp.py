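"""Two-group negative-binomial differential expression.

Genes not flagged present in every sample of their higher-expressing group
are eliminated; fold change is the ratio of arithmetic mean normalized
expression between groups; significance comes from an exact conditional NB
test: conditioning on the total (normalized) count of a gene, the p-value
sums the probabilities of all splits between the two groups that are no
more likely than the observed one, under group-wise NB laws sharing a
per-gene dispersion. Genes with fold change >= 1.5 in either direction and
p <= 0.01 are called significantly perturbed; no multiple-testing
correction is applied to this selection.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CountMatrix, flag_presence, normalize

__all__ = [
    "DEConfig",
    "estimate_dispersion",
    "eliminate_absent",
    "nb_exact_test",
    "run_de",
]

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
ENUM_LIMIT = 10_000  # max conditioned-support size before normal approximation


@dataclasses.dataclass
class DEConfig:
    """Selection thresholds and dispersion handling for the DE call."""

    fc_threshold: float = 1.5
    p_threshold: float = 0.01
    dispersion_method: Literal["pooled_mom", "per_gene_mom"] = "pooled_mom"
    dispersion_floor: float = DISPERSION_FLOOR
    min_reads: int = 10
    enum_limit: int = ENUM_LIMIT

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0 or self.p_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.dispersion_floor < 0:
            raise ValueError("dispersion_floor must be >= 0")


def _group_columns(groups: pd.Series, group_a: str, group_b: str) -> tuple[list, list]:
    cols_a = groups.index[groups == group_a].tolist()
    cols_b = groups.index[groups == group_b].tolist()
    if not cols_a or not cols_b:
        empty = group_a if not cols_a else group_b
        raise ValueError(f"group {empty!r} has no samples")
    return cols_a, cols_b


def eliminate_absent(
    m: CountMatrix,
    mask: pd.DataFrame,
    normalized: pd.DataFrame,
    group_a: str,
    group_b: str,
) -> pd.Series:
    """Boolean per-gene 'tested' flag.

    A gene is retained iff it is flagged present in every sample of
    whichever group has the higher arithmetic mean normalized expression for
    that gene (ties go to group A's mask).
    """
    if m.groups is None:
        raise ValueError("count matrix has no group labels")
    cols_a, cols_b = _group_columns(m.groups, group_a, group_b)
    mean_a = normalized[cols_a].mean(axis=1)
    mean_b = normalized[cols_b].mean(axis=1)
    present_a = mask[cols_a].all(axis=1)
    present_b = mask[cols_b].all(axis=1)
    return pd.Series(
        np.where(mean_a >= mean_b, present_a, present_b),
        index=m.genes,
        name="tested",
    )


def estimate_dispersion(
    normalized: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    method: Literal["pooled_mom", "per_gene_mom"] = "pooled_mom",
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Method-of-moments NB dispersion from within-group variability.

    Per gene, the within-group residual variance s2 (pooled over the two
    groups) and the overall mean mu give alpha = (s2 - mu) / mu^2.
    ``pooled_mom`` (default) fits one alpha for all genes by least squares
    through the origin of (s2 - mu) on mu^2, which is far more stable at
    n = 5 per group; ``per_gene_mom`` keeps the per-gene estimates.
    Negative estimates are clamped to ``floor``.
    """
    cols_a, cols_b = _group_columns(groups, group_a, group_b)
    xa, xb = normalized[cols_a].to_numpy(), normalized[cols_b].to_numpy()
    n_a, n_b = xa.shape[1], xb.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 samples per group to estimate dispersion")
    rss = ((xa - xa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xb - xb.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = rss / (n_a + n_b - 2)
    mu = np.concatenate([xa, xb], axis=1).mean(axis=1)

    # denominator corrected for E[mu_hat^2] = mu^2 + sigma^2/n (guarded so a
    # noisy s2 cannot collapse it)
    n_tot = n_a + n_b
    denom = mu**2 - s2 / n_tot
    denom = np.where(denom > 0.5 * mu**2, denom, mu**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_gene = (s2 - mu) / denom
    per_gene = np.where(np.isfinite(per_gene), per_gene, floor)

    if method == "per_gene_mom":
        n_clamped = int((per_gene < floor).sum())
        if n_clamped:
            logger.info("dispersion clamped to floor for %d genes", n_clamped)
        alpha = np.maximum(per_gene, floor)
    else:
        # average the per-gene moment ratios over well-expressed genes: each
        # ratio has bounded variance ~2*alpha^2/df there, so the pooled value
        # is stable, unlike a mu^4-weighted fit dominated by a few top genes
        ok = mu >= 20
        if not ok.any():
            ok = mu > 0
        pooled = float(per_gene[ok].mean()) if ok.any() else floor
        if pooled < floor:
            logger.info("pooled dispersion %.3g clamped to floor", pooled)
        alpha = np.full(len(mu), max(pooled, floor))
    return pd.Series(alpha, index=normalized.index, name="dispersion")


def nb_exact_test(
    sum_a: float,
    sum_b: float,
    n_a: int,
    n_b: int,
    mu: float,
    alpha: float,
    enum_limit: int = ENUM_LIMIT,
) -> float:
    """Exact conditional NB test on the split of the total count.

    ``sum_a``/``sum_b`` are the (normalized, hence common-scale) group count
    sums, rounded internally to integers; ``mu`` is the common per-sample
    mean under the null and ``alpha`` the shared dispersion. Conditioning on
    K = ka + kb, the two-sided p-value sums P(K_A = k | K) over every split
    k whose probability does not exceed the observed split's. When the
    support K + 1 exceeds ``enum_limit``, a normal approximation to the
    conditional law (with continuity correction) is used instead.
    """
    ka, kb = int(round(sum_a)), int(round(sum_b))
    K = ka + kb
    if K == 0:
        return 1.0
    mu = max(mu, 1e-12)

    if K + 1 <= enum_limit:
        k = np.arange(K + 1)
        offset = 0
    else:
        # window the support around the conditional mean: +/- 12 conditional
        # SDs holds all non-negligible mass, and the window is widened to
        # cover the observed split so extreme outcomes stay in range
        va = n_a * (mu + alpha * mu**2)
        vb = n_b * (mu + alpha * mu**2)
        ma = n_a * mu
        cond_mean = ma + va / (va + vb) * (K - n_a * mu - n_b * mu)
        cond_sd = math.sqrt(va * vb / (va + vb))
        lo = max(0, min(int(cond_mean - 12 * cond_sd), ka - 5))
        hi = min(K, max(int(cond_mean + 12 * cond_sd) + 1, ka + 5))
        k = np.arange(lo, hi + 1)
        offset = lo

    if alpha < 1e-10:
        pa = stats.poisson.logpmf(k, n_a * mu)
        pb = stats.poisson.logpmf(K - k, n_b * mu)
    else:
        r = 1.0 / alpha
        p = r / (r + mu)
        pa = stats.nbinom.logpmf(k, n_a * r, p)
        pb = stats.nbinom.logpmf(K - k, n_b * r, p)
    logjoint = pa + pb
    logjoint -= logjoint.max()
    joint = np.exp(logjoint)
    total = joint.sum()
    if not np.isfinite(total) or total <= 0:
        return 1.0
    pobs = joint[ka - offset]
    # tolerance absorbs float ties so the modal split yields p = 1
    return float(min(joint[joint <= pobs * (1 + 1e-12)].sum() / total, 1.0))


def run_de(
    m: CountMatrix,
    group_a: str,
    group_b: str,
    cfg: DEConfig | None = None,
    normalized: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full per-gene DE table for group_b vs group_a.

    Columns: mean_a, mean_b, fc (magnitude >= 1), direction ("up" = higher
    in group_b), p, tested, significant. ``significant`` requires the gene
    to be tested, fc >= fc_threshold (inclusive) and p <= p_threshold
    (inclusive).
    """
    cfg = cfg or DEConfig()
    if normalized is None:
        normalized, _ = normalize(m, min_reads=cfg.min_reads)
    mask = flag_presence(m, cfg.min_reads)
    tested = eliminate_absent(m, mask, normalized, group_a, group_b)
    cols_a, cols_b = _group_columns(m.groups, group_a, group_b)
    xa, xb = normalized[cols_a], normalized[cols_b]
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)

    alpha = estimate_dispersion(
        normalized, m.groups, group_a, group_b, cfg.dispersion_method, cfg.dispersion_floor
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        hi = np.maximum(mean_a, mean_b)
        lo = np.minimum(mean_a, mean_b)
        fc = np.where(lo > 0, hi / lo, np.where(hi > 0, np.inf, 1.0))
    direction = np.where(mean_b >= mean_a, "up", "down")

    mu = (xa.sum(axis=1) + xb.sum(axis=1)) / (len(cols_a) + len(cols_b))
    sums_a, sums_b = xa.sum(axis=1).to_numpy(), xb.sum(axis=1).to_numpy()
    pvals = np.full(len(m.genes), np.nan)
    tested_arr = tested.to_numpy()
    mu_arr = mu.to_numpy()
    alpha_arr = alpha.to_numpy()
    for i in np.flatnonzero(tested_arr):
        pvals[i] = nb_exact_test(
            sums_a[i],
            sums_b[i],
            len(cols_a),
            len(cols_b),
            mu_arr[i],
            alpha_arr[i],
            cfg.enum_limit,
        )

    significant = tested_arr & (fc >= cfg.fc_threshold) & (pvals <= cfg.p_threshold)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fc": fc,
            "direction": direction,
            "p": pvals,
            "tested": tested_arr,
            "significant": significant,
        },
        index=m.genes,
    )
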