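"""Group-comparison decision procedure: outlier exclusion and test selection.

Data points 2 or more (population) standard deviations from their group
mean, and/or points flagged by a one-pass two-sided Grubbs' test, are
excluded before analysis. Two-group comparisons use an unpaired t-test
unless the variance-ratio F-test rejects equality of variances, in which
case the Mann-Whitney test is used. Factorial designs use ANOVA (with
Tukey post hoc pairwise tests on significant effects) gated by the
Brown-Forsythe homogeneity test, falling back to Kruskal-Wallis on the
group cells; repeated-measures designs apply the Greenhouse-Geisser
epsilon correction to within-factor degrees of freedom. All tests are
two-tailed at alpha = 0.05 unless configured otherwise.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatsConfig",
    "Exclusion",
    "ComparisonReport",
    "grubbs_critical",
    "exclude_outliers",
    "compare_two_groups",
    "compare_factorial",
    "compare_repeated_measures",
]


@dataclasses.dataclass
class StatsConfig:
    alpha: float = 0.05  # two-tailed significance threshold, set a priori
    outlier_sd: float = 2.0
    grubbs_alpha: float = 0.05
    iterative_grubbs: bool = False
    gate_alpha: float | None = None  # variance-gate alpha; defaults to alpha

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")

    @property
    def effective_gate_alpha(self) -> float:
        return self.alpha if self.gate_alpha is None else self.gate_alpha


@dataclasses.dataclass
class Exclusion:
    group: str
    index: int
    value: float
    rules: list[str]  # subset of {"sd", "grubbs"}


@dataclasses.dataclass
class ComparisonReport:
    test: str
    statistic: float
    p: float
    branch: dict  # variance-gate outcome that selected the test
    exclusions: list[Exclusion] = dataclasses.field(default_factory=list)
    posthoc: pd.DataFrame | None = None
    effects: pd.DataFrame | None = None
    flags: list[str] = dataclasses.field(default_factory=list)


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G_crit for sample size n."""
    if n < 3:
        raise ValueError("Grubbs' test requires n >= 3")
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def _grubbs_flag(x: np.ndarray, alpha: float) -> int | None:
    """Index of the single Grubbs outlier, if the test flags one."""
    n = len(x)
    s = x.std(ddof=1)
    if s == 0:
        return None
    dev = np.abs(x - x.mean())
    i = int(dev.argmax())
    if dev[i] / s > grubbs_critical(n, alpha):
        return i
    return None


def _exclude_group(x: np.ndarray, cfg: StatsConfig) -> list[tuple[int, list[str]]]:
    out: dict[int, list[str]] = {}
    # 2-SD rule: population SD with the point included, inclusive at the bound.
    # (With the sample SD no point in a small group can ever reach 2 SDs.)
    sd = x.std(ddof=0)
    if sd > 0:
        z = np.abs(x - x.mean()) / sd
        for i in np.flatnonzero(z >= cfg.outlier_sd):
            out.setdefault(int(i), []).append("sd")
    if len(x) >= 3:
        remaining = list(range(len(x)))
        while True:
            i = _grubbs_flag(x[remaining], cfg.grubbs_alpha)
            if i is None:
                break
            out.setdefault(remaining[i], []).append("grubbs")
            if not cfg.iterative_grubbs:
                break
            del remaining[i]
    else:
        warnings.warn("group too small for Grubbs' test; SD rule only", stacklevel=2)
    return sorted((i, rules) for i, rules in out.items())


def exclude_outliers(
    values: dict[str, np.ndarray] | pd.Series, cfg: StatsConfig | None = None
) -> tuple[dict[str, np.ndarray], list[Exclusion]]:
    """Apply the 2-SD and Grubbs exclusion rules within each group.

    ``values`` is a mapping group -> 1-D array (or a Series whose index is
    the group label). A point is excluded if either rule flags it (the rules
    are combined with OR); every exclusion records which rule(s) fired.
    """
    cfg = cfg or StatsConfig()
    if isinstance(values, pd.Series):
        values = {g: sub.to_numpy(dtype=float) for g, sub in values.groupby(level=0)}
    kept: dict[str, np.ndarray] = {}
    exclusions: list[Exclusion] = []
    for g, arr in values.items():
        arr = np.asarray(arr, dtype=float)
        flagged = _exclude_group(arr, cfg)
        drop = {i for i, _ in flagged}
        for i, rules in flagged:
            exclusions.append(Exclusion(str(g), i, float(arr[i]), rules))
        kept[g] = arr[[i for i in range(len(arr)) if i not in drop]]
    return kept, exclusions


def variance_ratio_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided F-test for equality of two variances."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return float("nan"), 1.0
    if vb == 0 or va == 0:
        return float("inf"), 0.0
    f = va / vb
    p = 2 * min(
        stats.f.cdf(f, len(a) - 1, len(b) - 1),
        stats.f.sf(f, len(a) - 1, len(b) - 1),
    )
    return float(f), float(min(p, 1.0))


def compare_two_groups(
    a: np.ndarray,
    b: np.ndarray,
    cfg: StatsConfig | None = None,
    exclude: bool = True,
    labels: tuple[str, str] = ("a", "b"),
) -> ComparisonReport:
    """F-test gated two-group comparison: t-test or Mann-Whitney."""
    cfg = cfg or StatsConfig()
    exclusions: list[Exclusion] = []
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if exclude:
        kept, exclusions = exclude_outliers({labels[0]: a, labels[1]: b}, cfg)
        a, b = kept[labels[0]], kept[labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group after exclusion")

    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return ComparisonReport(
            test="degenerate",
            statistic=float("nan"),
            p=1.0,
            branch={"f_stat": float("nan"), "f_p": 1.0, "equal_variances": True},
            exclusions=exclusions,
            flags=["zero variance in both groups with equal means"],
        )

    f_stat, f_p = variance_ratio_test(a, b)
    equal_var = f_p >= cfg.effective_gate_alpha
    branch = {"f_stat": f_stat, "f_p": f_p, "equal_variances": bool(equal_var)}
    if equal_var:
        stat, p = stats.ttest_ind(a, b, equal_var=True)
        test = "t-test"
    else:
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (len(a) <= 20 and len(b) <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = res.statistic, res.pvalue
        test = "mann-whitney"
    return ComparisonReport(
        test=test, statistic=float(stat), p=float(p), branch=branch, exclusions=exclusions
    )


def _cells(table: pd.DataFrame, value: str, factors: list[str]) -> dict[tuple, np.ndarray]:
    cells = {}
    levels = [sorted(table[f].unique()) for f in factors]
    from itertools import product

    for combo in product(*levels):
        sel = np.ones(len(table), dtype=bool)
        for f, lv in zip(factors, combo):
            sel &= (table[f] == lv).to_numpy()
        vals = table.loc[sel, value].to_numpy(dtype=float)
        if len(vals) == 0:
            raise ValueError(f"empty cell {dict(zip(factors, combo))}")
        cells[combo] = vals
    return cells


def compare_factorial(
    table: pd.DataFrame,
    value: str,
    factors: list[str],
    cfg: StatsConfig | None = None,
    exclude: bool = False,
) -> ComparisonReport:
    """Brown-Forsythe gated factorial comparison: ANOVA (+ Tukey) or Kruskal-Wallis.

    ``table`` is tidy (one row per observation) with ``value`` and one or two
    ``factors`` columns. Homogeneity of the factor-cell variances is checked
    with the Brown-Forsythe test (Levene on medians); if it holds, a
    factorial ANOVA is fitted (type-II sums of squares) and Tukey pairwise
    comparisons are run across cells when any effect is significant; if not,
    a Kruskal-Wallis test on the cells is reported instead.
    """
    cfg = cfg or StatsConfig()
    table = table.copy()
    exclusions: list[Exclusion] = []
    if exclude:
        cell_label = table[factors].astype(str).agg("/".join, axis=1)
        kept_rows = []
        for g, sub in table.groupby(cell_label.to_numpy()):
            arr = sub[value].to_numpy(dtype=float)
            flagged = _exclude_group(arr, cfg)
            drop = {i for i, _ in flagged}
            for i, rules in flagged:
                exclusions.append(Exclusion(str(g), i, float(arr[i]), rules))
            kept_rows.append(sub.iloc[[i for i in range(len(sub)) if i not in drop]])
        table = pd.concat(kept_rows, ignore_index=True)

    cells = _cells(table, value, factors)
    vals = table[value].to_numpy(dtype=float)
    if vals.var(ddof=0) == 0:
        return ComparisonReport(
            test="degenerate",
            statistic=float("nan"),
            p=1.0,
            branch={"bf_stat": float("nan"), "bf_p": 1.0, "homogeneous": True},
            exclusions=exclusions,
            flags=["constant response"],
        )

    bf_stat, bf_p = stats.levene(*cells.values(), center="median")
    homogeneous = bf_p >= cfg.effective_gate_alpha
    branch = {"bf_stat": float(bf_stat), "bf_p": float(bf_p), "homogeneous": bool(homogeneous)}

    if not homogeneous:
        h, p = stats.kruskal(*cells.values())
        return ComparisonReport(
            test="kruskal-wallis",
            statistic=float(h),
            p=float(p),
            branch=branch,
            exclusions=exclusions,
        )

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table.rename(columns={value: "_y"})
    terms = " * ".join(f"C(Q('{f}'))" for f in factors)
    model = smf.ols(f"_y ~ {terms}", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    effects = anova.rename(index=lambda s: s.replace("C(Q('", "").replace("'))", ""))

    # headline statistic: the highest-order effect (interaction for two-way)
    head = effects.index[-2] if "Residual" in effects.index else effects.index[-1]
    stat = float(effects.loc[head, "F"])
    p = float(effects.loc[head, "PR(>F)"])

    posthoc = None
    if (effects.drop(index="Residual", errors="ignore")["PR(>F)"] < cfg.alpha).any():
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        cell_label = table[factors].astype(str).agg("/".join, axis=1)
        tk = pairwise_tukeyhsd(table[value].to_numpy(dtype=float), cell_label.to_numpy(), alpha=cfg.alpha)
        posthoc = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
    return ComparisonReport(
        test="anova",
        statistic=stat,
        p=p,
        branch=branch,
        exclusions=exclusions,
        posthoc=posthoc,
        effects=effects,
    )


def compare_repeated_measures(
    table: pd.DataFrame,
    value: str,
    within: str,
    subject: str,
    between: str | None = None,
    cfg: StatsConfig | None = None,
) -> ComparisonReport:
    """Repeated-measures (or mixed) ANOVA with Greenhouse-Geisser correction.

    Used for time-course data (e.g. daily body weights): the within factor's
    degrees of freedom are corrected by the Greenhouse-Geisser epsilon to
    guard against sphericity violations. With ``between`` set, a mixed
    design (group x time) is fitted.
    """
    cfg = cfg or StatsConfig()
    import pingouin as pg

    if between is None:
        aov = pg.rm_anova(data=table, dv=value, within=within, subject=subject, correction=True)
        row = aov.iloc[0]
        p = (
            float(row["p_GG_corr"])
            if "p_GG_corr" in aov.columns and not pd.isna(row.get("p_GG_corr"))
            else float(row["p_unc"])
        )
        eps = float(row["eps"]) if "eps" in aov.columns else float("nan")
        branch = {"gg_epsilon": eps, "gg_corrected": "p_GG_corr" in aov.columns}
        return ComparisonReport(
            test="rm-anova", statistic=float(row["F"]), p=p, branch=branch, effects=aov
        )
    aov = pg.mixed_anova(
        data=table, dv=value, within=within, subject=subject, between=between, correction=True
    )
    inter = aov[aov["Source"] == "Interaction"].iloc[0]
    eps = (
        float(aov["eps"].dropna().iloc[0])
        if "eps" in aov.columns and aov["eps"].notna().any()
        else float("nan")
    )
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    return ComparisonReport(
        test="mixed-anova",
        statistic=float(inter["F"]),
        p=float(inter[p_col]),
        branch={"gg_epsilon": eps},
        effects=aov,
    )
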