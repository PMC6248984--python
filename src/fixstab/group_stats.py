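"""Cohort-level inference: paired comparisons, correlations, power.

The study design is fully within-subject — every participant is measured
under all three viewing conditions (DEF, N-DEF, BF) in both phases — so
condition contrasts are paired t-tests on the per-participant differences,
with a Bonferroni family of m = 3 (the three condition pairs).  Adjusted
p-values are presented as min(1, m·p).  Associations with the clinical
covariates use Pearson's product–moment correlation.  The a priori sample
size for a within-factors repeated-measures ANOVA is computed from the
noncentral-F distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CONDITION_PAIRS",
    "PairedComparison",
    "PowerSpec",
    "paired_t",
    "bonferroni_adjust",
    "pearson_r",
    "rm_anova_power",
    "required_n_rm_anova",
    "compare_conditions",
]

#: The three condition contrasts reported by the analysis.
CONDITION_PAIRS = (("DEF", "N-DEF"), ("DEF", "BF"), ("N-DEF", "BF"))


@dataclass(frozen=True)
class PairedComparison:
    """Result of one paired t-test, optionally Bonferroni-adjusted."""

    metric: str
    pair: tuple[str, str]
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    df: int
    p_raw: float
    p_adjusted: float | None = None
    m: int | None = None
    n: int = 0
    degenerate: bool = False


@dataclass(frozen=True)
class PowerSpec:
    """Inputs (and output) of the repeated-measures sample-size search.

    Parameters
    ----------
    f : float
        Cohen's effect size f (0.25 is the conventional "medium").
    alpha, power : float
        Type-I error rate and target power.
    m : int
        Number of repeated measurements (3 viewing conditions here).
    eps : float
        Non-sphericity correction ε in (0, 1]; multiplies both F-test
        degrees of freedom and the noncentrality.
    corr_rm : float
        Correlation among repeated measures; the noncentrality scales
        with 1/(1 − corr_rm).
    n_required : int or None
        Filled in by :func:`required_n_rm_anova`.
    """

    f: float = 0.25
    alpha: float = 0.05
    power: float = 0.80
    m: int = 3
    eps: float = 0.5
    corr_rm: float = 0.5
    n_required: int | None = None

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("effect size f must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.m < 2:
            raise ValueError("need at least 2 repeated measurements")
        if not 0 < self.eps <= 1:
            raise ValueError("eps must lie in (0, 1]")
        if not -1 < self.corr_rm < 1:
            raise ValueError("corr_rm must lie in (-1, 1)")


def paired_t(
    a: Sequence[float],
    b: Sequence[float],
    *,
    metric: str = "",
    pair: tuple[str, str] = ("a", "b"),
) -> PairedComparison:
    """Classical two-sided paired t-test on participant-matched vectors.

    Zero-variance differences (including identical vectors) are reported
    as t = 0, p = 1 with the degenerate flag rather than an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-d and equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    base = dict(
        metric=metric, pair=tuple(pair),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        df=n - 1, n=n,
    )
    if np.std(d, ddof=1) == 0.0:
        return PairedComparison(t=0.0, p_raw=1.0, degenerate=True, **base)
    res = stats.ttest_rel(a, b)
    return PairedComparison(t=float(res.statistic), p_raw=float(res.pvalue), **base)


def bonferroni_adjust(p_values: Iterable[float], m: int) -> list[float]:
    """Bonferroni adjustment: each p multiplied by the family size, capped at 1."""
    ps = [float(p) for p in p_values]
    if m < len(ps):
        raise ValueError("family size m must be >= the number of p-values")
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    return [min(1.0, m * p) for p in ps]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Pearson product–moment r with its two-sided p (t transform, n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-d and equal length")
    n = x.size
    if n < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("correlation undefined: an input has zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n


def rm_anova_power(n: int, spec: PowerSpec) -> float:
    """Power of the within-factors repeated-measures F test at sample size n.

    Noncentrality λ = f²·n·m·ε/(1 − corr_rm); numerator df (m−1)·ε and
    denominator df (n−1)·(m−1)·ε, with the critical value from the central
    F and the power from the noncentral F.
    """
    if n < 2:
        return 0.0
    lam = spec.f**2 * n * spec.m * spec.eps / (1.0 - spec.corr_rm)
    df1 = (spec.m - 1) * spec.eps
    df2 = (n - 1) * (spec.m - 1) * spec.eps
    fcrit = stats.f.isf(spec.alpha, df1, df2)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def required_n_rm_anova(spec: PowerSpec, n_cap: int = 10**6) -> PowerSpec:
    """Smallest n whose repeated-measures F-test power reaches the target.

    Monotone upward search from n = 2; raises ``ValueError`` if the target
    is unattainable below ``n_cap``.
    """
    n = 2
    while n <= n_cap:
        if rm_anova_power(n, spec) >= spec.power:
            return replace(spec, n_required=n)
        n += 1
    raise ValueError(f"target power {spec.power} not reached below n = {n_cap}")


def compare_conditions(
    table: pd.DataFrame,
    metrics: Sequence[str],
    pairs: Sequence[tuple[str, str]] = CONDITION_PAIRS,
    *,
    allow_missing: bool = False,
) -> pd.DataFrame:
    """Pairwise condition comparisons of cohort metrics, per phase.

    ``table`` has one row per (participant, condition, phase) with metric
    columns.  For every metric × phase the per-condition mean ± SD and the
    Bonferroni-adjusted paired p for each condition pair (family size
    m = len(pairs)) are returned in a long-format frame.

    With ``allow_missing=False`` (default) any participant missing a cell
    raises ``ValueError`` listing the missing (participant, condition)
    combinations; with ``allow_missing=True`` each pair uses its
    pairwise-complete participants.
    """
    required = {"participant", "condition", "phase"}
    if not required.issubset(table.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    dup = table.duplicated(subset=["participant", "condition", "phase"])
    if dup.any():
        raise ValueError("duplicate (participant, condition, phase) rows")
    m = len(pairs)
    conditions = sorted({c for pr in pairs for c in pr})
    rows = []
    for phase, sub in table.groupby("phase", sort=False):
        wide = {
            cond: sub[sub["condition"] == cond].set_index("participant")
            for cond in conditions
        }
        if not allow_missing:
            participants = set(sub["participant"])
            missing = [
                (p, c)
                for c in conditions
                for p in sorted(participants - set(wide[c].index))
            ]
            if missing:
                raise ValueError(f"missing cohort cells (participant, condition): {missing}")
        for metric in metrics:
            if metric not in table.columns:
                raise ValueError(f"metric column {metric!r} not in cohort table")
            stats_by_cond = {
                c: (float(wide[c][metric].mean()), float(wide[c][metric].std(ddof=1)))
                for c in conditions
            }
            comps = []
            for ca, cb in pairs:
                common = wide[ca].index.intersection(wide[cb].index)
                if len(common) < 2:
                    # pairwise-complete set too small for a paired test
                    comps.append(PairedComparison(
                        metric=metric, pair=(ca, cb),
                        mean_a=np.nan, mean_b=np.nan, sd_a=np.nan, sd_b=np.nan,
                        t=np.nan, df=max(0, len(common) - 1), p_raw=np.nan,
                        n=len(common), degenerate=True,
                    ))
                    continue
                comp = paired_t(
                    wide[ca].loc[common, metric],
                    wide[cb].loc[common, metric],
                    metric=metric,
                    pair=(ca, cb),
                )
                comps.append(comp)
            adj = bonferroni_adjust(
                [0.0 if np.isnan(c.p_raw) else c.p_raw for c in comps], m=m
            )
            adj = [np.nan if np.isnan(c.p_raw) else a for c, a in zip(comps, adj)]
            for comp, p_adj in zip(comps, adj):
                row = {
                    "phase": phase,
                    "metric": metric,
                    "condition_a": comp.pair[0],
                    "condition_b": comp.pair[1],
                    "mean_a": comp.mean_a,
                    "sd_a": comp.sd_a,
                    "mean_b": comp.mean_b,
                    "sd_b": comp.sd_b,
                    "n_pairs": comp.n,
                    "t": comp.t,
                    "df": comp.df,
                    "p_raw": comp.p_raw,
                    "p_adjusted": p_adj,
                    "m": m,
                }
                for c in conditions:
                    row[f"mean_{c}"] = stats_by_cond[c][0]
                    row[f"sd_{c}"] = stats_by_cond[c][1]
                rows.append(row)
    return pd.DataFrame(rows)
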