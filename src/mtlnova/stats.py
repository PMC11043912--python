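"""Statistical machinery for group comparisons.

Covers everything the study design needs: 2x2 odds ratios with Woolf
intervals (Haldane-Anscombe corrected on zero cells), binary logistic and
cumulative-logit proportional-odds regression with Wald intervals,
Kruskal-Wallis with Dunn's pooled-rank post-hoc under Bonferroni
correction, Mann-Whitney U, Pearson chi-square, median/IQR descriptives,
median-split logistic models and linear (OLS) score models.

Model fitting is delegated to statsmodels / scipy; the 2x2 arithmetic and
Dunn's test are implemented directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

__all__ = [
    "ORResult",
    "GroupTestResult",
    "MeanDiffResult",
    "odds_ratio_2x2",
    "binary_logistic",
    "proportional_odds",
    "kruskal_wallis",
    "mann_whitney",
    "chi_square_independence",
    "median_iqr",
    "median_split_logistic",
    "linear_score_model",
]

Z95 = 1.96  # normal 95 % quantile, matching the printed CI arithmetic


@dataclass(frozen=True)
class ORResult:
    """Odds ratio with log-scale SE and 95 % CI.

    ``method`` is ``"woolf_2x2"`` or ``"wald_logistic"``; ``corrected`` is
    True when a 0.5 zero-cell (Haldane-Anscombe) correction was applied,
    which also marks separation fallbacks in regression fits.
    """

    estimate: float
    log_se: float
    ci_low: float
    ci_high: float
    method: str
    corrected: bool = False
    contrast: str = ""
    p_value: float | None = None


@dataclass(frozen=True)
class GroupTestResult:
    """Omnibus test with optional Bonferroni-adjusted pairwise follow-ups."""

    statistic: float
    df: int
    p_value: float
    pairwise: tuple = ()
    adjustment: str = "bonferroni"


@dataclass(frozen=True)
class MeanDiffResult:
    """Per-group mean difference vs reference from an OLS dummy model."""

    contrast: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float


def odds_ratio_2x2(a: float, b: float, c: float, d: float) -> ORResult:
    """Woolf odds ratio for the 2x2 table [[a, b], [c, d]].

    a/b are event/non-event counts in the exposed group, c/d in the
    reference group. estimate = ad/bc, SE(ln OR) = sqrt(1/a+1/b+1/c+1/d),
    CI = exp(ln OR -/+ 1.96 SE). Any zero cell triggers the
    Haldane-Anscombe +0.5 correction on all four cells.
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be >= 0")
    if a + b == 0 or c + d == 0:
        raise ValueError("a margin of the 2x2 table is zero; OR undefined")
    corrected = any(x == 0 for x in cells)
    if corrected:
        a, b, c, d = (x + 0.5 for x in cells)
    estimate = (a * d) / (b * c)
    log_se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(estimate)
    z = log_or / log_se
    p = 2 * sps.norm.sf(abs(z))
    return ORResult(
        estimate=estimate,
        log_se=log_se,
        ci_low=math.exp(log_or - Z95 * log_se),
        ci_high=math.exp(log_or + Z95 * log_se),
        method="woolf_2x2",
        corrected=corrected,
        p_value=float(p),
    )


def _as_groups(group, reference: str) -> tuple[np.ndarray, list[str]]:
    group = np.asarray([str(g) for g in group])
    labels = sorted(set(group))
    if reference not in labels:
        raise ValueError(f"reference group {reference!r} not present")
    others = [g for g in labels if g != reference]
    if not others:
        raise ValueError("need at least two groups")
    return group, others


def binary_logistic(
    group, outcome, reference: str
) -> list[ORResult]:
    """Dummy-coded ML logistic regression of a binary outcome on group.

    Returns one Wald OR (vs the reference group) per non-reference group.
    A group with constant outcome against a constant-outcome reference
    causes separation; such contrasts fall back to the 0.5-corrected 2x2
    Woolf OR and are flagged ``corrected=True``.
    """
    group, others = _as_groups(group, reference)
    outcome = np.asarray(outcome, dtype=float)
    if outcome.min() == outcome.max():
        raise ValueError("outcome is constant; model undefined")

    # detect per-contrast separation on the collapsed 2x2 tables
    ref_mask = group == reference
    c = outcome[ref_mask].sum()
    d = (~outcome[ref_mask].astype(bool)).sum()
    tables = {}
    separated = set()
    for g in others:
        mask = group == g
        a = outcome[mask].sum()
        b = mask.sum() - a
        tables[g] = (a, b, c, d)
        if min(a, b, c, d) == 0:
            separated.add(g)

    results: dict[str, ORResult] = {}
    fit_groups = [g for g in others if g not in separated]
    if fit_groups:
        keep = ref_mask | np.isin(group, fit_groups)
        sub_group, sub_y = group[keep], outcome[keep]
        X = np.column_stack(
            [np.ones(keep.sum())]
            + [(sub_group == g).astype(float) for g in fit_groups]
        )
        fit = sm.Logit(sub_y, X).fit(
            method="newton", tol=1e-10, maxiter=100, disp=False
        )
        for i, g in enumerate(fit_groups, start=1):
            beta, se = fit.params[i], fit.bse[i]
            results[g] = ORResult(
                estimate=math.exp(beta),
                log_se=se,
                ci_low=math.exp(beta - Z95 * se),
                ci_high=math.exp(beta + Z95 * se),
                method="wald_logistic",
                contrast=f"{g} vs {reference}",
                p_value=float(fit.pvalues[i]),
            )
    for g in separated:
        fallback = odds_ratio_2x2(*tables[g])
        results[g] = ORResult(
            estimate=fallback.estimate,
            log_se=fallback.log_se,
            ci_low=fallback.ci_low,
            ci_high=fallback.ci_high,
            method="woolf_2x2",
            corrected=True,
            contrast=f"{g} vs {reference}",
            p_value=fallback.p_value,
        )
    return [results[g] for g in others]


def proportional_odds(
    group,
    outcome,
    reference: str,
    direction: str = "higher_is_event",
) -> list[ORResult]:
    """Cumulative-logit proportional-odds model of an ordinal outcome.

    OR > 1 means higher odds of more-extreme levels in the stated
    direction (``higher_is_event``: toward the top level). Levels with no
    observations are dropped with a warning. Wald 95 % CIs.
    """
    if direction not in ("higher_is_event", "lower_is_event"):
        raise ValueError(f"unknown direction {direction!r}")
    group, others = _as_groups(group, reference)
    outcome = np.asarray(outcome)
    levels = np.unique(outcome)
    if len(levels) < 2:
        raise ValueError("need >= 2 outcome levels with nonzero counts")
    codes = np.searchsorted(levels, outcome)
    endog = pd.Categorical(codes, categories=range(len(levels)), ordered=True)
    exog = pd.DataFrame(
        {g: (group == g).astype(float) for g in others}
    )
    model = OrderedModel(endog, exog, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(method="bfgs", maxiter=200, disp=False, gtol=1e-8)
    if not fit.mle_retvals.get("converged", True):
        gnorm = float(np.linalg.norm(model.score(fit.params)))
        raise RuntimeError(
            f"proportional-odds fit did not converge; |gradient| = {gnorm:.3g}"
        )
    sign = 1.0 if direction == "higher_is_event" else -1.0
    params = np.asarray(fit.params)
    bses = np.asarray(fit.bse)
    pvals = np.asarray(fit.pvalues)
    results = []
    for i, g in enumerate(others):
        beta = sign * params[i]
        se = bses[i]
        results.append(
            ORResult(
                estimate=math.exp(beta),
                log_se=se,
                ci_low=math.exp(beta - Z95 * se),
                ci_high=math.exp(beta + Z95 * se),
                method="wald_logistic",
                contrast=f"{g} vs {reference}",
                p_value=float(pvals[i]),
            )
        )
    return results


def _dunn_pairwise(groups: list[np.ndarray], labels: list[str]):
    """Dunn's z-tests on pooled ranks with Bonferroni adjustment."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (
        (tie_counts**3 - tie_counts).sum() / (12 * (n - 1)) if n > 1 else 0.0
    )
    var_base = n * (n + 1) / 12 - tie_term
    k = len(groups)
    m = k * (k - 1) // 2
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            denom = var_base * (1 / len(groups[i]) + 1 / len(groups[j]))
            if denom <= 0:
                z = 0.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(denom)
            p_raw = 2 * sps.norm.sf(abs(z))
            pairwise.append((labels[i], labels[j], min(1.0, p_raw * m)))
    return tuple(pairwise)


def kruskal_wallis(groups, labels=None) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H with Dunn/Bonferroni post-hoc.

    ``groups`` is a list of numeric samples. If every pooled observation is
    identical the statistic is 0 and p = 1 (the tie-correction denominator
    would otherwise vanish).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    labels = list(labels) if labels is not None else [
        str(i) for i in range(len(groups))
    ]
    pooled = np.concatenate(groups)
    df = len(groups) - 1
    if np.all(pooled == pooled[0]):
        pairwise = tuple(
            (labels[i], labels[j], 1.0)
            for i in range(len(groups))
            for j in range(i + 1, len(groups))
        )
        return GroupTestResult(0.0, df, 1.0, pairwise)
    stat, p = sps.kruskal(*groups)
    return GroupTestResult(
        float(stat), df, float(p), _dunn_pairwise(groups, labels)
    )


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie-corrected normal approximation
    and continuity correction. Returns (U, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def chi_square_independence(table) -> GroupTestResult:
    """Pearson chi-square on an r x c count table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    for axis_name, sums in (("row", row_sums), ("column", col_sums)):
        zero = np.nonzero(sums == 0)[0]
        if len(zero):
            raise ValueError(f"{axis_name} {zero[0]} has zero margin")
    stat, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return GroupTestResult(float(stat), int(dof), float(p))


def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles by the (n+1)p weighted-average convention.

    This is numpy's "weibull" method and the convention used by SPSS
    descriptives (e.g. {1,2,3,4,5} -> median 3, Q1 1.5, Q3 4.5).
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("empty sample")
    q = np.percentile(values, [50, 25, 75], method="weibull")
    return float(q[0]), float(q[1]), float(q[2])


def median_split_logistic(group, values, reference: str) -> list[ORResult]:
    """Binary logistic model of above-median status on group.

    Values are dichotomised at the whole-sample median (event = strictly
    above); groups entirely above or below the pooled median fall back to
    the corrected 2x2 estimate via :func:`binary_logistic`.
    """
    values = np.asarray(values, dtype=float)
    med, _, _ = median_iqr(values)
    outcome = (values > med).astype(float)
    if outcome.min() == outcome.max():
        raise ValueError("no items on one side of the pooled median")
    return binary_logistic(group, outcome, reference)


def linear_score_model(group, score, reference: str) -> list[MeanDiffResult]:
    """OLS of a numeric score on dummy-coded group.

    Each coefficient equals the group-mean difference vs the reference;
    95 % CI from the t distribution. Groups with fewer than two items are
    dropped with a warning.
    """
    group, others = _as_groups(group, reference)
    score = np.asarray(score, dtype=float)
    sizes = {g: int((group == g).sum()) for g in [reference, *others]}
    usable = [g for g in others if sizes[g] >= 2]
    for g in others:
        if g not in usable:
            warnings.warn(f"group {g!r} has < 2 items; dropped", stacklevel=2)
    if sizes[reference] < 2:
        raise ValueError("reference group has < 2 items")
    keep = (group == reference) | np.isin(group, usable)
    sub_group, sub_y = group[keep], score[keep]
    X = np.column_stack(
        [np.ones(keep.sum())]
        + [(sub_group == g).astype(float) for g in usable]
    )
    fit = sm.OLS(sub_y, X).fit()
    conf = fit.conf_int(alpha=0.05)
    return [
        MeanDiffResult(
            contrast=f"{g} vs {reference}",
            estimate=float(fit.params[i]),
            se=float(fit.bse[i]),
            ci_low=float(conf[i][0]),
            ci_high=float(conf[i][1]),
            p_value=float(fit.pvalues[i]),
        )
        for i, g in enumerate(usable, start=1)
    ]
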