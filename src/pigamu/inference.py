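"""Statistical comparisons of per-animal usage.

Three layers:

* a Kruskal-Wallis omnibus test across the four age categories (midranks,
  standard tie correction, chi-square reference distribution with an exact
  or Monte-Carlo permutation alternative for small samples);
* Bonferroni-corrected pairwise post-hoc tests (unpaired rank-sum by
  default; paired signed-rank as an option, since the four categories come
  from the same farms);
* simple linear regressions (OLS) with adjusted R-squared, used for the six
  within-herd category pairs and for the herd-size model, plus advisory
  residual diagnostics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparisonResult",
    "RegressionResult",
    "DiagnosticsResult",
    "kruskal_wallis",
    "pairwise_posthoc",
    "simple_regression",
    "regression_suite",
    "residual_diagnostics",
    "REGRESSION_PAIRS",
]

#: Predictor -> response pairs of the within-herd analysis: the sow (or the
#: respective older category) predicts the younger category's usage.
REGRESSION_PAIRS = [
    ("sow", "piglet"),
    ("sow", "weaner"),
    ("sow", "fattener"),
    ("piglet", "weaner"),
    ("piglet", "fattener"),
    ("weaner", "fattener"),
]


@dataclass
class GroupComparisonResult:
    h_statistic: float
    df: int
    p_value: float
    p_method: str
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    pairwise_raw: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    slope_se: float
    t_statistic: float
    p_value: float
    r2: float
    adj_r2: float
    n: int


def _h_statistic(groups: Sequence[np.ndarray]) -> float:
    """Kruskal-Wallis H with midranks and the tie-correction divisor."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    start = 0
    rank_sum_term = 0.0
    for g in groups:
        r = ranks[start : start + g.size]
        start += g.size
        rank_sum_term += r.sum() ** 2 / g.size
    h = 12.0 / (n_total * (n_total + 1)) * rank_sum_term - 3.0 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    divisor = 1.0 - tie_term / (n_total**3 - n_total)
    if divisor == 0.0:  # all observations identical
        return 0.0
    return h / divisor


def _index_partitions(sizes: Sequence[int]):
    """All ways to split range(sum(sizes)) into ordered groups of the given sizes."""
    idx = frozenset(range(sum(sizes)))

    def rec(remaining: frozenset, sizes_left):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        for comb in itertools.combinations(sorted(remaining), k):
            for tail in rec(remaining - set(comb), sizes_left[1:]):
                yield [list(comb)] + tail

    yield from rec(idx, list(sizes))


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    p_method: str = "chi2",
    n_permutations: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> GroupComparisonResult:
    """Kruskal-Wallis rank test across k groups.

    ``p_method='chi2'`` uses the chi-square approximation with k-1 degrees
    of freedom; ``'permutation'`` uses the exact permutation distribution
    when the pooled sample has at most 10 observations and otherwise a
    Monte-Carlo approximation with ``n_permutations`` resamples.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs at least one observation")
    n_total = sum(a.size for a in arrays)
    if n_total < 3:
        raise ValueError("need at least three observations in total")
    h = _h_statistic(arrays)
    df = len(arrays) - 1

    if np.unique(np.concatenate(arrays)).size == 1:
        return GroupComparisonResult(0.0, df, 1.0, p_method)

    if p_method == "chi2":
        p = float(stats.chi2.sf(h, df))
    elif p_method == "permutation":
        pooled = np.concatenate(arrays)
        sizes = [a.size for a in arrays]
        tol = 1e-12
        if n_total <= 10:
            count = total = 0
            for partition in _index_partitions(sizes):
                total += 1
                perm_groups = [pooled[ix] for ix in partition]
                if _h_statistic(perm_groups) >= h - tol:
                    count += 1
            p = count / total
        else:
            gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
            count = 0
            bounds = np.cumsum(sizes)[:-1]
            for _ in range(n_permutations):
                perm = gen.permutation(pooled)
                perm_groups = np.split(perm, bounds)
                if _h_statistic(perm_groups) >= h - tol:
                    count += 1
            p = (count + 1) / (n_permutations + 1)
    else:
        raise ValueError("p_method must be 'chi2' or 'permutation'")
    return GroupComparisonResult(float(h), df, float(min(p, 1.0)), p_method)


def pairwise_posthoc(
    groups: dict[str, Sequence[float]],
    method: str = "rank_sum",
    correction: str = "bonferroni",
) -> tuple[dict[tuple[str, str], float], dict[tuple[str, str], float]]:
    """Two-sided pairwise tests with Bonferroni adjustment.

    ``method='rank_sum'`` applies the unpaired Wilcoxon rank-sum
    (Mann-Whitney U) test; ``'signed_rank'`` the paired Wilcoxon
    signed-rank test (groups must be farm-aligned and equal length). Raw
    two-sided p-values are multiplied by the number of pairs k(k-1)/2 and
    capped at 1.

    Returns ``(adjusted, raw)`` maps keyed by (group_a, group_b).
    """
    if correction != "bonferroni":
        raise ValueError("only the Bonferroni correction is implemented")
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    m = len(names) * (len(names) - 1) // 2
    raw: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(names, 2):
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        if np.array_equal(xa, xb):
            p = 1.0
        elif method == "rank_sum":
            exact_ok = max(xa.size, xb.size) <= 25 and np.unique(
                np.concatenate([xa, xb])
            ).size == xa.size + xb.size
            p = float(
                stats.mannwhitneyu(
                    xa, xb, alternative="two-sided",
                    method="exact" if exact_ok else "asymptotic",
                ).pvalue
            )
        elif method == "signed_rank":
            if xa.size != xb.size:
                raise ValueError("signed_rank needs equal-length, aligned groups")
            d = xa - xb
            if np.all(d == 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(xa, xb, zero_method="wilcox").pvalue)
        else:
            raise ValueError("method must be 'rank_sum' or 'signed_rank'")
        raw[(a, b)] = p
    adjusted = {k: min(1.0, m * p) for k, p in raw.items()}
    return adjusted, raw


def simple_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with a two-sided slope t-test.

    adj R^2 = 1 - (1 - R^2)(n - 1)/(n - 2) for the single predictor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be the same length")
    n = x.size
    if n < 3:
        raise ValueError("need at least three observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: predictor is constant")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    t = fit.slope / fit.stderr if fit.stderr > 0 else math.inf * np.sign(fit.slope)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_se=float(fit.stderr),
        t_statistic=float(t),
        p_value=float(fit.pvalue),
        r2=r2,
        adj_r2=float(adj),
        n=int(n),
    )


def regression_suite(per_animal_wide: pd.DataFrame) -> dict[str, RegressionResult]:
    """The six within-herd models plus the herd-size model.

    ``per_animal_wide`` needs one row per farm with columns ``piglet``,
    ``weaner``, ``fattener``, ``sow`` (nDDDch/animal/year), ``total``
    (farm total per animal) and ``n_sows`` (herd size). Farms with any
    missing value in a model's pair are dropped from that model.
    """
    results: dict[str, RegressionResult] = {}
    for predictor, response in REGRESSION_PAIRS:
        sub = per_animal_wide[[predictor, response]].dropna()
        results[f"{predictor}->{response}"] = simple_regression(
            sub[predictor], sub[response]
        )
    sub = per_animal_wide[["n_sows", "total"]].dropna()
    results["herd_size->total"] = simple_regression(sub["n_sows"], sub["total"])
    return results


@dataclass(frozen=True)
class DiagnosticsResult:
    """Advisory model checks; never alters the OLS estimates."""

    normality_stat: float
    normality_p: float
    het_stat: float
    het_p: float
    assessable: bool
    residuals: np.ndarray
    fitted: np.ndarray


def residual_diagnostics(
    x: Sequence[float], residuals: Sequence[float], fitted: Sequence[float] | None = None
) -> DiagnosticsResult:
    """Shapiro-Wilk normality check and a Breusch-Pagan-style
    heteroscedasticity check (LM test from the auxiliary regression of
    squared residuals on the predictor).
    """
    x = np.asarray(x, dtype=float)
    e = np.asarray(residuals, dtype=float)
    fitted_arr = np.asarray(fitted, dtype=float) if fitted is not None else np.zeros_like(e)
    if np.allclose(e, 0) or np.ptp(e) == 0:
        return DiagnosticsResult(
            math.nan, math.nan, math.nan, math.nan, False, e, fitted_arr
        )
    sw = stats.shapiro(e)
    aux = stats.linregress(x, e**2)
    lm = e.size * aux.rvalue**2
    het_p = float(stats.chi2.sf(lm, 1))
    return DiagnosticsResult(
        normality_stat=float(sw.statistic),
        normality_p=float(sw.pvalue),
        het_stat=float(lm),
        het_p=het_p,
        assessable=True,
        residuals=e,
        fitted=fitted_arr,
    )
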