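"""Descriptive reporting: category/class distributions, HPCIA shares,
descriptive statistics tables, and figure-ready data.

Percent shares are computed on unrounded totals (they sum to 100 exactly);
for display they are rounded half-up to the nearest integer, matching the
convention of published usage-monitoring tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formulary import Formulary
from .quantification import AMUResult, CATEGORY_ORDER

__all__ = [
    "DescriptiveStats",
    "round_half_up",
    "category_distribution",
    "class_distribution",
    "hpcia_share",
    "describe",
    "descriptive_table",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from the floor (0.5 -> 1), unlike banker's rounding."""
    scale = 10.0**ndigits
    return math.floor(x * scale + 0.5) / scale


def _by_class_frame(amu) -> pd.DataFrame:
    df = amu.by_class if isinstance(amu, AMUResult) else amu
    required = {"age_category", "mass_mg", "ndddch"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"input table missing columns: {sorted(missing)}")
    return df


def category_distribution(amu) -> pd.DataFrame:
    """Totals and percent shares per age category for both metrics.

    Accepts an :class:`AMUResult` or a tidy frame with ``age_category``,
    ``mass_mg`` and ``ndddch`` columns. Returns one row per category plus
    an ``overall`` row; shares carry both the unrounded value and the
    half-up integer display value. Mass is reported in kg.
    """
    df = _by_class_frame(amu)
    totals = (
        df.groupby("age_category")[["ndddch", "mass_mg"]]
        .sum()
        .reindex(CATEGORY_ORDER, fill_value=0.0)
    )
    nd_total = float(math.fsum(totals["ndddch"]))
    mass_total = float(math.fsum(totals["mass_mg"]))
    out = pd.DataFrame(
        {
            "age_category": totals.index,
            "ndddch_total": totals["ndddch"].to_numpy(),
            "mass_kg": totals["mass_mg"].to_numpy() / 1e6,
        }
    )
    out["ndddch_share_pct"] = (
        100.0 * out["ndddch_total"] / nd_total if nd_total > 0 else 0.0
    )
    out["mass_share_pct"] = (
        100.0 * out["mass_kg"] * 1e6 / mass_total if mass_total > 0 else 0.0
    )
    overall = pd.DataFrame(
        {
            "age_category": ["overall"],
            "ndddch_total": [nd_total],
            "mass_kg": [mass_total / 1e6],
            "ndddch_share_pct": [100.0 if nd_total > 0 else 0.0],
            "mass_share_pct": [100.0 if mass_total > 0 else 0.0],
        }
    )
    out = pd.concat([out, overall], ignore_index=True)
    out["ndddch_share_display"] = out["ndddch_share_pct"].map(round_half_up)
    out["mass_share_display"] = out["mass_share_pct"].map(round_half_up)
    return out


def class_distribution(amu, metric: str = "ndddch", category: str | None = None) -> pd.DataFrame:
    """Per-antimicrobial-class totals and shares under one metric.

    ``metric`` is ``'ndddch'`` or ``'mass'``; ``category`` restricts the
    scope to one age category (default: overall).
    """
    if metric not in ("ndddch", "mass"):
        raise ValueError("metric must be 'ndddch' or 'mass'")
    df = _by_class_frame(amu)
    if category is not None:
        df = df[df["age_category"] == str(category)]
    col = "ndddch" if metric == "ndddch" else "mass_mg"
    totals = df.groupby("antimicrobial_class")[col].sum().sort_values(ascending=False)
    totals = totals[totals.index != "_none"]  # placeholder rows for zero-usage farms
    grand = float(math.fsum(totals))
    out = pd.DataFrame(
        {
            "antimicrobial_class": totals.index,
            "total": totals.to_numpy(),
            "share_pct": 100.0 * totals.to_numpy() / grand if grand > 0 else 0.0,
        }
    )
    out["share_display"] = out["share_pct"].map(round_half_up)
    return out.reset_index(drop=True)


def hpcia_share(amu, formulary: Formulary, metric: str = "ndddch",
                category: str | None = None) -> float:
    """Percent share of the configured HPCIA classes under one metric."""
    dist = class_distribution(amu, metric=metric, category=category)
    mask = dist["antimicrobial_class"].map(formulary.is_hpcia)
    return float(dist.loc[mask, "share_pct"].sum())


@dataclass(frozen=True)
class DescriptiveStats:
    """Summary statistics of one distribution (herd sizes, per-animal usage)."""

    n: int
    mean: float
    median: float
    sd: float
    min: float
    max: float
    q25: float
    q75: float
    ci95_low: float
    ci95_high: float


def describe(values, quartile_method: str = "linear") -> DescriptiveStats:
    """Descriptive statistics with a t-based 95% CI of the mean.

    Quartiles use linear interpolation between order statistics by default
    (``quartile_method='linear'``, the common type-7 convention);
    ``'weibull'`` selects the type-6 alternative. With n = 1 the CI is
    undefined and reported as NaN.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 1:
        raise ValueError("describe requires at least one value")
    if np.isnan(x).any():
        raise ValueError("describe requires finite values (drop missing first)")
    n = x.size
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    if n > 1:
        half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
        ci = (mean - half, mean + half)
    else:
        ci = (float("nan"), float("nan"))
    return DescriptiveStats(
        n=n,
        mean=mean,
        median=float(np.quantile(x, 0.5, method=quartile_method)),
        sd=sd,
        min=float(np.min(x)),
        max=float(np.max(x)),
        q25=float(np.quantile(x, 0.25, method=quartile_method)),
        q75=float(np.quantile(x, 0.75, method=quartile_method)),
        ci95_low=float(ci[0]),
        ci95_high=float(ci[1]),
    )


def descriptive_table(values_by_group: dict[str, "np.ndarray"],
                      quartile_method: str = "linear") -> pd.DataFrame:
    """One :func:`describe` row per named group (e.g. per age category)."""
    rows = []
    for name, vals in values_by_group.items():
        d = describe(vals, quartile_method=quartile_method)
        rows.append({"group": name, **d.__dict__})
    return pd.DataFrame(rows)
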