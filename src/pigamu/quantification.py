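"""Defined-daily-dose quantification of antimicrobial usage.

The number of Swiss defined daily doses for a prescription is

    nDDDch = ingredient mass (mg) / (DDDch (mg/kg) x standard weight (kg))

computed separately per active ingredient and summed. Dividing the per-farm,
per-age-category nDDDch total by the number of animals kept (sows) or
produced per year (piglets, weaners, fatteners) gives nDDDch/animal/year,
an estimate of potential treatment days per animal; per-category values are
summed to a farm total per animal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formulary import AgeCategory, Formulary, FormularyLookupError

__all__ = [
    "UsageRecord",
    "FarmCensus",
    "AMUResult",
    "QuantificationError",
    "record_ndddch",
    "quantify",
    "per_animal_year",
]

#: Canonical category order used in all tidy outputs.
CATEGORY_ORDER = [c.value for c in AgeCategory]


class QuantificationError(ValueError):
    """A usage record cannot be quantified (unknown product or dose)."""


@dataclass(frozen=True)
class UsageRecord:
    """One prescription allocation: a product quantity for one age category."""

    farm_id: str
    product_id: str
    quantity: float
    age_category: AgeCategory
    year: int

    def __post_init__(self) -> None:
        if self.quantity < 0:
            raise ValueError(
                f"quantity must be >= 0, got {self.quantity} "
                f"(farm {self.farm_id}, product {self.product_id})"
            )
        object.__setattr__(self, "age_category", AgeCategory(self.age_category))


@dataclass(frozen=True)
class FarmCensus:
    """Animals per category: sows kept; other categories produced per year."""

    farm_id: str
    counts: Mapping[AgeCategory, int]

    def __post_init__(self) -> None:
        counts = {AgeCategory(c): int(n) for c, n in self.counts.items()}
        missing = [c.value for c in AgeCategory if c not in counts]
        if missing:
            raise ValueError(
                f"census for farm {self.farm_id} missing categories: {missing}"
            )
        for c, n in counts.items():
            if n < 0:
                raise ValueError(
                    f"census count for farm {self.farm_id}, {c.value} must be >= 0"
                )
        object.__setattr__(self, "counts", counts)


@dataclass
class AMUResult:
    """Quantified usage, tidy by farm x age category x antimicrobial class.

    Attributes
    ----------
    by_class
        Columns ``farm_id, age_category, antimicrobial_class, mass_mg,
        ndddch``; one row per combination with any usage (plus explicit
        zero rows for farms without usage).
    per_animal
        Filled by :func:`per_animal_year`. Columns ``farm_id, age_category,
        ndddch, n_animals, ndddch_per_animal_year``; the per-animal value is
        NaN where usage is positive but the census count is zero
        (undefined, reported as missing rather than 0 or infinity).
    farm_totals
        Filled by :func:`per_animal_year`. Columns ``farm_id,
        total_ndddch, total_ndddch_per_animal_year`` (the farm total per
        animal is the plain sum of the four category values).
    excluded
        ``(record, reason)`` pairs skipped under ``on_error='report'``.
    """

    by_class: pd.DataFrame
    per_animal: pd.DataFrame | None = None
    farm_totals: pd.DataFrame | None = None
    excluded: list[tuple[UsageRecord, str]] = field(default_factory=list)
    n_year_filtered: int = 0

    def category_totals(self) -> pd.Series:
        """nDDDch summed over farms and classes, indexed by category."""
        s = self.by_class.groupby("age_category", sort=False)["ndddch"].sum()
        return s.reindex(CATEGORY_ORDER, fill_value=0.0)

    def total_ndddch(self) -> float:
        return float(math.fsum(self.by_class["ndddch"]))

    def total_mass_mg(self) -> float:
        return float(math.fsum(self.by_class["mass_mg"]))


def record_ndddch(
    amount_mg: float, dose_mg_per_kg: float, standard_weight_kg: float
) -> float:
    """Defined daily doses for one ingredient amount.

    ``amount_mg / (dose_mg_per_kg * standard_weight_kg)``.
    """
    if not dose_mg_per_kg > 0:
        raise ValueError(f"DDDch dose must be > 0 mg/kg, got {dose_mg_per_kg}")
    if not standard_weight_kg > 0:
        raise ValueError(f"standard weight must be > 0 kg, got {standard_weight_kg}")
    if amount_mg < 0:
        raise ValueError(f"ingredient amount must be >= 0 mg, got {amount_mg}")
    return amount_mg / (dose_mg_per_kg * standard_weight_kg)


def quantify(
    records: Iterable[UsageRecord],
    formulary: Formulary,
    year: int | None = None,
    on_error: str = "raise",
) -> AMUResult:
    """Quantify usage records into mass and nDDDch totals.

    Each record's product is resolved into per-ingredient amounts; each
    ingredient contributes ``record_ndddch`` with the record's category
    standard weight, accumulated by (farm, category, antimicrobial class).
    Aggregation is order-independent.

    Parameters
    ----------
    year
        If given, records from other calendar years are excluded and
        counted in ``AMUResult.n_year_filtered``.
    on_error
        ``'raise'`` (default) fails on the first unresolvable record;
        ``'report'`` skips it and appends ``(record, reason)`` to
        ``AMUResult.excluded``.
    """
    if on_error not in ("raise", "report"):
        raise ValueError("on_error must be 'raise' or 'report'")

    rows: list[tuple[str, str, str, float, float]] = []
    excluded: list[tuple[UsageRecord, str]] = []
    n_year_filtered = 0
    farms_seen: set[str] = set()

    for rec in records:
        if year is not None and rec.year != year:
            n_year_filtered += 1
            continue
        farms_seen.add(rec.farm_id)
        try:
            components = formulary.resolve_product(rec.product_id, rec.quantity)
            weight = formulary.standard_weight(rec.age_category)
            for ingredient, amount_mg, route in components:
                dose = formulary.lookup_dddch(ingredient, route)
                cls = formulary.class_of(ingredient, route)
                rows.append(
                    (
                        rec.farm_id,
                        rec.age_category.value,
                        cls,
                        amount_mg,
                        record_ndddch(amount_mg, dose, weight),
                    )
                )
        except FormularyLookupError as e:
            msg = (
                f"record (farm {rec.farm_id}, product {rec.product_id}, "
                f"{rec.age_category.value}, {rec.year}): {e}"
            )
            if on_error == "raise":
                raise QuantificationError(msg) from e
            excluded.append((rec, str(e)))

    by_class = pd.DataFrame(
        rows,
        columns=["farm_id", "age_category", "antimicrobial_class", "mass_mg", "ndddch"],
    )
    if not by_class.empty:
        by_class = (
            by_class.groupby(
                ["farm_id", "age_category", "antimicrobial_class"], sort=True
            )[["mass_mg", "ndddch"]]
            .sum()
            .reset_index()
        )
    # keep farms whose every record was zero-quantity visible downstream
    zero_farms = farms_seen - set(by_class["farm_id"]) if not by_class.empty else farms_seen
    if zero_farms:
        extra = pd.DataFrame(
            [(f, AgeCategory.PIGLET.value, "_none", 0.0, 0.0) for f in sorted(zero_farms)],
            columns=by_class.columns,
        )
        by_class = extra if by_class.empty else pd.concat([by_class, extra], ignore_index=True)
    return AMUResult(
        by_class=by_class, excluded=excluded, n_year_filtered=n_year_filtered
    )


def per_animal_year(
    amu: AMUResult, censuses: Iterable[FarmCensus], include_zero_farms: bool = True
) -> AMUResult:
    """Fill ``per_animal`` and ``farm_totals`` from census denominators.

    Every censused farm appears with all four categories; farms with zero
    usage keep explicit zeros (they stay in every denominator and
    statistic). A category with positive usage but a zero census count is
    undefined and reported as NaN; its farm total is NaN as well.
    """
    census_map = {c.farm_id: c for c in censuses}
    usage_farms = set(amu.by_class["farm_id"]) if not amu.by_class.empty else set()
    missing = sorted(usage_farms - set(census_map))
    if missing:
        raise ValueError(f"no census for farms with usage: {missing}")

    farm_ids = sorted(census_map) if include_zero_farms else sorted(usage_farms)
    grid = pd.MultiIndex.from_product(
        [farm_ids, CATEGORY_ORDER], names=["farm_id", "age_category"]
    )
    cat_nd = (
        amu.by_class.groupby(["farm_id", "age_category"])["ndddch"].sum()
        if not amu.by_class.empty
        else pd.Series(dtype=float)
    )
    per = pd.DataFrame(index=grid).reset_index()
    per["ndddch"] = (
        cat_nd.reindex(grid, fill_value=0.0).to_numpy() if len(cat_nd) else 0.0
    )
    per["n_animals"] = [
        census_map[f].counts[AgeCategory(c)]
        for f, c in zip(per["farm_id"], per["age_category"])
    ]
    with np.errstate(divide="ignore", invalid="ignore"):
        value = per["ndddch"].to_numpy() / per["n_animals"].to_numpy(dtype=float)
    value = np.where(per["n_animals"] > 0, value, np.where(per["ndddch"] > 0, np.nan, 0.0))
    per["ndddch_per_animal_year"] = value

    totals = per.groupby("farm_id", sort=True).agg(
        total_ndddch=("ndddch", "sum"),
        total_ndddch_per_animal_year=("ndddch_per_animal_year", lambda s: s.sum(skipna=False)),
    ).reset_index()

    amu.per_animal = per
    amu.farm_totals = totals
    return amu
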