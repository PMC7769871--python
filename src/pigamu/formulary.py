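"""Reference data for antimicrobial-usage quantification.

The formulary bundles everything a defined-daily-dose calculation depends
on: national defined daily doses (DDDch, mg of active ingredient per kg
bodyweight per day), product compositions (mg of each active ingredient per
dispensing unit), the ESVAC standard weights of the four pig age
categories, and the set of antimicrobial classes counted as Highest
Priority Critically Important Antimicrobials (HPCIA).

DDDch values are national reference data and must be supplied by the user;
the packaged demo formulary (:func:`demo_formulary`) carries illustrative,
non-authoritative doses for testing and simulation only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AgeCategory",
    "Route",
    "DDDchEntry",
    "ProductComponent",
    "ProductDefinition",
    "Formulary",
    "FormularySchemaError",
    "FormularyLookupError",
    "DEFAULT_STANDARD_WEIGHTS",
    "DEFAULT_HPCIA_CLASSES",
    "load_formulary",
    "save_formulary",
    "demo_formulary",
]


class AgeCategory(str, enum.Enum):
    """The four age categories animals and prescriptions are allocated to.

    Piglets run from birth to the end of week 4, weaners from week 5 to the
    end of week 12, fatteners from week 13 to slaughter; gilts and boars
    count as sows from 7 months of age.
    """

    PIGLET = "piglet"
    WEANER = "weaner"
    FATTENER = "fattener"
    SOW = "sow"

    @classmethod
    def parse(cls, label: str) -> "AgeCategory":
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            valid = ", ".join(c.value for c in cls)
            raise ValueError(
                f"unknown age category {label!r}; valid labels: {valid} "
                "(gilts and boars count as sows)"
            ) from None


class Route(str, enum.Enum):
    """Formulation/route of administration a defined dose is keyed by."""

    INJECTABLE = "injectable"
    ORAL_PREMIX = "oral_premix"
    ORAL_OTHER = "oral_other"
    OTHER = "other"

    @classmethod
    def parse(cls, label: str) -> "Route":
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            valid = ", ".join(r.value for r in cls)
            raise ValueError(f"unknown route {label!r}; valid labels: {valid}") from None


#: ESVAC standard weights per age category (kg bodyweight).
DEFAULT_STANDARD_WEIGHTS: dict[AgeCategory, float] = {
    AgeCategory.PIGLET: 4.0,
    AgeCategory.WEANER: 12.0,
    AgeCategory.FATTENER: 50.0,
    AgeCategory.SOW: 220.0,
}

#: WHO highest-priority critically important antimicrobial classes.
DEFAULT_HPCIA_CLASSES: frozenset[str] = frozenset(
    {"cephalosporins", "fluoroquinolones", "macrolides", "polypeptides"}
)


class FormularySchemaError(ValueError):
    """A formulary file violates the documented schema or an invariant."""


class FormularyLookupError(KeyError):
    """A product or defined-dose key is not registered in the formulary."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


@dataclass(frozen=True)
class DDDchEntry:
    """One national defined daily dose, keyed by (ingredient, route)."""

    ingredient: str
    antimicrobial_class: str
    route: Route
    dose_mg_per_kg: float

    def __post_init__(self) -> None:
        if not self.dose_mg_per_kg > 0:
            raise FormularySchemaError(
                f"DDDch dose for ({self.ingredient}, {self.route.value}) must be "
                f"> 0 mg/kg, got {self.dose_mg_per_kg}"
            )


@dataclass(frozen=True)
class ProductComponent:
    ingredient: str
    concentration_mg_per_unit: float
    route: Route

    def __post_init__(self) -> None:
        if not self.concentration_mg_per_unit > 0:
            raise FormularySchemaError(
                f"concentration of {self.ingredient} must be > 0 mg/unit, "
                f"got {self.concentration_mg_per_unit}"
            )


@dataclass(frozen=True)
class ProductDefinition:
    """A marketed product: one component per active ingredient.

    Combination products (e.g. sulfonamide + trimethoprim premixes) carry
    one component entry per active ingredient; each ingredient contributes
    its own defined-daily-dose terms downstream.
    """

    product_id: str
    unit: str
    components: tuple[ProductComponent, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise FormularySchemaError(
                f"product {self.product_id!r} has no components"
            )


@dataclass(frozen=True)
class Formulary:
    """Validated registry of weights, defined doses, products and HPCIA set."""

    weights: Mapping[AgeCategory, float]
    dddch: Mapping[tuple[str, Route], DDDchEntry]
    products: Mapping[str, ProductDefinition]
    hpcia_classes: frozenset[str] = field(default=DEFAULT_HPCIA_CLASSES)

    def __post_init__(self) -> None:
        missing = [c.value for c in AgeCategory if c not in self.weights]
        if missing:
            raise FormularySchemaError(
                f"standard weight missing for categories: {', '.join(missing)}"
            )
        for cat, w in self.weights.items():
            if not w > 0:
                raise FormularySchemaError(
                    f"standard weight for {cat.value} must be > 0 kg, got {w}"
                )

    # -- lookups -----------------------------------------------------------

    def standard_weight(self, category: AgeCategory) -> float:
        return self.weights[AgeCategory(category)]

    def lookup_dddch(self, ingredient: str, route: Route) -> float:
        """Defined daily dose (mg/kg) for an (ingredient, route) key.

        Raises instead of falling back to another route: doses differ by
        formulation and silent substitution is a correctness hazard.
        """
        key = (ingredient, Route(route))
        try:
            return self.dddch[key].dose_mg_per_kg
        except KeyError:
            raise FormularyLookupError(
                f"no DDDch registered for ({ingredient}, {Route(route).value})"
            ) from None

    def class_of(self, ingredient: str, route: Route) -> str:
        key = (ingredient, Route(route))
        try:
            return self.dddch[key].antimicrobial_class
        except KeyError:
            raise FormularyLookupError(
                f"no DDDch registered for ({ingredient}, {Route(route).value})"
            ) from None

    def resolve_product(
        self, product_id: str, quantity: float
    ) -> list[tuple[str, float, Route]]:
        """Expand ``quantity`` dispensing units into per-ingredient milligrams.

        Returns ``[(ingredient, amount_mg, route), ...]``, one entry per
        active ingredient. Linear in quantity.
        """
        if quantity < 0:
            raise ValueError(f"quantity must be >= 0, got {quantity}")
        try:
            product = self.products[product_id]
        except KeyError:
            known = ", ".join(sorted(self.products)) or "(none)"
            raise FormularyLookupError(
                f"unknown product {product_id!r}; known products: {known}"
            ) from None
        return [
            (c.ingredient, c.concentration_mg_per_unit * quantity, c.route)
            for c in product.components
        ]

    def is_hpcia(self, antimicrobial_class: str) -> bool:
        return antimicrobial_class in self.hpcia_classes


# -- CSV schema ------------------------------------------------------------
#
# A formulary directory holds three UTF-8 CSV files with header rows:
#   weights.csv   category,weight_kg
#   dddch.csv     ingredient,class,route,dose_mg_per_kg,hpcia
#   products.csv  product_id,ingredient,concentration_mg_per_unit,unit,route
# hpcia is 0/1 and must be consistent within an antimicrobial class.

_WEIGHTS_COLS = ["category", "weight_kg"]
_DDDCH_COLS = ["ingredient", "class", "route", "dose_mg_per_kg", "hpcia"]
_PRODUCTS_COLS = ["product_id", "ingredient", "concentration_mg_per_unit", "unit", "route"]


def _read_table(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.is_file():
        raise FormularySchemaError(f"formulary file not found: {path}")
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormularySchemaError(
            f"{path.name}: missing required columns {missing}"
        )
    return df


def _parse_positive(value: str, what: str, where: str) -> float:
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise FormularySchemaError(f"{where}: unparseable {what} {value!r}") from None
    if not x > 0:
        raise FormularySchemaError(f"{where}: {what} must be > 0, got {x}")
    return x


def load_formulary(path: str | Path) -> Formulary:
    """Load and validate a formulary from a directory of CSV tables."""
    path = Path(path)
    wdf = _read_table(path / "weights.csv", _WEIGHTS_COLS)
    ddf = _read_table(path / "dddch.csv", _DDDCH_COLS)
    pdf = _read_table(path / "products.csv", _PRODUCTS_COLS)

    weights: dict[AgeCategory, float] = {}
    for i, row in wdf.iterrows():
        where = f"weights.csv row {i + 2}"
        try:
            cat = AgeCategory.parse(row["category"])
        except ValueError as e:
            raise FormularySchemaError(f"{where}: {e}") from None
        if cat in weights:
            raise FormularySchemaError(f"{where}: duplicate category {cat.value}")
        weights[cat] = _parse_positive(row["weight_kg"], "weight_kg", where)

    dddch: dict[tuple[str, Route], DDDchEntry] = {}
    hpcia_by_class: dict[str, bool] = {}
    for i, row in ddf.iterrows():
        where = f"dddch.csv row {i + 2}"
        try:
            route = Route.parse(row["route"])
        except ValueError as e:
            raise FormularySchemaError(f"{where}: {e}") from None
        key = (row["ingredient"], route)
        if key in dddch:
            raise FormularySchemaError(
                f"{where}: duplicate DDDch key ({key[0]}, {route.value})"
            )
        dose = _parse_positive(row["dose_mg_per_kg"], "dose_mg_per_kg", where)
        cls = row["class"]
        flag = str(row["hpcia"]).strip() in {"1", "true", "True"}
        if cls in hpcia_by_class and hpcia_by_class[cls] != flag:
            raise FormularySchemaError(
                f"{where}: inconsistent hpcia flag for class {cls!r}"
            )
        hpcia_by_class[cls] = flag
        dddch[key] = DDDchEntry(key[0], cls, route, dose)

    components: dict[str, list[ProductComponent]] = {}
    units: dict[str, str] = {}
    for i, row in pdf.iterrows():
        where = f"products.csv row {i + 2}"
        try:
            route = Route.parse(row["route"])
        except ValueError as e:
            raise FormularySchemaError(f"{where}: {e}") from None
        conc = _parse_positive(
            row["concentration_mg_per_unit"], "concentration_mg_per_unit", where
        )
        pid = row["product_id"]
        if pid in units and units[pid] != row["unit"]:
            raise FormularySchemaError(f"{where}: conflicting unit for product {pid!r}")
        units[pid] = row["unit"]
        components.setdefault(pid, []).append(
            ProductComponent(row["ingredient"], conc, route)
        )

    products = {
        pid: ProductDefinition(pid, units[pid], tuple(comps))
        for pid, comps in components.items()
    }
    hpcia = frozenset(cls for cls, flag in hpcia_by_class.items() if flag)
    return Formulary(weights=weights, dddch=dddch, products=products, hpcia_classes=hpcia)


def save_formulary(formulary: Formulary, path: str | Path) -> None:
    """Write a formulary back to the three-table CSV layout (round-trips)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(c.value, formulary.weights[c]) for c in AgeCategory],
        columns=_WEIGHTS_COLS,
    ).to_csv(path / "weights.csv", index=False)
    pd.DataFrame(
        [
            (
                e.ingredient,
                e.antimicrobial_class,
                e.route.value,
                e.dose_mg_per_kg,
                int(e.antimicrobial_class in formulary.hpcia_classes),
            )
            for e in sorted(formulary.dddch.values(), key=lambda e: (e.ingredient, e.route.value))
        ],
        columns=_DDDCH_COLS,
    ).to_csv(path / "dddch.csv", index=False)
    rows = []
    for pid in sorted(formulary.products):
        p = formulary.products[pid]
        for c in p.components:
            rows.append((pid, c.ingredient, c.concentration_mg_per_unit, p.unit, c.route.value))
    pd.DataFrame(rows, columns=_PRODUCTS_COLS).to_csv(path / "products.csv", index=False)


def demo_formulary() -> Formulary:
    """The packaged demo formulary.

    Doses are illustrative placeholders for tests and simulation, NOT the
    published national DDDch reference values.
    """
    root = resources.files("pigamu") / "data" / "demo_formulary"
    with resources.as_file(root) as p:
        return load_formulary(p)
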