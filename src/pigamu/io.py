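"""CSV readers/writers, run configuration and the pipeline orchestrator.

File schemas (UTF-8, header row, decimal point '.'):

* ``usage.csv``: farm_id,product_id,quantity,unit,age_category,year
* ``census.csv``: farm_id,piglets,weaners,fatteners,sows
* formulary: a directory with weights.csv / dddch.csv / products.csv
  (see :mod:`pigamu.formulary`)
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .formulary import AgeCategory, Formulary, load_formulary
from .inference import kruskal_wallis, pairwise_posthoc, regression_suite
from .quantification import (
    AMUResult,
    FarmCensus,
    UsageRecord,
    per_animal_year,
    quantify,
)
from .reporting import (
    category_distribution,
    class_distribution,
    descriptive_table,
    hpcia_share,
)

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_usage",
    "read_census",
    "write_usage",
    "write_census",
    "run_pipeline",
]

log = logging.getLogger("pigamu")

_USAGE_COLS = ["farm_id", "product_id", "quantity", "unit", "age_category", "year"]
_CENSUS_COLS = ["farm_id", "piglets", "weaners", "fatteners", "sows"]
_CENSUS_CAT = {
    "piglets": AgeCategory.PIGLET,
    "weaners": AgeCategory.WEANER,
    "fatteners": AgeCategory.FATTENER,
    "sows": AgeCategory.SOW,
}


class SchemaError(ValueError):
    """An input file violates its documented schema."""


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.is_file():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    return df


def read_usage(path: str | Path) -> list[UsageRecord]:
    """Read prescription records; malformed rows fail with line numbers."""
    df = _read_csv(path, _USAGE_COLS)
    records: list[UsageRecord] = []
    for i, row in df.iterrows():
        where = f"{Path(path).name} row {i + 2}"
        try:
            quantity = float(row["quantity"])
        except ValueError:
            raise SchemaError(f"{where}: unparseable quantity {row['quantity']!r}") from None
        try:
            category = AgeCategory.parse(row["age_category"])
            year = int(row["year"])
            records.append(
                UsageRecord(row["farm_id"], row["product_id"], quantity, category, year)
            )
        except ValueError as e:
            raise SchemaError(f"{where}: {e}") from None
    if not records:
        log.warning("%s: no usage rows found", path)
    return records


def read_census(path: str | Path) -> list[FarmCensus]:
    df = _read_csv(path, _CENSUS_COLS)
    censuses: list[FarmCensus] = []
    for i, row in df.iterrows():
        where = f"{Path(path).name} row {i + 2}"
        try:
            counts = {cat: int(row[col]) for col, cat in _CENSUS_CAT.items()}
            censuses.append(FarmCensus(row["farm_id"], counts))
        except ValueError as e:
            raise SchemaError(f"{where}: {e}") from None
    return censuses


def write_usage(records: list[UsageRecord], formulary: Formulary, path: str | Path) -> None:
    rows = [
        (
            r.farm_id,
            r.product_id,
            repr(r.quantity),
            formulary.products[r.product_id].unit if r.product_id in formulary.products else "",
            r.age_category.value,
            r.year,
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=_USAGE_COLS).to_csv(path, index=False)


def write_census(censuses: list[FarmCensus], path: str | Path) -> None:
    rows = [
        (c.farm_id, *[c.counts[cat] for cat in _CENSUS_CAT.values()]) for c in censuses
    ]
    pd.DataFrame(rows, columns=_CENSUS_COLS).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    formulary_path: str
    usage_path: str
    census_path: str
    output_dir: str
    year: int | None = 2017
    quartile_method: str = "linear"
    pairwise_method: str = "rank_sum"
    alpha: float = 0.05
    skip_bad_rows: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _per_animal_wide(amu: AMUResult) -> pd.DataFrame:
    wide = amu.per_animal.pivot(
        index="farm_id", columns="age_category", values="ndddch_per_animal_year"
    )
    counts = amu.per_animal.pivot(index="farm_id", columns="age_category", values="n_animals")
    wide = wide.rename_axis(columns=None)
    wide["total"] = amu.farm_totals.set_index("farm_id")["total_ndddch_per_animal_year"]
    wide["n_sows"] = counts["sow"]
    return wide.reset_index()


def run_pipeline(config: RunConfig, stages: set[str] | None = None) -> dict[str, Path]:
    """Quantify -> per-animal -> report tables -> statistics; write a bundle.

    ``stages`` selects which output groups to write (any of ``'quantify'``,
    ``'report'``, ``'stats'``; default all). Returns a name -> path map of
    the written files. All outputs are deterministic given identical
    inputs and configuration.
    """
    all_stages = {"quantify", "report", "stats"}
    stages = all_stages if stages is None else set(stages)
    unknown = stages - all_stages
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    formulary = load_formulary(config.formulary_path)
    records = read_usage(config.usage_path)
    censuses = read_census(config.census_path)

    amu = quantify(
        records,
        formulary,
        year=config.year,
        on_error="report" if config.skip_bad_rows else "raise",
    )
    if amu.excluded:
        log.warning("excluded %d unresolvable records", len(amu.excluded))
    if amu.n_year_filtered:
        log.info("filtered %d records outside year %s", amu.n_year_filtered, config.year)
    per_animal_year(amu, censuses)

    files: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        files[name] = p

    if "quantify" in stages:
        save("by_class", amu.by_class)
        save("per_animal", amu.per_animal)
        save("farm_totals", amu.farm_totals)
    if "report" in stages:
        save("category_distribution", category_distribution(amu))
        save("class_distribution_ndddch", class_distribution(amu, "ndddch"))
        save("class_distribution_mass", class_distribution(amu, "mass"))

    wide = _per_animal_wide(amu)
    groups = {
        c.value: wide[c.value].dropna().to_numpy() for c in AgeCategory
    }
    if "report" in stages:
        save(
            "descriptives_per_animal",
            descriptive_table(groups, quartile_method=config.quartile_method),
        )

    if "stats" in stages:
        kw = kruskal_wallis([groups[c.value] for c in AgeCategory])
        adjusted, raw = pairwise_posthoc(groups, method=config.pairwise_method)
        stats_rows = [
            {
                "test": "kruskal_wallis",
                "groups": "all",
                "statistic": kw.h_statistic,
                "df_or_n": kw.df,
                "p_raw": kw.p_value,
                "p_adjusted": kw.p_value,
            }
        ] + [
            {
                "test": f"pairwise_{config.pairwise_method}",
                "groups": f"{a}|{b}",
                "statistic": float("nan"),
                "df_or_n": len(groups[a]),
                "p_raw": raw[(a, b)],
                "p_adjusted": adjusted[(a, b)],
            }
            for (a, b) in adjusted
        ]
        save("group_tests", pd.DataFrame(stats_rows))
        regs = regression_suite(wide)
        save(
            "regressions",
            pd.DataFrame(
                [
                    {"model": name, **r.__dict__, "significant": r.p_value <= config.alpha}
                    for name, r in regs.items()
                ]
            ),
        )

    manifest = {
        "package_version": __version__,
        "config": {**config.__dict__},
        "inputs": {
            "usage": _sha256(config.usage_path),
            "census": _sha256(config.census_path),
        },
        "hpcia_share_ndddch_pct": hpcia_share(amu, formulary, "ndddch"),
        "hpcia_share_mass_pct": hpcia_share(amu, formulary, "mass"),
        "n_records": len(records),
        "n_farms": len(censuses),
        "n_excluded": len(amu.excluded),
        "n_year_filtered": amu.n_year_filtered,
    }
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    files["manifest"] = mp
    return files
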