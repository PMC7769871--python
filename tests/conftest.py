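import numpy as np
import pandas as pd
import pytest

import pigamu as pg


@pytest.fixture(scope="session")
def formulary():
    return pg.demo_formulary()


@pytest.fixture(scope="session")
def small_cohort(formulary):
    """A 71-farm default cohort with emitted records, quantified end to end."""
    cohort = pg.generate_cohort(pg.default_config(), seed=7)
    pg.emit_usage_records(cohort, formulary, seed=7)
    amu = pg.quantify(cohort.usage_records, formulary, year=2017)
    pg.per_animal_year(amu, cohort.censuses)
    return cohort, amu


def per_animal_wide(amu):
    wide = amu.per_animal.pivot(
        index="farm_id", columns="age_category", values="ndddch_per_animal_year"
    ).rename_axis(columns=None)
    counts = amu.per_animal.pivot(
        index="farm_id", columns="age_category", values="n_animals"
    )
    wide["total"] = amu.farm_totals.set_index("farm_id")["total_ndddch_per_animal_year"]
    wide["n_sows"] = counts["sow"]
    return wide.reset_index()
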