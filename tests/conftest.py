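import numpy as np
import pandas as pd
import pytest

from abilitysim.score_tables import (
    GSVTable,
    SEMReliabilityTable,
    TableSet,
    VScaleTable,
)
from abilitysim.generative import DesignConfig
from abilitysim.synthetic_tables import SynthConfig, generate_table_set

# Hand-built "alpha" subdomain: max raw 20, two age bands [36,60) and [60,84).
# The GSV column contains a 3-run (raws 4-6 -> 40) and a 4-run (raws 7-10 ->
# 44) to exercise the median-raw rule, and spans 10..110 to satisfy the
# ability-scale range invariant.
ALPHA_GSV = np.array(
    [10, 12, 15, 30, 40, 40, 40, 44, 44, 44, 44,
     50, 55, 60, 65, 70, 80, 90, 100, 105, 110]
)

ALPHA_VSCALE_ROWS = [
    # age_min, age_max, vscale, raw_min, raw_max
    (36, 60, 1, 0, 0),
    (36, 60, 3, 1, 4),
    (36, 60, 6, 5, 12),
    (36, 60, 12, 13, 20),
    (60, 84, 1, 0, 2),
    (60, 84, 3, 3, 9),
    (60, 84, 6, 10, 14),
    (60, 84, 12, 15, 20),
]


def make_alpha_tableset(n_subdomains: int = 2) -> TableSet:
    """Small fully hand-specified TableSet (subdomains 'alpha', 'beta')."""
    names = ["alpha", "beta"][:n_subdomains]
    gsv_tables, vscale_tables, sem_tables = {}, {}, {}
    for name in names:
        gsv_tables[name] = GSVTable(name, np.arange(21), ALPHA_GSV)
        vscale_tables[name] = VScaleTable(
            name,
            pd.DataFrame(
                ALPHA_VSCALE_ROWS,
                columns=["age_min_months", "age_max_months", "vscale",
                         "raw_min", "raw_max"],
            ),
        )
        sem_tables[name] = SEMReliabilityTable(
            name,
            pd.DataFrame(
                {
                    "age_min_months": [36, 60],
                    "age_max_months": [60, 84],
                    "sem_gsv": [3.0, 2.5],
                    "reliability": [0.75, 0.84],
                }
            ),
        )
    return TableSet(gsv_tables, vscale_tables, sem_tables, provenance="synthetic")


@pytest.fixture
def alpha_tables() -> TableSet:
    return make_alpha_tableset()


@pytest.fixture(scope="session")
def default_tables() -> TableSet:
    """The default synthetic study tables (seed 1)."""
    return generate_table_set(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def design() -> DesignConfig:
    return DesignConfig()
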