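import numpy as np
import pandas as pd
import pytest

from neotraj import SimConfig, generate_cohort
from neotraj.io import ClinicalRecord, ImmuneMatrix, TaxaTable


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_parameters=10, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def toy_immune() -> ImmuneMatrix:
    idx = pd.MultiIndex.from_tuples(
        [("a", 1.0), ("a", 8.0), ("b", 2.0), ("b", 9.0)],
        names=["subject_id", "postnatal_age_days"],
    )
    data = pd.DataFrame(
        {"p1": [10.0, 20.0, 30.0, 40.0], "p2": [5.0, np.nan, 15.0, 25.0]},
        index=idx,
    )
    return ImmuneMatrix(data=data, kinds={"p1": "frequency_percent",
                                          "p2": "frequency_percent"}).validate()


@pytest.fixture()
def toy_taxa() -> TaxaTable:
    idx = pd.MultiIndex.from_tuples(
        [("a", 2.0), ("a", 9.0), ("b", 3.0)],
        names=["subject_id", "postnatal_age_days"],
    )
    data = pd.DataFrame(
        {
            "Enterobacteriaceae": [0.8, 0.6, 0.5],
            "Veillonellaceae": [0.15, 0.3, 0.25],
            "Bifidobacteriaceae": [0.05, 0.1, 0.25],
        },
        index=idx,
    )
    return TaxaTable(data=data).validate()


@pytest.fixture()
def toy_clinical() -> dict[str, ClinicalRecord]:
    return {
        "a": ClinicalRecord("a", gestational_age_days=196.0, group="stable"),
        "b": ClinicalRecord("b", gestational_age_days=175.0, group="unstable"),
    }
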