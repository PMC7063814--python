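import numpy as np
import pandas as pd
import pytest

import morbtraj as mt
from morbtraj.cohort import CohortSpec


@pytest.fixture(scope="session")
def block_table():
    return mt.default_block_table()


@pytest.fixture(scope="session")
def small_data(block_table):
    """A small synthetic registry run through cohort selection."""
    stays, truth = mt.generate_registry(mt.GeneratorConfig(n_patients=2500, seed=11))
    spec = CohortSpec()
    cohort = mt.select_washout_cohort(stays, spec)
    states = mt.build_health_states(stays, cohort, spec, block_table)
    return {"stays": stays, "truth": truth, "spec": spec, "cohort": cohort, "states": states}


@pytest.fixture(scope="session")
def small_model(small_data):
    return mt.fit_divclus(small_data["states"], small_data["truth"].n_states)


@pytest.fixture(scope="session")
def small_assignments(small_data, small_model):
    labels = mt.assign_many(small_data["states"], small_model)
    return small_data["states"].assignment_frame(labels)


@pytest.fixture(scope="session")
def small_net(small_assignments):
    return mt.estimate_transition_rates(small_assignments)


def make_stays(rows):
    """Hand-built stay table from (pid, sex, age_group, adm, rel, rtype, codes) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "sex",
            "age_group",
            "admission_date",
            "release_date",
            "release_type",
            "diagnoses",
        ],
    )


def make_assignments(per_patient, sex="male", age_group="50-59", start_year=2003):
    """Assignment frame from {pid: [cluster, ...]} with optional 'D' suffix
    marking the death year (e.g. [0, 3, 'D5'] dies in the third year)."""
    rows = []
    for pid, seq in per_patient.items():
        for i, c in enumerate(seq):
            death = isinstance(c, str) and c.startswith("D")
            cl = int(c[1:]) if death else int(c)
            rows.append(
                {
                    "patient_id": pid,
                    "year": start_year + i,
                    "sex": sex,
                    "age": 55,
                    "age_group": age_group,
                    "cluster": cl,
                    "is_death_year": death,
                }
            )
    return pd.DataFrame(rows)
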