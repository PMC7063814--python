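"""Shared paths and loaders for the numbered analysis scripts."""

from pathlib import Path

import pandas as pd

import morbtraj as mt
from morbtraj.cohort import CohortSpec, build_health_states, select_washout_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

N_PATIENTS = 20_000
SEED = 1


def load_registry():
    path = RESULTS / "registry.csv"
    if not path.exists():
        raise SystemExit("run 01_generate_registry.py first")
    return pd.read_csv(path, dtype=str)


def load_states():
    stays = load_registry()
    spec = CohortSpec()
    blocks = mt.default_block_table()
    cohort = select_washout_cohort(stays, spec)
    return build_health_states(stays, cohort, spec, blocks), blocks


def load_truth():
    return mt.GroundTruth.from_json(RESULTS / "ground_truth.json")


def load_realised_truth():
    """Ground truth including the realised latent state sequence.

    The JSON export stores only the planted parameters; re-running the
    deterministic generator with the same configuration recreates the
    per-patient realisation."""
    _, truth = mt.generate_registry(mt.GeneratorConfig(n_patients=N_PATIENTS, seed=SEED))
    return truth


def fitted(states, k=5):
    model = mt.fit_divclus(states, k)
    labels = mt.assign_many(states, model)
    return model, labels, states.assignment_frame(labels)
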