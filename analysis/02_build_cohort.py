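"""Select the washout cohort and build cumulative year-end health states.

Patients with any A00-N99 hospital diagnosis during 1997-2002 are
excluded, standardising everyone's initial health state to the zero
vector; the remaining patients get one cumulative binary vector over the
131 diagnosis blocks per observation year (2003-2014), up to and
including an in-hospital death year.
"""

import pandas as pd

from _common import RESULTS, load_registry, load_states

stays = load_registry()
states, blocks = load_states()

states.to_sparse_csv(RESULTS / "health_states_sparse.csv")
pd.DataFrame({"patient_id": states.patients["patient_id"]}).to_csv(
    RESULTS / "cohort_patients.csv", index=False
)

n_all = stays["patient_id"].nunique()
m = states.patients["patient_id"].nunique()
print(f"cohort M = {m} of {n_all} patients ({100 * m / n_all:.1f}% pass the washout)")
print(f"{states.n_rows} patient-year health states over D = {blocks.n_blocks} blocks")
print(f"non-zero vectors: {(states.matrix.sum(axis=1) > 0).mean():.1%} of patient-years")
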