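"""Generate the synthetic hospital-stay registry used by all later steps.

Emulates a population registry (1997-2014): multi-year stays, 5-year age
bands at admission, in-hospital deaths, washout-compatible patients, and
latent multimorbidity states with sex/age-dependent yearly acquisition
rates (state 1 carries a planted double hazard of progressing into the
terminal high-mortality state).
"""

import morbtraj as mt

from _common import N_PATIENTS, RESULTS, SEED

stays, truth = mt.generate_registry(mt.GeneratorConfig(n_patients=N_PATIENTS, seed=SEED))
stays.to_csv(RESULTS / "registry.csv", index=False)
truth.to_json(RESULTS / "ground_truth.json")

print(f"registry: {len(stays)} stays, {stays['patient_id'].nunique()} patients -> {RESULTS/'registry.csv'}")
print(f"latent states: {truth.n_states}; planted block sets: {[sorted(s) for s in truth.state_blocks]}")
print(f"in-hospital deaths: {(stays['release_type'] == 'death').sum()}")
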