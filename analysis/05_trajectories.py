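"""Descriptive trajectory statistics on the clustered cohort.

Reduced trajectories (consecutive repeats removed), the distribution of
their lengths overall and in a diagnosis-defined subcohort, the modal
length-3 trajectory under both counting modes, and mean length by
starting age.
"""

import numpy as np

from morbtraj.trajectories import (
    length_distribution,
    mean_length_by_age,
    most_frequent_reduced,
    reduced_summary,
    subcohort_with_block,
    trajectories_from_assignments,
)

from _common import RESULTS, fitted, load_states

states, blocks = load_states()
model, labels, assignments = fitted(states)
trajs = trajectories_from_assignments(assignments)

dist = length_distribution(trajs)
dist.rename("freq").reset_index().to_csv(RESULTS / "reduced_length_distribution.csv", index=False)
reduced_summary(trajs).to_csv(RESULTS / "reduced_trajectories.csv", index=False)

start_age = assignments.sort_values("year").groupby("patient_id")["age"].first()
curve = mean_length_by_age(trajs, start_age)
curve.to_csv(RESULTS / "mean_length_by_age.csv", index=False)

print("reduced-length distribution:", {int(k): round(v, 4) for k, v in dist.items()})
print(f"patients never leaving the healthy cluster: {100 * dist.get(1, 0):.1f}%")
for mode in ("exact", "prefix"):
    res = most_frequent_reduced(trajs, 3, mode=mode)
    if res:
        print(f"modal length-3 reduced trajectory ({mode}): {res[0]} followed by {res[1]} patients")

# subcohort: everyone ever diagnosed in the most prevalent block
block = int(np.argmax(states.matrix.sum(axis=0)))
sub = subcohort_with_block(states, block)
sub_dist = length_distribution(trajs, subcohort=sub)
print(
    f"subcohort with block {blocks.label(block)} (n={len(sub)}): "
    f"mean reduced length {sum(k * v for k, v in sub_dist.items()):.2f} "
    f"vs {sum(k * v for k, v in dist.items()):.2f} overall"
)
print(f"mean length by starting 5-year band rises from {curve['mean'].iloc[0]:.2f} to {curve['mean'].max():.2f}")
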