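"""Reduced disease trajectories and descriptive trajectory statistics.

A patient's disease trajectory is the year-by-year sequence of cluster
labels; the *reduced* trajectory removes consecutive repetitions, so its
length counts the number of distinct successive health states (e.g.
(0,1,1,1,5,5,3) reduces to (0,1,5,3), length 4).
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd


def reduce_trajectory(traj) -> tuple:
    """Collapse consecutive duplicates, preserving order; idempotent."""
    out = []
    prev = object()
    for c in traj:
        if c != prev:
            out.append(c)
            prev = c
    return tuple(out)


def trajectories_from_assignments(assignments: pd.DataFrame) -> pd.Series:
    """Per-patient cluster sequence (ordered by year), as a Series of tuples."""
    f = assignments.sort_values(["patient_id", "year"], kind="stable")
    return f.groupby("patient_id")["cluster"].agg(tuple)


def length_distribution(trajectories: pd.Series, subcohort=None) -> pd.Series:
    """Relative frequency of reduced-trajectory lengths (sums to 1)."""
    t = trajectories if subcohort is None else trajectories.loc[trajectories.index.isin(set(subcohort))]
    if len(t) == 0:
        return pd.Series(dtype=float)
    lengths = t.map(lambda s: len(reduce_trajectory(s)))
    dist = lengths.value_counts(normalize=True).sort_index()
    dist.index.name = "length"
    return dist


def mean_length_by_age(trajectories: pd.Series, start_age: pd.Series) -> pd.DataFrame:
    """Mean reduced length per starting 5-year age band, with SE = SD/sqrt(n).

    ``start_age`` maps patient_id to age (years) at the start of the
    observation period; empty bands are omitted.
    """
    lengths = trajectories.map(lambda s: len(reduce_trajectory(s)))
    ages = start_age.reindex(lengths.index)
    band = (ages // 5 * 5).astype(int)
    g = pd.DataFrame({"band": band, "length": lengths}).groupby("band")["length"]
    out = g.agg(mean="mean", sd="std", n="size").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out[["band", "mean", "se", "n"]]


def most_frequent_reduced(
    trajectories: pd.Series,
    length: int,
    subcohort=None,
    mode: str = "exact",
) -> tuple[tuple, int] | None:
    """Modal reduced trajectory of a given length.

    ``mode="exact"`` counts patients whose full reduced trajectory has
    exactly that length; ``mode="prefix"`` counts patients whose reduced
    trajectory *begins with* the candidate sequence.  Ties are broken
    lexicographically.  Returns ``None`` when no patient qualifies.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    t = trajectories if subcohort is None else trajectories.loc[trajectories.index.isin(set(subcohort))]
    reduced = t.map(reduce_trajectory)
    if mode == "exact":
        candidates = reduced[reduced.map(len) == length]
        if len(candidates) == 0:
            return None
        counts = Counter(candidates)
    elif mode == "prefix":
        prefixes = reduced[reduced.map(len) >= length].map(lambda s: s[:length])
        if len(prefixes) == 0:
            return None
        counts = Counter(prefixes)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    top = max(counts.values())
    winner = min(seq for seq, c in counts.items() if c == top)
    return winner, top


def reduced_summary(trajectories: pd.Series) -> pd.DataFrame:
    """All reduced trajectories with patient counts, most frequent first."""
    reduced = trajectories.map(reduce_trajectory)
    counts = Counter(reduced)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {"sequence": ["-".join(map(str, s)) for s, _ in rows], "count": [c for _, c in rows]}
    )


def subcohort_with_block(states, block: int) -> set:
    """Patients whose vector ever has ``block`` set during observation."""
    rows = states.matrix[:, block] == 1
    return set(states.index.loc[rows, "patient_id"].unique())
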