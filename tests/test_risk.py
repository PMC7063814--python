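import numpy as np
import pandas as pd
import pytest
from scipy import stats

import morbtraj as mt
from morbtraj.errors import ConfigurationError
from morbtraj.evaluation import match_clusters_to_states
from morbtraj.risk import (
    bootstrap_rr_ci,
    compare_comorbidities,
    gender_biased_transitions,
    presence_at_reference,
    progredient_split,
    region_entry_risk,
)

from conftest import make_assignments
from oracles import fisher_two_sided


def _rr_frame():
    """10 exposed (cluster 5) with 3 events; 90 others (cluster 0) with 7."""
    pats = {}
    for i in range(10):
        pats[f"e{i}"] = [5, 9 if i < 3 else 5]
    for i in range(90):
        pats[f"b{i}"] = [0, 9 if i < 7 else 0]
    return make_assignments(pats)


def test_relative_risk_is_ratio_of_frequencies():
    est = region_entry_risk(_rr_frame(), 5, {9}, "male", "50-59", horizon=1, baseline="all")
    assert est.absolute_risk == pytest.approx(0.3)
    assert est.baseline_risk == pytest.approx(0.1)  # baseline = all 100 trials
    assert est.relative_risk == pytest.approx(3.0)
    assert est.ci_low < 3.0 < est.ci_high


def test_self_comparison_gives_rr_exactly_one():
    pats = {f"e{i}": [5, 9 if i < 3 else 5] for i in range(10)}
    est = region_entry_risk(make_assignments(pats), 5, {9}, "male", "50-59", baseline="all")
    assert est.relative_risk == 1.0
    assert est.exposed_trials == est.baseline_trials


def test_zero_baseline_events_flagged_not_divided():
    pats = {f"e{i}": [5, 9 if i == 0 else 5] for i in range(5)}
    pats.update({f"b{i}": [0, 0] for i in range(5)})
    est = region_entry_risk(make_assignments(pats), 5, {9}, "male", "50-59", baseline="cluster0")
    assert not est.defined
    assert np.isnan(est.relative_risk)


def test_source_inside_region_rejected():
    with pytest.raises(ConfigurationError):
        region_entry_risk(_rr_frame(), 9, {9}, "male", "50-59")


def test_incomplete_followup_excluded():
    # one-year horizon; a patient observed for a single year cannot be a trial
    pats = {"a": [5], "b": [5, 5]}
    est = region_entry_risk(make_assignments(pats), 5, {9}, "male", "50-59", baseline="all")
    assert est.exposed_trials == 1  # only b's first year qualifies


def test_katz_ci_close_to_bootstrap():
    e1, n1, e0, n0 = 30, 200, 50, 1000
    rr = (e1 / n1) / (e0 / n0)
    se = np.sqrt(1 / e1 - 1 / n1 + 1 / e0 - 1 / n0)
    lo, hi = rr * np.exp(-1.96 * se), rr * np.exp(1.96 * se)
    blo, bhi = bootstrap_rr_ci(e1, n1, e0, n0, n_resamples=10_000, seed=0)
    assert lo == pytest.approx(blo, rel=0.10)
    assert hi == pytest.approx(bhi, rel=0.10)


def test_progredient_definition():
    frame = make_assignments(
        {
            "prog": [7, 7, 7, 9],    # in set 2003, outside (region) 2006
            "stable": [7, 7, 7, 7],  # still inside after 3 years
            "censored": [7, 7],      # unobserved at reference + 3
        }
    )
    prog, stable, refs = progredient_split(frame, {7}, horizon=3, region={9})
    assert prog == {"prog"}
    assert stable == {"stable"}
    assert "censored" not in refs


def test_progredient_without_region_counts_any_leaver():
    frame = make_assignments({"x": [7, 7, 7, 8], "y": [7, 7, 7, 7]})
    prog, stable, _ = progredient_split(frame, {7}, horizon=3)
    assert prog == {"x"} and stable == {"y"}


def test_fisher_p_matches_enumeration_and_bonferroni_caps():
    presence = pd.DataFrame(
        {0: [True] * 5 + [False] * 5, 1: [True, False] * 5},
        index=[f"p{i}" for i in range(10)],
    )
    out = compare_comorbidities(set(presence.index[:5]), set(presence.index[5:]), presence)
    row0 = out[out["feature"] == 0].iloc[0]
    assert row0["p_value"] == pytest.approx(fisher_two_sided(5, 0, 0, 5))
    assert row0["p_value"] == pytest.approx(2 / 252)
    assert (out["p_adjusted"] == np.minimum(1.0, out["p_value"] * 2)).all()
    assert (out["p_adjusted"] >= out["p_value"]).all()


def test_bonferroni_scales_with_number_of_blocks():
    rng = np.random.default_rng(0)
    presence = pd.DataFrame(rng.uniform(size=(40, 131)) < 0.2, index=[f"p{i}" for i in range(40)])
    out = compare_comorbidities(set(presence.index[:20]), set(presence.index[20:]), presence)
    assert np.allclose(out["p_adjusted"], np.minimum(1.0, out["p_value"] * 131))


def test_absent_feature_degenerate():
    presence = pd.DataFrame({0: [False] * 6}, index=[f"p{i}" for i in range(6)])
    out = compare_comorbidities({"p0", "p1", "p2"}, {"p3", "p4", "p5"}, presence)
    assert out.iloc[0]["degenerate"] and out.iloc[0]["p_value"] == 1.0


def test_overlapping_groups_rejected():
    presence = pd.DataFrame({0: [True, False]}, index=["a", "b"])
    with pytest.raises(ConfigurationError):
        compare_comorbidities({"a"}, {"a", "b"}, presence)


def test_presence_at_reference_uses_reference_year(small_data):
    states = small_data["states"]
    pids = states.index["patient_id"].unique()[:5]
    refs = {p: 2008 for p in pids}
    pres = presence_at_reference(states, refs)
    sel = states.index[(states.index["patient_id"].isin(pids)) & (states.index["year"] == 2008)]
    assert len(pres) == len(sel)


def test_identical_sex_rates_not_significant():
    rows = []
    for sex in ("male", "female"):
        rows += [
            (sex, "50-59", 0, 1, 30, 0),
            (sex, "50-59", 0, 0, 270, 0),
        ]
    net = mt.MultilayerNetwork(
        pd.DataFrame(rows, columns=["sex", "age_group", "src", "dst", "count", "age_sum"])
    )
    out = gender_biased_transitions(net, min_count=100)
    assert (out["p_value"] == 1.0).all()
    assert not out["significant"].any()


def test_sex_specific_rows_are_skipped():
    rows = [("male", "50-59", 0, 1, 30, 0), ("male", "50-59", 0, 0, 270, 0)]
    net = mt.MultilayerNetwork(
        pd.DataFrame(rows, columns=["sex", "age_group", "src", "dst", "count", "age_sum"])
    )
    assert len(gender_biased_transitions(net, min_count=100)) == 0


def test_planted_female_excess_detected():
    """A 3x female progression rate on the high-risk transition must survive
    Bonferroni screening across all tested triples."""
    mult = np.ones((2, 4, 4))
    mult[1, 1, 3] = 3.0  # female excess on state 1 -> terminal
    truth = mt.default_ground_truth(4, 131, seed=3, sex_multipliers=mult)
    cfg = mt.GeneratorConfig(n_patients=10_000, seed=21, n_latent_states=4, initial_age_bands=(10,))
    stays, realised = mt.generate_registry(cfg, ground_truth=truth)
    from morbtraj.cohort import CohortSpec

    spec = CohortSpec()
    blocks = mt.default_block_table()
    states = mt.build_health_states(stays, mt.select_washout_cohort(stays, spec), spec, blocks)
    model = mt.fit_divclus(states, 4)
    asg = states.assignment_frame(mt.assign_many(states, model))
    mapping = match_clusters_to_states(asg, realised)
    inv = {s: c for c, s in mapping.items()}
    net = mt.estimate_transition_rates(asg)
    out = gender_biased_transitions(net, min_count=100)
    hits = out[(out["src"] == inv[1]) & (out["dst"] == inv[3]) & out["significant"]]
    assert len(hits) >= 1
    assert (hits["female_rate"] > hits["male_rate"]).all()
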