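import numpy as np
import pandas as pd
import pytest

import morbtraj as mt
from morbtraj.errors import ConfigurationError
from morbtraj.evaluation import match_clusters_to_states
from morbtraj.transitions import (
    CENSOR,
    DEATH,
    MultilayerNetwork,
    acyclicity_check,
    collapse_layers,
    estimate_transition_rates,
    find_sink_states,
    label_mortality_regions,
    rank_entry_clusters,
    robustness_filter,
)

from conftest import make_assignments


def test_frequency_definition_of_rates():
    # 10 source patient-years in cluster 1; 3 found in cluster 2 next year
    per_patient = {f"p{i}": [1, 2] for i in range(3)}
    per_patient.update({f"q{i}": [1, 1] for i in range(7)})
    net = estimate_transition_rates(make_assignments(per_patient))
    r = net.rates().set_index(["src", "dst"])
    assert r.loc[(1, 2), "rate"] == pytest.approx(0.3)
    assert r.loc[(1, 1), "rate"] == pytest.approx(0.7)


def test_death_and_censoring_classification():
    net = estimate_transition_rates(make_assignments({"a": [3, 3, "D3"], "b": [3, 3]}))
    c = net.counts.set_index(["src", "dst"])["count"]
    # a: 3->3, then 3->death; b: 3->3, then censored at the window end
    assert c.loc[(3, 3)] == 2
    assert c.loc[(3, DEATH)] == 1
    assert c.loc[(3, CENSOR)] == 1
    # rates computed over at-risk years (transitions + deaths)
    r = net.rates().set_index(["src", "dst"])
    assert r.loc[(3, 3), "at_risk"] == 3
    assert r.loc[(3, DEATH), "rate"] == pytest.approx(1 / 3)


def test_row_stochasticity_per_layer(small_net):
    r = small_net.rates()
    r = r[r["dst"] != CENSOR]
    sums = r.groupby(["sex", "age_group", "src"])["rate"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_sources_without_at_risk_years_are_undefined_not_zero():
    # the only source year is the last observed year -> censored only
    net = estimate_transition_rates(make_assignments({"a": [4]}, start_year=2014))
    und = net.undefined_sources()
    assert len(und) == 1 and und.iloc[0]["src"] == 4
    assert not (net.rates()["rate"].fillna(-1) == 0).any()


def test_collapse_pools_counts_exactly():
    f1 = make_assignments({f"p{i}": [1, 2] for i in range(3)}, sex="male")
    f1b = make_assignments({f"q{i}": [1, 1] for i in range(7)}, sex="male")
    f2 = make_assignments({f"r{i}": [1, 2 if i == 0 else 1] for i in range(10)}, sex="female")
    net = estimate_transition_rates(pd.concat([f1, f1b, f2], ignore_index=True))
    coll = collapse_layers(net)
    r = coll.rates().set_index(["src", "dst"])
    assert r.loc[(1, 2), "count"] == 4
    assert r.loc[(1, 2), "rate"] == pytest.approx(4 / 20)
    # collapsed counts equal the sum over layers, exactly
    per_layer = net.counts.groupby(["src", "dst"])["count"].sum()
    for (src, dst), cnt in per_layer.items():
        assert coll.counts.set_index(["src", "dst"]).loc[(src, dst), "count"] == cnt


def test_collapse_of_single_layer_is_identity(small_net):
    one = MultilayerNetwork(small_net.counts[small_net.counts["age_group"] == small_net.layers[0][1]])
    coll = collapse_layers(one)
    a = one.counts.groupby(["src", "dst"])["count"].sum().sort_index()
    b = coll.counts.groupby(["src", "dst"])["count"].sum().sort_index()
    assert a.equals(b)


def test_robustness_filter_rules():
    counts = pd.DataFrame(
        [
            ("male", "50-59", 0, 1, 4, 0),     # rate 4/1000 = 0.004 -> dropped
            ("male", "50-59", 0, 0, 996, 0),
            ("male", "50-59", 2, 3, 1, 0),     # rate 0.2 but n=1 -> dropped by count
            ("male", "50-59", 2, 2, 4, 0),
        ],
        columns=["sex", "age_group", "src", "dst", "count", "age_sum"],
    )
    net = MultilayerNetwork(counts)
    kept = robustness_filter(net, min_rate=0.005, min_count=100)
    assert set(zip(kept["src"], kept["dst"])) == {(0, 0)}
    # identity filter keeps every observed edge
    assert len(robustness_filter(net, min_rate=0.0, min_count=0)) == 4
    hi = robustness_filter(net, min_rate=0.0, min_count=100)
    assert (2, 3) not in set(zip(hi["src"], hi["dst"]))


def test_sink_detection_rules():
    counts = pd.DataFrame(
        [
            ("all", "all", 0, 1, 5, 0),
            ("all", "all", 1, 1, 5, 0),        # self-loop only
            ("all", "all", 1, DEATH, 2, 0),    # death does not count as outgoing
            ("all", "all", 2, 0, 1, 0),
            ("all", "all", 0, 2, 1, 0),
        ],
        columns=["sex", "age_group", "src", "dst", "count", "age_sum"],
    )
    net = MultilayerNetwork(counts)
    assert find_sink_states(net) == [1]
    full = MultilayerNetwork(
        pd.DataFrame(
            [("all", "all", a, b, 1, 0) for a in (0, 1) for b in (0, 1) if a != b],
            columns=["sex", "age_group", "src", "dst", "count", "age_sum"],
        )
    )
    assert find_sink_states(full) == []


def test_terminal_planted_state_is_a_sink(small_data, small_assignments, small_net):
    truth = small_data["truth"]
    mapping = match_clusters_to_states(small_assignments, truth)
    terminal_clusters = [c for c, s in mapping.items() if s == truth.n_states - 1]
    sinks = find_sink_states(small_net)
    assert set(terminal_clusters) <= set(sinks)


def test_acyclicity_on_fitted_model_and_injected_cycle(small_net):
    ok, cycle = acyclicity_check(small_net)
    assert ok and cycle is None
    bad = small_net.counts.copy()
    back = pd.DataFrame(
        [{"sex": "male", "age_group": "50-59", "src": 99, "dst": 98, "count": 1, "age_sum": 0},
         {"sex": "male", "age_group": "50-59", "src": 98, "dst": 99, "count": 1, "age_sum": 0}]
    )
    ok2, cycle2 = acyclicity_check(MultilayerNetwork(pd.concat([bad, back], ignore_index=True)))
    assert not ok2
    assert set(cycle2) == {(98, 99), (99, 98)}


def test_mortality_region_labelling():
    profiles = pd.DataFrame(
        {
            "cluster_id": [1, 2, 3, 4, 5],
            "size": [10] * 5,
            "n_male": [5] * 5,
            "n_female": [5] * 5,
            "mean_age": [72.0, 70.0, 68.0, 40.0, 60.0],
            "annual_mortality": [0.0025, 0.05, 0.015, 0.05, np.nan],
        }
    )
    regions = {r.name: r.members for r in label_mortality_regions(profiles)}
    assert regions["low"] == [1]
    assert regions["high"] == [2]
    assert regions["unlabelled"] == [3]  # 1.5% falls in the printed band gap
    assert 4 not in sum(regions.values(), [])  # too young to be labelled
    with pytest.raises(ConfigurationError):
        label_mortality_regions(profiles, bands={"a": (0.0, 0.01), "b": (0.005, 0.02)})


def test_entry_ranking_credits_the_cluster_before_first_entry():
    frame = make_assignments(
        {
            "a": [0, 7, 42, 42],   # credits 7
            "b": [0, 7, 42, 43],   # credits 7 once (first entry only)
            "c": [0, 0, 5, 42],    # credits 5
            "d": [42, 42, 42, 42], # already inside at first observation: nobody credited
            "e": [0, 0, 0, 0],     # never enters
        }
    )
    ranked = rank_entry_clusters(frame, {42, 43})
    assert list(ranked["cluster"]) == [7, 5]
    assert list(ranked["entries"]) == [2, 1]
    assert len(rank_entry_clusters(make_assignments({"x": [0, 0]}), {42})) == 0


def test_planted_high_risk_state_is_top_entry_route(small_data, small_assignments):
    """The generator routes most region entries through latent state 1
    (double progression rate); its cluster must rank first."""
    truth = small_data["truth"]
    mapping = match_clusters_to_states(small_assignments, truth)
    inv = {s: c for c, s in mapping.items()}
    region = [inv[truth.n_states - 1]]
    ranked = rank_entry_clusters(small_assignments, region)
    assert int(ranked.iloc[0]["cluster"]) == inv[1]
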