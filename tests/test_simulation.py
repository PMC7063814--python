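import numpy as np
import pandas as pd
import pytest

import morbtraj as mt
from morbtraj.cohort import CohortSpec, build_health_states, select_washout_cohort
from morbtraj.simulation import (
    SimulationConfig,
    _layer_tables,
    benchmark_assign,
    compare_models,
    simulate_cohort,
    start_distribution_from,
    total_variation,
)
from morbtraj.transitions import DEATH, MultilayerNetwork, estimate_transition_rates

from conftest import make_stays
from oracles import binom_ci


def _net(rows):
    return MultilayerNetwork(
        pd.DataFrame(rows, columns=["sex", "age_group", "src", "dst", "count", "age_sum"])
    )


def _start(cluster=0, age=52, sex="male"):
    return pd.DataFrame({"sex": [sex], "age": [age], "cluster": [cluster], "prob": [1.0]})


def test_identity_network_gives_constant_trajectories():
    net = _net([("male", "50-59", 0, 0, 100, 0)])
    sim, diag = simulate_cohort(
        net, SimulationConfig(n_patients=50, years=(2003, 2008), seed=0), start=_start()
    )
    assert (sim["cluster"] == 0).all()
    assert not sim["is_death_year"].any()
    assert sim.groupby("patient_id")["year"].count().eq(6).all()


def test_chain_transition_fraction_matches_planted_half():
    net = _net([("male", "50-59", 0, 0, 500, 0), ("male", "50-59", 0, 1, 500, 0),
                ("male", "50-59", 1, 1, 100, 0)])
    sim, _ = simulate_cohort(
        net, SimulationConfig(n_patients=10_000, years=(2003, 2004), seed=3), start=_start()
    )
    moved = int((sim[sim["year"] == 2004]["cluster"] == 1).sum())
    lo, hi = binom_ci(moved, 10_000)
    assert lo <= 0.5 <= hi


def test_death_absorbs_and_is_terminal():
    net = _net([("male", "50-59", 0, 0, 50, 0), ("male", "50-59", 0, DEATH, 50, 0)])
    sim, _ = simulate_cohort(
        net, SimulationConfig(n_patients=500, years=(2003, 2010), seed=1), start=_start()
    )
    deaths = sim[sim["is_death_year"]]
    last = sim.groupby("patient_id")["year"].max()
    for pid, y in zip(deaths["patient_id"], deaths["year"]):
        assert last[pid] == y


def test_sampling_tables_are_probability_vectors(small_net):
    tables, _ = _layer_tables(small_net, small_net.clusters)
    for P, defined in tables.values():
        if defined.any():
            assert np.allclose(P[defined].sum(axis=1), 1.0, atol=1e-12)


def test_seed_reproducibility(small_net, small_assignments):
    start = start_distribution_from(small_assignments)
    cfg = SimulationConfig(n_patients=200, years=(2003, 2010), seed=7)
    s1, _ = simulate_cohort(small_net, cfg, start=start)
    s2, _ = simulate_cohort(small_net, cfg, start=start)
    pd.testing.assert_frame_equal(s1, s2)
    s3, _ = simulate_cohort(
        small_net, SimulationConfig(n_patients=200, years=(2003, 2010), seed=8), start=start
    )
    assert not s1["cluster"].equals(s3["cluster"])


def test_undefined_rows_leave_patient_in_place_and_are_logged():
    # no data at all for cluster 1, but patients start there
    net = _net([("male", "50-59", 0, 0, 10, 0)])
    sim, diag = simulate_cohort(
        net, SimulationConfig(n_patients=20, years=(2003, 2006), seed=0), start=_start(cluster=1)
    )
    assert (sim["cluster"] == 1).all()
    assert diag["undefined_row_events"] > 0


@pytest.fixture(scope="module")
def bench_states(block_table):
    stays = make_stays(
        [
            # patient A: hypertension (2004) then heart disease (2007)
            ("A", "male", "50-54", "2004-03-01", "2004-03-02", "normal", "I10"),
            ("A", "male", "53-57", "2007-03-01", "2007-03-02", "normal", "I30"),
            # patient B: two blocks, one common one rare in this toy cohort
            ("B", "male", "50-54", "2004-05-01", "2004-05-02", "normal", "I10;B99"),
            # patient C: healthy
            ("C", "female", "40-44", "2005-01-01", "2005-01-02", "normal", "Z03"),
            # extra carriers making I10 the common block
            ("E1", "male", "50-54", "2004-01-01", "2004-01-02", "normal", "I10"),
            ("E2", "male", "50-54", "2004-01-01", "2004-01-02", "normal", "I10"),
        ]
    )
    spec = CohortSpec()
    return build_health_states(stays, select_washout_cohort(stays, spec), spec, block_table)


def test_most_recent_label_tracks_latest_acquisition(bench_states, block_table):
    out = benchmark_assign(bench_states, "most_recent").set_index(["patient_id", "year"])
    b_i10 = block_table.map_code("I10")
    b_i30 = block_table.map_code("I30")
    assert out.loc[("A", 2005), "cluster"] == b_i10
    assert out.loc[("A", 2008), "cluster"] == b_i30


def test_least_frequent_label_picks_rare_block(bench_states, block_table):
    out = benchmark_assign(bench_states, "least_frequent").set_index(["patient_id", "year"])
    b_rare = block_table.map_code("B99")
    assert out.loc[("B", 2010), "cluster"] == b_rare


def test_all_zero_vectors_get_dedicated_healthy_label(bench_states, block_table):
    for mode in ("most_recent", "least_frequent"):
        out = benchmark_assign(bench_states, mode).set_index(["patient_id", "year"])
        assert out.loc[("C", 2010), "cluster"] == block_table.n_blocks
        assert out.loc[("A", 2003), "cluster"] == block_table.n_blocks  # before first diagnosis


def test_total_variation_bounds_and_degenerate_model():
    p = pd.Series({0: 1.0})
    q = pd.Series({0: 0.25, 1: 0.25, 2: 0.5})
    tv = total_variation(p, q)
    assert tv == pytest.approx(0.75)
    assert 0 <= tv <= 1


def test_self_consistent_model_has_small_divergence(small_assignments, small_net):
    years = (int(small_assignments["year"].min()), int(small_assignments["year"].max()))
    out = compare_models({"self": (small_assignments, small_net)}, years, seed=2)
    assert out.iloc[0]["score"] < 0.05
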