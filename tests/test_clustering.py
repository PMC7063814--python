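import numpy as np
import pytest

import morbtraj as mt
from morbtraj.clustering import (
    LeafNode,
    assign,
    assign_many,
    best_binary_split,
    choose_k_diagnostic,
    cluster_inertia,
    fit_divclus,
)
from morbtraj.errors import ValidationError

from oracles import brute_best_split, brute_greedy_fit, brute_inertia


def test_two_group_split_gain_matches_closed_form():
    X = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])
    var, gain = best_binary_split(X)
    assert var in (0, 1)
    assert var == 0  # tie broken by lowest variable index
    assert gain == pytest.approx(2.0)  # parent inertia 4 x 0.5, children pure


def test_identical_vectors_yield_no_split():
    X = np.ones((5, 3), dtype=int)
    assert best_binary_split(X) == (None, 0.0)


@pytest.mark.parametrize("seed", range(10))
def test_best_split_matches_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(6, 4))
    w = rng.integers(1, 4, size=6).astype(float)
    var, gain = best_binary_split(X, w)
    bvar, bgain = brute_best_split(X, w)
    assert var == bvar
    assert gain == pytest.approx(bgain, abs=1e-9)


def test_k1_returns_single_cluster_with_total_inertia():
    rng = np.random.default_rng(0)
    X = rng.integers(0, 2, size=(20, 5))
    m = fit_divclus(X, 1)
    assert m.K == 1 and isinstance(m.root, LeafNode)
    assert m.criteria[0] == (frozenset(), frozenset())
    assert m.inertia_path[0] == pytest.approx(brute_inertia(X))


def test_k2_separates_pure_groups():
    X = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])
    m = fit_divclus(X, 2)
    labels = assign_many(X, m)
    assert cluster_inertia(X, labels) == pytest.approx(0.0)
    assert len(set(labels)) == 2


@pytest.mark.parametrize("seed", range(8))
def test_greedy_fit_matches_bruteforce_tree(seed):
    rng = np.random.default_rng(100 + seed)
    n, d, k = rng.integers(4, 13), rng.integers(2, 6), rng.integers(2, 5)
    X = rng.integers(0, 2, size=(n, d))
    m = fit_divclus(X, int(k))
    labels = assign_many(X, m)
    oracle_inertia, _ = brute_greedy_fit(X, int(k))
    assert cluster_inertia(X, labels) == pytest.approx(oracle_inertia, abs=1e-9)


def test_k_beyond_achievable_sets_truncated_flag():
    X = np.array([[0, 0], [0, 0], [1, 1]])
    m = fit_divclus(X, 5)
    assert m.truncated
    assert m.K == 2  # only one informative split exists


def test_all_zero_vector_lands_in_full_exclusion_leaf(small_model):
    cid = assign(np.zeros(small_model.D, dtype=int), small_model)
    inc, exc = small_model.criteria[cid]
    assert cid == 0 and inc == frozenset()


def test_assignment_agrees_with_criteria_scan(small_model):
    rng = np.random.default_rng(5)
    X = (rng.uniform(size=(1000, small_model.D)) < 0.05).astype(np.uint8)
    labels = assign_many(X, small_model)
    for x, lab in zip(X, labels):
        bits = set(np.nonzero(x)[0])
        matches = [
            c
            for c, (inc, exc) in small_model.criteria.items()
            if inc <= bits and not (exc & bits)
        ]
        assert matches == [lab]


def test_wrong_vector_length_rejected(small_model):
    with pytest.raises(ValidationError):
        assign(np.zeros(small_model.D + 1), small_model)


def test_partition_and_pairwise_criteria(small_data, small_model):
    X = small_data["states"].matrix
    labels = assign_many(X, small_model)
    # partition: each observed vector satisfies exactly the assigned leaf
    for cid in small_model.cluster_ids:
        inc, exc = small_model.criteria[cid]
        sel = labels == cid
        if inc:
            assert (X[sel][:, sorted(inc)] == 1).all()
        if exc:
            assert (X[sel][:, sorted(exc)] == 0).all()
        assert not (inc & exc)
    # every leaf pair disagrees on at least one path variable
    ids = small_model.cluster_ids
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ia, ea = small_model.criteria[a]
            ib, eb = small_model.criteria[b]
            assert (ia & eb) or (ib & ea)


def test_inertia_matches_bruteforce_on_random_labels():
    rng = np.random.default_rng(2)
    X = rng.integers(0, 2, size=(100, 7))
    labels = rng.integers(0, 4, size=100)
    expected = sum(brute_inertia(X[labels == c]) for c in range(4))
    assert cluster_inertia(X, labels) == pytest.approx(expected, abs=1e-9)
    # one state per cluster -> zero
    assert cluster_inertia(X[:10], np.arange(10)) == pytest.approx(0.0)


def test_inertia_path_weakly_decreasing(small_model):
    path = small_model.inertia_path
    assert all(a >= b - 1e-9 for a, b in zip(path, path[1:]))


def test_duplicate_weighting_is_exact():
    rng = np.random.default_rng(9)
    U = rng.integers(0, 2, size=(8, 4))
    reps = rng.integers(1, 5, size=8)
    X = np.repeat(U, reps, axis=0)
    m_dup = fit_divclus(X, 3)
    assert cluster_inertia(X, assign_many(X, m_dup)) == pytest.approx(
        brute_greedy_fit(X, 3)[0], abs=1e-9
    )


def test_choose_k_on_correlated_two_block_data():
    rng = np.random.default_rng(4)
    z = rng.integers(0, 2, size=400)
    X = np.stack([z, z], axis=1)  # perfectly correlated columns
    diag = choose_k_diagnostic(X, [1, 2], n_null=20, seed=0)
    k2 = diag[diag["k"] == 2].iloc[0]
    assert k2["mean_inertia"] < k2["null_mean"]
    # curves weakly decreasing in k
    assert diag["mean_inertia"].is_monotonic_decreasing
    assert diag["null_mean"].is_monotonic_decreasing


def test_choose_k_on_independent_data_matches_null():
    rng = np.random.default_rng(8)
    X = (rng.uniform(size=(400, 6)) < 0.3).astype(np.uint8)
    diag = choose_k_diagnostic(X, [2, 4, 6], n_null=30, seed=1)
    inside = (diag["mean_inertia"] >= diag["null_lo"]) & (diag["mean_inertia"] <= diag["null_hi"])
    assert inside.mean() >= 2 / 3  # independent columns: data curve sits in the null band
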