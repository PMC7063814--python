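"""Monothetic divisive clustering of binary health-state vectors.

The algorithm repeatedly bisects one cluster by asking a single yes/no
question "has block *b* been diagnosed?", choosing the (cluster, block)
pair whose bipartition maximally decreases the total within-cluster
inertia (sum of squared Euclidean distances to the cluster centroid).
Because every split questions a single variable, each final cluster is
described by interpretable *inclusion* criteria (blocks answered 1 on the
path) and *exclusion* criteria (blocks answered 0), and every pair of
clusters disagrees on at least one path variable.

Cluster labels follow the splitting history: the root cluster is 0, the
zero-branch of a split keeps its parent's label and the one-branch
receives the next fresh integer.  The all-exclusion ("healthy") path
therefore always keeps label 0.  Ties in the split gain (within 1e-12)
are broken by lowest cluster label, then lowest block index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

GAIN_TOL = 1e-12


@dataclass
class SplitNode:
    variable: int
    zero: "SplitNode | LeafNode"
    one: "SplitNode | LeafNode"


@dataclass
class LeafNode:
    cluster_id: int


@dataclass
class ClusterModel:
    """Fitted monothetic tree with per-leaf inclusion/exclusion criteria."""

    root: SplitNode | LeafNode
    K: int
    D: int
    criteria: dict[int, tuple[frozenset, frozenset]]  # cluster -> (inclusion, exclusion)
    truncated: bool = False
    split_sequence: list[tuple[int, int, float]] = field(default_factory=list)  # (leaf, var, gain)
    inertia_path: list[float] = field(default_factory=list)  # total within-inertia at 1..K leaves

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(self.criteria)

    def to_json_dict(self) -> dict:
        def enc(node):
            if isinstance(node, LeafNode):
                return {"cluster": node.cluster_id}
            return {"variable": int(node.variable), "zero": enc(node.zero), "one": enc(node.one)}

        return {
            "D": self.D,
            "K": self.K,
            "truncated": self.truncated,
            "tree": enc(self.root),
            "criteria": {
                str(c): {"include": sorted(inc), "exclude": sorted(exc)}
                for c, (inc, exc) in self.criteria.items()
            },
        }

    @classmethod
    def from_json_dict(cls, payload: dict) -> "ClusterModel":
        def dec(node):
            if "cluster" in node:
                return LeafNode(int(node["cluster"]))
            return SplitNode(int(node["variable"]), dec(node["zero"]), dec(node["one"]))

        criteria = {
            int(c): (frozenset(v["include"]), frozenset(v["exclude"]))
            for c, v in payload["criteria"].items()
        }
        return cls(root=dec(payload["tree"]), K=payload["K"], D=payload["D"], criteria=criteria,
                   truncated=payload["truncated"])

    def criteria_frame(self, blocks=None) -> pd.DataFrame:
        """Long-format criteria export: cluster_id, criterion_type, block_id, block_label."""
        rows = []
        for cid in self.cluster_ids:
            inc, exc = self.criteria[cid]
            for b in sorted(inc):
                rows.append((cid, "include", b))
            for b in sorted(exc):
                rows.append((cid, "exclude", b))
        out = pd.DataFrame(rows, columns=["cluster_id", "criterion_type", "block_id"])
        out["block_label"] = (
            out["block_id"].map(lambda b: blocks.label(b)) if blocks is not None else out["block_id"].astype(str)
        )
        return out


def _as_matrix(states) -> np.ndarray:
    if hasattr(states, "matrix"):
        return states.matrix
    X = np.asarray(states)
    if X.ndim != 2:
        raise ValidationError("health states must form a 2-D binary matrix")
    return X


def _col_inertia(s: np.ndarray, n: float) -> float:
    """Within inertia of a binary cluster from weighted column sums s and weight n."""
    if n <= 0:
        return 0.0
    return float(np.sum(s - s * s / n))


def best_binary_split(vectors, weights=None) -> tuple[int | None, float]:
    """Best single-variable bipartition by inertia gain.

    Returns ``(variable, gain)``; ``(None, 0.0)`` when no variable yields a
    positive gain (e.g. all vectors identical).  The gain is parent inertia
    minus the two children's inertia and is always non-negative.
    """
    X = _as_matrix(vectors).astype(np.float64, copy=False)
    n_rows, D = X.shape
    w = np.ones(n_rows) if weights is None else np.asarray(weights, dtype=float)
    n = w.sum()
    Xw = X * w[:, None]
    s = Xw.sum(axis=0)
    M = Xw.T @ X  # M[v, j] = weighted co-occurrence
    parent = _col_inertia(s, n)

    n1 = s.copy()
    n0 = n - n1
    valid = (n1 > 0) & (n0 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        i1 = np.where(n1 > 0, (M - M * M / np.maximum(n1[:, None], 1e-300)).sum(axis=1), 0.0)
        M0 = s[None, :] - M
        i0 = np.where(n0 > 0, (M0 - M0 * M0 / np.maximum(n0[:, None], 1e-300)).sum(axis=1), 0.0)
    gains = np.where(valid, parent - i1 - i0, -np.inf)
    if not valid.any():
        return None, 0.0
    best = gains.max()
    if best <= GAIN_TOL:
        return None, 0.0
    var = int(np.nonzero(gains >= best - GAIN_TOL)[0][0])
    return var, float(gains[var])


@dataclass
class _Leaf:
    label: int
    rows: np.ndarray  # indices into the unique-vector matrix
    inclusion: frozenset
    exclusion: frozenset
    node: LeafNode
    best: tuple[int | None, float] = (None, 0.0)


def _dedupe(X: np.ndarray, weights) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    Xc = np.ascontiguousarray(X.astype(np.uint8, copy=False))
    void = Xc.view(np.dtype((np.void, Xc.shape[1])))[:, 0]
    _, first_idx, inverse = np.unique(void, return_index=True, return_inverse=True)
    U = Xc[first_idx]
    w = np.bincount(inverse, weights=weights, minlength=len(first_idx)).astype(float)
    return U, w, inverse


def fit_divclus(states, K: int, weights=None) -> ClusterModel:
    """Greedy divisive fit: split the leaf with the largest achievable gain
    until ``K`` leaves exist or no positive gain remains.

    Duplicate vectors are collapsed and weighted by multiplicity, which is
    exact for inertia computations.  If fewer than ``K`` leaves are
    achievable the model is returned with ``truncated=True``.
    """
    X = _as_matrix(states)
    if K < 1:
        raise ValidationError("K must be >= 1")
    n_rows, D = X.shape
    if n_rows == 0:
        raise ValidationError("cannot cluster an empty state table")
    base_w = np.ones(n_rows) if weights is None else np.asarray(weights, dtype=float)
    U, w, _ = _dedupe(X, base_w)

    root_node = LeafNode(0)
    leaves: dict[int, _Leaf] = {
        0: _Leaf(0, np.arange(len(U)), frozenset(), frozenset(), root_node)
    }
    leaves[0].best = best_binary_split(U, w)
    model_root: SplitNode | LeafNode = root_node
    parent_of: dict[int, SplitNode | None] = {0: None}
    which_child: dict[int, str] = {}
    next_label = 1
    split_sequence: list[tuple[int, int, float]] = []
    total_inertia = _col_inertia((U * w[:, None]).sum(axis=0), w.sum())
    inertia_path = [total_inertia]
    truncated = False

    while len(leaves) < K:
        cands = [(lf.best[1], lab) for lab, lf in leaves.items() if lf.best[0] is not None]
        if not cands:
            truncated = True
            break
        best_gain = max(g for g, _ in cands)
        lab = min(l for g, l in cands if g >= best_gain - GAIN_TOL)
        lf = leaves[lab]
        var, gain = lf.best
        mask = U[lf.rows, var] == 1
        rows1, rows0 = lf.rows[mask], lf.rows[~mask]

        node = SplitNode(var, LeafNode(lab), LeafNode(next_label))
        parent = parent_of[lab]
        if parent is None:
            model_root = node
        else:
            setattr(parent, which_child[lab], node)
        zero = _Leaf(lab, rows0, lf.inclusion, lf.exclusion | {var}, node.zero)
        one = _Leaf(next_label, rows1, lf.inclusion | {var}, lf.exclusion, node.one)
        parent_of[lab] = node
        which_child[lab] = "zero"
        parent_of[next_label] = node
        which_child[next_label] = "one"
        for child in (zero, one):
            child.best = best_binary_split(U[child.rows], w[child.rows])
            leaves[child.label] = child
        split_sequence.append((lab, var, gain))
        total_inertia -= gain
        inertia_path.append(max(total_inertia, 0.0))
        next_label += 1

    criteria = {lab: (lf.inclusion, lf.exclusion) for lab, lf in leaves.items()}
    return ClusterModel(
        root=model_root,
        K=len(leaves),
        D=D,
        criteria=criteria,
        truncated=truncated or len(leaves) < K,
        split_sequence=split_sequence,
        inertia_path=inertia_path,
    )


def assign(vector, model: ClusterModel) -> int:
    """Descend the tree; the result satisfies the returned leaf's criteria."""
    v = np.asarray(vector)
    if v.shape != (model.D,):
        raise ValidationError(f"vector length {v.shape} != D={model.D}")
    node = model.root
    while isinstance(node, SplitNode):
        node = node.one if v[node.variable] else node.zero
    return node.cluster_id


def assign_many(states, model: ClusterModel) -> np.ndarray:
    """Vectorised tree descent for a whole state matrix."""
    X = _as_matrix(states)
    if X.shape[1] != model.D:
        raise ValidationError(f"matrix width {X.shape[1]} != D={model.D}")
    labels = np.empty(len(X), dtype=int)
    stack: list[tuple[SplitNode | LeafNode, np.ndarray]] = [(model.root, np.arange(len(X)))]
    while stack:
        node, idx = stack.pop()
        if isinstance(node, LeafNode):
            labels[idx] = node.cluster_id
            continue
        ones = X[idx, node.variable] == 1
        stack.append((node.one, idx[ones]))
        stack.append((node.zero, idx[~ones]))
    return labels


def cluster_inertia(states, labels, weights=None) -> float:
    """Total within-cluster inertia of a labelled binary state set."""
    X = _as_matrix(states).astype(np.float64, copy=False)
    labels = np.asarray(labels)
    w = np.ones(len(X)) if weights is None else np.asarray(weights, dtype=float)
    _, lab_idx = np.unique(labels, return_inverse=True)
    k = lab_idx.max() + 1
    S = np.zeros((k, X.shape[1]))
    np.add.at(S, lab_idx, X * w[:, None])
    n = np.bincount(lab_idx, weights=w, minlength=k)
    with np.errstate(divide="ignore", invalid="ignore"):
        per = S - np.where(n[:, None] > 0, S * S / np.maximum(n[:, None], 1e-300), 0.0)
    return float(per.sum())


@dataclass
class ClusterProfiles:
    frame: pd.DataFrame  # cluster_id, size, n_male, n_female, mean_age, annual_mortality
    prevalence: pd.DataFrame  # cluster_id x block_id


def characterise_clusters(model: ClusterModel, states, labels=None) -> ClusterProfiles:
    """Per-cluster size, sex split, mean age, yearly in-hospital mortality
    and block prevalences.

    Mortality is the fraction of the cluster's patient-years that end in
    an in-hospital death; empty clusters get size 0 and NaN mortality.
    """
    if labels is None:
        labels = assign_many(states, model)
    idx = states.index
    X = states.matrix
    rows = []
    prev_rows = {}
    for cid in model.cluster_ids:
        sel = labels == cid
        size = int(sel.sum())
        if size == 0:
            rows.append((cid, 0, 0, 0, np.nan, np.nan))
            prev_rows[cid] = np.full(model.D, np.nan)
            continue
        sexes = idx.loc[sel, "sex"]
        deaths = int(idx.loc[sel, "is_death_year"].sum())
        rows.append(
            (
                cid,
                size,
                int((sexes == "male").sum()),
                int((sexes == "female").sum()),
                float(idx.loc[sel, "age"].mean()),
                deaths / size,
            )
        )
        prev_rows[cid] = X[sel].mean(axis=0)
    frame = pd.DataFrame(
        rows, columns=["cluster_id", "size", "n_male", "n_female", "mean_age", "annual_mortality"]
    )
    prevalence = pd.DataFrame.from_dict(prev_rows, orient="index")
    prevalence.index.name = "cluster_id"
    return ClusterProfiles(frame=frame, prevalence=prevalence)


def choose_k_diagnostic(states, k_grid, n_null: int = 10, seed: int = 0) -> pd.DataFrame:
    """Mean within-cluster inertia along the divisive sequence, on the data
    and on column-permuted null replicates (correlations destroyed,
    margins preserved).

    Returns one row per k in ``k_grid``: observed mean inertia and the
    null mean with a 95% band over replicates.
    """
    X = _as_matrix(states)
    k_grid = sorted(int(k) for k in k_grid)
    kmax = max(k_grid)
    n = len(X)

    def path_for(mat) -> list[float]:
        m = fit_divclus(mat, kmax)
        path = list(m.inertia_path)
        while len(path) < kmax:
            path.append(path[-1])
        return path

    data_path = path_for(X)
    rng = np.random.default_rng(seed)
    null_paths = []
    for _ in range(n_null):
        Xp = X.copy()
        for j in range(X.shape[1]):
            rng.shuffle(Xp[:, j])
        null_paths.append(path_for(Xp))
    null_arr = np.asarray(null_paths) / n
    data_arr = np.asarray(data_path) / n
    rows = []
    for k in k_grid:
        nul = null_arr[:, k - 1]
        rows.append(
            {
                "k": k,
                "mean_inertia": data_arr[k - 1],
                "null_mean": nul.mean(),
                "null_lo": np.quantile(nul, 0.025),
                "null_hi": np.quantile(nul, 0.975),
            }
        )
    return pd.DataFrame(rows)
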