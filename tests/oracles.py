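"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities by direct definition (naive loops,
exact integer arithmetic), deliberately avoiding the package's optimised
code paths.
"""

from math import comb

import numpy as np

TOL = 1e-12


def brute_inertia(X, w=None) -> float:
    """Sum of squared Euclidean distances to the (weighted) centroid."""
    X = np.asarray(X, dtype=float)
    w = np.ones(len(X)) if w is None else np.asarray(w, dtype=float)
    n = w.sum()
    if n == 0:
        return 0.0
    c = (X * w[:, None]).sum(axis=0) / n
    return float((w * ((X - c) ** 2).sum(axis=1)).sum())


def brute_best_split(X, w=None):
    """Exhaustive single-variable split search by direct inertia recomputation."""
    X = np.asarray(X)
    w = np.ones(len(X)) if w is None else np.asarray(w, dtype=float)
    parent = brute_inertia(X, w)
    best_gain, best_var = 0.0, None
    for v in range(X.shape[1]):
        m = X[:, v] == 1
        if m.all() or not m.any():
            continue
        gain = parent - brute_inertia(X[m], w[m]) - brute_inertia(X[~m], w[~m])
        if gain > best_gain + TOL:
            best_gain, best_var = gain, v
    if best_var is None or best_gain <= TOL:
        return None, 0.0
    return best_var, best_gain


def brute_greedy_fit(X, K):
    """Greedy monothetic divisive fit by naive recomputation.

    Mirrors the documented tie rule (lowest leaf label, then lowest
    variable; zero-branch inherits its parent's label) but shares no code
    with the package.  Returns (total within inertia, {label: row indices}).
    """
    X = np.asarray(X)
    leaves = {0: np.arange(len(X))}
    next_label = 1
    while len(leaves) < K:
        best = None  # (gain, label, var)
        for label in sorted(leaves):
            rows = leaves[label]
            parent = brute_inertia(X[rows])
            for v in range(X.shape[1]):
                m = X[rows, v] == 1
                if m.all() or not m.any():
                    continue
                gain = parent - brute_inertia(X[rows[m]]) - brute_inertia(X[rows[~m]])
                if gain > TOL and (best is None or gain > best[0] + TOL):
                    best = (gain, label, v)
        if best is None:
            break
        _, label, v = best
        rows = leaves[label]
        m = X[rows, v] == 1
        leaves[label] = rows[~m]
        leaves[next_label] = rows[m]
        next_label += 1
    total = sum(brute_inertia(X[rows]) for rows in leaves.values())
    return total, leaves


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration with exact
    integer weights: sum of outcome probabilities not exceeding the
    observed one, conditioned on all margins."""
    r1, r2, cs = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lo, hi = max(0, cs - r2), min(r1, cs)
    weights = [comb(r1, k) * comb(r2, cs - k) for k in range(lo, hi + 1)]
    obs = weights[a - lo]
    return sum(w for w in weights if w <= obs) / comb(n, cs)


def binom_ci(k: int, n: int, alpha: float = 0.05):
    """Exact (Clopper-Pearson) binomial interval via direct tail search."""
    from scipy import stats

    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(lo), float(hi)
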