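"""Generative trajectory simulation and single-disease benchmark models.

The fitted multilayer network defines a probabilistic model of disease
progression: next year's cluster depends only on sex, current age band
and current cluster.  The simulator evolves a cohort year by year under
those rates (death absorbs; censoring, an observation artifact, is
renormalised away), which supports round-trip rate recovery checks and
forecast-vs-data comparisons.  Two benchmark labellings assign each
patient-year a single disease block (the most recently acquired, or the
population-least-frequent one) instead of a multimorbidity cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterModel, cluster_inertia
from .errors import ConfigurationError
from .registry import N_AGE_BANDS, age_band_10y, age_band_label
from .transitions import CENSOR, DEATH, MultilayerNetwork
from .trajectories import reduce_trajectory, trajectories_from_assignments


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int
    years: tuple[int, int]
    seed: int = 0

    def validate(self):
        if self.n_patients < 1:
            raise ConfigurationError("n_patients", "must be >= 1")
        if self.years[0] > self.years[1]:
            raise ConfigurationError("years", "empty simulation window")


def start_distribution_from(assignments: pd.DataFrame) -> pd.DataFrame:
    """Empirical (sex, age, cluster) distribution of the first observed year."""
    y0 = assignments["year"].min()
    first = assignments[assignments["year"] == y0]
    g = first.groupby(["sex", "age", "cluster"], as_index=False).size()
    g["prob"] = g["size"] / g["size"].sum()
    return g[["sex", "age", "cluster", "prob"]]


def _layer_tables(net: MultilayerNetwork, clusters: list[int]):
    """Per-layer sampling tables: renormalised (K, K+1) matrices of
    transition + death probabilities, and a defined-row mask."""
    pos = {c: i for i, c in enumerate(clusters)}
    k = len(clusters)
    tables = {}
    for sex, ag in net.layers:
        Q, death, risk = net.layer_matrix(sex, ag, clusters)
        P = np.zeros((k, k + 1))
        defined = risk > 0
        P[defined, :k] = np.nan_to_num(Q[defined])
        P[defined, k] = np.nan_to_num(death[defined])
        # renormalise over transitions + death (drop censor mass, none here
        # since layer_matrix already excludes censored years)
        s = P.sum(axis=1, keepdims=True)
        np.divide(P, s, out=P, where=s > 0)
        tables[(sex, ag)] = (P, defined)
    return tables, pos


def simulate_cohort(
    net: MultilayerNetwork,
    config: SimulationConfig,
    start: pd.DataFrame | None = None,
    model: ClusterModel | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate yearly trajectories under the network's rates.

    Patients are drawn from ``start`` (columns sex, age, cluster, prob);
    each year the next cluster or death is sampled from the layer matching
    the patient's sex and current 10-year band, ages advance by one year
    (the oldest band is absorbing), and death ends the trajectory with a
    terminal death-year row.  Undefined rows (no at-risk data) leave the
    patient in place and are counted in the diagnostics, as are logically
    impossible steps (entering a cluster that excludes a block implied
    earlier) when a fitted ``model`` is supplied.

    Returns ``(assignments, diagnostics)``; reproducible via the seed.
    """
    config.validate()
    if start is None:
        raise ConfigurationError("start", "a start distribution is required")
    rng = np.random.default_rng(config.seed)
    clusters = sorted(set(net.clusters) | set(int(c) for c in start["cluster"].unique()))
    tables, pos = _layer_tables(net, clusters)
    k = len(clusters)
    n = config.n_patients
    y0, y1 = config.years

    draw = rng.choice(len(start), size=n, p=start["prob"].to_numpy())
    sexes = start["sex"].to_numpy()[draw]
    ages = start["age"].to_numpy()[draw].astype(int)
    cur = np.array([pos[c] for c in start["cluster"].to_numpy()[draw]])
    alive = np.ones(n, dtype=bool)
    pids = np.array([f"S{i:07d}" for i in range(n)])
    cluster_arr = np.array(clusters)
    band_labels = np.array([age_band_label(b) for b in range(N_AGE_BANDS)])
    label_to_band = {lab: b for b, lab in enumerate(band_labels)}
    # integer-keyed sampling tables for fast per-year selection
    sex_names = sorted(set(sexes) | {s for s, _ in tables})
    sex_code = {s: i for i, s in enumerate(sex_names)}
    sexes_c = np.array([sex_code[s] for s in sexes])
    int_tables = {}
    for (sex, ag), tab in tables.items():
        if ag in label_to_band:
            int_tables[(sex_code[sex], label_to_band[ag])] = tab

    diagnostics = {"undefined_row_events": 0, "impossible_steps": 0}
    if model is not None:
        incl_mask = np.zeros((k, model.D), dtype=bool)
        excl_mask = np.zeros((k, model.D), dtype=bool)
        for i, c in enumerate(clusters):
            inc, exc = model.criteria.get(c, (frozenset(), frozenset()))
            incl_mask[i, list(inc)] = True
            excl_mask[i, list(exc)] = True
        seen_incl = incl_mask[cur].copy()

    rows_pid, rows_year, rows_sex, rows_age, rows_cluster, rows_death = [], [], [], [], [], []

    def emit(maskbool, year, death_flags):
        idx = np.nonzero(maskbool)[0]
        rows_pid.append(pids[idx])
        rows_year.append(np.full(len(idx), year))
        rows_sex.append(sexes[idx])
        rows_age.append(ages[idx].copy())
        rows_cluster.append(cluster_arr[cur[idx]])
        rows_death.append(death_flags[idx])

    dead_now = np.zeros(n, dtype=bool)
    emit(alive, y0, dead_now)
    for year in range(y0, y1):
        u = rng.uniform(size=n)
        nxt = cur.copy()
        died = np.zeros(n, dtype=bool)
        bands = age_band_10y(ages)
        known = np.zeros(n, dtype=bool)
        for (sc, b), (P, defined) in int_tables.items():
            sel = alive & (sexes_c == sc) & (bands == b)
            known |= (sexes_c == sc) & (bands == b)
            if not sel.any():
                continue
            idx = np.nonzero(sel)[0]
            rows = cur[idx]
            ok = defined[rows]
            diagnostics["undefined_row_events"] += int((~ok).sum())
            if ok.any():
                sub = idx[ok]
                cum = np.cumsum(P[cur[sub]], axis=1)
                choice = (u[sub][:, None] < cum).argmax(axis=1)
                nohit = u[sub] >= cum[:, -1]
                choice = np.where(nohit, cur[sub], choice)  # numerical guard
                died_sub = choice == k
                died[sub] = died_sub
                nxt[sub] = np.where(died_sub, cur[sub], choice)
        # layers absent from the network entirely: stay in place
        diagnostics["undefined_row_events"] += int((alive & ~known).sum())

        if model is not None:
            moved = alive & ~died & (nxt != cur)
            if moved.any():
                clash = (excl_mask[nxt[moved]] & seen_incl[moved]).any(axis=1)
                diagnostics["impossible_steps"] += int(clash.sum())
            seen_incl[alive] |= incl_mask[nxt[alive]]

        cur = nxt
        ages = ages + 1
        newly_dead = died
        alive = alive & ~died
        live_or_dying = alive | newly_dead
        emit(live_or_dying, year + 1, newly_dead)
        if not alive.any():
            break

    frame = pd.DataFrame(
        {
            "patient_id": np.concatenate(rows_pid),
            "year": np.concatenate(rows_year),
            "sex": np.concatenate(rows_sex),
            "age": np.concatenate(rows_age),
            "cluster": np.concatenate(rows_cluster),
            "is_death_year": np.concatenate(rows_death),
        }
    )
    frame["age_group"] = band_labels[age_band_10y(frame["age"].to_numpy())]
    frame = frame.sort_values(["patient_id", "year"], kind="stable").reset_index(drop=True)
    return frame, diagnostics


HEALTHY_LABEL_OFFSET = 0  # healthy benchmark label = n_blocks (one past the last block id)


def benchmark_assign(states, mode: str) -> pd.DataFrame:
    """Single-disease benchmark labelling of every patient-year.

    ``mode="most_recent"`` labels each year with the most recently
    acquired block (ties within a year: lowest block id);
    ``mode="least_frequent"`` with the patient's block of lowest
    population prevalence.  All-zero vectors get the dedicated healthy
    label ``D`` (one past the last block id).
    """
    if mode not in ("most_recent", "least_frequent"):
        raise ConfigurationError("mode", f"unknown benchmark mode {mode!r}")
    acq = states.acquisitions
    healthy = states.blocks.n_blocks
    if mode == "most_recent":
        ev = acq.sort_values(["patient_id", "year", "block"], ascending=[True, True, False], kind="stable")
        ev = ev.drop_duplicates(["patient_id", "year"], keep="last")  # lowest block of the latest year
        ev = ev.rename(columns={"block": "label"})
    else:
        prev = states.matrix.mean(axis=0)  # population prevalence per block
        ev = acq.sort_values(["patient_id", "year", "block"], kind="stable").copy()
        labels = np.empty(len(ev), dtype=int)
        cur_pid, best = None, None
        for i, (pid, block, year) in enumerate(ev[["patient_id", "block", "year"]].itertuples(index=False)):
            if pid != cur_pid:
                cur_pid, best = pid, None
            cand = (prev[block], block)
            if best is None or cand < best:
                best = cand
            labels[i] = best[1]
        ev["label"] = labels
        ev = ev.drop_duplicates(["patient_id", "year"], keep="last")
    out = states.index.copy()
    out = out.merge(ev[["patient_id", "year", "label"]], on=["patient_id", "year"], how="left")
    out["label"] = out.groupby("patient_id")["label"].ffill()
    out["cluster"] = out["label"].fillna(healthy).astype(int)
    return out.drop(columns=["label"])


def total_variation(p: pd.Series, q: pd.Series) -> float:
    """TV distance between two discrete distributions (aligned on the union)."""
    idx = p.index.union(q.index)
    return float(0.5 * (p.reindex(idx, fill_value=0) - q.reindex(idx, fill_value=0)).abs().sum())


def _length_dist(frame: pd.DataFrame) -> pd.Series:
    trajs = trajectories_from_assignments(frame)
    return trajs.map(lambda s: len(reduce_trajectory(s))).value_counts(normalize=True)


def _final_dist(frame: pd.DataFrame) -> pd.Series:
    last = frame.sort_values(["patient_id", "year"]).groupby("patient_id")["cluster"].last()
    return last.value_counts(normalize=True)


def compare_models(
    models: dict[str, tuple[pd.DataFrame, MultilayerNetwork]],
    years: tuple[int, int],
    seed: int = 0,
    n_patients: int | None = None,
    states=None,
) -> pd.DataFrame:
    """Forecast-vs-data comparison per model.

    Each entry maps a model name to (real assignments in that model's own
    label space, fitted network).  A cohort matched to the real first-year
    start distribution is simulated from the network and compared with
    the real data via total-variation divergence of the reduced-length
    and final-occupancy distributions; ``score`` is their mean.  When
    ``states`` is given, the within-inertia of each model's induced
    partition of the real health states is reported too.
    """
    rows = []
    for i, (name, (real, net)) in enumerate(sorted(models.items())):
        start = start_distribution_from(real)
        n = n_patients or real["patient_id"].nunique()
        cfg = SimulationConfig(n_patients=n, years=years, seed=seed + i)
        sim, _ = simulate_cohort(net, cfg, start=start)
        tv_len = total_variation(_length_dist(real), _length_dist(sim))
        tv_occ = total_variation(_final_dist(real), _final_dist(sim))
        row = {
            "model": name,
            "tv_length": tv_len,
            "tv_occupancy": tv_occ,
            "score": 0.5 * (tv_len + tv_occ),
        }
        if states is not None:
            lab = real.merge(states.index.reset_index()[["index", "patient_id", "year"]],
                             on=["patient_id", "year"], how="inner")
            labels = np.full(states.n_rows, -1, dtype=int)
            labels[lab["index"].to_numpy()] = lab["cluster"].to_numpy()
            keep = labels >= 0
            row["inertia"] = cluster_inertia(states.matrix[keep], labels[keep])
        rows.append(row)
    return pd.DataFrame(rows)
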