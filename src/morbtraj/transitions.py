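"""Sex/age-stratified yearly cluster-transition network.

Each (sex, 10-year age band) stratum is one layer of a multilayer
network over the shared cluster set.  The transition rate q[g, a, k, j]
is the probability that a patient of sex g and age band a observed in
cluster k is found in cluster j one year later; the stratum of a
transition is taken in the *source* year.  Death acts as an absorbing
pseudo-state per layer; a source patient-year is *at risk* when the
patient is observed (or dies in hospital) in the following year, while
end-of-window years are counted as censored and excluded from rate
denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError

DEATH = -1
CENSOR = -2

DEFAULT_MORTALITY_BANDS = {
    "low": (0.002, 0.003),
    "medium": (0.003, 0.01),
    "high": (0.02, 0.11),
}


@dataclass
class MultilayerNetwork:
    """Transition counts per layer; rates are derived on demand.

    ``counts`` columns: sex, age_group, src, dst, count, age_sum where
    ``dst`` is a cluster id or the DEATH / CENSOR pseudo-states and
    ``age_sum`` accumulates source-year ages (for mean transit age after
    collapsing).
    """

    counts: pd.DataFrame

    @property
    def clusters(self) -> list[int]:
        c = self.counts
        ids = set(c["src"].unique()) | set(c.loc[c["dst"] >= 0, "dst"].unique())
        return sorted(int(i) for i in ids)

    @property
    def layers(self) -> list[tuple[str, str]]:
        return sorted(set(zip(self.counts["sex"], self.counts["age_group"])))

    def at_risk(self) -> pd.DataFrame:
        """Non-censored source patient-years per (layer, src cluster)."""
        c = self.counts[self.counts["dst"] != CENSOR]
        return (
            c.groupby(["sex", "age_group", "src"], as_index=False)["count"].sum()
            .rename(columns={"count": "at_risk"})
        )

    def rates(self) -> pd.DataFrame:
        """Counts annotated with at-risk denominators and rates.

        Censor rows get NaN rate; rows whose (layer, src) has zero at-risk
        patient-years are undefined (NaN), not zero.
        """
        out = self.counts.merge(self.at_risk(), on=["sex", "age_group", "src"], how="left")
        out["at_risk"] = out["at_risk"].fillna(0).astype(int)
        with np.errstate(divide="ignore", invalid="ignore"):
            out["rate"] = np.where(
                (out["dst"] != CENSOR) & (out["at_risk"] > 0),
                out["count"] / np.maximum(out["at_risk"], 1),
                np.nan,
            )
        return out

    def undefined_sources(self) -> pd.DataFrame:
        """(layer, src) combinations observed only as censored."""
        r = self.at_risk()
        allsrc = self.counts.groupby(["sex", "age_group", "src"], as_index=False)["count"].sum()
        m = allsrc.merge(r, on=["sex", "age_group", "src"], how="left")
        return m[m["at_risk"].isna()][["sex", "age_group", "src"]]

    def layer_matrix(self, sex: str, age_group: str, clusters: list[int] | None = None):
        """(Q, death_rate, at_risk) arrays over ``clusters`` for one layer."""
        clusters = clusters if clusters is not None else self.clusters
        pos = {c: i for i, c in enumerate(clusters)}
        k = len(clusters)
        Q = np.zeros((k, k))
        death = np.zeros(k)
        risk = np.zeros(k)
        sub = self.counts[(self.counts["sex"] == sex) & (self.counts["age_group"] == age_group)]
        for row in sub.itertuples(index=False):
            if row.src not in pos:
                continue
            i = pos[row.src]
            if row.dst == CENSOR:
                continue
            risk[i] += row.count
            if row.dst == DEATH:
                death[i] += row.count
            elif row.dst in pos:
                Q[i, pos[row.dst]] += row.count
        with np.errstate(divide="ignore", invalid="ignore"):
            Qr = np.where(risk[:, None] > 0, Q / np.maximum(risk[:, None], 1), np.nan)
            dr = np.where(risk > 0, death / np.maximum(risk, 1), np.nan)
        return Qr, dr, risk


def estimate_transition_rates(assignments: pd.DataFrame) -> MultilayerNetwork:
    """Build the multilayer network from per patient-year cluster labels.

    ``assignments`` needs columns patient_id, year, sex, age, age_group,
    cluster, is_death_year with consecutive years per patient up to the
    death year.  A patient-year is a source unless it is the death year;
    its outcome is the next year's cluster, DEATH when the next year is
    the patient's death year, or CENSOR when unobserved.
    """
    f = assignments.sort_values(["patient_id", "year"], kind="stable").reset_index(drop=True)
    pid = f["patient_id"].to_numpy()
    year = f["year"].to_numpy()
    clus = f["cluster"].to_numpy()
    dth = f["is_death_year"].to_numpy()
    nxt_same = np.zeros(len(f), dtype=bool)
    nxt_same[:-1] = (pid[:-1] == pid[1:]) & (year[:-1] + 1 == year[1:])
    dst = np.full(len(f), CENSOR, dtype=int)
    nxt_idx = np.arange(1, len(f) + 1)
    valid = nxt_same
    dst[valid] = np.where(dth[np.minimum(nxt_idx[valid], len(f) - 1)], DEATH, clus[np.minimum(nxt_idx[valid], len(f) - 1)])
    source = ~dth  # death-year rows are terminal, never sources
    g = pd.DataFrame(
        {
            "sex": f["sex"].to_numpy()[source],
            "age_group": f["age_group"].to_numpy()[source],
            "src": clus[source],
            "dst": dst[source],
            "age": f["age"].to_numpy()[source],
        }
    )
    counts = (
        g.groupby(["sex", "age_group", "src", "dst"], as_index=False)
        .agg(count=("age", "size"), age_sum=("age", "sum"))
    )
    return MultilayerNetwork(counts=counts)


def collapse_layers(net: MultilayerNetwork) -> MultilayerNetwork:
    """Sum counts over layers; rates are recomputed from pooled counts."""
    c = (
        net.counts.groupby(["src", "dst"], as_index=False)[["count", "age_sum"]].sum()
        .assign(sex="all", age_group="all")
    )
    return MultilayerNetwork(counts=c[["sex", "age_group", "src", "dst", "count", "age_sum"]])


def robustness_filter(
    net: MultilayerNetwork,
    min_rate: float = 0.005,
    min_count: int = 100,
    collapsed: bool = False,
) -> pd.DataFrame:
    """Edges with rate > ``min_rate`` and count >= ``min_count``.

    Per layer by default; with ``collapsed=True`` the filter applies to
    rates recomputed from pooled counts.  Death/censor rows are dropped.
    """
    n = collapse_layers(net) if collapsed else net
    r = n.rates()
    keep = (r["dst"] >= 0) & (r["rate"] > min_rate) & (r["count"] >= min_count)
    cols = ["sex", "age_group", "src", "dst", "count", "rate"]
    return r.loc[keep, cols].reset_index(drop=True)


def find_sink_states(net: MultilayerNetwork, filtered: pd.DataFrame | None = None) -> list[int]:
    """Clusters with no outgoing inter-cluster links (self-loops and death
    do not count as outgoing); evaluated on the collapsed, optionally
    filtered, edge set."""
    edges = filtered if filtered is not None else collapse_layers(net).rates()
    inter = edges[(edges["dst"] >= 0) & (edges["dst"] != edges["src"]) & (edges["count"] > 0)]
    has_out = set(inter["src"].astype(int))
    return [c for c in net.clusters if c not in has_out]


def acyclicity_check(net_or_edges) -> tuple[bool, list | None]:
    """Pass iff the observed inter-cluster transition graph is acyclic."""
    if isinstance(net_or_edges, MultilayerNetwork):
        edges = collapse_layers(net_or_edges).counts
    else:
        edges = net_or_edges
    inter = edges[(edges["dst"] >= 0) & (edges["dst"] != edges["src"]) & (edges["count"] > 0)]
    G = nx.DiGraph()
    G.add_edges_from(zip(inter["src"].astype(int), inter["dst"].astype(int)))
    try:
        cycle = nx.find_cycle(G)
        return False, [(int(u), int(v)) for u, v, *_ in cycle]
    except nx.NetworkXNoCycle:
        return True, None


@dataclass
class RegionLabel:
    name: str
    members: list[int]
    band: tuple[float, float]


def label_mortality_regions(
    profiles: pd.DataFrame,
    bands: dict[str, tuple[float, float]] | None = None,
    min_mean_age: float = 55.0,
) -> list[RegionLabel]:
    """Label elderly clusters by yearly in-hospital mortality bands.

    Only clusters with mean age >= ``min_mean_age`` are labelled; clusters
    whose mortality falls between bands stay unlabelled.  Default bands:
    low 0.2-0.3%, medium 0.3-1%, high 2-11%.
    """
    bands = bands if bands is not None else DEFAULT_MORTALITY_BANDS
    items = list(bands.items())
    for i, (n1, (lo1, hi1)) in enumerate(items):
        if lo1 > hi1:
            raise ConfigurationError("bands", f"band {n1} is inverted")
        for n2, (lo2, hi2) in items[i + 1 :]:
            if max(lo1, lo2) < min(hi1, hi2):
                raise ConfigurationError("bands", f"bands {n1} and {n2} overlap")
    out = [RegionLabel(name, [], (lo, hi)) for name, (lo, hi) in items]
    unlabelled = RegionLabel("unlabelled", [], (np.nan, np.nan))
    for row in profiles.itertuples(index=False):
        if not np.isfinite(row.annual_mortality) or not np.isfinite(row.mean_age):
            continue
        if row.mean_age < min_mean_age:
            continue
        for lab in out:
            lo, hi = lab.band
            if lo <= row.annual_mortality <= hi:
                lab.members.append(int(row.cluster_id))
                break
        else:
            unlabelled.members.append(int(row.cluster_id))
    return out + [unlabelled]


def rank_entry_clusters(assignments: pd.DataFrame, region: set[int] | list[int]) -> pd.DataFrame:
    """Clusters ranked by the number of patients entering ``region`` via them.

    For each patient, the first year assigned to a region cluster credits
    the cluster occupied the year before (one credit per patient; patients
    already in the region at their first observed year credit nobody).
    """
    region = set(int(r) for r in region)
    if not region:
        raise ConfigurationError("region", "region must be non-empty")
    f = assignments.sort_values(["patient_id", "year"], kind="stable")
    inr = f["cluster"].isin(region)
    entries = f.loc[inr].groupby("patient_id", as_index=False)["year"].min()
    entries["prev_year"] = entries["year"] - 1
    prev = f[["patient_id", "year", "cluster"]].rename(columns={"year": "prev_year", "cluster": "via"})
    merged = entries.merge(prev, on=["patient_id", "prev_year"], how="inner")
    merged = merged[~merged["via"].isin(region)]
    out = (
        merged.groupby("via", as_index=False).size().rename(columns={"via": "cluster", "size": "entries"})
        .sort_values(["entries", "cluster"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    return out


def export_graphml(
    net: MultilayerNetwork,
    path,
    profiles: pd.DataFrame | None = None,
    min_rate: float = 0.0,
    min_count: int = 0,
) -> None:
    """Collapsed-network GraphML export with node size/mortality and edge
    rate/mean-transit-age attributes."""
    coll = collapse_layers(net)
    edges = robustness_filter(coll, min_rate=min_rate, min_count=min_count)
    G = nx.DiGraph()
    for c in net.clusters:
        G.add_node(int(c))
    if profiles is not None:
        for row in profiles.itertuples(index=False):
            if int(row.cluster_id) in G:
                G.nodes[int(row.cluster_id)]["size"] = int(row.size)
                if np.isfinite(row.annual_mortality):
                    G.nodes[int(row.cluster_id)]["mortality"] = float(row.annual_mortality)
    cc = coll.counts.set_index(["src", "dst"])
    for row in edges.itertuples(index=False):
        if row.src == row.dst:
            continue
        age_sum = float(cc.loc[(row.src, row.dst), "age_sum"])
        G.add_edge(int(row.src), int(row.dst), rate=float(row.rate), count=int(row.count),
                   mean_age=age_sum / max(row.count, 1))
    nx.write_graphml(G, path)


def edge_list_frame(net: MultilayerNetwork) -> pd.DataFrame:
    """Per-layer edge list (sex, age_group, src, dst, count, rate)."""
    r = net.rates()
    return r[r["dst"] >= 0][["sex", "age_group", "src", "dst", "count", "rate"]].reset_index(drop=True)
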