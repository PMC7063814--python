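"""Region-entry risks, progredient comparisons and sex-bias screening.

Relative risks of stepping into a target cluster region within a fixed
horizon are estimated per (sex, 10-year age band) stratum on a
patient-year basis: every observation year a patient spends in the
source cluster is one at-risk trial.  Confidence intervals use the Katz
log-RR normal approximation.  Comorbidity differences between
progredient and stable patients, and male/female differences in
transition rates, are tested with Fisher's exact test under Bonferroni
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .transitions import MultilayerNetwork, CENSOR, DEATH

Z95 = 1.959963984540054


@dataclass
class RiskEstimate:
    source: object
    region: frozenset
    sex: str
    age_group: str
    horizon: int
    baseline_kind: str
    exposed_events: int
    exposed_trials: int
    baseline_events: int
    baseline_trials: int
    absolute_risk: float
    baseline_risk: float
    relative_risk: float
    ci_low: float
    ci_high: float
    defined: bool = True

    @property
    def ci_half_width(self) -> float:
        """Largest deviation of the CI from the point estimate (the paper's
        "±" reading on the RR scale)."""
        return max(self.relative_risk - self.ci_low, self.ci_high - self.relative_risk)


def _entry_trials(assignments: pd.DataFrame, region: set[int], horizon: int) -> pd.DataFrame:
    """Per patient-year trial table with region-entry outcome within horizon.

    Rows already inside the region are not trials; rows with fewer than
    ``horizon`` remaining observed years and no event are excluded.
    """
    f = assignments.sort_values(["patient_id", "year"], kind="stable").reset_index(drop=True)
    inr = f["cluster"].isin(region).to_numpy()
    pid = f["patient_id"].to_numpy()
    year = f["year"].to_numpy()
    # first region year per patient (inf when never)
    fr = pd.Series(np.where(inr, year, np.iinfo(np.int64).max), index=pid).groupby(level=0).min()
    first_region = f["patient_id"].map(fr).to_numpy()
    last_obs = f.groupby("patient_id")["year"].transform("max").to_numpy()
    event = (first_region > year) & (first_region <= year + horizon)
    enough = last_obs >= year + horizon
    keep = ~inr & ~f["is_death_year"].to_numpy() & (event | enough)
    out = f.loc[keep, ["patient_id", "year", "sex", "age_group", "cluster"]].copy()
    out["event"] = event[keep]
    return out


def region_entry_risk(
    assignments: pd.DataFrame,
    source: int,
    region: set[int] | list[int],
    sex: str,
    age_group: str,
    horizon: int = 1,
    baseline: object = "all",
) -> RiskEstimate:
    """Relative risk of entering ``region`` within ``horizon`` years from
    ``source``, against a same-stratum baseline.

    ``baseline`` is ``"all"`` (all patient-years of the stratum not in the
    region, the paper-style comparison), ``"cluster0"`` (healthy-cluster
    years only), or an explicit iterable of baseline cluster ids.  The CI
    is the Katz normal approximation on log RR.  When either arm has zero
    events the RR is flagged undefined (no division).
    """
    region = set(int(r) for r in region)
    if int(source) in region:
        raise ConfigurationError("source", "source cluster must lie outside the region")
    if horizon < 1:
        raise ConfigurationError("horizon", "must be >= 1")
    trials = _entry_trials(assignments, region, horizon)
    stratum = trials[(trials["sex"] == sex) & (trials["age_group"] == age_group)]
    exposed = stratum[stratum["cluster"] == source]
    if baseline == "all":
        base = stratum
        kind = "all"
    elif baseline == "cluster0":
        base = stratum[stratum["cluster"] == 0]
        kind = "cluster0"
    else:
        ids = set(int(b) for b in baseline)
        base = stratum[stratum["cluster"].isin(ids)]
        kind = f"clusters:{sorted(ids)}"
    e1, n1 = int(exposed["event"].sum()), len(exposed)
    e0, n0 = int(base["event"].sum()), len(base)
    p1 = e1 / n1 if n1 else np.nan
    p0 = e0 / n0 if n0 else np.nan
    defined = e1 > 0 and e0 > 0 and n1 > 0 and n0 > 0
    if defined:
        rr = p1 / p0
        se = np.sqrt(max(1.0 / e1 - 1.0 / n1 + 1.0 / e0 - 1.0 / n0, 0.0))
        lo, hi = rr * np.exp(-Z95 * se), rr * np.exp(Z95 * se)
    else:
        rr, lo, hi = np.nan, np.nan, np.nan
    return RiskEstimate(
        source=source,
        region=frozenset(region),
        sex=sex,
        age_group=age_group,
        horizon=horizon,
        baseline_kind=kind,
        exposed_events=e1,
        exposed_trials=n1,
        baseline_events=e0,
        baseline_trials=n0,
        absolute_risk=p1,
        baseline_risk=p0,
        relative_risk=rr,
        ci_low=lo,
        ci_high=hi,
        defined=defined,
    )


def bootstrap_rr_ci(
    e1: int, n1: int, e0: int, n0: int, n_resamples: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Nonparametric percentile bootstrap CI for a risk ratio (resampling
    individuals within each arm); used as an independent check of the Katz
    interval."""
    rng = np.random.default_rng(seed)
    b1 = rng.binomial(n1, e1 / n1, n_resamples) / n1
    b0 = rng.binomial(n0, e0 / n0, n_resamples) / n0
    ok = b0 > 0
    rr = b1[ok] / b0[ok]
    return float(np.quantile(rr, 0.025)), float(np.quantile(rr, 0.975))


def progredient_split(
    assignments: pd.DataFrame,
    cluster_set: set[int] | list[int],
    horizon: int = 3,
    region: set[int] | list[int] | None = None,
) -> tuple[set, set, dict]:
    """Split patients of a cluster set into progredient and stable.

    A patient's reference year is their first observed year inside
    ``cluster_set`` with a row ``horizon`` years later; progredient means
    being outside the set then (or, when ``region`` is given, inside that
    region -- the narrowed high-mortality variant); stable means still
    inside the set.  Patients unobserved at reference + horizon are
    excluded.  Returns (progredient ids, stable ids, reference years).
    """
    cset = set(int(c) for c in cluster_set)
    rset = set(int(c) for c in region) if region is not None else None
    f = assignments.sort_values(["patient_id", "year"], kind="stable")
    later = f[["patient_id", "year", "cluster"]].copy()
    later["ref_year"] = later["year"] - horizon
    inside = f.loc[f["cluster"].isin(cset), ["patient_id", "year", "cluster"]].rename(
        columns={"year": "ref_year", "cluster": "ref_cluster"}
    )
    m = inside.merge(later[["patient_id", "ref_year", "cluster"]], on=["patient_id", "ref_year"], how="inner")
    m = m.sort_values(["patient_id", "ref_year"]).drop_duplicates("patient_id", keep="first")
    if rset is None:
        prog_mask = ~m["cluster"].isin(cset)
    else:
        prog_mask = m["cluster"].isin(rset)
        m = m[prog_mask | m["cluster"].isin(cset)]  # leavers outside the region are neither
        prog_mask = m["cluster"].isin(rset)
    prog = set(m.loc[prog_mask, "patient_id"])
    stable = set(m.loc[~prog_mask & m["cluster"].isin(cset), "patient_id"])
    ref_years = dict(zip(m["patient_id"], m["ref_year"]))
    return prog, stable, ref_years


def compare_comorbidities(
    progredient: set,
    stable: set,
    presence: pd.DataFrame,
    features=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher-exact comparison of feature prevalence between the groups.

    ``presence`` is a boolean DataFrame indexed by patient id (one column
    per block or code, e.g. built with :func:`presence_at_reference`).
    Two-sided p-values are Bonferroni-adjusted over the tested features;
    a feature absent in both groups is flagged degenerate with p = 1.
    """
    if progredient & stable:
        raise ConfigurationError("groups", "progredient and stable sets must be disjoint")
    feats = list(presence.columns) if features is None else list(features)
    pr = presence.loc[presence.index.isin(progredient)]
    st = presence.loc[presence.index.isin(stable)]
    m = len(feats)
    rows = []
    for ft in feats:
        a, na = int(pr[ft].sum()), len(pr)
        b, nb = int(st[ft].sum()), len(st)
        degenerate = (a + b == 0) or (a + b == na + nb)
        if degenerate:
            p = 1.0
            odds = np.nan
        else:
            odds, p = stats.fisher_exact([[a, na - a], [b, nb - b]], alternative="two-sided")
        p_adj = min(1.0, p * m)
        rows.append(
            {
                "feature": ft,
                "progredient_count": a,
                "progredient_total": na,
                "stable_count": b,
                "stable_total": nb,
                "odds_ratio": odds,
                "p_value": p,
                "p_adjusted": p_adj,
                "significant": p_adj < alpha,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).sort_values("p_adjusted", kind="stable").reset_index(drop=True)


def presence_at_reference(states, ref_years: dict) -> pd.DataFrame:
    """Block presence (boolean) per patient at their reference year."""
    idx = states.index
    key = pd.DataFrame({"patient_id": list(ref_years), "year": list(ref_years.values())})
    pos = idx.reset_index().merge(key, on=["patient_id", "year"], how="inner")
    mat = states.matrix[pos["index"].to_numpy()].astype(bool)
    return pd.DataFrame(mat, index=pos["patient_id"].to_numpy())


def code_presence_at_reference(stays: pd.DataFrame, ref_years: dict, codes: list[str]) -> pd.DataFrame:
    """Level-3 code presence per patient by the end of their reference year
    (for paper-style code-level comparisons such as J44 or E66)."""
    s = stays[stays["patient_id"].isin(ref_years)].copy()
    s["year"] = s["admission_date"].str.slice(0, 4).astype(int)
    s = s[s["year"] <= s["patient_id"].map(ref_years)]
    ex = s.assign(code=s["diagnoses"].str.split(";")).explode("code")
    ex["code"] = ex["code"].str.slice(0, 3)
    out = pd.DataFrame(False, index=pd.Index(list(ref_years), name="patient_id"), columns=codes)
    for c in codes:
        hit = ex.loc[ex["code"] == c, "patient_id"].unique()
        out.loc[out.index.isin(hit), c] = True
    return out


def gender_biased_transitions(
    net: MultilayerNetwork,
    alpha: float = 0.05,
    min_count: int = 100,
) -> pd.DataFrame:
    """Screen all (age band, src, dst) transitions for male/female rate
    differences via Fisher's exact test on the 2x2 (sex x transitioned)
    table, Bonferroni-corrected over the tested triples.

    Triples require >= ``min_count`` at-risk patient-years in both sexes;
    sex-specific combinations are skipped.  Returns every tested triple
    sorted by adjusted p with a significance flag.
    """
    r = net.rates()
    r = r[(r["dst"] >= 0)]
    risk = net.at_risk()
    risk_map = {(row.sex, row.age_group, row.src): row.at_risk for row in risk.itertuples(index=False)}
    cnt = {(row.sex, row.age_group, row.src, row.dst): row.count for row in r.itertuples(index=False)}
    triples = sorted(set((ag, s, d) for (_, ag, s, d) in cnt))
    rows = []
    for ag, src, dst in triples:
        n_m = risk_map.get(("male", ag, src), 0)
        n_f = risk_map.get(("female", ag, src), 0)
        if n_m < min_count or n_f < min_count:
            continue
        k_m = cnt.get(("male", ag, src, dst), 0)
        k_f = cnt.get(("female", ag, src, dst), 0)
        _, p = stats.fisher_exact([[k_m, n_m - k_m], [k_f, n_f - k_f]], alternative="two-sided")
        rows.append(
            {
                "age_group": ag,
                "src": src,
                "dst": dst,
                "male_rate": k_m / n_m,
                "female_rate": k_f / n_f,
                "male_at_risk": n_m,
                "female_at_risk": n_f,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out) == 0:
        return out
    out["p_adjusted"] = np.minimum(1.0, out["p_value"] * len(out))
    out["significant"] = out["p_adjusted"] < alpha
    return out.sort_values("p_adjusted", kind="stable").reset_index(drop=True)
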