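"""Recovery diagnostics against planted ground truth.

These utilities compare estimated transition networks with the planted
generator dynamics (or with a reference network, for simulator round
trips) cell by cell, using exact binomial (Clopper-Pearson) confidence
intervals on the observed transition counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .registry import SEXES, GroundTruth, age_band_label, N_AGE_BANDS
from .transitions import DEATH, CENSOR, MultilayerNetwork


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial CI for a proportion."""
    if n == 0:
        return (0.0, 1.0)
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def match_clusters_to_states(assignments: pd.DataFrame, truth: GroundTruth) -> dict[int, int]:
    """Majority-vote mapping from fitted clusters to planted latent states."""
    m = assignments.merge(truth.patient_states, on=["patient_id", "year"], how="inner")
    maj = m.groupby("cluster")["state"].agg(lambda s: s.value_counts().idxmax())
    return {int(c): int(s) for c, s in maj.items()}


def _healthy_exposure(truth: GroundTruth) -> tuple[dict, dict]:
    """Never-sick patients' at-risk years and deaths per (sex, age band).

    The generator marks a fraction of patients as never acquiring a
    somatic block; they pool into the healthy cluster but are not
    latently at risk of a transition, so cluster-level rates out of the
    healthy cluster dilute the planted dynamic rates.  Returns
    ``(at_risk_years, deaths)`` keyed by (sex, age-band label).
    """
    pats = truth.patients
    if pats is None:
        return {}, {}
    healthy = pats[pats["category"] == "healthy"]
    if len(healthy) == 0:
        return {}, {}
    seq = truth.patient_states.merge(healthy[["patient_id", "sex", "eff_birth_year", "death_year"]],
                                     on="patient_id", how="inner")
    last = seq.groupby("patient_id")["year"].transform("max")
    at_risk_rows = seq[seq["year"] < last]  # terminal row (death or censor) is not a source
    band = at_risk_rows["year"] - at_risk_rows["eff_birth_year"]
    labels = np.array([age_band_label(b) for b in range(N_AGE_BANDS)])
    key = list(zip(at_risk_rows["sex"], labels[np.clip(band // 10, 0, N_AGE_BANDS - 1)]))
    at_risk = pd.Series(1, index=pd.MultiIndex.from_tuples(key)).groupby(level=[0, 1]).sum().to_dict() if key else {}
    died = healthy[healthy["death_year"] >= 0]
    dband = died["death_year"] - 1 - died["eff_birth_year"]
    dkey = list(zip(died["sex"], labels[np.clip(dband // 10, 0, N_AGE_BANDS - 1)]))
    deaths = pd.Series(1, index=pd.MultiIndex.from_tuples(dkey)).groupby(level=[0, 1]).sum().to_dict() if dkey else {}
    return at_risk, deaths


def transition_recovery(
    net: MultilayerNetwork,
    truth: GroundTruth,
    mapping: dict[int, int],
    min_at_risk: int = 100,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cellwise comparison of estimated rates with the planted rates.

    One row per (layer, source cluster, destination) -- destinations are
    every fitted cluster plus death -- restricted to sources with at
    least ``min_at_risk`` at-risk patient-years.  ``covered`` flags
    whether the planted rate lies inside the exact binomial CI of the
    observed count.

    Cells whose source is the healthy cluster are corrected for the
    never-sick patients it contains (known from the ground truth): their
    years are removed from the at-risk denominator of move and stay
    cells, and from the stay numerator; death cells need no correction
    because never-sick patients share the healthy-state death rate.
    """
    band_idx = {age_band_label(b): b for b in range(N_AGE_BANDS)}
    sex_idx = {s: i for i, s in enumerate(SEXES)}
    clusters = net.clusters
    cnt = {
        (r.sex, r.age_group, r.src, r.dst): r.count for r in net.counts.itertuples(index=False)
    }
    risk = {
        (r.sex, r.age_group, r.src): r.at_risk for r in net.at_risk().itertuples(index=False)
    }
    healthy_risk, healthy_deaths = _healthy_exposure(truth)
    stay = truth.stay_rates()
    rows = []
    for (sex, ag, src), n_risk in risk.items():
        if n_risk < min_at_risk or ag not in band_idx:
            continue
        g, a = sex_idx[sex], band_idx[ag]
        s_src = mapping.get(int(src))
        if s_src is None:
            continue
        h_risk = healthy_risk.get((sex, ag), 0) if s_src == 0 else 0
        h_self = h_risk - (healthy_deaths.get((sex, ag), 0) if s_src == 0 else 0)
        dests = [(int(c), "cluster") for c in clusters] + [(DEATH, "death")]
        for dst, kind in dests:
            k = cnt.get((sex, ag, src, dst), 0)
            n_eff = n_risk
            if kind == "death":
                planted = truth.death_rates[g, a, s_src]
            else:
                s_dst = mapping.get(dst)
                if s_dst is None:
                    continue
                n_eff = n_risk - h_risk
                if dst == src:
                    planted = stay[g, a, s_src]
                    k = k - h_self
                elif s_dst == s_src:
                    planted = 0.0  # two clusters mapping to one state
                else:
                    planted = truth.move_rates[g, a, s_src, s_dst]
            if n_eff < min_at_risk or k < 0:
                continue
            lo, hi = clopper_pearson(k, n_eff, alpha)
            rows.append(
                {
                    "sex": sex,
                    "age_group": ag,
                    "src": int(src),
                    "dst": dst,
                    "at_risk": int(n_eff),
                    "count": int(k),
                    "estimate": k / n_eff,
                    "planted": float(planted),
                    "ci_low": lo,
                    "ci_high": hi,
                    "covered": lo <= planted <= hi,
                }
            )
    return pd.DataFrame(rows)


def network_recovery(
    estimated: MultilayerNetwork,
    reference: MultilayerNetwork,
    min_at_risk: int = 100,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Round-trip check: do the reference network's rates fall inside the
    binomial CIs of the counts re-estimated from simulated trajectories?

    Only cells whose reference row is defined and whose estimated source
    has ``min_at_risk`` at-risk patient-years are compared; reference
    rates are censor-stripped (renormalised over transitions + death).
    """
    ref_rates = reference.rates()
    ref_rates = ref_rates[ref_rates["dst"] != CENSOR]
    ref = {
        (r.sex, r.age_group, r.src, r.dst): r.rate for r in ref_rates.itertuples(index=False)
    }
    ref_defined = {
        (r.sex, r.age_group, r.src) for r in reference.at_risk().itertuples(index=False) if r.at_risk > 0
    }
    est_risk = {
        (r.sex, r.age_group, r.src): r.at_risk for r in estimated.at_risk().itertuples(index=False)
    }
    cnt = {
        (r.sex, r.age_group, r.src, r.dst): r.count
        for r in estimated.counts.itertuples(index=False)
        if r.dst != CENSOR
    }
    clusters = sorted(set(reference.clusters) | set(estimated.clusters))
    rows = []
    for (sex, ag, src), n_risk in est_risk.items():
        if n_risk < min_at_risk or (sex, ag, src) not in ref_defined:
            continue
        for dst in [int(c) for c in clusters] + [DEATH]:
            planted = ref.get((sex, ag, src, dst), 0.0)
            if planted is None or (isinstance(planted, float) and np.isnan(planted)):
                planted = 0.0
            k = cnt.get((sex, ag, src, dst), 0)
            lo, hi = clopper_pearson(k, n_risk, alpha)
            rows.append(
                {
                    "sex": sex,
                    "age_group": ag,
                    "src": int(src),
                    "dst": dst,
                    "at_risk": int(n_risk),
                    "count": int(k),
                    "estimate": k / n_risk,
                    "planted": float(planted),
                    "ci_low": lo,
                    "ci_high": hi,
                    "covered": lo <= planted <= hi,
                }
            )
    return pd.DataFrame(rows)


def coverage(cells: pd.DataFrame) -> float:
    """Fraction of compared cells whose CI covers the planted rate."""
    if len(cells) == 0:
        return float("nan")
    return float(cells["covered"].mean())
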