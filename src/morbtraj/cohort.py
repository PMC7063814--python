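"""Washout cohort selection and cumulative binary health states.

A patient's health state at the end of a calendar year is the binary
vector over diagnosis blocks recording every block diagnosed on any stay
up to that year (cumulative encoding: diagnoses are never removed).  The
cohort consists of patients without any code in the excluded range
(default A00--N99) during the washout window, which standardises the
initial health state to the zero vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import BlockTable, in_code_range, normalise_code
from .errors import ConfigurationError, DataConsistencyError
from .registry import age_band_10y, age_band_label


@dataclass(frozen=True)
class CohortSpec:
    washout: tuple[int, int] = (1997, 2002)
    observation: tuple[int, int] = (2003, 2014)
    excluded_range: tuple[str, str] = ("A00", "N99")

    def validate(self) -> None:
        if self.washout[1] >= self.observation[0]:
            raise ConfigurationError("washout", "washout must precede the observation interval")
        if self.washout[0] > self.washout[1] or self.observation[0] > self.observation[1]:
            raise ConfigurationError("observation", "intervals must be non-empty")


def map_code_to_block(code: str, blocks: BlockTable) -> int | None:
    """Level-3 block lookup; codes with a 4th character are truncated first."""
    return blocks.map_code(normalise_code(code))


def _admission_year(stays: pd.DataFrame) -> pd.Series:
    return stays["admission_date"].str.slice(0, 4).astype(int)


def select_washout_cohort(stays: pd.DataFrame, spec: CohortSpec, blocks: BlockTable | None = None) -> set[str]:
    """Patients with no excluded-range code on any washout-window stay.

    Patients absent from the washout years entirely, or present with only
    codes outside the excluded range, are retained.
    """
    spec.validate()
    if len(stays) == 0:
        return set()
    year = _admission_year(stays)
    in_washout = (year >= spec.washout[0]) & (year <= spec.washout[1])
    all_patients = set(stays["patient_id"].unique())
    w = stays.loc[in_washout, ["patient_id", "diagnoses"]]
    if len(w) == 0:
        return all_patients
    exploded = w.assign(code=w["diagnoses"].str.split(";")).explode("code")
    bad = in_code_range(exploded["code"], *spec.excluded_range)
    excluded = set(exploded.loc[bad, "patient_id"].unique())
    return all_patients - excluded


@dataclass
class HealthStateTable:
    """Row-aligned index frame and dense 0/1 matrix of health states.

    ``index`` columns: patient_id, year, sex, age, age_group,
    is_death_year -- one row per (cohort patient, observation year) up to
    and including the in-hospital death year.  ``matrix[r, b] = 1`` iff
    the patient of row ``r`` had received a diagnosis in block ``b`` by
    31 December of that row's year.
    """

    index: pd.DataFrame
    matrix: np.ndarray
    blocks: BlockTable
    patients: pd.DataFrame = field(repr=False, default=None)
    acquisitions: pd.DataFrame = field(repr=False, default=None)  # patient_id, block, year

    @property
    def n_rows(self) -> int:
        return len(self.index)

    def assignment_frame(self, labels: np.ndarray, column: str = "cluster") -> pd.DataFrame:
        """Index frame annotated with per-row cluster labels."""
        out = self.index.copy()
        out[column] = labels
        return out

    def to_dense_csv(self, path) -> None:
        vec = ["".join(map(str, row)) for row in self.matrix]
        self.index.assign(vector=vec)[["patient_id", "year", "sex", "age_group", "vector"]].to_csv(
            path, index=False
        )

    def to_sparse_csv(self, path) -> None:
        r, b = np.nonzero(self.matrix)
        pd.DataFrame(
            {
                "patient_id": self.index["patient_id"].to_numpy()[r],
                "year": self.index["year"].to_numpy()[r],
                "block_id": b,
            }
        ).to_csv(path, index=False)


def build_health_states(
    stays: pd.DataFrame,
    cohort: set[str],
    spec: CohortSpec,
    blocks: BlockTable,
) -> HealthStateTable:
    """Year-end cumulative health states for every cohort patient.

    A stay contributes to the vector of the calendar year containing its
    admission date.  Sex and the 10-year age band are derived from the
    5-year band recorded at the patient's first admission ("effective
    birth year" convention).  Raises :class:`DataConsistencyError` when a
    stay is dated after a death-typed release.
    """
    spec.validate()
    t0, t1 = spec.observation
    s = stays.loc[stays["patient_id"].isin(cohort)].copy()
    if len(s) == 0:
        empty = pd.DataFrame(columns=["patient_id", "year", "sex", "age", "age_group", "is_death_year"])
        return HealthStateTable(empty, np.zeros((0, blocks.n_blocks), dtype=np.uint8), blocks)
    s["adm_year"] = _admission_year(s)
    s = s.sort_values(["patient_id", "admission_date"], kind="stable")

    # death consistency: at most one death stay, nothing dated after its release
    deaths = s.loc[s["release_type"] == "death", ["patient_id", "admission_date", "release_date", "adm_year"]]
    if deaths["patient_id"].duplicated().any():
        pid = deaths.loc[deaths["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise DataConsistencyError(f"patient {pid} has more than one death-typed release")
    death_release = deaths.set_index("patient_id")["release_date"]
    last_adm = s.groupby("patient_id")["admission_date"].max()
    both = death_release.index.intersection(last_adm.index)
    late = last_adm.loc[both] > death_release.loc[both]
    if late.any():
        raise DataConsistencyError(f"patient {late.index[late][0]} has a stay after the death release")
    death_year = deaths.set_index("patient_id")["adm_year"]

    # effective birth year from the 5-year band at first admission
    first = s.drop_duplicates("patient_id", keep="first")
    band_lo = first["age_group"].str.split("-").str[0].astype(int)
    eff_birth = first["adm_year"].to_numpy() - band_lo.to_numpy()
    patients = pd.DataFrame(
        {
            "patient_id": first["patient_id"].to_numpy(),
            "sex": first["sex"].to_numpy(),
            "eff_birth_year": eff_birth,
        }
    )
    patients["death_year"] = patients["patient_id"].map(death_year).fillna(-1).astype(int)
    patients.loc[(patients["death_year"] > t1), "death_year"] = -1  # deaths beyond window: censored
    patients["last_year"] = np.where(patients["death_year"] >= t0, patients["death_year"], t1)

    # first diagnosis year per (patient, block); washout stays of cohort
    # patients carry no excluded-range codes, so only observation years matter
    obs_stays = s.loc[(s["adm_year"] >= t0) & (s["adm_year"] <= t1), ["patient_id", "adm_year", "diagnoses"]]
    ex = obs_stays.assign(code=obs_stays["diagnoses"].str.split(";")).explode("code")
    ex["block"] = blocks.map_codes(ex["code"])
    ex = ex.dropna(subset=["block"])
    acq = (
        ex.groupby(["patient_id", "block"], sort=True)["adm_year"].min().reset_index()
        .rename(columns={"adm_year": "year"})
    )
    acq["block"] = acq["block"].astype(int)

    # row grid: one row per patient-year from t0 to last_year
    n_per = (patients["last_year"] - t0 + 1).to_numpy()
    pid_rep = np.repeat(patients["patient_id"].to_numpy(), n_per)
    sex_rep = np.repeat(patients["sex"].to_numpy(), n_per)
    eby_rep = np.repeat(patients["eff_birth_year"].to_numpy(), n_per)
    dy_rep = np.repeat(patients["death_year"].to_numpy(), n_per)
    offs = np.concatenate([np.arange(k) for k in n_per])
    years = t0 + offs
    age = years - eby_rep
    bands = age_band_10y(age)
    index = pd.DataFrame(
        {
            "patient_id": pid_rep,
            "year": years,
            "sex": sex_rep,
            "age": age,
            "age_group": [age_band_label(b) for b in bands],
            "is_death_year": years == dy_rep,
        }
    )

    # dense cumulative matrix: set bits from the acquisition year onwards
    row_start = np.concatenate([[0], np.cumsum(n_per)])
    pid_pos = {p: i for i, p in enumerate(patients["patient_id"].to_numpy())}
    matrix = np.zeros((len(index), blocks.n_blocks), dtype=np.uint8)
    last_arr = patients["last_year"].to_numpy()
    for pid, block, year in acq.itertuples(index=False):
        i = pid_pos[pid]
        y = max(year, t0)
        if y > last_arr[i]:
            continue
        matrix[row_start[i] + (y - t0) : row_start[i + 1], block] = 1

    if matrix.size:
        dec = np.nonzero(
            (pid_rep[1:] == pid_rep[:-1]) & (matrix[1:].astype(np.int16) < matrix[:-1]).any(axis=1)
        )[0]
        if len(dec):  # pragma: no cover - impossible with cumulative construction
            raise DataConsistencyError(f"non-monotone vector for patient {pid_rep[dec[0] + 1]}")

    return HealthStateTable(index=index, matrix=matrix, blocks=blocks, patients=patients, acquisitions=acq)
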