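"""Synthetic hospital-stay registry with planted ground-truth dynamics.

The generator emulates a population-wide inpatient registry: one row per
hospital stay with pseudonymous patient id, sex, 5-year age band at
admission, admission/release dates, release type (normal / transfer /
in-hospital death) and a ';'-separated list of level-3 ICD-10 codes.

Disease dynamics are driven by a small set of *latent multimorbidity
states* with nested diagnosis-block sets: state 0 is "no somatic
diagnoses"; intermediate states each add a pair of blocks; the terminal
state contains the union of all intermediate sets plus extra blocks, so
block sets grow monotonically along every allowed transition and the
latent transition graph is acyclic by construction.  Yearly transition
and in-hospital death probabilities are stratified by sex and 10-year age
band.  One intermediate state (state 1) carries a configurable multiple
of the others' progression rate into the terminal state -- the "high-risk"
pattern whose relative risk downstream estimation should recover.

Ages are only observable at 5-year resolution (as in the data the
registry emulates), so the dynamics use the *effective* age convention
"age = years since the start of the 5-year band at the first admission";
the cohort module reconstructs exactly the same quantity, making the
sex/age stratification of estimated transition rates self-consistent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import BlockTable, default_block_table
from .errors import ConfigurationError

SEXES = ("male", "female")
N_AGE_BANDS = 10  # 10-year bands 0-9, 10-19, ..., 80-89, 90+


def age_band_10y(age) -> np.ndarray:
    """10-year age band index (0..9, open-ended top band)."""
    return np.clip(np.asarray(age) // 10, 0, N_AGE_BANDS - 1).astype(int)


def age_band_label(band: int) -> str:
    return f"{band * 10}-{band * 10 + 9}" if band < N_AGE_BANDS - 1 else "90+"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic registry."""

    n_patients: int
    years: tuple[int, int] = (1997, 2014)
    n_blocks: int = 131
    n_latent_states: int = 5
    seed: int = 0
    frac_healthy: float = 0.25
    frac_washout_diseased: float = 0.05
    mean_stays_per_year: float = 0.4
    diagnosis_noise: float = 0.05
    mean_extra_diagnoses: float = 1.7
    initial_age_bands: tuple[int, ...] | None = None  # 5-year bands at observation start

    def validate(self) -> None:
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 1:
            raise ConfigurationError("n_patients", "must be an integer >= 1")
        if self.years[1] - self.years[0] + 1 < 7:
            raise ConfigurationError("years", "must span >= 7 calendar years (6 washout + 1 observation)")
        for name in ("frac_healthy", "frac_washout_diseased", "diagnosis_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(name, "must lie in [0, 1]")
        if self.mean_stays_per_year <= 0:
            raise ConfigurationError("mean_stays_per_year", "must be positive")
        if self.n_latent_states < 2:
            raise ConfigurationError("n_latent_states", "must be >= 2")
        if self.n_blocks < 2 * max(self.n_latent_states - 2, 0) + 2:
            raise ConfigurationError("n_blocks", "too few blocks for the requested latent states")
        if self.initial_age_bands is not None and any(b < 0 for b in self.initial_age_bands):
            raise ConfigurationError("initial_age_bands", "band indices must be >= 0")

    @property
    def washout_years(self) -> tuple[int, int]:
        return (self.years[0], self.years[0] + 5)

    @property
    def observation_years(self) -> tuple[int, int]:
        return (self.years[0] + 6, self.years[1])


@dataclass
class GroundTruth:
    """Planted dynamics plus (after generation) their realisation.

    ``move_rates[g, a, k, j]`` is the yearly probability that a patient of
    sex index ``g`` in 10-year band ``a`` moves from latent state ``k`` to
    ``j``; ``death_rates[g, a, k]`` the yearly in-hospital death
    probability.  The implied stay probability is the remainder, so each
    stratum's outgoing probabilities sum to one.
    """

    state_blocks: list[frozenset[int]]
    move_rates: np.ndarray  # (2, N_AGE_BANDS, S, S), zero diagonal
    death_rates: np.ndarray  # (2, N_AGE_BANDS, S)
    patient_states: pd.DataFrame | None = field(default=None, repr=False)
    patients: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_states(self) -> int:
        return len(self.state_blocks)

    def validate(self) -> None:
        S = self.n_states
        if self.move_rates.shape != (len(SEXES), N_AGE_BANDS, S, S):
            raise ConfigurationError("move_rates", f"shape must be (2, {N_AGE_BANDS}, {S}, {S})")
        if (self.move_rates < 0).any() or (self.death_rates < 0).any():
            raise ConfigurationError("move_rates", "probabilities must be non-negative")
        if np.abs(np.diagonal(self.move_rates, axis1=2, axis2=3)).max() > 0:
            raise ConfigurationError("move_rates", "diagonal (stay) must be zero; stay is the remainder")
        total = self.move_rates.sum(axis=3) + self.death_rates
        if total.max() > 1 + 1e-12:
            raise ConfigurationError("move_rates", "outgoing probabilities exceed 1")
        for k in range(S):
            for j in range(S):
                if k != j and self.move_rates[:, :, k, j].max() > 0:
                    if not self.state_blocks[k] < self.state_blocks[j]:
                        raise ConfigurationError(
                            "state_blocks", f"transition {k}->{j} does not strictly grow the block set"
                        )

    def stay_rates(self) -> np.ndarray:
        return 1.0 - self.move_rates.sum(axis=3) - self.death_rates

    def to_json(self, path) -> None:
        payload = {
            "state_blocks": [sorted(s) for s in self.state_blocks],
            "move_rates": self.move_rates.tolist(),
            "death_rates": self.death_rates.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            state_blocks=[frozenset(s) for s in payload["state_blocks"]],
            move_rates=np.asarray(payload["move_rates"], dtype=float),
            death_rates=np.asarray(payload["death_rates"], dtype=float),
        )


def default_ground_truth(
    n_latent_states: int = 5,
    n_blocks: int = 131,
    seed: int = 0,
    onset_rate: float = 0.06,
    direct_entry_rate: float = 0.002,
    progression_rate: float = 0.025,
    high_risk_multiplier: float = 2.0,
    state_mortality: tuple[float, float, float] = (0.001, 0.004, 0.04),
    age_base: float = 0.4,
    age_slope: float = 0.2,
    sex_multipliers: np.ndarray | None = None,
) -> GroundTruth:
    """Nested-state dynamics: healthy -> intermediate patterns -> terminal sink.

    ``onset_rate`` is split evenly over the intermediate states;
    intermediate state 1 progresses into the terminal state at
    ``high_risk_multiplier`` times the rate of the other intermediates
    (the planted high-risk pattern).  All rates scale with age by
    ``age_base + age_slope * band`` and, optionally, elementwise by
    ``sex_multipliers`` of shape (2, S, S) (used to plant sex biases).
    """
    S = n_latent_states
    rng = np.random.default_rng(seed)
    n_mid = max(S - 2, 0)
    chosen = rng.choice(n_blocks, size=2 * n_mid + 2, replace=False)
    state_blocks: list[frozenset[int]] = [frozenset()]
    for i in range(n_mid):
        state_blocks.append(frozenset(chosen[2 * i : 2 * i + 2].tolist()))
    union = frozenset(chosen.tolist())
    state_blocks.append(union)

    base = np.zeros((S, S))
    if n_mid:
        for i in range(1, S - 1):
            base[0, i] = onset_rate / n_mid
            base[i, S - 1] = progression_rate * (high_risk_multiplier if i == 1 else 1.0)
        base[0, S - 1] = direct_entry_rate
    else:
        base[0, S - 1] = onset_rate
    mort = np.empty(S)
    mort[0] = state_mortality[0]
    mort[1 : S - 1] = state_mortality[1]
    mort[S - 1] = state_mortality[2]

    age_mult = age_base + age_slope * np.arange(N_AGE_BANDS)
    move = np.zeros((len(SEXES), N_AGE_BANDS, S, S))
    death = np.zeros((len(SEXES), N_AGE_BANDS, S))
    for g in range(len(SEXES)):
        smul = np.ones((S, S)) if sex_multipliers is None else np.asarray(sex_multipliers)[g]
        for a in range(N_AGE_BANDS):
            move[g, a] = base * smul * age_mult[a]
            death[g, a] = mort * age_mult[a]
    # keep rows honest probabilities under extreme multipliers
    total = move.sum(axis=3) + death
    scale = np.where(total > 0.95, 0.95 / np.maximum(total, 1e-12), 1.0)
    move *= scale[..., None]
    death *= scale
    truth = GroundTruth(state_blocks=state_blocks, move_rates=move, death_rates=death)
    truth.validate()
    return truth


def generate_registry(
    config: GeneratorConfig,
    ground_truth: GroundTruth | None = None,
    block_table: BlockTable | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a registry; returns the stay table and the realised ground truth.

    The returned :class:`GroundTruth` carries the planted rates plus the
    realised per-patient latent state sequence (``patient_states``) and a
    per-patient demographic frame (``patients``), which downstream recovery
    tests compare estimates against.  Identical ``config`` reproduces the
    table bit-for-bit.
    """
    config.validate()
    blocks = block_table if block_table is not None else default_block_table(config.n_blocks)
    ss = np.random.SeedSequence(config.seed)
    ss_truth, ss_dyn, ss_stays = ss.spawn(3)
    if ground_truth is None:
        truth_seed = int(ss_truth.generate_state(1)[0] % (2**31))
        truth = default_ground_truth(config.n_latent_states, config.n_blocks, seed=truth_seed)
    else:
        ground_truth.validate()
        truth = GroundTruth(
            state_blocks=ground_truth.state_blocks,
            move_rates=ground_truth.move_rates,
            death_rates=ground_truth.death_rates,
        )
    S = truth.n_states

    n = config.n_patients
    y0, y1 = config.years
    w0, w1 = config.washout_years
    t0, t1 = config.observation_years
    n_years = y1 - y0 + 1
    n_obs = t1 - t0 + 1
    years_axis = np.arange(y0, y1 + 1)

    rng = np.random.default_rng(ss_dyn)
    sex_idx = rng.integers(0, 2, n)
    if config.initial_age_bands is not None:
        bands5 = rng.choice(np.asarray(config.initial_age_bands, dtype=int), size=n)
    else:
        bands5 = rng.integers(0, 16, n)  # ages 0-79 at observation start
    age0 = bands5 * 5 + rng.integers(0, 5, n)
    birth_year = t0 - age0

    u_cat = rng.uniform(size=n)
    u_wd = rng.uniform(size=n)
    is_healthy = u_cat < config.frac_healthy
    # washout disease is drawn conditionally among the non-healthy remainder
    is_washout_diseased = (~is_healthy) & (u_wd < config.frac_washout_diseased)

    reg_lo = np.clip(birth_year, w0, None)
    reg_year = np.where(
        reg_lo > w1, reg_lo, rng.integers(0, 10_000, n) % np.maximum(w1 - reg_lo + 1, 1) + reg_lo
    )

    # stay skeleton (background hospital contacts), before dynamics
    rng_st = np.random.default_rng(ss_stays)
    counts = rng_st.poisson(config.mean_stays_per_year, size=(n, n_years))
    counts[years_axis[None, :] < birth_year[:, None]] = 0
    counts[np.arange(n), reg_year - y0] = np.maximum(counts[np.arange(n), reg_year - y0], 1)

    wd_year = np.where(reg_lo > w1, reg_lo, (reg_year - reg_lo) % np.maximum(w1 - reg_lo + 1, 1) + reg_lo)
    wd_year = np.where(is_washout_diseased, wd_year, -1)
    mask_wd = is_washout_diseased
    counts[np.arange(n)[mask_wd], wd_year[mask_wd] - y0] = np.maximum(
        counts[np.arange(n)[mask_wd], wd_year[mask_wd] - y0], 1
    )

    first_year = y0 + (counts > 0).argmax(axis=1)  # reg stay guarantees one exists
    eff_birth = first_year - 5 * ((first_year - birth_year) // 5)

    # latent dynamics over observation years (effective ages)
    states = np.zeros((n, n_obs), dtype=np.int16)
    death_year = np.full(n, -1, dtype=int)
    alive = np.ones(n, dtype=bool)
    can_move = ~is_healthy
    STAY = -1
    for step in range(n_obs - 1):
        y = t0 + step
        band = age_band_10y(y - eff_birth)
        cur = states[:, step]
        moves = truth.move_rates[sex_idx, band, cur, :]  # (n, S)
        moves = np.where(can_move[:, None], moves, 0.0)
        death_p = truth.death_rates[sex_idx, band, cur]
        cum = np.cumsum(np.concatenate([death_p[:, None], moves], axis=1), axis=1)
        u = rng.uniform(size=n)
        hit = u[:, None] < cum
        choice = np.where(hit.any(axis=1), hit.argmax(axis=1), STAY)
        choice = np.where(alive, choice, STAY)
        died = alive & (choice == 0)
        death_year[died] = y + 1
        alive &= ~died
        nxt = np.where(choice > 0, choice - 1, cur)
        nxt = np.where(alive | died, nxt, cur)
        states[:, step + 1] = np.where(died, cur, nxt)

    obs_cols = np.arange(t0, t1 + 1)
    acquired = states[:, 1:] != states[:, :-1]
    # force a stay in acquisition and death years; drop stays after death
    acq_rows, acq_steps = np.nonzero(acquired)
    acq_years = t0 + 1 + acq_steps
    counts[acq_rows, acq_years - y0] = np.maximum(counts[acq_rows, acq_years - y0], 1)
    has_death = death_year >= 0
    counts[np.arange(n)[has_death], death_year[has_death] - y0] = np.maximum(
        counts[np.arange(n)[has_death], death_year[has_death] - y0], 1
    )
    after_death = has_death[:, None] & (years_axis[None, :] > np.where(has_death, death_year, y1 + 1)[:, None])
    counts[after_death] = 0

    # per-patient acquisition events: (patient, year, new blocks)
    new_blocks_by_py: dict[tuple[int, int], list[int]] = {}
    for r, s_ in zip(acq_rows.tolist(), acq_steps.tolist()):
        prev, nxt = int(states[r, s_]), int(states[r, s_ + 1])
        gained = sorted(truth.state_blocks[nxt] - truth.state_blocks[prev])
        new_blocks_by_py[(r, t0 + 1 + s_)] = gained

    # precompute block code-range arrays for fast code emission
    bf = blocks.frame
    blk_letter = bf["first_code"].str[0].to_numpy()
    blk_lo = bf["first_code"].str[1:].astype(int).to_numpy()
    blk_span = bf["last_code"].str[1:].astype(int).to_numpy() - blk_lo + 1
    blk_ids = bf["block_id"].to_numpy()
    id_pos = {int(b): i for i, b in enumerate(blk_ids)}

    def code_of(block: int, u: float) -> str:
        i = id_pos[block]
        return f"{blk_letter[i]}{blk_lo[i] + int(u * blk_span[i]):02d}"

    total_stays = int(counts.sum())
    extra_diag = rng_st.poisson(config.mean_extra_diagnoses, total_stays)
    los = np.minimum(rng_st.geometric(0.25, total_stays) - 1, 30)
    u_transfer = rng_st.uniform(size=total_stays)
    u_noise = rng_st.uniform(size=total_stays)
    adm_day = rng_st.integers(0, 365, total_stays)
    u_pool = rng_st.uniform(size=total_stays * (2 + int(config.mean_extra_diagnoses * 2)) + 16)
    up = 0  # pointer into u_pool

    pid_fmt = f"P{{:0{max(7, len(str(n)))}d}}"
    rows_pid, rows_sex, rows_age, rows_year, rows_day = [], [], [], [], []
    rows_los, rows_type, rows_diag = [], [], []
    stay_ptr = 0
    n_pool_u = len(u_pool)

    for i in range(n):
        pool: list[int] = []
        pid = pid_fmt.format(i)
        sex = SEXES[sex_idx[i]]
        dy = death_year[i]
        for yi in range(n_years):
            c = int(counts[i, yi])
            if c == 0:
                continue
            year = y0 + yi
            gained = new_blocks_by_py.get((i, year))
            if gained:
                pool.extend(gained)
            wd_here = mask_wd[i] and wd_year[i] == year
            days = np.sort(adm_day[stay_ptr : stay_ptr + c])
            is_death_year = dy == year
            for s_i in range(c):
                k = stay_ptr + s_i
                codes: list[str] = []
                if s_i == 0 and gained:
                    for b in gained:
                        if up >= n_pool_u:
                            u_pool = rng_st.uniform(size=n_pool_u)
                            up = 0
                        codes.append(code_of(b, u_pool[up]))
                        up += 1
                if s_i == 0 and wd_here:
                    if up >= n_pool_u:
                        u_pool = rng_st.uniform(size=n_pool_u)
                        up = 0
                    wd_block = int(blk_ids[int(u_pool[up] * len(blk_ids))])
                    up += 1
                    if up >= n_pool_u:
                        u_pool = rng_st.uniform(size=n_pool_u)
                        up = 0
                    codes.append(code_of(wd_block, u_pool[up]))
                    up += 1
                n_draw = 1 + int(extra_diag[k])
                for _ in range(n_draw):
                    if up + 1 >= n_pool_u:
                        u_pool = rng_st.uniform(size=n_pool_u)
                        up = 0
                    if pool:
                        b = pool[int(u_pool[up] * len(pool))]
                        up += 1
                        codes.append(code_of(b, u_pool[up]))
                        up += 1
                    else:
                        codes.append(f"Z{int(u_pool[up] * 100):02d}")
                        up += 1
                if (
                    year >= t0
                    and not is_healthy[i]
                    and u_noise[k] < config.diagnosis_noise
                ):
                    if up + 1 >= n_pool_u:
                        u_pool = rng_st.uniform(size=n_pool_u)
                        up = 0
                    b = int(blk_ids[int(u_pool[up] * len(blk_ids))])
                    up += 1
                    codes.append(code_of(b, u_pool[up]))
                    up += 1
                # dedupe preserving order
                seen = set()
                codes = [c_ for c_ in codes if not (c_ in seen or seen.add(c_))]
                age_adm = year - birth_year[i]
                lo5 = 5 * (age_adm // 5)
                day = int(days[s_i])
                rel = day + int(los[k])
                rtype = "transfer" if u_transfer[k] < 0.1 else "normal"
                if is_death_year and s_i == c - 1:
                    rtype = "death"
                rows_pid.append(pid)
                rows_sex.append(sex)
                rows_age.append(f"{lo5}-{lo5 + 4}")
                rows_year.append(year)
                rows_day.append(day)
                rows_los.append(rel)
                rows_type.append(rtype)
                rows_diag.append(";".join(codes))
            if is_death_year and c > 1:
                # clamp earlier same-year stays to end by the death admission
                death_day = int(days[-1])
                for s_i in range(c - 1):
                    j = len(rows_los) - c + s_i
                    rows_los[j] = min(rows_los[j], death_day)
            stay_ptr += c

    adm = pd.to_datetime({"year": rows_year, "month": 1, "day": 1}) + pd.to_timedelta(rows_day, unit="D")
    rel = pd.to_datetime({"year": rows_year, "month": 1, "day": 1}) + pd.to_timedelta(
        np.maximum(rows_los, rows_day), unit="D"
    )
    stays = pd.DataFrame(
        {
            "patient_id": rows_pid,
            "sex": rows_sex,
            "age_group": rows_age,
            "admission_date": adm.dt.strftime("%Y-%m-%d"),
            "release_date": rel.dt.strftime("%Y-%m-%d"),
            "release_type": rows_type,
            "diagnoses": rows_diag,
        }
    ).sort_values(["patient_id", "admission_date"], kind="stable").reset_index(drop=True)

    # realised latent-state sequence (up to and including the death year)
    pids = np.array([pid_fmt.format(i) for i in range(n)])
    last_step = np.where(has_death, death_year - t0, n_obs - 1)
    grid = np.arange(n_obs)
    keep = grid[None, :] <= last_step[:, None]
    truth.patient_states = pd.DataFrame(
        {
            "patient_id": np.repeat(pids, keep.sum(axis=1)),
            "year": np.tile(t0 + grid, n)[keep.ravel()],
            "state": states[keep].astype(int),
        }
    )
    truth.patients = pd.DataFrame(
        {
            "patient_id": pids,
            "sex": np.array(SEXES)[sex_idx],
            "birth_year": birth_year,
            "eff_birth_year": eff_birth,
            "category": np.where(is_healthy, "healthy", np.where(is_washout_diseased, "washout_diseased", "dynamic")),
            "death_year": death_year,
        }
    )
    return stays, truth
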