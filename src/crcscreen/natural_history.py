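"""Monthly-cycle cohort microsimulation of the adenoma–carcinoma process.

Persons enter healthy at age 20 and are followed to age 100 or death on
1-month cycles.  Within a cycle a single multinomial draw over the state's
exit probabilities (disease transitions, all-cause death, and — for the first
120 months after a cancer diagnosis — stage-specific cancer death) decides
the outcome; the remainder is the self-loop.  Undetected (preclinical) cancer
carries no excess mortality.

Randomness is counter-based: each (purpose, cycle) pair owns an independent
stream of per-person uniforms derived from the master seed, so traces are
reproducible and interventions can be compared under common random numbers —
screening draws never perturb the disease-process stream.

A deterministic companion, :func:`cohort_matrix_oracle`, propagates expected
state occupancy through the same transition structure and serves as the
convergence oracle for the microsimulation; :func:`nh_forward_summary` is a
reduced forward operator over the undiagnosed population used as the
noise-free forward model during calibration.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .states import (
    CLIN_STATES,
    Event,
    Modality,
    TestReason,
    DiseaseState,
    N_STATES,
)
from .tables import (
    ENTRY_AGE_YEARS,
    HORIZON_AGE_YEARS,
    Lifetable,
    NaturalHistoryParams,
    StageSurvival,
)

ENTRY_AGE_MONTHS = ENTRY_AGE_YEARS * 12
HORIZON_AGE_MONTHS = HORIZON_AGE_YEARS * 12
CANCER_MORTALITY_WINDOW_MONTHS = 120

# random-stream purposes (counter-based; one stream per purpose per cycle)
_P_DISEASE = 0
_P_ADHERENCE = 1
_P_SCREEN_TEST = 2
_P_FU_ADHERENCE = 3
_P_FU_TEST = 4
_P_COMP_SCREEN = 5
_P_COMP_FU = 6
_P_SURV_TEST = 7
_P_COMP_SURV = 8
_P_COMP_DIAG = 9
_P_PERSISTENT = 10


def _uniforms(seed: int, purpose: int, cycle: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence([int(seed), purpose, cycle])
    return np.random.Generator(np.random.Philox(ss)).random(n)


@dataclass
class CohortConfig:
    """Cohort settings: size, entry/horizon ages, master seed."""

    n: int = 100_000
    entry_age_years: int = ENTRY_AGE_YEARS
    horizon_age_years: int = HORIZON_AGE_YEARS
    seed: int = 20240101

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if self.entry_age_years >= self.horizon_age_years:
            raise ValueError("entry age must precede horizon age")
        if self.entry_age_years != ENTRY_AGE_YEARS or self.horizon_age_years != HORIZON_AGE_YEARS:
            raise ValueError("model is defined on ages 20..100")

    @property
    def n_cycles(self) -> int:
        return (self.horizon_age_years - self.entry_age_years) * 12


@dataclass
class PersonState:
    """Single-person state used by the scalar stepping API."""

    state: DiseaseState = DiseaseState.HEALTHY
    age_months: int = ENTRY_AGE_MONTHS
    dx_month: int = -1  # age in months at diagnosis, -1 if undiagnosed
    dx_stage: int = -1
    screen_detected: bool = False
    in_surveillance: bool = False
    next_screen_month: int = -1

    @property
    def months_since_dx(self) -> int:
        if self.dx_month < 0:
            raise ValueError("months since diagnosis undefined before diagnosis")
        return self.age_months - self.dx_month


@dataclass
class CohortTrace:
    """Per-cycle occupancy, event log, and per-person endpoint arrays."""

    n: int
    n_cycles: int
    occupancy: np.ndarray  # (n_cycles + 1, 11) counts, cycle 0 = entry
    events: pd.DataFrame  # person_id, age_months, event, stage, modality, reason
    death_month: np.ndarray  # age in months, -1 = alive at horizon
    death_cause: np.ndarray  # -1 alive, 0 CRC, 1 other
    dx_month: np.ndarray
    dx_stage: np.ndarray
    screen_detected: np.ndarray
    seed: int

    def events_equal(self, other: "CohortTrace") -> bool:
        return self.events.equals(other.events)

    def n_colonoscopies(self) -> int:
        ev = self.events
        return int(
            ((ev["event"] == int(Event.TEST)) & (ev["modality"] == int(Modality.COLONOSCOPY))).sum()
        )

    def write(self, events_path, occupancy_path, header: str | None = None) -> None:
        for path, df in (
            (events_path, self.events),
            (
                occupancy_path,
                pd.DataFrame(self.occupancy, columns=[s.name for s in DiseaseState]).rename_axis(
                    "cycle"
                ),
            ),
        ):
            with open(path, "w") as fh:
                if header:
                    fh.write(f"# {header}\n")
                df.to_csv(fh, index=path == occupancy_path)


class _EventBuffer:
    """Append-only event store; scalar columns expanded lazily at frame time."""

    __slots__ = ("rows",)

    def __init__(self):
        self.rows = []  # (pid array, age, event, stage scalar-or-array, modality, reason)

    def add(self, pid: np.ndarray, age: int, event: int, stage=-1, modality=-1, reason=-1):
        if len(pid) == 0:
            return
        self.rows.append((pid, age, event, stage, modality, reason))

    def frame(self) -> pd.DataFrame:
        if not self.rows:
            return pd.DataFrame(
                {
                    "person_id": np.array([], dtype=np.int64),
                    "age_months": np.array([], dtype=np.int32),
                    "event": np.array([], dtype=np.int8),
                    "stage": np.array([], dtype=np.int8),
                    "modality": np.array([], dtype=np.int8),
                    "reason": np.array([], dtype=np.int8),
                }
            )
        sizes = [len(r[0]) for r in self.rows]
        total = sum(sizes)
        pid = np.empty(total, dtype=np.int64)
        age = np.empty(total, dtype=np.int32)
        cols = {
            "event": np.empty(total, dtype=np.int8),
            "stage": np.empty(total, dtype=np.int8),
            "modality": np.empty(total, dtype=np.int8),
            "reason": np.empty(total, dtype=np.int8),
        }
        at = 0
        for (p, a, e, s, m, r), k in zip(self.rows, sizes):
            sl = slice(at, at + k)
            pid[sl] = p
            age[sl] = a
            cols["event"][sl] = e
            cols["stage"][sl] = s
            cols["modality"][sl] = m
            cols["reason"][sl] = r
            at += k
        return pd.DataFrame(
            {"person_id": pid, "age_months": age, **cols}
        )


_TGT1 = np.array([1, 2, 3, 6, 7, 8], dtype=np.int8)
_TGT2 = np.array([1, 2, 3, 4, 5, 8], dtype=np.int8)


@njit(cache=True)
def _disease_step_kernel(
    state,
    u,
    thr1,
    thr2,
    thr3,
    tgt1,
    tgt2,
    mdo,
    mcd,
    dx_month,
    dx_stage,
    death_month,
    death_cause,
    age,
    counts,
    out_idx,
    out_old,
    out_new,
):
    """One monthly transition for every person; compiled inner loop.

    Returns the number of state changes; changed (index, old, new) triples
    are written to the out_* buffers and the occupancy counts are updated in
    place.
    """
    k = 0
    for i in range(state.shape[0]):
        s = state[i]
        if s >= 9:
            continue
        ui = u[i]
        if s < 6:
            if ui < thr1[s]:
                ns = tgt1[s]
            elif ui < thr2[s]:
                ns = tgt2[s]
            elif ui < thr3[s]:
                ns = 10
            else:
                continue
        else:
            dur = age - dx_month[i]
            p_cd = 0.0
            if dur >= 1 and dur <= 120:
                y = (dur - 1) // 12
                if y > 9:
                    y = 9
                p_cd = mcd[dx_stage[i], y]
            if ui < p_cd:
                ns = 9
            elif ui < p_cd + mdo:
                ns = 10
            else:
                continue
        out_idx[k] = i
        out_old[k] = s
        out_new[k] = ns
        k += 1
        counts[s] -= 1
        counts[ns] += 1
        state[i] = ns
        if ns >= 9:
            death_month[i] = age
            death_cause[i] = 0 if ns == 9 else 1
        elif ns >= 6 and s < 6:
            dx_month[i] = age
            dx_stage[i] = ns - 6
    return k


def _exit_table(pm: np.ndarray, ay: int, mdo: float):
    """Cumulative exit thresholds and targets per non-clinical state at one age.

    Returns (thr1, thr2, thr3, tgt1, tgt2) arrays of length 6 where a uniform
    u < thr1 takes tgt1, < thr2 takes tgt2, < thr3 dies of other causes.
    """
    onset, lr_hr, hr_pre, loc_reg, reg_dist, d_loc, d_reg, d_dis = pm[:, ay]
    p1 = np.array([onset, lr_hr, hr_pre, d_loc, d_reg, d_dis])
    p2 = np.array([0.0, 0.0, 0.0, loc_reg, reg_dist, 0.0])
    thr1 = p1
    thr2 = p1 + p2
    thr3 = thr2 + mdo
    return thr1, thr2, thr3, _TGT1, _TGT2


def step_person(
    person: PersonState,
    params: NaturalHistoryParams,
    lifetable: Lifetable,
    survival: StageSurvival,
    rng: np.random.Generator,
) -> PersonState:
    """Advance one person a single monthly cycle (disease process only).

    Exactly one outcome is sampled from the current state's exit-probability
    vector (self-loop included).  Cancer-specific mortality applies only while
    clinically diagnosed and within 120 months of diagnosis.
    """
    s = int(person.state)
    if s >= int(DiseaseState.DEATH_CRC):
        raise ValueError("person is not alive")
    ay = person.age_months // 12 - ENTRY_AGE_YEARS
    if not 0 <= ay < HORIZON_AGE_YEARS - ENTRY_AGE_YEARS:
        raise ValueError(f"age {person.age_months} months outside the model horizon")
    mdo = float(lifetable.monthly_q_model_ages()[ay])
    u = rng.random()
    new = s
    if s < int(DiseaseState.CLIN_LOCAL):
        thr1, thr2, thr3, tgt1, tgt2 = _exit_table(params.age_matrix(), ay, mdo)
        if u < thr1[s]:
            new = int(tgt1[s])
        elif u < thr2[s]:
            new = int(tgt2[s])
        elif u < thr3[s]:
            new = int(DiseaseState.DEATH_OTHER)
    else:
        dur = person.months_since_dx
        p_cd = 0.0
        if 1 <= dur <= CANCER_MORTALITY_WINDOW_MONTHS:
            p_cd = float(survival.monthly_q()[person.dx_stage, min((dur - 1) // 12, 9)])
        if u < p_cd:
            new = int(DiseaseState.DEATH_CRC)
        elif u < p_cd + mdo:
            new = int(DiseaseState.DEATH_OTHER)
    out = PersonState(
        state=DiseaseState(new),
        age_months=person.age_months + 1,
        dx_month=person.dx_month,
        dx_stage=person.dx_stage,
        screen_detected=person.screen_detected,
        in_surveillance=person.in_surveillance,
        next_screen_month=person.next_screen_month,
    )
    if s < int(DiseaseState.CLIN_LOCAL) <= new <= int(DiseaseState.CLIN_DISTANT):
        out.dx_month = person.age_months
        out.dx_stage = new - int(DiseaseState.CLIN_LOCAL)
    return out


def simulate_cohort(
    config: CohortConfig,
    params: NaturalHistoryParams,
    lifetable: Lifetable,
    survival: StageSurvival,
    strategy=None,
    tests=None,
) -> CohortTrace:
    """Simulate the cohort, optionally overlaid with a screening strategy.

    ``strategy`` is a :class:`~crcscreen.screening.StrategySpec` (or ``None``
    for pure natural history); ``tests`` maps modality names to
    :class:`~crcscreen.screening.TestCharacteristics` and must include
    ``"colonoscopy"`` whenever a strategy is given (follow-up, surveillance,
    and diagnostic work-up are always colonoscopies).  Identical
    (seed, config, params) inputs reproduce identical traces.
    """
    params.validate_exit_sums(lifetable)
    n, seed = config.n, config.seed
    n_cycles = config.n_cycles
    pm = params.age_matrix()
    mdo_by_ay = lifetable.monthly_q_model_ages()
    mcd = survival.monthly_q()

    state = np.zeros(n, dtype=np.int8)
    dx_month = np.full(n, -1, dtype=np.int32)
    dx_stage = np.full(n, -1, dtype=np.int8)
    screen_det = np.zeros(n, dtype=bool)
    death_month = np.full(n, -1, dtype=np.int32)
    death_cause = np.full(n, -1, dtype=np.int8)

    colo = tests.get("colonoscopy") if tests else None
    diag_comp_p = colo.complication_prob if colo is not None else 0.0

    if strategy is not None:
        if colo is None:
            raise ValueError("screening requires colonoscopy test characteristics")
        phases = strategy.phase_table()  # list of (modality name, interval, start_m, stop_m)
        first_line = tests[phases[0][0]]
        next_screen = np.full(n, phases[0][2], dtype=np.int32)
        in_surv = np.zeros(n, dtype=bool)
        next_surv = np.full(n, -1, dtype=np.int32)
        surv_stop_m = strategy.surveillance_stop_age * 12
        surv_first, surv_repeat = strategy.surveillance_intervals
        if strategy.adherence_mode == "persistent":
            persistent_attend = _uniforms(seed, _P_PERSISTENT, 0, n) < strategy.adherence

    occupancy = np.zeros((n_cycles + 1, N_STATES), dtype=np.int64)
    occupancy[0, 0] = n
    ev = _EventBuffer()
    pid = np.arange(n, dtype=np.int64)

    # the disease-process stream is drawn every cycle in fixed order, so a
    # single sequential generator reproduces the per-(cycle) keyed streams
    disease_gen = np.random.Generator(
        np.random.Philox(np.random.SeedSequence([int(seed), _P_DISEASE]))
    )
    # per-model-age exit thresholds for the non-clinical states, precomputed
    exit_tables = [
        _exit_table(pm, ay, float(mdo_by_ay[ay])) for ay in range(len(mdo_by_ay))
    ]
    min_start_m = min(p[2] for p in strategy.phase_table()) if strategy is not None else None
    any_surv = False
    scratch_counts = np.zeros(N_STATES, dtype=np.int64)
    buf_idx = np.empty(n, dtype=np.int64)
    buf_old = np.empty(n, dtype=np.int8)
    buf_new = np.empty(n, dtype=np.int8)

    def sens_for_state(test, st):
        """Per-person detection probability given current lesion class."""
        p = np.zeros(len(st))
        p[st == 1] = test.sens_adenoma_lr
        p[st == 2] = test.sens_adenoma_hr
        p[(st >= 3) & (st <= 5)] = test.sens_crc
        return p

    def do_colonoscopy(mask, age, cycle, reason, p_test, p_comp, lockout):
        nonlocal any_surv
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            return
        ev.add(idx, age, int(Event.TEST), modality=int(Modality.COLONOSCOPY), reason=int(reason))
        u = _uniforms(seed, p_test, cycle, n)[idx]
        uc = _uniforms(seed, p_comp, cycle, n)[idx]
        ev.add(idx[uc < colo.complication_prob], age, int(Event.COMPLICATION), reason=int(reason))
        st = state[idx]
        found = u < sens_for_state(colo, st)
        f_idx, f_st = idx[found], st[found]
        # complete removal of detected adenomas
        state[f_idx[f_st == 1]] = 0
        hr = f_idx[f_st == 2]
        state[hr] = 0
        in_surv[hr] = True
        next_surv[hr] = age + surv_first
        if len(hr):
            any_surv = True
        # screen-detected cancer moves to the clinical state of the same stage
        crc = f_idx[(f_st >= 3) & (f_st <= 5)]
        crc_stage = (st[found][(f_st >= 3) & (f_st <= 5)] - 3).astype(np.int8)
        state[crc] = 6 + crc_stage
        dx_month[crc] = age
        dx_stage[crc] = crc_stage
        screen_det[crc] = True
        ev.add(crc, age, int(Event.SCREEN_DX), stage=crc_stage)
        if reason == TestReason.SURVEILLANCE:
            nneg = idx[~found]
            next_surv[nneg] = age + surv_repeat
            next_surv[f_idx[f_st == 1]] = age + surv_repeat
        if lockout:
            neg = idx[~found]
            next_screen[neg] = np.maximum(next_screen[neg], age + 120)

    for t in range(n_cycles):
        age = ENTRY_AGE_MONTHS + t
        ay = age // 12 - ENTRY_AGE_YEARS
        alive = state < 9

        if strategy is not None and (age >= min_start_m or any_surv):
            nonclin = alive & (state < 6)
            if any_surv:
                # surveillance colonoscopies after high-risk polypectomy
                sdue = nonclin & in_surv & (next_surv == age) & (age <= surv_stop_m)
                do_colonoscopy(
                    sdue, age, t, TestReason.SURVEILLANCE, _P_SURV_TEST, _P_COMP_SURV, lockout=False
                )
            phase = strategy.phase_at(age)
            if phase is not None:
                due = nonclin & ~in_surv & (next_screen == age)
                if due.any():
                    if strategy.adherence_mode == "persistent":
                        attend = due & persistent_attend
                    else:
                        attend = due & (
                            _uniforms(seed, _P_ADHERENCE, t, n) < strategy.adherence
                        )
                    nxt = strategy.next_offer_after(age)
                    next_screen[due] = nxt if nxt is not None else np.iinfo(np.int32).max
                    test = tests[phase[0]]
                    if test.is_stool:
                        idx = np.flatnonzero(attend)
                        ev.add(
                            idx,
                            age,
                            int(Event.TEST),
                            modality=int(test.modality),
                            reason=int(TestReason.SCREEN),
                        )
                        u = _uniforms(seed, _P_SCREEN_TEST, t, n)[idx]
                        p_pos = sens_for_state(test, state[idx])
                        p_pos[state[idx] == 0] = 1.0 - test.specificity
                        pos = np.zeros(n, dtype=bool)
                        pos[idx[u < p_pos]] = True
                        fu = pos & (
                            _uniforms(seed, _P_FU_ADHERENCE, t, n) < strategy.followup_adherence
                        )
                        do_colonoscopy(
                            fu, age, t, TestReason.FOLLOWUP, _P_FU_TEST, _P_COMP_FU, lockout=True
                        )
                    elif test.modality == Modality.COLONOSCOPY:
                        do_colonoscopy(
                            attend,
                            age,
                            t,
                            TestReason.SCREEN,
                            _P_SCREEN_TEST,
                            _P_COMP_SCREEN,
                            lockout=True,
                        )
                    else:  # sigmoidoscopy: distal reach, positives referred to colonoscopy
                        idx = np.flatnonzero(attend)
                        ev.add(
                            idx,
                            age,
                            int(Event.TEST),
                            modality=int(Modality.SIGMOIDOSCOPY),
                            reason=int(TestReason.SCREEN),
                        )
                        uc = _uniforms(seed, _P_COMP_SCREEN, t, n)[idx]
                        ev.add(
                            idx[uc < test.complication_prob],
                            age,
                            int(Event.COMPLICATION),
                            reason=int(TestReason.SCREEN),
                        )
                        u = _uniforms(seed, _P_SCREEN_TEST, t, n)[idx]
                        reach = 1.0 if test.whole_colon else test.distal_fraction
                        found = np.zeros(n, dtype=bool)
                        found[idx[u < sens_for_state(test, state[idx]) * reach]] = True
                        fu = found & (
                            _uniforms(seed, _P_FU_ADHERENCE, t, n) < strategy.followup_adherence
                        )
                        do_colonoscopy(
                            fu, age, t, TestReason.FOLLOWUP, _P_FU_TEST, _P_COMP_FU, lockout=True
                        )

        # disease-process transition (one multinomial draw per person);
        # state changes are applied inside the compiled kernel, once per cycle
        u = disease_gen.random(n)
        mdo = float(mdo_by_ay[ay])
        thr1, thr2, thr3, tgt1, tgt2 = exit_tables[ay]
        k = _disease_step_kernel(
            state,
            u,
            thr1,
            thr2,
            thr3,
            tgt1,
            tgt2,
            mdo,
            mcd,
            dx_month,
            dx_stage,
            death_month,
            death_cause,
            age,
            scratch_counts,
            buf_idx,
            buf_old,
            buf_new,
        )
        if k:
            ci, cs, cn = buf_idx[:k], buf_old[:k], buf_new[:k]
            ev.add(ci[(cs == 0) & (cn == 1)], age, int(Event.ADENOMA_ONSET))
            ev.add(ci[(cs == 1) & (cn == 2)], age, int(Event.STAGE_TRANSITION), stage=-1)
            for frm, to in ((3, 4), (4, 5)):
                ev.add(
                    ci[(cs == frm) & (cn == to)],
                    age,
                    int(Event.STAGE_TRANSITION),
                    stage=to - 3,
                )
            ev.add(ci[(cs < 6) & (cn == 10)], age, int(Event.DEATH_OTHER))
            sym = (cs >= 3) & (cs <= 5) & (cn >= 6) & (cn <= 8)
            sym_i = ci[sym].copy()
            if len(sym_i):
                sym_stage = (cn[sym] - 6).astype(np.int8)
                ev.add(sym_i, age, int(Event.SYMPTOMATIC_DX), stage=sym_stage)
                # symptomatic presentation is worked up with one diagnostic colonoscopy
                ev.add(
                    sym_i,
                    age,
                    int(Event.TEST),
                    modality=int(Modality.COLONOSCOPY),
                    reason=int(TestReason.DIAGNOSTIC),
                )
                ucd = _uniforms(seed, _P_COMP_DIAG, t, n)[sym_i]
                ev.add(
                    sym_i[ucd < diag_comp_p],
                    age,
                    int(Event.COMPLICATION),
                    reason=int(TestReason.DIAGNOSTIC),
                )
            cl_dead = cs >= 6
            for code, evk in ((9, Event.DEATH_CRC), (10, Event.DEATH_OTHER)):
                di = ci[cl_dead & (cn == code)].copy()
                if len(di):
                    ev.add(di, age, int(evk), stage=dx_stage[di])
        occupancy[t + 1] = np.bincount(state, minlength=N_STATES)

    return CohortTrace(
        n=n,
        n_cycles=n_cycles,
        occupancy=occupancy,
        events=ev.frame(),
        death_month=death_month,
        death_cause=death_cause,
        dx_month=dx_month,
        dx_stage=dx_stage,
        screen_detected=screen_det,
        seed=seed,
    )


@dataclass
class OracleResult:
    """Expected (per-person) state occupancy and diagnosis flows by cycle."""

    occupancy: np.ndarray  # (n_cycles + 1, 11) expected fractions
    dx_inflow: np.ndarray  # (n_cycles, 3) expected diagnoses per cycle by stage


def cohort_matrix_oracle(
    config: CohortConfig,
    params: NaturalHistoryParams,
    lifetable: Lifetable,
    survival: StageSurvival,
) -> OracleResult:
    """Exact expected occupancy trajectory of the no-screening process.

    Forward recursion over the monthly transition structure, tracking the
    diagnosed population by months-since-diagnosis so the 10-year
    cancer-mortality window is applied exactly as in the microsimulation.
    Microsimulation occupancy means converge to this as cohort size grows.
    """
    params.validate_exit_sums(lifetable)
    n_cycles = config.n_cycles
    pm = params.age_matrix()
    mdo_by_ay = lifetable.monthly_q_model_ages()
    mcd = survival.monthly_q()

    occ = np.zeros(6)
    occ[0] = 1.0
    # clinical mass by (stage, months since dx = 1..120); post-window bucket separate
    C = np.zeros((3, CANCER_MORTALITY_WINDOW_MONTHS))
    C_post = np.zeros(3)
    dead_crc = 0.0
    dead_oth = 0.0
    dur_years = np.minimum(np.arange(CANCER_MORTALITY_WINDOW_MONTHS) // 12, 9)

    occupancy = np.zeros((n_cycles + 1, N_STATES))
    occupancy[0, :6] = occ
    dx_inflow = np.zeros((n_cycles, 3))

    for t in range(n_cycles):
        ay = (ENTRY_AGE_MONTHS + t) // 12 - ENTRY_AGE_YEARS
        onset, lr_hr, hr_pre, loc_reg, reg_dist, d_loc, d_reg, d_dis = pm[:, ay]
        mdo = float(mdo_by_ay[ay])

        new_dx = np.array([occ[3] * d_loc, occ[4] * d_reg, occ[5] * d_dis])
        dx_inflow[t] = new_dx
        dead_oth += occ.sum() * mdo
        occ_new = np.empty(6)
        occ_new[0] = occ[0] * (1 - onset - mdo)
        occ_new[1] = occ[1] * (1 - lr_hr - mdo) + occ[0] * onset
        occ_new[2] = occ[2] * (1 - hr_pre - mdo) + occ[1] * lr_hr
        occ_new[3] = occ[3] * (1 - d_loc - loc_reg - mdo) + occ[2] * hr_pre
        occ_new[4] = occ[4] * (1 - d_reg - reg_dist - mdo) + occ[3] * loc_reg
        occ_new[5] = occ[5] * (1 - d_dis - mdo) + occ[4] * reg_dist
        occ = occ_new

        p_cd = mcd[np.arange(3)[:, None], dur_years[None, :]]  # (3, 120)
        dead_crc += float((C * p_cd).sum())
        dead_oth += float(C.sum() * mdo) + float(C_post.sum() * mdo)
        surv = C * (1.0 - p_cd - mdo)
        C_post = C_post * (1.0 - mdo) + surv[:, -1]
        C = np.roll(surv, 1, axis=1)
        C[:, 0] = new_dx

        occupancy[t + 1, :6] = occ
        occupancy[t + 1, 6:9] = C.sum(axis=1) + C_post
        occupancy[t + 1, 9] = dead_crc
        occupancy[t + 1, 10] = dead_oth

    return OracleResult(occupancy=occupancy, dx_inflow=dx_inflow)


@dataclass
class NHForwardSummary:
    """Outputs of the reduced undiagnosed-population forward recursion."""

    person_years_by_age: np.ndarray  # (80,) alive-and-undiagnosed person-years
    dx_by_age_stage: np.ndarray  # (80, 3) expected diagnoses
    adenoma_prev_by_age: np.ndarray  # (80,) LR+HR fraction among alive undiagnosed

    def incidence_per_100k(self, band_edges: np.ndarray) -> np.ndarray:
        """Diagnoses per 100,000 undiagnosed person-years per age band."""
        ages = np.arange(ENTRY_AGE_YEARS, HORIZON_AGE_YEARS)
        idx = np.searchsorted(band_edges, ages, "right") - 1
        nb = len(band_edges) - 1
        out = np.zeros(nb)
        for b in range(nb):
            m = idx == b
            py = self.person_years_by_age[m].sum()
            out[b] = self.dx_by_age_stage[m].sum() / py * 1e5 if py > 0 else 0.0
        return out

    def prevalence_at(self, ages) -> np.ndarray:
        return self.adenoma_prev_by_age[np.asarray(ages, dtype=int) - ENTRY_AGE_YEARS]

    def stage_distribution(self) -> np.ndarray:
        total = self.dx_by_age_stage.sum()
        if total <= 0:
            return np.full(3, np.nan)
        return self.dx_by_age_stage.sum(axis=0) / total

    @property
    def lifetime_incidence(self) -> float:
        """Expected lifetime probability of a CRC diagnosis per person."""
        return float(self.dx_by_age_stage.sum())


def nh_forward_summary(params: NaturalHistoryParams, lifetable: Lifetable) -> NHForwardSummary:
    """Deterministic forward recursion restricted to the undiagnosed population.

    Diagnosed persons leave the tracked population, so incidence targets
    (denominator: alive-and-undiagnosed person-time), adenoma prevalence and
    the stage mix at diagnosis are computable without the post-diagnosis
    survival model.  This is the noise-free forward operator calibration
    optimizes against.
    """
    pm = params.age_matrix()
    mdo_by_ay = lifetable.monthly_q_model_ages()
    n_ages = HORIZON_AGE_YEARS - ENTRY_AGE_YEARS
    o0, o1, o2, o3, o4, o5 = 1.0, 0.0, 0.0, 0.0, 0.0, 0.0
    py = np.zeros(n_ages)
    dx = np.zeros((n_ages, 3))
    prev = np.zeros(n_ages)
    for t in range(n_ages * 12):
        ay = t // 12
        if t % 12 == 0:
            tot = o0 + o1 + o2 + o3 + o4 + o5
            prev[ay] = (o1 + o2) / tot if tot > 0 else 0.0
        onset, lr_hr, hr_pre, loc_reg, reg_dist, d_loc, d_reg, d_dis = pm[:, ay]
        mdo = float(mdo_by_ay[ay])
        py[ay] += (o0 + o1 + o2 + o3 + o4 + o5) / 12.0
        dx[ay, 0] += o3 * d_loc
        dx[ay, 1] += o4 * d_reg
        dx[ay, 2] += o5 * d_dis
        o0, o1, o2, o3, o4, o5 = (
            o0 * (1 - onset - mdo),
            o1 * (1 - lr_hr - mdo) + o0 * onset,
            o2 * (1 - hr_pre - mdo) + o1 * lr_hr,
            o3 * (1 - d_loc - loc_reg - mdo) + o2 * hr_pre,
            o4 * (1 - d_reg - reg_dist - mdo) + o3 * loc_reg,
            o5 * (1 - d_dis - mdo) + o4 * reg_dist,
        )
    return NHForwardSummary(person_years_by_age=py, dx_by_age_stage=dx, adenoma_prev_by_age=prev)


@dataclass
class IncidenceSummary:
    """Empirical incidence/stage/lifetime summary of a simulated trace."""

    incidence_per_100k: np.ndarray  # per single year of age 20..99
    person_years_by_age: np.ndarray
    dx_by_age: np.ndarray
    stage_distribution: Optional[np.ndarray]  # None when no diagnoses occurred
    lifetime_case_fraction: float
    lifetime_crc_death_fraction: float
    empty: bool = False

    def incidence_band(self, lo: int, hi: int) -> float:
        """Incidence per 100k person-years over ages [lo, hi)."""
        sl = slice(lo - ENTRY_AGE_YEARS, hi - ENTRY_AGE_YEARS)
        py = self.person_years_by_age[sl].sum()
        return float(self.dx_by_age[sl].sum() / py * 1e5) if py > 0 else 0.0


def incidence_and_stage_summary(trace: CohortTrace) -> IncidenceSummary:
    """Age-specific CRC incidence, stage mix at diagnosis, lifetime fractions.

    The incidence denominator counts alive-and-undiagnosed person-time.
    """
    n_ages = HORIZON_AGE_YEARS - ENTRY_AGE_YEARS
    end = np.where(trace.death_month >= 0, trace.death_month, HORIZON_AGE_MONTHS)
    end = np.where(trace.dx_month >= 0, np.minimum(end, trace.dx_month), end).astype(np.int64)
    ages12 = (np.arange(n_ages) + ENTRY_AGE_YEARS) * 12
    py = (
        np.clip(end[None, :] - ages12[:, None], 0, 12).sum(axis=1) / 12.0
        if trace.n <= 200_000
        else np.array(
            [np.clip(end - a, 0, 12).sum() / 12.0 for a in ages12]
        )
    )
    diagnosed = trace.dx_month >= 0
    dx_age = trace.dx_month[diagnosed] // 12 - ENTRY_AGE_YEARS
    dx_by_age = np.bincount(dx_age, minlength=n_ages).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(py > 0, dx_by_age / py * 1e5, 0.0)
    n_dx = int(diagnosed.sum())
    stage = (
        np.bincount(trace.dx_stage[diagnosed], minlength=3) / n_dx if n_dx else None
    )
    return IncidenceSummary(
        incidence_per_100k=inc,
        person_years_by_age=py,
        dx_by_age=dx_by_age,
        stage_distribution=stage,
        lifetime_case_fraction=n_dx / trace.n,
        lifetime_crc_death_fraction=float((trace.death_cause == 0).sum()) / trace.n,
        empty=n_dx == 0,
    )
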