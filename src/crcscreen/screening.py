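"""Screening policies layered on the natural-history process.

A strategy is one or more phases (modality, interval, age window) plus
adherence assumptions and a post-polypectomy surveillance schedule.  Positive
stool tests and positive sigmoidoscopies are referred to a follow-up
colonoscopy; a negative colonoscopy — irrespective of true lesion status —
locks further first-line screening out for 120 months.  Detected adenomas are
completely removed; a detected high-risk adenoma enrolls the person in
colonoscopy surveillance (first interval 3 years, then every 5) until the
surveillance stop age.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .natural_history import CohortConfig, CohortTrace, PersonState, simulate_cohort
from .states import MODALITY_NAMES, DiseaseState, Modality, TestReason

SCREEN_LOCKOUT_MONTHS = 120


@dataclass
class TestCharacteristics:
    """Operating characteristics of one screening test."""

    modality: Modality
    sens_adenoma_lr: float
    sens_adenoma_hr: float
    sens_crc: float
    specificity: float
    complication_prob: float = 0.0
    whole_colon: bool = True
    distal_fraction: float = 1.0

    def __post_init__(self):
        if isinstance(self.modality, str):
            self.modality = Modality(MODALITY_NAMES.index(self.modality))
        for name in (
            "sens_adenoma_lr",
            "sens_adenoma_hr",
            "sens_crc",
            "specificity",
            "complication_prob",
            "distal_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.is_stool and self.complication_prob != 0.0:
            raise ValueError("stool tests cannot carry a complication probability")

    @property
    def is_stool(self) -> bool:
        return self.modality in (Modality.FIT, Modality.FOBT)

    @property
    def name(self) -> str:
        return MODALITY_NAMES[self.modality]


def test_characteristics_frame(tests: dict) -> pd.DataFrame:
    rows = []
    for t in tests.values():
        rows.append(
            {
                "modality": t.name,
                "sens_adenoma_lr": t.sens_adenoma_lr,
                "sens_adenoma_hr": t.sens_adenoma_hr,
                "sens_crc": t.sens_crc,
                "specificity": t.specificity,
                "complication_prob": t.complication_prob,
                "whole_colon": int(t.whole_colon),
                "distal_fraction": t.distal_fraction,
            }
        )
    return pd.DataFrame(rows)


def test_characteristics_from_frame(df: pd.DataFrame) -> dict:
    out = {}
    for _, r in df.iterrows():
        out[r["modality"]] = TestCharacteristics(
            modality=r["modality"],
            sens_adenoma_lr=float(r["sens_adenoma_lr"]),
            sens_adenoma_hr=float(r["sens_adenoma_hr"]),
            sens_crc=float(r["sens_crc"]),
            specificity=float(r["specificity"]),
            complication_prob=float(r["complication_prob"]),
            whole_colon=bool(r["whole_colon"]),
            distal_fraction=float(r["distal_fraction"]),
        )
    return out


@dataclass
class SurveillanceSchedule:
    """Colonoscopy intervals after high-risk polypectomy: 3 years, then 5."""

    first_months: int = 36
    repeat_months: int = 60
    stop_age_years: int = 85

    def __post_init__(self):
        if self.first_months <= 0 or self.repeat_months <= 0:
            raise ValueError("surveillance intervals must be positive")


@dataclass
class StrategyPhase:
    modality: str
    interval_months: int
    start_age_years: int
    stop_age_years: int


@dataclass
class StrategySpec:
    """A screening policy: phased offer schedule plus adherence assumptions.

    Base-case policies have a single phase (e.g. biennial FIT from 45 to 75);
    the FIT-then-colonoscopy switch policy has two.  First-line adherence is
    an independent Bernoulli draw per offer unless ``adherence_mode`` is
    ``"persistent"`` (one draw per person).
    """

    name: str
    phases: list = field(default_factory=list)
    adherence: float = 0.606
    followup_adherence: float = 1.0
    surveillance: SurveillanceSchedule = field(default_factory=SurveillanceSchedule)
    adherence_mode: str = "per_offer"

    def __post_init__(self):
        if not self.phases:
            raise ValueError("strategy needs at least one phase")
        self.phases = [
            StrategyPhase(**p) if isinstance(p, dict) else p for p in self.phases
        ]
        for p in self.phases:
            if p.start_age_years >= p.stop_age_years:
                raise ValueError(f"{self.name}: phase start age must precede stop age")
        for a in (self.adherence, self.followup_adherence):
            if not 0.0 <= a <= 1.0:
                raise ValueError("adherence outside [0, 1]")
        if self.adherence_mode not in ("per_offer", "persistent"):
            raise ValueError("adherence_mode must be per_offer or persistent")

    @property
    def surveillance_stop_age(self) -> int:
        return self.surveillance.stop_age_years

    @property
    def surveillance_intervals(self):
        return self.surveillance.first_months, self.surveillance.repeat_months

    def phase_table(self):
        return [
            (p.modality, p.interval_months, p.start_age_years * 12, p.stop_age_years * 12)
            for p in self.phases
        ]

    def phase_at(self, age_months: int):
        """The phase whose offer window [start, stop] contains this age.

        At a boundary shared by two phases the later phase wins (the
        FIT-to-colonoscopy switch hands over exactly at the switch age).
        """
        for p in reversed(self.phase_table()):
            if p[2] <= age_months <= p[3]:
                return p
        return None

    def next_offer_after(self, age_months: int) -> Optional[int]:
        """Age in months of the next scheduled offer after one at ``age_months``."""
        table = self.phase_table()
        for i, p in reversed(list(enumerate(table))):
            if p[2] <= age_months <= p[3]:
                cand = age_months + p[1]
                if cand <= p[3]:
                    return cand
                if i + 1 < len(table) and table[i + 1][2] > age_months:
                    return table[i + 1][2]
                return None
        later = [p[2] for p in table if p[2] > age_months]
        return min(later) if later else None


def single_phase_strategy(
    name: str,
    modality: str,
    interval_months: int,
    start_age: int = 45,
    stop_age: int = 75,
    **kwargs,
) -> StrategySpec:
    return StrategySpec(
        name=name,
        phases=[StrategyPhase(modality, interval_months, start_age, stop_age)],
        **kwargs,
    )


def fit_colo_switch_strategy(switch_age: int = 50, stop_age: int = 75, **kwargs) -> StrategySpec:
    """Biennial FIT up to the switch age, then 10-yearly colonoscopy."""
    return StrategySpec(
        name="FIT-Colo",
        phases=[
            StrategyPhase("fit", 24, 45, switch_age),
            StrategyPhase("colonoscopy", 120, switch_age, stop_age),
        ],
        **kwargs,
    )


# ---------------------------------------------------------------------------
# per-person operations (the scalar counterparts of the vectorized engine)
# ---------------------------------------------------------------------------


def next_action(person: PersonState, strategy: StrategySpec, age_months: int) -> str:
    """What, if anything, the policy offers this person at this age.

    Returns ``"offer_screen"``, ``"offer_surveillance_colo"`` or ``"none"``.
    No first-line offer arrives before the start age, after the stop age, or
    within the 120-month lockout following a negative colonoscopy;
    surveillance offers follow their own schedule until the surveillance stop
    age.
    """
    if not person.state.is_alive or person.state.is_clinical:
        raise ValueError("next_action applies to alive, undiagnosed persons")
    if person.in_surveillance:
        if age_months <= strategy.surveillance_stop_age * 12:
            return "offer_surveillance_colo"
        return "none"
    if strategy.phase_at(age_months) is None:
        return "none"
    due = person.next_screen_month < 0 or age_months >= person.next_screen_month
    return "offer_screen" if due else "none"


def perform_stool_test(
    person: PersonState, test: TestCharacteristics, rng: np.random.Generator
) -> bool:
    """One stool test; ``True`` = positive.

    Positivity follows the test's sensitivity for the person's lesion class,
    or ``1 - specificity`` when no lesion is present.
    """
    if not test.is_stool:
        raise ValueError("perform_stool_test requires a stool modality")
    s = person.state
    if s == DiseaseState.ADENOMA_LR:
        p = test.sens_adenoma_lr
    elif s == DiseaseState.ADENOMA_HR:
        p = test.sens_adenoma_hr
    elif s.is_preclinical:
        p = test.sens_crc
    else:
        p = 1.0 - test.specificity
    return bool(rng.random() < p)


@dataclass
class EndoscopyResult:
    finding: str  # none | LR | HR | CRC
    stage: int  # -1 unless CRC
    complication: bool


def perform_endoscopy(
    person: PersonState,
    test: TestCharacteristics,
    reason: TestReason,
    rng: np.random.Generator,
) -> EndoscopyResult:
    """One endoscopy; mutates ``person`` with its consequences.

    Detection probability is sensitivity times the distal-lesion fraction for
    distal-reach instruments.  Detected adenomas are removed (person returns
    to Healthy; high-risk detection enrolls surveillance); detected
    preclinical cancer becomes clinical at the same stage; a negative
    colonoscopy starts the 120-month screening lockout.
    """
    if test.is_stool:
        raise ValueError("perform_endoscopy requires an endoscopic modality")
    s = person.state
    reach = 1.0 if test.whole_colon else test.distal_fraction
    if s == DiseaseState.ADENOMA_LR:
        p, finding = test.sens_adenoma_lr * reach, "LR"
    elif s == DiseaseState.ADENOMA_HR:
        p, finding = test.sens_adenoma_hr * reach, "HR"
    elif s.is_preclinical:
        p, finding = test.sens_crc * reach, "CRC"
    else:
        p, finding = 0.0, "none"
    detected = rng.random() < p
    complication = bool(rng.random() < test.complication_prob)
    if not detected:
        if test.modality == Modality.COLONOSCOPY:
            person.next_screen_month = max(
                person.next_screen_month, person.age_months + SCREEN_LOCKOUT_MONTHS
            )
        return EndoscopyResult("none", -1, complication)
    if finding in ("LR", "HR"):
        person.state = DiseaseState.HEALTHY
        if finding == "HR":
            person.in_surveillance = True
    else:
        stage = int(s) - int(DiseaseState.PRECLIN_LOCAL)
        person.state = DiseaseState(int(DiseaseState.CLIN_LOCAL) + stage)
        person.dx_month = person.age_months
        person.dx_stage = stage
        person.screen_detected = True
        return EndoscopyResult("CRC", stage, complication)
    return EndoscopyResult(finding, -1, complication)


def run_strategy(
    config: CohortConfig,
    params,
    lifetable,
    survival,
    strategy: StrategySpec,
    tests: dict,
) -> CohortTrace:
    """Simulate the cohort under a screening policy (common random numbers).

    With first-line adherence 0 the disease trajectory — and hence the event
    log — is identical to the natural-history run under the same seed.
    """
    return simulate_cohort(config, params, lifetable, survival, strategy=strategy, tests=tests)
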