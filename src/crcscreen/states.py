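"""Disease-state space and event vocabulary for the adenoma–carcinoma model.

The natural-history chain runs Healthy → low-risk adenoma → high-risk adenoma
→ preclinical cancer (local → regional → distant).  Each preclinical stage may
surface clinically through symptomatic detection; the two death states are
absorbing.  Cancer-specific death is only reachable from the clinical states.
"""
from __future__ import annotations

from enum import IntEnum


class DiseaseState(IntEnum):
    HEALTHY = 0
    ADENOMA_LR = 1
    ADENOMA_HR = 2
    PRECLIN_LOCAL = 3
    PRECLIN_REGIONAL = 4
    PRECLIN_DISTANT = 5
    CLIN_LOCAL = 6
    CLIN_REGIONAL = 7
    CLIN_DISTANT = 8
    DEATH_CRC = 9
    DEATH_OTHER = 10

    @property
    def is_alive(self) -> bool:
        return self < DiseaseState.DEATH_CRC

    @property
    def is_adenoma(self) -> bool:
        return self in (DiseaseState.ADENOMA_LR, DiseaseState.ADENOMA_HR)

    @property
    def is_preclinical(self) -> bool:
        return DiseaseState.PRECLIN_LOCAL <= self <= DiseaseState.PRECLIN_DISTANT

    @property
    def is_clinical(self) -> bool:
        return DiseaseState.CLIN_LOCAL <= self <= DiseaseState.CLIN_DISTANT


#: stage codes shared by preclinical/clinical states and survival tables
STAGE_LOCAL, STAGE_REGIONAL, STAGE_DISTANT = 0, 1, 2
STAGE_NAMES = ("local", "regional", "distant")

N_STATES = 11
ALIVE_STATES = tuple(range(9))
PRECLIN_STATES = (3, 4, 5)
CLIN_STATES = (6, 7, 8)


class Event(IntEnum):
    """Event kinds recorded in the cohort event log."""

    ADENOMA_ONSET = 0
    STAGE_TRANSITION = 1
    SYMPTOMATIC_DX = 2
    SCREEN_DX = 3
    TEST = 4
    COMPLICATION = 5
    DEATH_CRC = 6
    DEATH_OTHER = 7


class Modality(IntEnum):
    COLONOSCOPY = 0
    SIGMOIDOSCOPY = 1
    FIT = 2
    FOBT = 3


MODALITY_NAMES = ("colonoscopy", "sigmoidoscopy", "fit", "fobt")
STOOL_MODALITIES = (Modality.FIT, Modality.FOBT)
ENDOSCOPIC_MODALITIES = (Modality.COLONOSCOPY, Modality.SIGMOIDOSCOPY)


class TestReason(IntEnum):
    SCREEN = 0
    FOLLOWUP = 1
    SURVEILLANCE = 2
    DIAGNOSTIC = 3


REASON_NAMES = ("screen", "followup", "surveillance", "diagnostic")
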