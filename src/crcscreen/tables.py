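"""Input tables: lifetable, stage-specific survival, natural-history parameters.

All tables are plain CSV on disk and numpy-backed in memory.  Transition
probabilities are stored on the monthly time step the simulation runs on;
``annual_to_monthly`` converts published annual risks.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .states import STAGE_NAMES

ENTRY_AGE_YEARS = 20
HORIZON_AGE_YEARS = 100
N_MODEL_AGES = HORIZON_AGE_YEARS - ENTRY_AGE_YEARS  # simulated ages 20..99

PARAM_NAMES = (
    "p_adenoma_onset",
    "p_LR_to_HR",
    "p_HR_to_preclin",
    "p_local_to_regional",
    "p_regional_to_distant",
    "p_detect_local",
    "p_detect_regional",
    "p_detect_distant",
)


def annual_to_monthly(p_annual):
    """Convert an annual probability to the equivalent monthly probability.

    Uses the constant-hazard identity ``1 - (1 - p)**(1/12)``.  Accepts
    scalars or arrays; raises ``ValueError`` outside [0, 1].
    """
    p = np.asarray(p_annual, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("annual probability outside [0, 1]")
    out = 1.0 - (1.0 - p) ** (1.0 / 12.0)
    return float(out) if np.isscalar(p_annual) else out


def monthly_to_annual(p_monthly):
    """Inverse of :func:`annual_to_monthly`."""
    p = np.asarray(p_monthly, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("monthly probability outside [0, 1]")
    out = 1.0 - (1.0 - p) ** 12.0
    return float(out) if np.isscalar(p_monthly) else out


@dataclass
class Lifetable:
    """All-cause annual death probability by single year of age (0–100)."""

    annual_q: np.ndarray  # indexed by age in years, length 101

    def __post_init__(self):
        self.annual_q = np.asarray(self.annual_q, dtype=float)
        if self.annual_q.shape != (101,):
            raise ValueError("lifetable must cover ages 0..100")
        if np.any((self.annual_q < 0) | (self.annual_q > 1)):
            raise ValueError("lifetable probabilities outside [0, 1]")

    def monthly_q_model_ages(self) -> np.ndarray:
        """Monthly all-cause death probability for ages 20..99 (length 80)."""
        return annual_to_monthly(self.annual_q[ENTRY_AGE_YEARS:HORIZON_AGE_YEARS])

    def life_expectancy_at(self, age: int) -> float:
        """Curtate life expectancy at `age`, horizon-capped at 100."""
        q = self.annual_q[age:HORIZON_AGE_YEARS]
        surv = np.cumprod(1.0 - q)
        return float(surv.sum())

    @classmethod
    def read_csv(cls, path) -> "Lifetable":
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        q = np.zeros(101)
        q[df["age"].to_numpy(int)] = df["qx"].to_numpy(float)
        return cls(q)

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": np.arange(101), "qx": self.annual_q}).to_csv(
            path, index=False, float_format="%.17g"
        )


@dataclass
class StageSurvival:
    """Annual cancer-specific death probability by stage and year since diagnosis.

    Excess mortality applies for 10 years after diagnosis; beyond year 10 only
    all-cause mortality remains.
    """

    annual_q: np.ndarray  # shape (3 stages, 10 years)

    def __post_init__(self):
        self.annual_q = np.asarray(self.annual_q, dtype=float)
        if self.annual_q.shape != (3, 10):
            raise ValueError("stage survival must be 3 stages x 10 years")
        if np.any((self.annual_q < 0) | (self.annual_q > 1)):
            raise ValueError("cancer death probabilities outside [0, 1]")

    def validate_ordering(self) -> None:
        """Fixture sanity: distant >= regional >= local hazard at every year."""
        if np.any(self.annual_q[2] < self.annual_q[1]) or np.any(
            self.annual_q[1] < self.annual_q[0]
        ):
            raise ValueError("stage survival ordering violated (distant>=regional>=local)")

    def monthly_q(self) -> np.ndarray:
        return annual_to_monthly(self.annual_q)

    @classmethod
    def read_csv(cls, path) -> "StageSurvival":
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        q = np.zeros((3, 10))
        for _, row in df.iterrows():
            q[STAGE_NAMES.index(row["stage"]), int(row["year"]) - 1] = row["qx_cancer"]
        return cls(q)

    def to_csv(self, path) -> None:
        rows = [
            {"stage": STAGE_NAMES[s], "year": y + 1, "qx_cancer": self.annual_q[s, y]}
            for s in range(3)
            for y in range(10)
        ]
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def five_year_bands() -> np.ndarray:
    """Default age-band edges: 5-year bands from 20 to 100."""
    return np.arange(ENTRY_AGE_YEARS, HORIZON_AGE_YEARS + 1, 5)


@dataclass
class NaturalHistoryParams:
    """Age-banded monthly transition probabilities of the natural-history chain.

    ``values[name]`` holds one monthly probability per band; ``edges[name]``
    the band edges in years (length ``len(values[name]) + 1``, spanning
    [20, 100]).  Bands are half-open ``[lo, hi)`` and piecewise constant.
    """

    values: dict = field(default_factory=dict)
    edges: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in PARAM_NAMES:
            if name not in self.values:
                raise ValueError(f"missing parameter {name}")
            v = np.atleast_1d(np.asarray(self.values[name], dtype=float))
            e = np.atleast_1d(
                np.asarray(
                    self.edges.get(name, (ENTRY_AGE_YEARS, HORIZON_AGE_YEARS)),
                    dtype=int,
                )
            )
            if len(e) != len(v) + 1 or e[0] != ENTRY_AGE_YEARS or e[-1] != HORIZON_AGE_YEARS:
                raise ValueError(
                    f"band edges for {name} must span 20..100 with len(values)+1 edges"
                )
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name}: probability outside [0, 1]")
            self.values[name] = v
            self.edges[name] = e

    def by_model_age(self, name: str) -> np.ndarray:
        """Monthly probability per single year of age 20..99 (length 80)."""
        idx = (
            np.searchsorted(
                self.edges[name], np.arange(ENTRY_AGE_YEARS, HORIZON_AGE_YEARS), "right"
            )
            - 1
        )
        return self.values[name][np.clip(idx, 0, len(self.values[name]) - 1)]

    def age_matrix(self) -> np.ndarray:
        """All parameters expanded to (n_params, 80) by model age."""
        return np.stack([self.by_model_age(n) for n in PARAM_NAMES])

    def validate_exit_sums(self, lifetable: Lifetable) -> None:
        """Every state's monthly exit mass (incl. all-cause death) must be <= 1."""
        m = {n: self.by_model_age(n) for n in PARAM_NAMES}
        mdo = lifetable.monthly_q_model_ages()
        exits = {
            "Healthy": m["p_adenoma_onset"] + mdo,
            "AdenomaLR": m["p_LR_to_HR"] + mdo,
            "AdenomaHR": m["p_HR_to_preclin"] + mdo,
            "PreclinLocal": m["p_detect_local"] + m["p_local_to_regional"] + mdo,
            "PreclinRegional": m["p_detect_regional"] + m["p_regional_to_distant"] + mdo,
            "PreclinDistant": m["p_detect_distant"] + mdo,
        }
        for state, total in exits.items():
            if np.any(total > 1.0 + 1e-12):
                age = int(np.argmax(total > 1.0)) + ENTRY_AGE_YEARS
                raise ValueError(f"exit probabilities for {state} exceed 1 at age {age}")

    # -- flat-vector view used by calibration ---------------------------------
    def to_vector(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = names or PARAM_NAMES
        return np.concatenate([self.values[n] for n in names])

    def with_vector(self, vec: np.ndarray, names: Sequence[str] | None = None):
        names = names or PARAM_NAMES
        values = {n: v.copy() for n, v in self.values.items()}
        i = 0
        for n in names:
            k = len(values[n])
            values[n] = np.asarray(vec[i : i + k], dtype=float)
            i += k
        if i != len(vec):
            raise ValueError("vector length mismatch")
        return NaturalHistoryParams(values=values, edges={n: e.copy() for n, e in self.edges.items()})

    def copy(self) -> "NaturalHistoryParams":
        return NaturalHistoryParams(
            values={n: v.copy() for n, v in self.values.items()},
            edges={n: e.copy() for n, e in self.edges.items()},
        )

    # -- CSV round trip --------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in PARAM_NAMES:
            e, v = self.edges[name], self.values[name]
            for i, p in enumerate(v):
                rows.append(
                    {
                        "parameter": name,
                        "age_band_start": int(e[i]),
                        "age_band_end": int(e[i + 1]),
                        "monthly_probability": float(p),
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NaturalHistoryParams":
        values, edges = {}, {}
        for name, g in df.groupby("parameter", sort=False):
            g = g.sort_values("age_band_start")
            values[name] = g["monthly_probability"].to_numpy(float)
            edges[name] = np.r_[g["age_band_start"].to_numpy(int), int(g["age_band_end"].iloc[-1])]
        return cls(values=values, edges=edges)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "NaturalHistoryParams":
        return cls.from_frame(pd.read_csv(path, comment="#", float_precision="round_trip"))
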