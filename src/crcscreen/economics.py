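"""Costing and DALY accounting over simulated cohort traces.

Costs are taken from the healthcare-payer perspective: screening tests,
follow-up/diagnostic/surveillance colonoscopies, complication episodes, and a
stage-specific treatment bundle charged once at diagnosis.  Health burden is
expressed in discounted life years (DLY) and years lived with disability
(YLD); the effect of a strategy against a reference is

    DALYs averted = (DLY_S - DLY_ref) + (YLD_ref - YLD_S),

i.e. life years gained plus disability avoided, which is antisymmetric in the
two traces and needs no external life-expectancy standard.

Discounting uses 3% per annum applied at monthly resolution,
``(1 + r)^(-t/12)`` with t in months from model entry at age 20.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .natural_history import (
    CANCER_MORTALITY_WINDOW_MONTHS,
    ENTRY_AGE_MONTHS,
    HORIZON_AGE_MONTHS,
    CohortTrace,
)
from .states import STAGE_NAMES, Event, Modality, TestReason

COST_KEYS = (
    "test_colonoscopy",
    "test_sigmoidoscopy",
    "test_fit",
    "test_fobt",
    "colonoscopy_followup",
    "colonoscopy_surveillance",
    "colonoscopy_diagnostic",
    "complication",
    "treat_local",
    "treat_regional",
    "treat_distant",
)


@dataclass
class CurrencySpec:
    """Dominican peso to 2024 USD conversion."""

    dop_to_usd: float = 0.017
    inflation_factor: float = 1.0

    def __post_init__(self):
        if self.dop_to_usd <= 0 or self.inflation_factor <= 0:
            raise ValueError("currency factors must be positive")


def convert_currency(amount_dop: float, spec: CurrencySpec) -> float:
    """DOP to inflation-adjusted 2024 USD."""
    amount = np.asarray(amount_dop, dtype=float)
    if np.any(amount < 0):
        raise ValueError("negative amount")
    out = amount * spec.dop_to_usd * spec.inflation_factor
    return float(out) if np.isscalar(amount_dop) else out


@dataclass
class DiscountSpec:
    annual_rate: float = 0.03

    def __post_init__(self):
        if self.annual_rate < 0:
            raise ValueError("discount rate must be >= 0")

    def factor(self, t_months):
        t = np.asarray(t_months, dtype=float)
        if np.any(t < 0):
            raise ValueError("negative time")
        return (1.0 + self.annual_rate) ** (-t / 12.0)

    def monthly_factor(self) -> float:
        return (1.0 + self.annual_rate) ** (-1.0 / 12.0)


def discount(value, t_months, spec: DiscountSpec):
    """Present value of `value` accruing `t_months` after model entry."""
    return value * spec.factor(t_months)


def _geom_sum(delta: float, start: np.ndarray, length: np.ndarray) -> np.ndarray:
    """sum_{t=start}^{start+length-1} delta^t, vectorized, delta in (0, 1]."""
    length = np.maximum(length, 0)
    if delta == 1.0:
        return length.astype(float)
    return delta**start * (1.0 - delta**length) / (1.0 - delta)


@dataclass
class CostTable:
    """Unit costs in 2024 USD keyed by the event kinds the model prices."""

    values: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [k for k in COST_KEYS if k not in self.values]
        if missing:
            raise ValueError(f"cost table missing entries: {missing}")
        for k, v in self.values.items():
            if v < 0:
                raise ValueError(f"negative cost for {k}")

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def scaled(self, factor: float) -> "CostTable":
        return CostTable({k: v * factor for k, v in self.values.items()})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"item": k, "currency": "USD", "amount": v} for k, v in self.values.items()]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path, currency: CurrencySpec | None = None) -> "CostTable":
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        values = {}
        for _, r in df.iterrows():
            amount = float(r["amount"])
            if str(r.get("currency", "USD")).upper() == "DOP":
                amount = convert_currency(amount, currency or CurrencySpec())
            values[r["item"]] = amount
        return cls(values)


@dataclass
class DisabilityWeights:
    """Episode and health-state disability weights.

    Episode weights (endoscopy, complication, initial treatment) apply for a
    fixed number of days at the event; the living-with-cancer weight
    (1 - stage utility) applies for 120 months after diagnosis or until death.
    """

    endoscopy: float = 0.01
    endoscopy_days: float = 2.0
    complication: float = 0.2
    complication_days: float = 14.0
    treatment: float = 0.29
    treatment_days: float = 180.0
    cancer: dict = field(default_factory=lambda: {"local": 0.12, "regional": 0.23, "distant": 0.40})

    def __post_init__(self):
        for w in (self.endoscopy, self.complication, self.treatment, *self.cancer.values()):
            if not 0.0 <= w <= 1.0:
                raise ValueError("disability weight outside [0, 1]")
        missing = [s for s in STAGE_NAMES if s not in self.cancer]
        if missing:
            raise ValueError(f"missing cancer weights: {missing}")

    def cancer_by_stage(self) -> np.ndarray:
        return np.array([self.cancer[s] for s in STAGE_NAMES])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"item": "endoscopy", "weight": self.endoscopy, "duration_days": self.endoscopy_days},
            {
                "item": "complication",
                "weight": self.complication,
                "duration_days": self.complication_days,
            },
            {"item": "treatment", "weight": self.treatment, "duration_days": self.treatment_days},
        ]
        for s in STAGE_NAMES:
            rows.append({"item": f"cancer_{s}", "weight": self.cancer[s], "duration_days": np.nan})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DisabilityWeights":
        d = {r["item"]: r for _, r in df.iterrows()}
        return cls(
            endoscopy=float(d["endoscopy"]["weight"]),
            endoscopy_days=float(d["endoscopy"]["duration_days"]),
            complication=float(d["complication"]["weight"]),
            complication_days=float(d["complication"]["duration_days"]),
            treatment=float(d["treatment"]["weight"]),
            treatment_days=float(d["treatment"]["duration_days"]),
            cancer={s: float(d[f"cancer_{s}"]["weight"]) for s in STAGE_NAMES},
        )


_TEST_COST_KEY = {
    (int(Modality.COLONOSCOPY), int(TestReason.SCREEN)): "test_colonoscopy",
    (int(Modality.COLONOSCOPY), int(TestReason.FOLLOWUP)): "colonoscopy_followup",
    (int(Modality.COLONOSCOPY), int(TestReason.SURVEILLANCE)): "colonoscopy_surveillance",
    (int(Modality.COLONOSCOPY), int(TestReason.DIAGNOSTIC)): "colonoscopy_diagnostic",
    (int(Modality.SIGMOIDOSCOPY), int(TestReason.SCREEN)): "test_sigmoidoscopy",
    (int(Modality.FIT), int(TestReason.SCREEN)): "test_fit",
    (int(Modality.FOBT), int(TestReason.SCREEN)): "test_fobt",
}


def accrue_costs(trace: CohortTrace, costs: CostTable, disc: DiscountSpec) -> np.ndarray:
    """Discounted lifetime cost per person (USD); mean is the reported figure.

    Raises ``KeyError``-style configuration errors when an event kind in the
    trace has no price.
    """
    ev = trace.events
    price = np.zeros(len(ev))
    event = ev["event"].to_numpy()
    is_test = event == int(Event.TEST)
    if is_test.any():
        lut = np.full(16, np.nan)
        for (m, r), key in _TEST_COST_KEY.items():
            lut[m * 4 + r] = costs[key]
        mod = ev["modality"].to_numpy()[is_test].astype(int)
        rsn = ev["reason"].to_numpy()[is_test].astype(int)
        p = lut[mod * 4 + rsn]
        if np.any(np.isnan(p)):
            bad = np.flatnonzero(np.isnan(p))[0]
            raise ValueError(f"unpriced test event: modality={mod[bad]} reason={rsn[bad]}")
        price[is_test] = p
    price[event == int(Event.COMPLICATION)] = costs["complication"]
    treat = np.array([costs[f"treat_{s}"] for s in STAGE_NAMES])
    for dx_kind in (Event.SYMPTOMATIC_DX, Event.SCREEN_DX):
        m = event == int(dx_kind)
        if m.any():
            price[m] = treat[ev["stage"].to_numpy()[m]]
    t = ev["age_months"].to_numpy() - ENTRY_AGE_MONTHS
    disc_price = price * disc.factor(t)
    return np.bincount(ev["person_id"].to_numpy(), weights=disc_price, minlength=trace.n)


@dataclass
class DalyAccrual:
    """Per-person discounted life years and years lived with disability."""

    dly: np.ndarray
    yld: np.ndarray

    def dalys_averted_vs(self, ref: "DalyAccrual") -> np.ndarray:
        return (self.dly - ref.dly) + (ref.yld - self.yld)


def accrue_dalys(trace: CohortTrace, weights: DisabilityWeights, disc: DiscountSpec) -> DalyAccrual:
    """Discounted life years and disability-weighted years per person.

    Life years accrue 1/12 per alive month; the living-with-cancer weight
    applies for the first 120 months after diagnosis; episode weights
    (endoscopy, complication, treatment period) are lumped at the event month.
    """
    delta = disc.monthly_factor()
    months_alive = np.where(
        trace.death_month >= 0, trace.death_month, HORIZON_AGE_MONTHS
    ) - ENTRY_AGE_MONTHS
    dly = _geom_sum(delta, np.zeros(trace.n), months_alive) / 12.0

    yld = np.zeros(trace.n)
    diagnosed = trace.dx_month >= 0
    if diagnosed.any():
        start = trace.dx_month[diagnosed] - ENTRY_AGE_MONTHS
        end = np.where(
            trace.death_month[diagnosed] >= 0, trace.death_month[diagnosed], HORIZON_AGE_MONTHS
        ) - ENTRY_AGE_MONTHS
        length = np.minimum(end - start, CANCER_MORTALITY_WINDOW_MONTHS)
        w = weights.cancer_by_stage()[trace.dx_stage[diagnosed]]
        yld[diagnosed] += w * _geom_sum(delta, start, length) / 12.0
        # initial-treatment episode at diagnosis
        yld[diagnosed] += (
            weights.treatment * weights.treatment_days / 365.25 * disc.factor(start)
        )

    ev = trace.events
    event = ev["event"].to_numpy()
    t = ev["age_months"].to_numpy() - ENTRY_AGE_MONTHS
    pid = ev["person_id"].to_numpy()
    endo = (event == int(Event.TEST)) & (
        np.isin(ev["modality"].to_numpy(), (int(Modality.COLONOSCOPY), int(Modality.SIGMOIDOSCOPY)))
    )
    burden = np.zeros(len(ev))
    burden[endo] = weights.endoscopy * weights.endoscopy_days / 365.25
    comp = event == int(Event.COMPLICATION)
    burden[comp] = weights.complication * weights.complication_days / 365.25
    yld += np.bincount(pid, weights=burden * disc.factor(t), minlength=trace.n)
    return DalyAccrual(dly=dly, yld=yld)


def mean_life_expectancy_years(trace: CohortTrace) -> float:
    """Mean age at death in years (alive at horizon counted at 100)."""
    death = np.where(trace.death_month >= 0, trace.death_month, HORIZON_AGE_MONTHS)
    return float(death.mean() / 12.0)
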