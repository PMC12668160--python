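"""Cost-effectiveness aggregation: ICERs, dominance, frontier, WTP decision.

Strategies are characterized by mean discounted per-person cost and mean
DALYs averted against the no-screening reference.  The efficiency frontier is
found by cost-ordering, removing strictly dominated strategies (at least as
costly and no more effective than some alternative, one comparison strict),
then iteratively removing extended dominance until the frontier's ICERs are
strictly increasing.  The decision rule picks the most effective frontier
strategy whose ICER against its frontier predecessor does not exceed the
willingness-to-pay threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .economics import (
    CostTable,
    DalyAccrual,
    DiscountSpec,
    DisabilityWeights,
    accrue_costs,
    accrue_dalys,
    mean_life_expectancy_years,
)
from .natural_history import CohortTrace

DEFAULT_WTP = 11_692.0  # USD per DALY averted (2024 GDP per capita)


@dataclass
class WtpThreshold:
    usd_per_daly: float = DEFAULT_WTP

    def __post_init__(self):
        if self.usd_per_daly <= 0:
            raise ValueError("WTP threshold must be positive")


@dataclass
class StrategyOutcome:
    """Per-strategy summary mirroring the headline results table."""

    name: str
    mean_cost: float
    dalys_averted: float  # vs the reference strategy
    life_expectancy: float
    crc_cases_per_100k: float
    crc_deaths_per_100k: float
    colonoscopies_per_1000: float
    sigmoidoscopies_per_1000: float = 0.0
    incidence_reduction: float = 0.0  # fraction vs reference
    mortality_reduction: float = 0.0


def icer(delta_cost: float, delta_effect: float) -> Optional[float]:
    """Incremental cost per DALY averted; ``None`` when the effect difference is 0."""
    if delta_effect == 0:
        return None
    return delta_cost / delta_effect


@dataclass
class FrontierEntry:
    name: str
    cost: float
    effect: float
    on_frontier: bool = False
    strictly_dominated: bool = False
    extendedly_dominated: bool = False
    icer: Optional[float] = None  # vs previous frontier strategy
    duplicate_of: Optional[str] = None


@dataclass
class FrontierResult:
    entries: list = field(default_factory=list)  # cost-ordered

    @property
    def frontier(self) -> list:
        return [e for e in self.entries if e.on_frontier]

    def entry(self, name: str) -> FrontierEntry:
        return next(e for e in self.entries if e.name == name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strategy": e.name,
                    "cost": e.cost,
                    "effect": e.effect,
                    "on_frontier": e.on_frontier,
                    "strictly_dominated": e.strictly_dominated,
                    "extendedly_dominated": e.extendedly_dominated,
                    "icer": e.icer,
                }
                for e in self.entries
            ]
        )


def find_frontier(outcomes: Sequence[StrategyOutcome]) -> FrontierResult:
    """Dominance analysis over (cost, effect) pairs.

    Ties in both cost and effect are flagged as duplicates rather than
    silently dropped; equal-ICER ties resolve toward the more effective
    strategy.
    """
    if not outcomes:
        raise ValueError("need at least one strategy outcome")
    names = [o.name for o in outcomes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names")
    entries = sorted(
        (FrontierEntry(o.name, o.mean_cost, o.dalys_averted) for o in outcomes),
        key=lambda e: (e.cost, e.effect),
    )
    for i, e in enumerate(entries):
        for other in entries:
            if other is e:
                continue
            if other.cost == e.cost and other.effect == e.effect:
                if e.duplicate_of is None and entries.index(other) < i:
                    e.duplicate_of = other.name
            if (
                other.cost <= e.cost
                and other.effect >= e.effect
                and (other.cost < e.cost or other.effect > e.effect)
            ):
                e.strictly_dominated = True
    cand = [e for e in entries if not e.strictly_dominated and e.duplicate_of is None]
    # iterative extended-dominance scan: ICERs along the frontier must increase
    while True:
        removed = False
        for i in range(1, len(cand) - 1):
            # survivors are strictly increasing in both cost and effect
            icer_prev = (cand[i].cost - cand[i - 1].cost) / (cand[i].effect - cand[i - 1].effect)
            icer_next = (cand[i + 1].cost - cand[i].cost) / (cand[i + 1].effect - cand[i].effect)
            if icer_next <= icer_prev:
                cand[i].extendedly_dominated = True
                cand.pop(i)
                removed = True
                break
        if not removed:
            break
    for i, e in enumerate(cand):
        e.on_frontier = True
        if i > 0:
            e.icer = icer(e.cost - cand[i - 1].cost, e.effect - cand[i - 1].effect)
    return FrontierResult(entries=entries)


def decide(frontier: FrontierResult, wtp: WtpThreshold) -> str:
    """Optimal strategy: most effective frontier member with ICER <= WTP."""
    front = frontier.frontier
    if not front:
        raise ValueError("empty frontier")
    best = front[0]
    for e in front[1:]:
        if e.icer is not None and e.icer <= wtp.usd_per_daly:
            best = e
    return best.name


def summarize_strategy(
    name: str,
    trace: CohortTrace,
    costs: CostTable,
    weights: DisabilityWeights,
    disc: DiscountSpec,
    reference_trace: CohortTrace,
    reference_daly: DalyAccrual | None = None,
) -> StrategyOutcome:
    """Fill a :class:`StrategyOutcome` from a trace and its reference.

    Requires common cohort sizes (the traces are meant to share seeds for
    common random numbers).
    """
    if trace.n != reference_trace.n:
        raise ValueError("trace and reference cohort sizes differ")
    daly = accrue_dalys(trace, weights, disc)
    ref = reference_daly if reference_daly is not None else accrue_dalys(
        reference_trace, weights, disc
    )
    cases = float((trace.dx_month >= 0).sum())
    deaths = float((trace.death_cause == 0).sum())
    ref_cases = float((reference_trace.dx_month >= 0).sum())
    ref_deaths = float((reference_trace.death_cause == 0).sum())
    ev = trace.events
    n_sig = int(((ev["event"] == 4) & (ev["modality"] == 1)).sum())
    return StrategyOutcome(
        name=name,
        mean_cost=float(accrue_costs(trace, costs, disc).mean()),
        dalys_averted=float(daly.dalys_averted_vs(ref).mean()),
        life_expectancy=mean_life_expectancy_years(trace),
        crc_cases_per_100k=cases / trace.n * 1e5,
        crc_deaths_per_100k=deaths / trace.n * 1e5,
        colonoscopies_per_1000=trace.n_colonoscopies() / trace.n * 1e3,
        sigmoidoscopies_per_1000=n_sig / trace.n * 1e3,
        incidence_reduction=(1.0 - cases / ref_cases) if ref_cases else 0.0,
        mortality_reduction=(1.0 - deaths / ref_deaths) if ref_deaths else 0.0,
    )


def cea_table(outcomes: Sequence[StrategyOutcome], wtp: WtpThreshold | None = None) -> pd.DataFrame:
    """Headline CEA table with both cumulative and incremental columns."""
    wtp = wtp or WtpThreshold()
    fr = find_frontier(outcomes)
    rows = []
    by_name = {o.name: o for o in outcomes}
    prev_front = None
    for e in fr.entries:
        o = by_name[e.name]
        incr_cost = e.cost - prev_front.cost if prev_front is not None else np.nan
        incr_eff = e.effect - prev_front.effect if prev_front is not None else np.nan
        if e.strictly_dominated or e.extendedly_dominated:
            icer_str = "Dominated"
        elif e.icer is not None:
            icer_str = f"{e.icer:.2f}"
        else:
            icer_str = "-"
        rows.append(
            {
                "strategy": e.name,
                "cost": e.cost,
                "incremental_cost": incr_cost,
                "life_expectancy": o.life_expectancy,
                "dalys_averted_vs_ref": e.effect,
                "incremental_dalys": incr_eff,
                "icer": icer_str,
                "crc_cases_per_100k": o.crc_cases_per_100k,
                "incidence_reduction_pct": o.incidence_reduction * 100,
                "crc_deaths_per_100k": o.crc_deaths_per_100k,
                "mortality_reduction_pct": o.mortality_reduction * 100,
                "colonoscopies_per_1000": o.colonoscopies_per_1000,
                "on_frontier": e.on_frontier,
            }
        )
        if e.on_frontier:
            prev_front = e
    df = pd.DataFrame(rows)
    df.attrs["optimal"] = decide(fr, wtp)
    return df
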