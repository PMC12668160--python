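"""Bundled model inputs and the strategy-evaluation loop.

:class:`ModelInputs` carries everything one simulation run needs; dotted
parameter paths (``"costs.test_fit"``, ``"tests.fit.specificity"``,
``"weights.cancer.local"``) address individual scalars for the sensitivity
analyses.  All strategies are evaluated under common random numbers: the
cohort seed is shared, and screening draws live on random streams separate
from the disease process.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .cea import StrategyOutcome, WtpThreshold, summarize_strategy
from .economics import CostTable, DiscountSpec, DisabilityWeights, accrue_dalys
from .natural_history import CohortConfig, CohortTrace, simulate_cohort
from .screening import StrategySpec, TestCharacteristics
from .tables import Lifetable, NaturalHistoryParams, StageSurvival

NH_NAME = "NH"


@dataclass
class ModelInputs:
    """Everything a cost-effectiveness run consumes."""

    params: NaturalHistoryParams
    lifetable: Lifetable
    survival: StageSurvival
    costs: CostTable
    tests: Dict[str, TestCharacteristics]
    weights: DisabilityWeights
    strategies: Dict[str, StrategySpec]
    cohort: CohortConfig = field(default_factory=CohortConfig)
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    wtp: WtpThreshold = field(default_factory=WtpThreshold)

    def copy(self) -> "ModelInputs":
        return copy.deepcopy(self)

    # -- dotted-path access for DSA/PSA ---------------------------------------
    def _resolve(self, path: str):
        parts = path.split(".")
        obj = self
        for p in parts[:-1]:
            if isinstance(obj, dict):
                obj = obj[p]
            elif hasattr(obj, "values") and isinstance(getattr(obj, "values"), dict) and p in obj.values:
                obj = obj.values  # CostTable-style wrapper
            else:
                obj = getattr(obj, p)
        return obj, parts[-1]

    def get_param(self, path: str) -> float:
        obj, leaf = self._resolve(path)
        if isinstance(obj, dict):
            return float(obj[leaf])
        return float(getattr(obj, leaf))

    def set_param(self, path: str, value: float) -> None:
        obj, leaf = self._resolve(path)
        if isinstance(obj, dict):
            if leaf not in obj:
                raise KeyError(f"unknown parameter path {path!r}")
            obj[leaf] = float(value)
        else:
            if not hasattr(obj, leaf):
                raise KeyError(f"unknown parameter path {path!r}")
            setattr(obj, leaf, float(value))


def simulate_all(
    inputs: ModelInputs, strategy_names: Optional[Sequence[str]] = None
) -> Dict[str, CohortTrace]:
    """Simulate NH plus the requested strategies under one cohort seed."""
    names = list(strategy_names) if strategy_names is not None else list(inputs.strategies)
    traces = {
        NH_NAME: simulate_cohort(
            inputs.cohort, inputs.params, inputs.lifetable, inputs.survival, tests=inputs.tests
        )
    }
    for name in names:
        if name == NH_NAME:
            continue
        traces[name] = simulate_cohort(
            inputs.cohort,
            inputs.params,
            inputs.lifetable,
            inputs.survival,
            strategy=inputs.strategies[name],
            tests=inputs.tests,
        )
    return traces


def evaluate_strategies(
    inputs: ModelInputs,
    strategy_names: Optional[Sequence[str]] = None,
    traces: Optional[Dict[str, CohortTrace]] = None,
) -> Dict[str, StrategyOutcome]:
    """Outcomes for NH and each strategy, with DALYs averted vs NH."""
    traces = traces if traces is not None else simulate_all(inputs, strategy_names)
    ref = traces[NH_NAME]
    ref_daly = accrue_dalys(ref, inputs.weights, inputs.discount)
    out = {}
    for name, tr in traces.items():
        out[name] = summarize_strategy(
            name, tr, inputs.costs, inputs.weights, inputs.discount, ref, reference_daly=ref_daly
        )
    return out
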