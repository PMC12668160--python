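"""Deterministic, probabilistic, and scenario sensitivity analyses.

One-way DSA moves a single parameter to its low/high bound and re-computes
the ICER of a strategy pair under common random numbers (tornado diagram).
The PSA samples costs from Gamma and probabilities/disability weights from
Beta distributions (method of moments), evaluates every strategy per draw
with the same cohort seed, and summarizes optimality by highest net monetary
benefit over a WTP grid (the cost-effectiveness acceptability curve).
Scenario analyses cover start/stop ages, adherence assumptions, halved and
doubled incidence (onset probabilities re-solved by bisection), an
alternative stage mix (detection parameters re-calibrated against it), and
the FIT-to-colonoscopy switch policy.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import AnnealSchedule, CalibrationTargets, anneal
from .cea import cea_table, icer
from .economics import accrue_costs, accrue_dalys
from .natural_history import nh_forward_summary
from .pipeline import NH_NAME, ModelInputs, evaluate_strategies, simulate_all
from .screening import fit_colo_switch_strategy


@dataclass
class DsaRange:
    """One-way range for a dotted parameter path."""

    path: str
    low: float
    high: float

    def validate(self, base: float) -> None:
        if not self.low <= base <= self.high:
            raise ValueError(
                f"DSA range for {self.path}: low {self.low} <= base {base} <= high {self.high} violated"
            )


def _pair_icer(inputs: ModelInputs, reference: str, comparator: str):
    names = [n for n in (reference, comparator) if n != NH_NAME]
    traces = simulate_all(inputs, names)
    ref_tr, cmp_tr = traces[reference], traces[comparator]
    d_ref = accrue_dalys(ref_tr, inputs.weights, inputs.discount)
    d_cmp = accrue_dalys(cmp_tr, inputs.weights, inputs.discount)
    d_cost = float(
        accrue_costs(cmp_tr, inputs.costs, inputs.discount).mean()
        - accrue_costs(ref_tr, inputs.costs, inputs.discount).mean()
    )
    d_eff = float(d_cmp.dalys_averted_vs(d_ref).mean())
    return icer(d_cost, d_eff)


def one_way_dsa(
    inputs: ModelInputs,
    ranges: Sequence[DsaRange],
    comparison: tuple = (NH_NAME, "FIT"),
) -> pd.DataFrame:
    """Tornado table for the comparison pair, widest bars first.

    All ranges are validated before any simulation runs; every run reuses
    the base cohort seed (common random numbers).
    """
    for r in ranges:
        r.validate(inputs.get_param(r.path))
    reference, comparator = comparison
    rows = []
    for r in ranges:
        base = inputs.get_param(r.path)
        icers = {}
        for which, value in (("low", r.low), ("high", r.high)):
            work = inputs.copy()
            work.set_param(r.path, value)
            icers[which] = _pair_icer(work, reference, comparator)
        lo, hi = icers["low"], icers["high"]
        width = abs(hi - lo) if lo is not None and hi is not None else np.nan
        rows.append(
            {
                "parameter": r.path,
                "base": base,
                "low": r.low,
                "high": r.high,
                "icer_low": lo,
                "icer_high": hi,
                "bar_width": width,
            }
        )
    df = pd.DataFrame(rows).sort_values("bar_width", ascending=False, kind="stable")
    return df.reset_index(drop=True)


@dataclass
class ParamDistribution:
    """PSA sampling distribution for one parameter path.

    Gamma for costs (non-negative), Beta for probabilities and disability
    weights; parameters by method of moments from (mean, se).
    """

    path: str
    family: str  # gamma | beta
    mean: float
    se: float

    def __post_init__(self):
        if self.family not in ("gamma", "beta"):
            raise ValueError("family must be gamma or beta")
        if self.family == "gamma" and self.mean < 0:
            raise ValueError("gamma requires a non-negative mean")
        if self.family == "beta" and not 0.0 < self.mean < 1.0:
            raise ValueError("beta requires a mean strictly inside (0, 1)")
        if self.se < 0:
            raise ValueError("se must be >= 0")


def fit_distribution(dist: ParamDistribution) -> Callable[[np.random.Generator], float]:
    """Method-of-moments sampler; degenerate at the mean when se == 0."""
    if dist.se == 0.0 or dist.mean == 0.0:
        return lambda rng: dist.mean
    if dist.family == "gamma":
        shape = dist.mean**2 / dist.se**2
        scale = dist.se**2 / dist.mean
        return lambda rng: float(rng.gamma(shape, scale))
    var = dist.se**2
    bound = dist.mean * (1.0 - dist.mean)
    if var >= bound:
        raise ValueError(
            f"beta mean/se infeasible for {dist.path}: se must be < {math.sqrt(bound):.4g}"
        )
    nu = bound / var - 1.0
    a, b = dist.mean * nu, (1.0 - dist.mean) * nu
    return lambda rng: float(rng.beta(a, b))


def default_psa_distributions(inputs: ModelInputs, se_frac: float = 0.2) -> list:
    """Gamma on every unit cost, Beta on test characteristics and weights.

    Natural-history transition probabilities stay fixed at their calibrated
    values; the PSA propagates uncertainty in costs, test performance, and
    disability weights only.
    """
    dists = []
    for key, value in inputs.costs.values.items():
        dists.append(ParamDistribution(f"costs.values.{key}", "gamma", value, se_frac * value))
    for tname, t in inputs.tests.items():
        for f in ("sens_adenoma_lr", "sens_adenoma_hr", "sens_crc", "specificity"):
            v = getattr(t, f)
            se = min(se_frac * v, 0.8 * math.sqrt(v * (1 - v)))
            dists.append(ParamDistribution(f"tests.{tname}.{f}", "beta", v, se))
    w = inputs.weights
    for f in ("endoscopy", "complication", "treatment"):
        v = getattr(w, f)
        dists.append(ParamDistribution(f"weights.{f}", "beta", v, se_frac * v))
    for stage, v in w.cancer.items():
        dists.append(ParamDistribution(f"weights.cancer.{stage}", "beta", v, se_frac * v))
    return dists


@dataclass
class PsaResult:
    iterations: pd.DataFrame  # iteration, strategy, cost, effect
    ceac: pd.DataFrame  # wtp x strategy -> fraction optimal
    base_wtp_fraction: Dict[str, float]
    n_redraws: int = 0


def run_psa(
    inputs: ModelInputs,
    distributions: Sequence[ParamDistribution],
    n_iter: int,
    wtp_grid: Sequence[float],
    seed: int,
) -> PsaResult:
    """Probabilistic sensitivity analysis with common cohort random numbers.

    Each iteration draws one joint parameter set.  The cohort stream is held
    fixed across iterations and strategies so that recorded differences
    reflect parameter uncertainty only; iterations whose sampled test
    characteristics match the base case reuse the base traces.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    samplers = [(d.path, fit_distribution(d)) for d in distributions]
    base_tests_state = {
        name: tuple(
            getattr(t, f)
            for f in ("sens_adenoma_lr", "sens_adenoma_hr", "sens_crc", "specificity", "complication_prob")
        )
        for name, t in inputs.tests.items()
    }
    base_traces = None
    records = []
    strategies = [NH_NAME] + list(inputs.strategies)
    for i in range(n_iter):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11, i]))
        work = inputs.copy()
        for path, sampler in samplers:
            work.set_param(path, sampler(rng))
        tests_state = {
            name: tuple(
                getattr(t, f)
                for f in ("sens_adenoma_lr", "sens_adenoma_hr", "sens_crc", "specificity", "complication_prob")
            )
            for name, t in work.tests.items()
        }
        if tests_state == base_tests_state:
            if base_traces is None:
                base_traces = simulate_all(inputs)
            traces = base_traces
        else:
            traces = simulate_all(work)
        outcomes = evaluate_strategies(work, traces=traces)
        for name in strategies:
            o = outcomes[name]
            records.append(
                {"iteration": i, "strategy": name, "cost": o.mean_cost, "effect": o.dalys_averted}
            )
    iters = pd.DataFrame(records)
    wide_cost = iters.pivot(index="iteration", columns="strategy", values="cost")
    wide_eff = iters.pivot(index="iteration", columns="strategy", values="effect")
    ceac_rows = []
    for wtp in wtp_grid:
        nmb = wide_eff * wtp - wide_cost
        winners = nmb.idxmax(axis=1)
        frac = winners.value_counts(normalize=True)
        ceac_rows.append({"wtp": wtp, **{s: float(frac.get(s, 0.0)) for s in strategies}})
    ceac = pd.DataFrame(ceac_rows)
    base_wtp = inputs.wtp.usd_per_daly
    nmb = wide_eff * base_wtp - wide_cost
    frac = nmb.idxmax(axis=1).value_counts(normalize=True)
    return PsaResult(
        iterations=iters,
        ceac=ceac,
        base_wtp_fraction={s: float(frac.get(s, 0.0)) for s in strategies},
    )


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass
class ScenarioSpec:
    """Named base-case overrides for a scenario analysis."""

    name: str
    start_age: Optional[int] = None
    stop_age: Optional[int] = None
    surveillance_stop_age: Optional[int] = None
    adherence: Optional[float] = None
    followup_adherence: Optional[float] = None
    incidence_scale: Optional[float] = None  # 0.5 or 2.0
    stage_mix: Optional[np.ndarray] = None  # alternative 3-vector target
    fit_colo_switch: bool = False


def solve_onset_scale(
    inputs: ModelInputs, scale: float, tol: float = 0.01, max_bisect: int = 60
) -> float:
    """Onset multiplier so lifetime NH incidence hits ``scale`` x base.

    Bisection on the deterministic forward model; raises after
    ``max_bisect`` iterations without convergence.
    """
    base = nh_forward_summary(inputs.params, inputs.lifetable).lifetime_incidence
    target = scale * base

    def lifetime(mult: float) -> float:
        p = inputs.params.copy()
        p.values["p_adenoma_onset"] = np.clip(p.values["p_adenoma_onset"] * mult, 0, 1)
        return nh_forward_summary(p, inputs.lifetable).lifetime_incidence

    lo, hi = (0.01, 1.0) if scale < 1 else (1.0, 50.0)
    for _ in range(max_bisect):
        mid = 0.5 * (lo + hi)
        val = lifetime(mid)
        if abs(val - target) / target <= tol:
            return mid
        if val < target:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(f"onset-scale bisection did not converge for scale {scale}")


def recalibrate_stage_mix(inputs: ModelInputs, stage_mix: np.ndarray, seed: int = 0) -> ModelInputs:
    """Re-fit the detection probabilities against an alternative stage mix."""
    fwd = lambda p: nh_forward_summary(p, inputs.lifetable)  # noqa: E731
    s = fwd(inputs.params)
    targets = CalibrationTargets(stage=(np.asarray(stage_mix, dtype=float), 1.0))
    detect = ("p_detect_local", "p_detect_regional", "p_detect_distant")
    schedule = AnnealSchedule(max_iter=800, seed=seed, step=0.1, cooling=0.85, iters_per_temp=40)
    res = anneal(targets, schedule, inputs.params, stage_masks=[(detect, ("stage",))], forward=fwd)
    out = inputs.copy()
    out.params = res.best_params
    return out


def apply_scenario(inputs: ModelInputs, spec: ScenarioSpec) -> ModelInputs:
    work = inputs.copy()
    if spec.incidence_scale is not None:
        mult = solve_onset_scale(work, spec.incidence_scale)
        work.params.values["p_adenoma_onset"] = np.clip(
            work.params.values["p_adenoma_onset"] * mult, 0, 1
        )
    if spec.stage_mix is not None:
        work = recalibrate_stage_mix(work, spec.stage_mix)
    for name, strat in work.strategies.items():
        if spec.start_age is not None:
            for p in strat.phases:
                if p.start_age_years == 45:
                    p.start_age_years = spec.start_age
        if spec.stop_age is not None:
            for p in strat.phases:
                p.stop_age_years = spec.stop_age
        if spec.surveillance_stop_age is not None:
            strat.surveillance.stop_age_years = spec.surveillance_stop_age
        if spec.adherence is not None:
            strat.adherence = spec.adherence
        if spec.followup_adherence is not None:
            strat.followup_adherence = spec.followup_adherence
    if spec.fit_colo_switch:
        base_fit = work.strategies.get("FIT")
        kwargs = {}
        if base_fit is not None:
            kwargs = dict(
                adherence=base_fit.adherence,
                followup_adherence=base_fit.followup_adherence,
                surveillance=base_fit.surveillance,
            )
        switch = fit_colo_switch_strategy(**kwargs)
        work.strategies[switch.name] = switch
    return work


def run_scenarios(inputs: ModelInputs, scenarios: Sequence[ScenarioSpec]) -> Dict[str, pd.DataFrame]:
    """CEA table per scenario; an empty list yields the base case only."""
    results = {"base": cea_table(list(evaluate_strategies(inputs).values()), inputs.wtp)}
    for spec in scenarios:
        work = apply_scenario(inputs, spec)
        results[spec.name] = cea_table(list(evaluate_strategies(work).values()), work.wtp)
    return results


def adherence_grid(
    inputs: ModelInputs,
    strategy_name: str,
    first_line: Sequence[float],
    followup: Sequence[float],
) -> pd.DataFrame:
    """Incidence/mortality reduction surface over adherence pairs."""
    rows = []
    for a in first_line:
        for fa in followup:
            work = inputs.copy()
            strat = work.strategies[strategy_name]
            strat.adherence = a
            strat.followup_adherence = fa
            outcomes = evaluate_strategies(work, strategy_names=[strategy_name])
            o = outcomes[strategy_name]
            rows.append(
                {
                    "strategy": strategy_name,
                    "adherence": a,
                    "followup_adherence": fa,
                    "incidence_reduction": o.incidence_reduction,
                    "mortality_reduction": o.mortality_reduction,
                }
            )
    return pd.DataFrame(rows)
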