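"""Synthetic fixture generation: every input the pipeline needs, no downloads.

The generators emulate the *statistical structure* of the real inputs — a
Gompertz–Makeham lifetable, stage survival ordered distant ≥ regional ≥
local, natural-history parameters whose forward model produces age-rising
CRC incidence (reaching hundreds per 100k person-years at old age), adenoma
prevalence rising to roughly a third by age 70, and a late-stage-skewed
stage mix for the "DR-like" variant (an earlier-stage mix for "SEER8-like").
All numeric values are documented placeholders with the field's ordinal
relationships (colonoscopy most sensitive, FIT dominating FOBT, stool tests
cheapest, distant-stage treatment dearest), not measured quantities.

Calibration targets are generated *from* the truth parameters through the
same forward operator calibration uses, so the truth scores an exact zero —
the basis of the parameter-recovery harness.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationTargets
from .economics import CostTable, DisabilityWeights
from .natural_history import nh_forward_summary
from .screening import (
    StrategySpec,
    SurveillanceSchedule,
    TestCharacteristics,
    single_phase_strategy,
    test_characteristics_frame,
    test_characteristics_from_frame,
)
from .tables import Lifetable, NaturalHistoryParams, StageSurvival

VARIANTS = ("dr", "seer8")

INCIDENCE_BANDS = tuple((lo, lo + 5) for lo in range(40, 95, 5))
PREVALENCE_AGES = (30, 40, 50, 60, 70, 80)


def _rng(seed: int, *salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *salt]))


def make_lifetable(level: str = "mid", seed: int = 0) -> Lifetable:
    """Gompertz–Makeham lifetable; ``level`` scales overall mortality.

    The "zero" level returns an all-zero table (useful for conservation
    tests).  The "mid" level yields a life expectancy at 20 in [50, 65] y.
    """
    if level == "zero":
        return Lifetable(np.zeros(101))
    mult = {"low": 0.7, "mid": 1.0, "high": 1.4}[level]
    r = _rng(seed, 1)
    makeham = 8e-4 * mult * r.uniform(0.9, 1.1)
    gomp_a = 2.2e-5 * mult * r.uniform(0.9, 1.1)
    gomp_b = 0.092 * r.uniform(0.99, 1.01)
    ages = np.arange(101)
    q = np.clip(makeham + gomp_a * np.exp(gomp_b * ages), 0.0, 1.0)
    q[100] = 1.0
    lt = Lifetable(q)
    if level == "mid":
        le = lt.life_expectancy_at(20)
        assert 50.0 <= le <= 65.0, f"mid lifetable out of envelope (LE20={le:.1f})"
    return lt


def make_stage_survival(seed: int = 0) -> StageSurvival:
    """Annual cancer mortality declining with time since diagnosis."""
    base = np.array(
        [
            [0.05, 0.04, 0.03, 0.025, 0.02, 0.018, 0.015, 0.012, 0.01, 0.01],
            [0.15, 0.12, 0.10, 0.08, 0.06, 0.05, 0.04, 0.035, 0.03, 0.03],
            [0.45, 0.35, 0.28, 0.22, 0.18, 0.15, 0.12, 0.10, 0.09, 0.08],
        ]
    )
    r = _rng(seed, 2)
    s = StageSurvival(np.clip(base * r.uniform(0.9, 1.1), 0.0, 1.0))
    s.validate_ordering()
    return s


_ONSET_EDGES = np.array([20, 30, 40, 50, 60, 70, 100])
_BASE_TRUTH = {
    "p_adenoma_onset": np.array([1.0e-4, 3.0e-4, 6.5e-4, 9.5e-4, 1.15e-3, 1.25e-3]),
    "p_LR_to_HR": np.array([1.0e-3]),
    "p_HR_to_preclin": np.array([1.6e-3]),
    "p_local_to_regional": np.array([3.5e-2]),
    "p_regional_to_distant": np.array([4.5e-2]),
    # DR-like: symptomatic detection slow at local stage -> late-stage mix
    "p_detect_local": np.array([6.0e-3]),
    "p_detect_regional": np.array([3.0e-2]),
    "p_detect_distant": np.array([3.0e-2]),
}
_SEER8_DETECT = {
    "p_detect_local": np.array([2.0e-2]),
    "p_detect_regional": np.array([4.5e-2]),
    "p_detect_distant": np.array([5.0e-2]),
}


def make_truth_params(variant: str = "dr", seed: int = 0) -> NaturalHistoryParams:
    """Jittered truth parameters for the chosen stage-mix variant."""
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    r = _rng(seed, 3)
    base = dict(_BASE_TRUTH)
    if variant == "seer8":
        base.update(_SEER8_DETECT)
    values = {k: np.clip(v * r.uniform(0.88, 1.12, size=len(v)), 0.0, 0.5) for k, v in base.items()}
    edges = {
        k: (_ONSET_EDGES.copy() if k == "p_adenoma_onset" else np.array([20, 100]))
        for k in values
    }
    return NaturalHistoryParams(values=values, edges=edges)


def make_truth_and_targets(seed: int = 0, variant: str = "dr", lifetable: Lifetable | None = None):
    """Truth parameters plus the calibration targets they generate.

    The targets are the forward operator's own outputs, so
    ``objective(truth, targets) == 0`` by construction.  The truth is
    checked against the generator envelopes (lifetime CRC incidence in
    [1.5%, 4%], adenoma prevalence by 70 in [25%, 45%], stage-mix skew per
    variant) and regeneration fails loudly if jitter ever leaves them.
    """
    lifetable = lifetable if lifetable is not None else make_lifetable("mid", seed)
    truth = make_truth_params(variant, seed)
    s = nh_forward_summary(truth, lifetable)
    li = s.lifetime_incidence
    prev70 = float(s.prevalence_at([70])[0])
    stage = s.stage_distribution()
    assert 0.015 <= li <= 0.04, f"lifetime incidence {li:.3f} out of envelope"
    assert 0.25 <= prev70 <= 0.45, f"prevalence at 70 {prev70:.3f} out of envelope"
    if variant == "dr":
        assert stage[1] + stage[2] >= 0.50 and stage[2] >= 0.30, f"stage mix {stage} not DR-like"
    else:
        assert stage[0] + stage[1] >= 0.55, f"stage mix {stage} not SEER8-like"
    edges = np.array([b[0] for b in INCIDENCE_BANDS] + [INCIDENCE_BANDS[-1][1]])
    inc = s.incidence_per_100k(edges)
    targets = CalibrationTargets(
        incidence=[(lo, hi, float(v), 1.0) for (lo, hi), v in zip(INCIDENCE_BANDS, inc)],
        prevalence=[(a, float(s.prevalence_at([a])[0]), 1.0) for a in PREVALENCE_AGES],
        stage=(stage, 3.0),
    )
    return truth, targets


def perturb_params(
    params: NaturalHistoryParams, rng: np.random.Generator, low: float = 0.5, high: float = 2.0
) -> NaturalHistoryParams:
    """Multiply every parameter by an independent U(low, high) factor."""
    values = {
        k: np.clip(v * rng.uniform(low, high, size=len(v)), 1e-8, 0.5)
        for k, v in params.values.items()
    }
    return NaturalHistoryParams(values=values, edges={k: e.copy() for k, e in params.edges.items()})


def run_parameter_recovery(
    seed: int,
    variant: str = "dr",
    max_iter: int = 800,
    low: float = 0.5,
    high: float = 2.0,
):
    """Parameter-recovery harness: anneal back to a known truth.

    Targets are generated from the truth, each calibrated parameter is
    multiplied by an independent U(low, high) factor, and the stepwise
    annealer is run.  Returns (truth, result, relative errors of the
    calibrated parameters).
    """
    from .calibration import CALIBRATED_PARAMS, DEFAULT_STAGES, AnnealSchedule, anneal

    lifetable = make_lifetable("mid", seed)
    truth, targets = make_truth_and_targets(seed, variant, lifetable)
    rng = _rng(seed, 7)
    tv = truth.to_vector(CALIBRATED_PARAMS)
    start = truth.with_vector(
        np.clip(tv * rng.uniform(low, high, size=len(tv)), 1e-8, 0.5), CALIBRATED_PARAMS
    )
    schedule = AnnealSchedule(
        max_iter=max_iter, seed=seed, step=0.08, cooling=0.85, iters_per_temp=50
    )
    # a hot coordinate-proposal anneal over the whole calibrated set, then a
    # long zero-temperature coordinate polish with mixed step sizes to walk
    # the curved, ill-conditioned valley near the optimum
    coarse = {"mode": "coordinate", "step": (0.2, 0.08), "max_iter": 4 * max_iter}
    polish = {
        "mode": "coordinate",
        "step": (0.08, 0.02, 0.006),
        "max_iter": 13 * max_iter,
        "initial_temp": 0.0,
    }
    joint = DEFAULT_STAGES[-1]
    stages = [(joint[0], joint[1], coarse), (joint[0], joint[1], polish)]
    result = anneal(
        targets,
        schedule,
        start,
        stage_masks=stages,
        forward=lambda p: nh_forward_summary(p, lifetable),
    )
    rel = np.abs(result.best_params.to_vector(CALIBRATED_PARAMS) - tv) / tv
    return truth, result, rel


def make_costs(seed: int = 0) -> CostTable:
    """Placeholder unit costs (2024 USD) with the expected cost ordering."""
    r = _rng(seed, 4)
    fit = 5.0 * r.uniform(0.9, 1.1)
    fobt = fit * r.uniform(0.5, 0.8)
    sig = 120.0 * r.uniform(0.9, 1.1)
    colo = sig * r.uniform(1.8, 2.4)
    treat_local = 5000.0 * r.uniform(0.9, 1.1)
    treat_regional = treat_local * r.uniform(1.6, 2.0)
    treat_distant = treat_regional * r.uniform(1.4, 1.7)
    return CostTable(
        {
            "test_fit": fit,
            "test_fobt": fobt,
            "test_sigmoidoscopy": sig,
            "test_colonoscopy": colo,
            "colonoscopy_followup": colo,
            "colonoscopy_surveillance": colo,
            "colonoscopy_diagnostic": colo * r.uniform(1.0, 1.3),
            "complication": 1200.0 * r.uniform(0.9, 1.1),
            "treat_local": treat_local,
            "treat_regional": treat_regional,
            "treat_distant": treat_distant,
        }
    )


def make_test_characteristics(seed: int = 0) -> dict:
    """Placeholder operating characteristics, ordered colo >= sig >= FIT >= FOBT."""
    r = _rng(seed, 5)
    colo = TestCharacteristics(
        modality="colonoscopy",
        sens_adenoma_lr=r.uniform(0.75, 0.80),
        sens_adenoma_hr=r.uniform(0.92, 0.96),
        sens_crc=r.uniform(0.93, 0.97),
        specificity=0.86,
        complication_prob=r.uniform(0.001, 0.003),
    )
    sig_f = r.uniform(0.92, 0.98)
    sig = TestCharacteristics(
        modality="sigmoidoscopy",
        sens_adenoma_lr=colo.sens_adenoma_lr * sig_f,
        sens_adenoma_hr=colo.sens_adenoma_hr * sig_f,
        sens_crc=colo.sens_crc * sig_f,
        specificity=0.92,
        complication_prob=r.uniform(0.0003, 0.001),
        whole_colon=False,
        distal_fraction=0.6,
    )
    fit = TestCharacteristics(
        modality="fit",
        sens_adenoma_lr=r.uniform(0.08, 0.12),
        sens_adenoma_hr=r.uniform(0.22, 0.28),
        sens_crc=r.uniform(0.70, 0.79),
        specificity=r.uniform(0.95, 0.97),
    )
    fobt_f = r.uniform(0.55, 0.80)
    fobt = TestCharacteristics(
        modality="fobt",
        sens_adenoma_lr=fit.sens_adenoma_lr * fobt_f,
        sens_adenoma_hr=fit.sens_adenoma_hr * fobt_f,
        sens_crc=fit.sens_crc * fobt_f,
        specificity=fit.specificity - r.uniform(0.02, 0.04),
    )
    return {t.name: t for t in (colo, sig, fit, fobt)}


def make_disability_weights(seed: int = 0) -> DisabilityWeights:
    r = _rng(seed, 6)
    local = r.uniform(0.08, 0.14)
    regional = local + r.uniform(0.06, 0.14)
    distant = regional + r.uniform(0.10, 0.20)
    return DisabilityWeights(
        endoscopy=r.uniform(0.005, 0.02),
        endoscopy_days=2.0,
        complication=r.uniform(0.15, 0.25),
        complication_days=14.0,
        treatment=r.uniform(0.25, 0.33),
        treatment_days=180.0,
        cancer={"local": local, "regional": regional, "distant": distant},
    )


def base_strategies(adherence: float = 0.606) -> dict:
    """The four guideline strategies: Colo q10y, Sig q5y, biennial FIT/FOBT."""
    surv = SurveillanceSchedule()
    return {
        "Colo": single_phase_strategy("Colo", "colonoscopy", 120, adherence=adherence, surveillance=surv),
        "Sig": single_phase_strategy("Sig", "sigmoidoscopy", 60, adherence=adherence, surveillance=surv),
        "FIT": single_phase_strategy("FIT", "fit", 24, adherence=adherence, surveillance=surv),
        "FOBT": single_phase_strategy("FOBT", "fobt", 24, adherence=adherence, surveillance=surv),
    }


@dataclass
class FixtureBundle:
    """A complete, mutually consistent set of model inputs."""

    variant: str
    seed: int
    lifetable: Lifetable
    survival: StageSurvival
    truth_params: NaturalHistoryParams
    targets: CalibrationTargets
    costs: CostTable
    tests: dict
    weights: DisabilityWeights
    strategies: dict

    def check_consistency(self) -> None:
        from .calibration import objective

        self.survival.validate_ordering()
        self.truth_params.validate_exit_sums(self.lifetable)
        score = objective(
            self.truth_params, self.targets, lambda p: nh_forward_summary(p, self.lifetable)
        )
        assert score < 1e-12, f"targets do not reproduce under truth (objective={score})"

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.lifetable.to_csv(d / "lifetable.csv")
        self.survival.to_csv(d / "stage_survival.csv")
        self.truth_params.to_csv(d / "natural_history_params.csv")
        self.targets.to_csv(d / "calibration_targets.csv")
        self.costs.to_csv(d / "costs.csv")
        test_characteristics_frame(self.tests).to_csv(
            d / "test_characteristics.csv", index=False, float_format="%.17g"
        )
        self.weights.to_frame().to_csv(d / "disability_weights.csv", index=False, float_format="%.17g")
        rows = []
        for s in self.strategies.values():
            for i, p in enumerate(s.phases):
                rows.append(
                    {
                        "name": s.name,
                        "phase": i,
                        "modality": p.modality,
                        "interval_months": p.interval_months,
                        "start_age": p.start_age_years,
                        "stop_age": p.stop_age_years,
                        "adherence": s.adherence,
                        "followup_adherence": s.followup_adherence,
                        "surveillance_stop_age": s.surveillance.stop_age_years,
                    }
                )
        pd.DataFrame(rows).to_csv(d / "strategies.csv", index=False, float_format="%.17g")
        pd.DataFrame(
            [
                {"field": "variant", "value": self.variant},
                {"field": "seed", "value": self.seed},
                {"field": "provenance", "value": "synthetic placeholders, ordinal structure only"},
            ]
        ).to_csv(d / "provenance.csv", index=False)

    @classmethod
    def read(cls, directory, variant: str = "dr", seed: int = -1) -> "FixtureBundle":
        d = Path(directory)
        sdf = pd.read_csv(d / "strategies.csv", float_precision="round_trip")
        strategies = {}
        for name, g in sdf.groupby("name", sort=False):
            g = g.sort_values("phase")
            strategies[name] = StrategySpec(
                name=name,
                phases=[
                    {
                        "modality": r["modality"],
                        "interval_months": int(r["interval_months"]),
                        "start_age_years": int(r["start_age"]),
                        "stop_age_years": int(r["stop_age"]),
                    }
                    for _, r in g.iterrows()
                ],
                adherence=float(g["adherence"].iloc[0]),
                followup_adherence=float(g["followup_adherence"].iloc[0]),
                surveillance=SurveillanceSchedule(
                    stop_age_years=int(g["surveillance_stop_age"].iloc[0])
                ),
            )
        prov = pd.read_csv(d / "provenance.csv").set_index("field")["value"]
        return cls(
            variant=str(prov.get("variant", variant)),
            seed=int(prov.get("seed", seed)),
            lifetable=Lifetable.read_csv(d / "lifetable.csv"),
            survival=StageSurvival.read_csv(d / "stage_survival.csv"),
            truth_params=NaturalHistoryParams.read_csv(d / "natural_history_params.csv"),
            targets=CalibrationTargets.read_csv(d / "calibration_targets.csv"),
            costs=CostTable.read_csv(d / "costs.csv"),
            tests=test_characteristics_from_frame(pd.read_csv(d / "test_characteristics.csv", float_precision="round_trip")),
            weights=DisabilityWeights.from_frame(pd.read_csv(d / "disability_weights.csv", float_precision="round_trip")),
            strategies=strategies,
        )


def make_fixture_bundle(variant: str = "dr", seed: int = 0) -> FixtureBundle:
    """Generate the full bundle; deterministic in (variant, seed)."""
    lifetable = make_lifetable("mid", seed)
    truth, targets = make_truth_and_targets(seed, variant, lifetable)
    bundle = FixtureBundle(
        variant=variant,
        seed=seed,
        lifetable=lifetable,
        survival=make_stage_survival(seed),
        truth_params=truth,
        targets=targets,
        costs=make_costs(seed),
        tests=make_test_characteristics(seed),
        weights=make_disability_weights(seed),
        strategies=base_strategies(),
    )
    bundle.check_consistency()
    return bundle
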