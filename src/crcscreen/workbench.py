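"""Run configuration, validation, staged pipeline commands, and manifests.

A single YAML config drives every stage.  Each command reads and writes only
documented files under the run's output directory; a manifest recording the
config hash, seeds, and produced files is written even on failure.
"""
from __future__ import annotations

import hashlib
import json
import time
import traceback
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .calibration import AnnealSchedule, CalibrationResult, anneal
from .cea import WtpThreshold, cea_table, decide, find_frontier
from .economics import DiscountSpec
from .natural_history import CohortConfig, CohortTrace
from .pipeline import NH_NAME, ModelInputs, evaluate_strategies
from .sensitivity import (
    DsaRange,
    ScenarioSpec,
    adherence_grid,
    default_psa_distributions,
    one_way_dsa,
    run_psa,
    run_scenarios,
)
from .states import Event
from .synthetic import FixtureBundle, make_fixture_bundle
from .tables import NaturalHistoryParams

_KNOWN_KEYS = {
    "fixtures_dir",
    "output_dir",
    "seed",
    "variant",
    "cohort",
    "discount_rate",
    "wtp",
    "strategies",
    "calibrate",
    "dsa",
    "psa",
    "scenarios",
    "adherence_grid",
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    cfg["_config_path"] = str(path)
    return cfg


def config_hash(cfg: dict) -> str:
    clean = {k: v for k, v in cfg.items() if not k.startswith("_")}
    return hashlib.sha256(json.dumps(clean, sort_keys=True, default=str).encode()).hexdigest()[:16]


def validate_config(cfg: dict) -> List[str]:
    """Schema and invariant checks; returns the list of violations (empty = ok)."""
    v: List[str] = []
    unknown = set(k for k in cfg if not k.startswith("_")) - _KNOWN_KEYS
    if unknown:
        v.append(f"unknown config keys: {sorted(unknown)}")
    if "seed" in cfg and not (isinstance(cfg["seed"], int) and cfg["seed"] >= 0):
        v.append("seed must be a non-negative integer")
    cohort = cfg.get("cohort", {})
    n = cohort.get("n", 100_000)
    if not (isinstance(n, int) and n >= 1):
        v.append("cohort.n must be an integer >= 1")
    if cfg.get("discount_rate", 0.03) < 0:
        v.append("discount_rate must be >= 0")
    if cfg.get("wtp", 11_692) <= 0:
        v.append("wtp must be positive")
    if cfg.get("variant", "dr") not in ("dr", "seer8"):
        v.append("variant must be 'dr' or 'seer8'")
    for s in cfg.get("scenarios", []) or []:
        sa, so = s.get("start_age"), s.get("stop_age")
        if sa is not None and so is not None and sa >= so:
            v.append(f"scenario {s.get('name')}: start age {sa} must precede stop age {so}")
        for k in ("adherence", "followup_adherence"):
            a = s.get(k)
            if a is not None and not 0.0 <= a <= 1.0:
                v.append(f"scenario {s.get('name')}: {k} {a} outside [0, 1]")
    for r in (cfg.get("dsa", {}) or {}).get("ranges", []) or []:
        if r.get("low") is not None and r.get("high") is not None and r["low"] > r["high"]:
            v.append(f"dsa range for {r.get('path')}: low > high")
    psa = cfg.get("psa", {}) or {}
    if psa.get("n_iter", 1) < 1:
        v.append("psa.n_iter must be >= 1")
    return v


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    stages: List[dict] = field(default_factory=list)
    outputs: List[str] = field(default_factory=list)
    error: Optional[str] = None

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _header(cfg: dict) -> str:
    return f"config_hash={config_hash(cfg)} seed={cfg.get('seed', 0)}"


def _write_csv(df: pd.DataFrame, path, cfg: dict, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {_header(cfg)}\n")
        df.to_csv(fh, index=index)


class Workbench:
    """Staged pipeline driver bound to one config."""

    def __init__(self, cfg: dict):
        violations = validate_config(cfg)
        if violations:
            raise ValueError("invalid config: " + "; ".join(violations))
        self.cfg = cfg
        self.seed = int(cfg.get("seed", 0))
        self.fixtures_dir = Path(cfg.get("fixtures_dir", "runs/fixtures"))
        self.output_dir = Path(cfg.get("output_dir", "runs/out"))
        self.manifest = RunManifest(
            config_hash=config_hash(cfg),
            seed=self.seed,
            package_version=_pkg_version("crcscreen"),
        )

    # -- helpers -------------------------------------------------------------
    def _finish_stage(self, name: str, t0: float, outputs: List[str]) -> None:
        self.manifest.stages.append({"stage": name, "seconds": round(time.time() - t0, 2)})
        self.manifest.outputs.extend(outputs)
        self.manifest.write(self.output_dir / "manifest.json")

    def _fail(self, name: str, exc: Exception) -> None:
        self.manifest.error = f"{name}: {exc}\n{traceback.format_exc()}"
        self.manifest.write(self.output_dir / "manifest.json")

    def load_inputs(self) -> ModelInputs:
        bundle = FixtureBundle.read(self.fixtures_dir)
        params_path = self.output_dir / "calibrated_params.csv"
        params = (
            NaturalHistoryParams.read_csv(params_path)
            if params_path.exists()
            else bundle.truth_params
        )
        names = self.cfg.get("strategies") or list(bundle.strategies)
        strategies = {n: bundle.strategies[n] for n in names if n != NH_NAME}
        return ModelInputs(
            params=params,
            lifetable=bundle.lifetable,
            survival=bundle.survival,
            costs=bundle.costs,
            tests=bundle.tests,
            weights=bundle.weights,
            strategies=strategies,
            cohort=CohortConfig(
                n=int(self.cfg.get("cohort", {}).get("n", 100_000)), seed=self.seed
            ),
            discount=DiscountSpec(annual_rate=float(self.cfg.get("discount_rate", 0.03))),
            wtp=WtpThreshold(float(self.cfg.get("wtp", 11_692))),
        )

    # -- stages --------------------------------------------------------------
    def fixtures(self) -> None:
        t0 = time.time()
        try:
            bundle = make_fixture_bundle(self.cfg.get("variant", "dr"), self.seed)
            bundle.write(self.fixtures_dir)
        except Exception as exc:
            self._fail("fixtures", exc)
            raise
        self._finish_stage("fixtures", t0, [str(self.fixtures_dir)])

    def calibrate(self) -> CalibrationResult:
        t0 = time.time()
        try:
            bundle = FixtureBundle.read(self.fixtures_dir)
            cal_cfg = self.cfg.get("calibrate", {}) or {}
            schedule = AnnealSchedule(
                max_iter=int(cal_cfg.get("max_iter", 2000)),
                seed=self.seed,
                step=float(cal_cfg.get("step", 0.08)),
            )
            from .natural_history import nh_forward_summary

            result = anneal(
                bundle.targets,
                schedule,
                bundle.truth_params,
                forward=lambda p: nh_forward_summary(p, bundle.lifetable),
            )
            result.best_params.to_csv(self.output_dir / "calibrated_params.csv")
            meta = pd.DataFrame(
                {
                    "iteration": np.arange(len(result.trajectory)),
                    "objective": result.trajectory,
                }
            )
            _write_csv(meta, self.output_dir / "calibration_trajectory.csv", self.cfg)
        except Exception as exc:
            self._fail("calibrate", exc)
            raise
        self._finish_stage(
            "calibrate",
            t0,
            [str(self.output_dir / "calibrated_params.csv")],
        )
        return result

    def simulate(self) -> Dict[str, CohortTrace]:
        t0 = time.time()
        try:
            inputs = self.load_inputs()
            from .pipeline import simulate_all

            traces = simulate_all(inputs)
            tdir = self.output_dir / "traces"
            tdir.mkdir(parents=True, exist_ok=True)
            for name, tr in traces.items():
                tr.write(
                    tdir / f"{name}_events.csv",
                    tdir / f"{name}_occupancy.csv",
                    header=_header(self.cfg),
                )
            meta = pd.DataFrame(
                [{"strategy": n, "n": tr.n, "seed": tr.seed} for n, tr in traces.items()]
            )
            _write_csv(meta, tdir / "traces_meta.csv", self.cfg)
        except Exception as exc:
            self._fail("simulate", exc)
            raise
        self._finish_stage("simulate", t0, [str(self.output_dir / "traces")])
        return traces

    def _load_traces(self) -> Dict[str, CohortTrace]:
        tdir = self.output_dir / "traces"
        meta_path = tdir / "traces_meta.csv"
        if not meta_path.exists():
            raise FileNotFoundError(
                "no simulated traces found; run the `simulate` command first"
            )
        meta = pd.read_csv(meta_path, comment="#")
        traces = {}
        for _, row in meta.iterrows():
            traces[row["strategy"]] = _trace_from_files(
                tdir / f"{row['strategy']}_events.csv",
                tdir / f"{row['strategy']}_occupancy.csv",
                int(row["n"]),
                int(row["seed"]),
            )
        return traces

    def cea(self) -> pd.DataFrame:
        t0 = time.time()
        try:
            inputs = self.load_inputs()
            traces = self._load_traces()
            outcomes = evaluate_strategies(inputs, traces=traces)
            table = cea_table(list(outcomes.values()), inputs.wtp)
            _write_csv(table, self.output_dir / "cea_table.csv", self.cfg)
            fr = find_frontier(list(outcomes.values()))
            _write_csv(fr.to_frame(), self.output_dir / "frontier.csv", self.cfg)
            summary = pd.DataFrame(
                [
                    {
                        "optimal_strategy": decide(fr, inputs.wtp),
                        "wtp": inputs.wtp.usd_per_daly,
                    }
                ]
            )
            _write_csv(summary, self.output_dir / "decision.csv", self.cfg)
        except Exception as exc:
            self._fail("cea", exc)
            raise
        self._finish_stage(
            "cea",
            t0,
            [str(self.output_dir / p) for p in ("cea_table.csv", "frontier.csv", "decision.csv")],
        )
        return table

    def dsa(self) -> pd.DataFrame:
        t0 = time.time()
        try:
            inputs = self.load_inputs()
            dsa_cfg = self.cfg.get("dsa", {}) or {}
            ranges = [
                DsaRange(r["path"], float(r["low"]), float(r["high"]))
                for r in dsa_cfg.get("ranges", [])
            ]
            if not ranges:
                ranges = _default_dsa_ranges(inputs)
            comparison = tuple(dsa_cfg.get("comparison", [NH_NAME, "FIT"]))
            tornado = one_way_dsa(inputs, ranges, comparison)
            _write_csv(tornado, self.output_dir / "tornado.csv", self.cfg)
        except Exception as exc:
            self._fail("dsa", exc)
            raise
        self._finish_stage("dsa", t0, [str(self.output_dir / "tornado.csv")])
        return tornado

    def psa(self):
        t0 = time.time()
        try:
            inputs = self.load_inputs()
            psa_cfg = self.cfg.get("psa", {}) or {}
            dists = default_psa_distributions(
                inputs, se_frac=float(psa_cfg.get("se_frac", 0.2))
            )
            wtp_grid = psa_cfg.get("wtp_grid") or list(
                np.linspace(0, 2 * inputs.wtp.usd_per_daly, 11)
            )
            result = run_psa(
                inputs,
                dists,
                n_iter=int(psa_cfg.get("n_iter", 200)),
                wtp_grid=wtp_grid,
                seed=self.seed,
            )
            _write_csv(result.iterations, self.output_dir / "psa_iterations.csv", self.cfg)
            _write_csv(result.ceac, self.output_dir / "ceac.csv", self.cfg)
        except Exception as exc:
            self._fail("psa", exc)
            raise
        self._finish_stage(
            "psa",
            t0,
            [str(self.output_dir / "psa_iterations.csv"), str(self.output_dir / "ceac.csv")],
        )
        return result

    def scenarios(self) -> Dict[str, pd.DataFrame]:
        t0 = time.time()
        try:
            inputs = self.load_inputs()
            specs = [
                ScenarioSpec(**{k: v for k, v in s.items()})
                for s in self.cfg.get("scenarios", []) or []
            ]
            results = run_scenarios(inputs, specs)
            sdir = self.output_dir / "scenarios"
            for name, table in results.items():
                _write_csv(table, sdir / f"{name}.csv", self.cfg)
            grid_cfg = self.cfg.get("adherence_grid")
            if grid_cfg:
                for strat in grid_cfg.get("strategies", ["FIT"]):
                    g = adherence_grid(
                        inputs,
                        strat,
                        grid_cfg.get("first_line", [0.25, 0.5, 0.75, 1.0]),
                        grid_cfg.get("followup", [0.5, 1.0]),
                    )
                    _write_csv(g, sdir / f"adherence_grid_{strat}.csv", self.cfg)
        except Exception as exc:
            self._fail("scenarios", exc)
            raise
        self._finish_stage("scenarios", t0, [str(self.output_dir / "scenarios")])
        return results

    def report(self) -> Path:
        """Assemble prior outputs verbatim into one report directory."""
        t0 = time.time()
        try:
            rdir = self.output_dir / "report"
            rdir.mkdir(parents=True, exist_ok=True)
            wanted = [
                ("cea_table.csv", "cea"),
                ("frontier.csv", "cea"),
                ("decision.csv", "cea"),
                ("tornado.csv", "dsa"),
                ("ceac.csv", "psa"),
            ]
            copied = []
            for fname, producer in wanted:
                src = self.output_dir / fname
                if fname in ("cea_table.csv", "frontier.csv", "decision.csv") and not src.exists():
                    raise FileNotFoundError(
                        f"missing {fname}; run the `{producer}` command first"
                    )
                if src.exists():
                    (rdir / fname).write_bytes(src.read_bytes())
                    copied.append(fname)
        except Exception as exc:
            self._fail("report", exc)
            raise
        self._finish_stage("report", t0, [str(rdir / f) for f in copied])
        return rdir


def _default_dsa_ranges(inputs: ModelInputs) -> List[DsaRange]:
    """±25% ranges on the test-cost and FIT-performance parameters."""
    paths = [
        "costs.values.test_fit",
        "costs.values.test_colonoscopy",
        "costs.values.colonoscopy_followup",
        "costs.values.treat_distant",
        "tests.fit.specificity",
        "tests.fit.sens_crc",
    ]
    out = []
    for p in paths:
        base = inputs.get_param(p)
        hi = min(base * 1.25, 1.0) if p.startswith("tests.") else base * 1.25
        out.append(DsaRange(p, base * 0.75, hi))
    return out


def _trace_from_files(events_path, occupancy_path, n: int, seed: int) -> CohortTrace:
    """Rebuild a CohortTrace from its written event log and occupancy table."""
    ev = pd.read_csv(events_path, comment="#")
    occ = pd.read_csv(occupancy_path, comment="#", index_col="cycle")
    death_month = np.full(n, -1, dtype=np.int64)
    death_cause = np.full(n, -1, dtype=np.int8)
    dx_month = np.full(n, -1, dtype=np.int64)
    dx_stage = np.full(n, -1, dtype=np.int8)
    screen_det = np.zeros(n, dtype=bool)
    for evk, cause in ((Event.DEATH_CRC, 0), (Event.DEATH_OTHER, 1)):
        sel = ev[ev["event"] == int(evk)]
        death_month[sel["person_id"].to_numpy()] = sel["age_months"].to_numpy()
        death_cause[sel["person_id"].to_numpy()] = cause
    for evk, flag in ((Event.SYMPTOMATIC_DX, False), (Event.SCREEN_DX, True)):
        sel = ev[ev["event"] == int(evk)]
        pid = sel["person_id"].to_numpy()
        dx_month[pid] = sel["age_months"].to_numpy()
        dx_stage[pid] = sel["stage"].to_numpy()
        screen_det[pid] = flag
    return CohortTrace(
        n=n,
        n_cycles=len(occ) - 1,
        occupancy=occ.to_numpy(),
        events=ev,
        death_month=death_month,
        death_cause=death_cause,
        dx_month=dx_month,
        dx_stage=dx_stage,
        screen_detected=screen_det,
        seed=seed,
    )
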