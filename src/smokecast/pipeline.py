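"""Staged end-to-end workflow and run configuration.

The study workflow splits the time series into three parts: a base estimation
window, a model-selection window for choosing the cross-sectional trend
controls by one-step forecast loss, and a post-break window for choosing the
survey-bridging mode.  ``run_pipeline`` executes (optional) simulation ->
specification search -> bridge selection -> final recursive fit ->
diagnostics -> forecast evaluation -> counterfactual scenarios, writing one
artifact per stage plus a manifest with the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import CS_CANDIDATES, ModelSpec, StatePanel, load_panel, write_panel
from .synth import SynthConfig, generate_panel
from .estimate import fit_2sls, panel_r2
from .panel import build_design
from .diagnostics import iv_diagnostics, pp_panel_unit_root, residual_autocorrelation
from .forecasting import forecast_metrics, one_step_forecasts, recursive_fit
from .search import enumerate_cs_specs, evaluate_specs, model_confidence_set, select_best, select_bridge
from .scenario import ScenarioSpec, simulate_savings

log = logging.getLogger("smokecast")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; serializable to/from YAML."""

    out_dir: str = "smokecast_run"
    panel_csv: str | None = None        # if None, simulate with synth
    synth: SynthConfig = field(default_factory=SynthConfig)
    spec: ModelSpec = field(default_factory=ModelSpec)
    cs_candidates: tuple[str, ...] = CS_CANDIDATES
    base_end: int = 2006
    select_start: int = 2007
    select_end: int = 2010
    bridge_start: int = 2011
    bridge_end: int = 2014
    mcs_alpha: float = 0.05
    mcs_reps: int = 1000
    mcs_block: int = 2
    scenario: ScenarioSpec = field(default_factory=lambda: ScenarioSpec(seed=0))
    run_search: bool = True
    run_bridge: bool = True
    run_scenarios: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.base_end < self.select_start <= self.select_end
                < self.bridge_start <= self.bridge_end):
            raise ValueError("windows must be ordered: base < selection < bridging")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key, sub in (("synth", SynthConfig), ("spec", ModelSpec),
                         ("scenario", ScenarioSpec)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=str))


def _dump_json(obj, path: Path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="index")
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)
    path.write_text(json.dumps(obj, indent=2, default=_default))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the staged workflow; returns a manifest of written artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = cfg.to_dict()
    cfg_hash = hashlib.sha256(json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:16]
    manifest: dict = {"config_hash": cfg_hash, "seed": cfg.seed, "artifacts": {},
                      "stages_completed": []}
    mpath = out / "manifest.json"

    def _stage(name):
        manifest["stages_completed"].append(name)
        _dump_json(manifest, mpath)

    try:
        # -------- data --------
        if cfg.panel_csv:
            panel = load_panel(cfg.panel_csv)
            log.info("loaded panel from %s", cfg.panel_csv)
        else:
            synth_cfg = dataclasses.replace(cfg.synth, seed=cfg.seed)
            _, panel, report = generate_panel(synth_cfg)
            write_panel(panel, out / "panel.csv")
            _dump_json(report.to_dict(), out / "generation_report.json")
            manifest["artifacts"]["panel"] = "panel.csv"
            manifest["artifacts"]["generation_report"] = "generation_report.json"
            log.info("simulated panel: %d states, %d-%d (seed %d)",
                     synth_cfg.n_states, synth_cfg.start_year, synth_cfg.end_year, cfg.seed)
        _stage("data")

        spec = cfg.spec

        # -------- phase 1: cross-sectional-average search --------
        if cfg.run_search:
            log.info("phase 1: specification search, selection window %d-%d (base through %d)",
                     cfg.select_start, cfg.select_end, cfg.base_end)
            specs = enumerate_cs_specs(list(cfg.cs_candidates), spec.with_(bridge_mode="none"))
            losses = evaluate_specs(panel, specs, cfg.base_end,
                                    cfg.select_start, cfg.select_end)
            losses.rmsfe().rename("rmsfe").to_csv(out / "search_rmsfe.csv")
            mcs = model_confidence_set(losses, alpha=cfg.mcs_alpha,
                                       reps=cfg.mcs_reps, block=cfg.mcs_block,
                                       seed=cfg.seed)
            _dump_json(mcs.to_dict(), out / "mcs.json")
            best = select_best(mcs, losses)
            spec = spec.with_(cs_averages=best.cs_averages)
            manifest["artifacts"]["search_rmsfe"] = "search_rmsfe.csv"
            manifest["artifacts"]["mcs"] = "mcs.json"
            manifest["selected_cs_averages"] = list(best.cs_averages)
            log.info("selected cross-sectional averages: %s", list(best.cs_averages))
        _stage("search")

        # -------- phase 2: bridge the survey break --------
        if cfg.run_bridge:
            log.info("phase 2: break bridging, window %d-%d", cfg.bridge_start, cfg.bridge_end)
            sel = select_bridge(panel, spec, eval_start=cfg.bridge_start,
                                eval_end=cfg.bridge_end)
            spec = spec.with_(bridge_mode=sel.best_mode)
            _dump_json({"best_mode": sel.best_mode, "rmsfe": sel.rmsfe,
                        "failed": sel.failed, "collinearity": sel.collinearity},
                       out / "bridge.json")
            manifest["artifacts"]["bridge"] = "bridge.json"
            log.info("selected bridge mode: %s", sel.best_mode)
        _stage("bridge")

        # -------- phase 3: final fit, diagnostics, forecasts --------
        final_spec = spec.with_(sample_end=cfg.bridge_end)
        design = build_design(panel, final_spec)
        fit = fit_2sls(design)
        (out / "final_fit.txt").write_text(fit.summary() + "\n")
        _dump_json({"fit": fit.to_dict(), "r2": panel_r2(fit, design).to_dict()},
                   out / "final_fit.json")
        manifest["artifacts"]["final_fit"] = "final_fit.json"
        _stage("fit")

        diag = {
            "unit_root": pp_panel_unit_root(fit.residuals).to_dict(),
            "residual_ar1": residual_autocorrelation(fit).to_dict(),
        }
        if fit.spec.endogenous:
            diag["iv"] = iv_diagnostics(design, fit).to_dict()
        _dump_json(diag, out / "diagnostics.json")
        manifest["artifacts"]["diagnostics"] = "diagnostics.json"
        _stage("diagnostics")

        fits = recursive_fit(panel, spec, cfg.base_end, cfg.bridge_end - 1)
        fs = one_step_forecasts(fits, panel)
        fs.to_csv(out / "forecasts.csv")
        _dump_json(forecast_metrics(fs).to_dict(), out / "forecast_metrics.json")
        manifest["artifacts"]["forecasts"] = "forecasts.csv"
        manifest["artifacts"]["forecast_metrics"] = "forecast_metrics.json"
        _stage("forecasts")

        # -------- scenarios --------
        if cfg.run_scenarios:
            base_year = cfg.scenario.baseline_year
            base_rows = panel.data.loc[panel.data["year"] == base_year]
            baseline = float(np.average(base_rows["hexp"], weights=base_rows["population"]))
            population = cfg.scenario.population or float(base_rows["population"].sum())
            scen = dataclasses.replace(cfg.scenario, population=population,
                                       seed=cfg.scenario.seed if cfg.scenario.seed is not None else cfg.seed)
            result = simulate_savings(fit, scen, baseline)
            table = result.per_capita.copy()
            table.columns = [f"per_capita_{c}" for c in table.columns]
            if result.national is not None:
                for c in result.national.columns:
                    table[f"national_{c}"] = result.national[c]
            table.to_csv(out / "scenario.csv")
            manifest["artifacts"]["scenario"] = "scenario.csv"
            log.info("scenario: r_prev=%.3f r_cons=%.3f baseline $%.0f/capita",
                     scen.r_prev, scen.r_cons, baseline)
        _stage("scenario")

        manifest["status"] = "complete"
        _dump_json(manifest, mpath)
        return manifest
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{manifest['stages_completed'][-1] if manifest['stages_completed'] else 'init'}: {exc}"
        _dump_json(manifest, mpath)
        raise
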