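"""Counterfactual expenditure-savings forecasts under smoking reductions.

A permanent annual relative reduction *r* in smoking prevalence and/or mean
consumption per smoker compounds multiplicatively, i.e. linearly in logs: the
log-scale effect after *t* years is ``(beta_prev * t * ln(1-r_prev)
+ beta_cons * t * ln(1-r_cons))``.  Savings per capita are
``baseline * (1 - exp(delta))``; uncertainty comes from Monte-Carlo draws of
the elasticities from a multivariate normal centered at the point estimates
with the cluster-robust covariance (via its Cholesky factor), with percentile
95% prediction intervals.  The regression-error back-transform applies
identically to the factual and counterfactual arms and cancels in the
difference, so it is omitted from the savings calculation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimate import FitResult


@dataclass
class ScenarioSpec:
    """Counterfactual configuration.

    ``r_prev`` / ``r_cons`` are annual relative reductions (fractions, e.g.
    0.05 for 5% a year); ``include_cs_trend`` adds the cross-sectional
    prevalence-trend elasticity to the shock propagation (off by default: the
    correlated national trends need not be causal for a new policy).
    """

    r_prev: float = 0.05
    r_cons: float = 0.05
    horizon: int = 5
    n_trials: int = 50_000
    seed: int | None = None
    baseline_year: int = 2014
    include_cs_trend: bool = False
    population: float | None = None     # persons, for national aggregation

    def __post_init__(self) -> None:
        for name, r in [("r_prev", self.r_prev), ("r_cons", self.r_cons)]:
            if not (0.0 <= r < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.n_trials < 1000:
            raise ValueError("n_trials must be >= 1000")


@dataclass
class ScenarioResult:
    """Per-year savings with 95% prediction intervals."""

    per_capita: pd.DataFrame    # index year 1..h; columns mean, low, high, pct_of_baseline
    national: pd.DataFrame | None
    baseline: float
    trials: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "per_capita": self.per_capita.to_dict(orient="index"),
            "national": (self.national.to_dict(orient="index")
                         if self.national is not None else None),
            "baseline": self.baseline,
            "trials": self.trials,
            "seed": self.seed,
        }


def scenario_path(r: float, horizon: int) -> np.ndarray:
    """Cumulative multipliers ``(1-r)^t`` for t = 1..horizon."""
    if not (0.0 <= r < 1.0):
        raise ValueError("r must lie in [0, 1)")
    return (1.0 - r) ** np.arange(1, horizon + 1)


def derived_reductions(national_prev: float, national_cons: float,
                       r: float) -> tuple[float, float]:
    """Absolute first-year reductions implied by a relative reduction ``r``.

    Returns (percentage points of prevalence, packs/year of consumption).
    """
    if national_prev <= 0 or national_cons <= 0:
        raise ValueError("national levels must be positive")
    return r * national_prev, r * national_cons


def closed_form_saving(beta_prev: float, beta_cons: float, r_prev: float,
                       r_cons: float, baseline: float, year: int) -> float:
    """Plug-in saving at fixed elasticities (no parameter uncertainty)."""
    delta = year * (beta_prev * np.log(1.0 - r_prev) + beta_cons * np.log(1.0 - r_cons))
    return baseline * (1.0 - np.exp(delta))


def simulate_savings(fit: FitResult, scen: ScenarioSpec,
                     baseline_expenditure: float) -> ScenarioResult:
    """Monte-Carlo per-capita (and national) savings under the scenario.

    Each trial draws the elasticity vector from a multivariate normal centered
    at the fitted coefficients with the cluster-robust covariance; the log
    effect accumulates linearly in the horizon year.  Intervals are 2.5/97.5
    trial percentiles.
    """
    if baseline_expenditure <= 0:
        raise ValueError("baseline expenditure must be positive")
    names = ["prev", "cons"]
    if scen.include_cs_trend and "avg_prev" in fit.beta.index:
        names.append("avg_prev")
    missing = [n for n in names if n not in fit.beta.index]
    if missing:
        raise ValueError(f"fit lacks required coefficients: {missing}")

    mu = fit.beta[names].to_numpy()
    V = fit.vcov.loc[names, names].to_numpy()
    V = 0.5 * (V + V.T)
    try:
        L = np.linalg.cholesky(V + 1e-15 * np.eye(len(names)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("coefficient covariance is not positive semidefinite") from exc

    rng = np.random.default_rng(scen.seed)
    draws = mu + rng.standard_normal((scen.n_trials, len(names))) @ L.T
    b_prev = draws[:, 0] + (draws[:, 2] if len(names) == 3 else 0.0)
    b_cons = draws[:, 1]

    lp, lc = np.log(1.0 - scen.r_prev), np.log(1.0 - scen.r_cons)
    years = np.arange(1, scen.horizon + 1)
    rows = {}
    for t in years:
        if scen.r_prev == 0.0 and scen.r_cons == 0.0:
            saving = np.zeros(scen.n_trials)
        else:
            delta = t * (b_prev * lp + b_cons * lc)
            saving = baseline_expenditure * (1.0 - np.exp(delta))
        lo, hi = np.percentile(saving, [2.5, 97.5])
        rows[int(t)] = {
            "mean": float(saving.mean()), "low": float(lo), "high": float(hi),
            "pct_of_baseline": float(saving.mean() / baseline_expenditure * 100.0),
        }
    per_capita = pd.DataFrame.from_dict(rows, orient="index")
    per_capita.index.name = "year"

    national = (aggregate_national(per_capita, scen.population)
                if scen.population else None)
    return ScenarioResult(per_capita=per_capita, national=national,
                          baseline=baseline_expenditure,
                          trials=scen.n_trials, seed=scen.seed)


def aggregate_national(per_capita: pd.DataFrame, population: float) -> pd.DataFrame:
    """Scale per-capita mean/low/high savings to national totals (dollars)."""
    if population <= 0:
        raise ValueError("population must be positive")
    out = per_capita[["mean", "low", "high"]] * population
    return out
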