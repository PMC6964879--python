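"""Seeded synthetic state-panel generator.

Emulates the statistical structure the expenditure model assumes so every
downstream stage (estimation, diagnostics, forecast validation, specification
search, scenario simulation) is testable without the proprietary source data:

* a cointegrating log-log relation: ln expenditure is an exact linear function
  of lagged state variables, lagged national averages and region-specific tax
  terms, plus a stationary AR(1) error;
* common national stochastic trends (random walks with drift) in the logs of
  the averaged variables, with AR(1) reversion of each state's log variable
  toward its national trend;
* state fixed effects;
* measurement error in mean cigarette consumption per smoker with a classical
  component and a component proportional to the interstate tax differential
  (high-tax states under-measure consumption via untaxed cross-border inflow);
* an additive post-2011 level shift in the survey-derived variables, mimicking
  the BRFSS redesign.

The generator emits the same long-format panel as :mod:`smokecast.panel`, both
as the latent (true) panel and the measured panel an analyst would observe.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import REGIONS, SURVEY_VARS, StatePanel

#: Default elasticities for the data-generating equation (state-specific
#: regressors, region tax terms, and the three national-trend controls).
DEFAULT_TRUE_BETA = {
    "prev": 0.104,
    "cons": 0.113,
    "income": 0.259,
    "elderly": 0.493,
    "black": 0.00935,
    "hispanic": 0.0121,
    "tax_NE": 0.0802,
    "tax_ME": 0.0167,
    "tax_GL": -0.00722,
    "tax_PL": 0.0196,
    "tax_SE": -0.00381,
    "tax_SW": 0.0113,
    "tax_RM": -0.00301,
    "tax_FW": 0.0277,
    "avg_elderly": -0.521,
    "avg_hispanic": 0.0478,
    "avg_hexp": 0.784,
}

# per-variable national-trend and state-dynamics defaults: initial national
# level, annual log drift, trend (random-walk) innovation sd, cross-state sd of
# initial log deviations, sd of annual idiosyncratic log innovations
_VAR_DEFAULTS = {
    #            init     drift   trend_sd  level_sd  innov_sd
    "prev":     (24.0,   -0.020,   0.010,    0.15,     0.025),
    "cons":     (420.0,  -0.025,   0.012,    0.18,     0.030),
    "income":   (30000.0, 0.015,   0.010,    0.20,     0.015),
    "elderly":  (12.3,    0.005,   0.004,    0.15,     0.008),
    "black":    (8.0,     0.002,   0.005,    0.80,     0.010),
    "hispanic": (6.0,     0.025,   0.006,    0.70,     0.015),
    "tax":      (0.55,    0.045,   0.010,    0.35,     0.060),
}


@dataclass
class SynthConfig:
    """Configuration of the synthetic panel; defaults are the study conditions.

    ``error_ar1`` and ``error_sd`` target the serial correlation (~0.56) and
    stationary standard deviation (~0.03) of the regression error; break shifts
    are additive on the level scale of the survey-derived variables from
    ``break_year`` onward.
    """

    n_states: int = 51
    start_year: int = 1992
    end_year: int = 2014
    region_map: dict[str, str] | None = None   # state id -> region; round-robin default
    true_beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA))
    fixed_effect_sd: float = 0.15
    error_ar1: float = 0.56
    error_sd: float = 0.0301            # stationary sd of the AR(1) error
    mean_reversion: float = 0.85        # state deviations toward national trend
    prev_cons_corr: float = 0.5         # correlation of prev/cons idiosyncratic shocks
    var_params: dict[str, tuple] = field(default_factory=lambda: dict(_VAR_DEFAULTS))
    hexp_init: float = 4500.0
    hexp_init_sd: float = 0.20
    cons_noise_sd: float = 0.05         # classical measurement error on ln cons
    cons_tax_kappa: float = 0.05        # per-$ tax-differential mismeasurement
    break_year: int = 2011
    break_means: dict[str, float] = field(
        default_factory=lambda: {"prev": 1.0, "cons": -15.0, "black": 0.3, "hispanic": 0.4})
    break_sds: dict[str, float] = field(
        default_factory=lambda: {"prev": 0.4, "cons": 8.0, "black": 0.15, "hispanic": 0.2})
    pop_log_mean: float = np.log(6.0e6)
    pop_log_sd: float = 1.0
    pop_growth: float = 0.008
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 < self.error_ar1 < 1.0):
            raise ValueError("error_ar1 must lie in (-1, 1)")
        for name, v in [("error_sd", self.error_sd), ("fixed_effect_sd", self.fixed_effect_sd),
                        ("cons_noise_sd", self.cons_noise_sd)]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.end_year - self.start_year < 4:
            raise ValueError("horizon too short for the lag structure (need >= 5 years)")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    @property
    def state_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_states)]

    def regions(self) -> dict[str, str]:
        if self.region_map is not None:
            return dict(self.region_map)
        return {s: REGIONS[i % len(REGIONS)] for i, s in enumerate(self.state_ids)}


@dataclass
class GenerationReport:
    """Statistics realized in one generated panel, recomputable from it."""

    realized_error_ar1_mean: float
    realized_fixed_effect_sd: float
    realized_break_shift_means: dict[str, float]
    seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _zero_mean_ar1(e: np.ndarray) -> float:
    """Lag-1 autoregression through the origin (series known to be mean zero)."""
    denom = float(e[:-1] @ e[:-1])
    return float(e[1:] @ e[:-1]) / denom if denom > 0 else np.nan


def generate_panel(cfg: SynthConfig) -> tuple[StatePanel, StatePanel, GenerationReport]:
    """Generate (latent panel, measured panel, report) under ``cfg``.

    The latent panel carries true consumption and unshifted survey variables;
    the measured panel carries mismeasured consumption and the post-break
    shifted survey series.  Expenditure is identical in both (it responds to
    the true values).
    """
    rng = np.random.default_rng(cfg.seed)
    years = cfg.years
    T, N = len(years), cfg.n_states
    states = cfg.state_ids
    region_of = cfg.regions()
    region_arr = np.array([region_of[s] for s in states])

    exog_vars = list(cfg.var_params)
    ln: dict[str, np.ndarray] = {}

    # national log trends: random walks with drift
    trend = {}
    for v in exog_vars:
        init, drift, trend_sd, _, _ = cfg.var_params[v]
        steps = drift + trend_sd * rng.standard_normal(T - 1)
        trend[v] = np.log(init) + np.concatenate([[0.0], np.cumsum(steps)])

    # state deviations: AR(1) around the national trend, prev/cons correlated
    phi = cfg.mean_reversion
    shocks = {v: rng.standard_normal((T - 1, N)) for v in exog_vars}
    if cfg.prev_cons_corr and "prev" in shocks and "cons" in shocks:
        rho = cfg.prev_cons_corr
        shocks["cons"] = rho * shocks["prev"] + np.sqrt(max(1 - rho ** 2, 0.0)) * shocks["cons"]
    for v in exog_vars:
        _, _, _, level_sd, innov_sd = cfg.var_params[v]
        dev = np.empty((T, N))
        dev[0] = level_sd * rng.standard_normal(N)
        for t in range(1, T):
            dev[t] = phi * dev[t - 1] + innov_sd * shocks[v][t - 1]
        ln[v] = trend[v][:, None] + dev

    # AR(1) regression error with stationary sd error_sd
    rho_e = cfg.error_ar1
    innov_sd_e = cfg.error_sd * np.sqrt(max(1.0 - rho_e ** 2, 0.0))
    eps = np.empty((T, N))
    eps[0] = cfg.error_sd * rng.standard_normal(N)
    for t in range(1, T):
        eps[t] = rho_e * eps[t - 1] + innov_sd_e * rng.standard_normal(N)

    beta = cfg.true_beta
    state_beta = {v: beta.get(v, 0.0) for v in ("prev", "cons", "income", "elderly", "black", "hispanic")}
    tau = np.array([beta.get(f"tax_{region_of[s]}", 0.0) for s in states])
    cs_terms = {k[len("avg_"):]: v for k, v in beta.items() if k.startswith("avg_")}

    # fixed effects centered so that expenditure starts near hexp_init
    c0 = np.log(cfg.hexp_init)
    base = c0 - sum(b * trend[v][0] for v, b in state_beta.items()) \
        - sum(g * (np.log(cfg.hexp_init) if v == "hexp" else trend[v][0])
              for v, g in cs_terms.items()) \
        - float(np.mean(tau)) * trend["tax"][0]
    alpha = base + cfg.fixed_effect_sd * rng.standard_normal(N)

    # expenditure recursion (depends on its own lagged national average)
    ln_hexp = np.empty((T, N))
    ln_hexp[0] = c0 + cfg.hexp_init_sd * rng.standard_normal(N)
    for t in range(1, T):
        cs_part = 0.0
        for v, gcoef in cs_terms.items():
            lvl = np.exp(ln_hexp[t - 1]) if v == "hexp" else np.exp(ln[v][t - 1])
            cs_part += gcoef * np.log(np.mean(lvl))
        ln_hexp[t] = (
            alpha
            + sum(b * ln[v][t - 1] for v, b in state_beta.items())
            + tau * ln["tax"][t - 1]
            + cs_part
            + eps[t]
        )

    # population levels
    pop0 = np.exp(cfg.pop_log_mean + cfg.pop_log_sd * rng.standard_normal(N))
    pop = pop0[None, :] * (1.0 + cfg.pop_growth) ** np.arange(T)[:, None]

    # measurement error on consumption: classical + tax-differential component
    tax_level = np.exp(ln["tax"])
    tax_diff = tax_level - tax_level.mean(axis=1, keepdims=True)
    cons_noise = cfg.cons_noise_sd * rng.standard_normal((T, N))
    ln_cons_meas = ln["cons"] + cons_noise - cfg.cons_tax_kappa * tax_diff

    # post-break additive level shifts on survey-derived variables
    shift_draws = {
        v: cfg.break_means.get(v, 0.0) + cfg.break_sds.get(v, 0.0) * rng.standard_normal(N)
        for v in SURVEY_VARS
    }
    post = years >= cfg.break_year

    def _frame(measured: bool) -> pd.DataFrame:
        lev = {v: np.exp(ln[v]) for v in exog_vars}
        if measured:
            lev["cons"] = np.exp(ln_cons_meas)
            for v in SURVEY_VARS:
                lev[v] = lev[v] + np.where(post[:, None], shift_draws[v][None, :], 0.0)
                if (lev[v] <= 0).any():
                    raise ValueError(f"break shift drove {v} non-positive; reduce shift magnitude")
        rows = {
            "state": np.repeat(states, T),
            "year": np.tile(years, N),
            "region": np.repeat(region_arr, T),
            "hexp": np.exp(ln_hexp).T.ravel(),
            "population": pop.T.ravel(),
        }
        for v in ("prev", "cons", "income", "elderly", "black", "hispanic", "tax"):
            rows[v] = lev[v].T.ravel()
        return pd.DataFrame(rows)

    latent = StatePanel(_frame(measured=False))
    measured = StatePanel(_frame(measured=True))

    ar1s = [a for a in (_zero_mean_ar1(eps[:, i]) for i in range(N)) if np.isfinite(a)]
    report = GenerationReport(
        realized_error_ar1_mean=float(np.mean(ar1s)) if ar1s else np.nan,
        realized_fixed_effect_sd=float(np.std(alpha, ddof=1)),
        realized_break_shift_means={v: float(np.mean(shift_draws[v])) for v in SURVEY_VARS},
        seed=cfg.seed,
    )
    return latent, measured, report


def noiseless(cfg: SynthConfig | None = None, **kw) -> SynthConfig:
    """A copy of ``cfg`` with all error sources switched off.

    On the resulting latent panel the regression holds exactly, so estimation
    must recover ``true_beta`` to machine precision (pipeline identity check).
    """
    cfg = cfg or SynthConfig(**kw)
    return dataclasses.replace(
        cfg,
        error_sd=0.0,
        cons_noise_sd=0.0,
        cons_tax_kappa=0.0,
        break_means={v: 0.0 for v in SURVEY_VARS},
        break_sds={v: 0.0 for v in SURVEY_VARS},
    )


def apply_break(panel: StatePanel, break_year: int,
                shifts: dict[tuple[str, str], float] | pd.DataFrame) -> StatePanel:
    """Additively shift variables for all years >= ``break_year``.

    ``shifts`` maps ``(state, variable) -> additive shift`` (or an equivalent
    DataFrame with columns state/variable/shift).  Raises if any shift drives a
    value non-positive.
    """
    lo, hi = panel.years
    if not (lo <= break_year <= hi):
        raise ValueError(f"break_year {break_year} outside panel range [{lo}, {hi}]")
    if isinstance(shifts, pd.DataFrame):
        shifts = {(r["state"], r["variable"]): r["shift"] for _, r in shifts.iterrows()}
    df = panel.data.copy()
    post = df["year"] >= break_year
    for var in {v for (_, v) in shifts}:
        df[var] = df[var].astype(float)
    for (state, var), delta in shifts.items():
        mask = post & (df["state"] == state)
        df.loc[mask, var] = df.loc[mask, var] + delta
        if (df.loc[mask, var] <= 0).any():
            raise ValueError(f"shift {delta} on {var} for state {state} drove values non-positive")
    return StatePanel(df, extra_covariates=panel.extra_covariates)
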