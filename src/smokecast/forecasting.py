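"""Recursive estimation and out-of-sample forecast evaluation.

Recursive regression re-estimates the model on expanding samples, one year of
all states' data at a time.  One-step-ahead forecasts for year ``t+1`` use only
data through year ``t`` (strict no-lookahead); multi-step forecasts condition
on the *observed* explanatory-variable paths at each target year minus one,
because the reduced form contains no lagged dependent variable and forecasting
the unit-root regressors themselves would blow up the intervals.

Accuracy is summarized by the log-scale RMSFE, the mean relative bias on the
level (dollar) scale, and the forecast-observed correlation across states;
level forecasts apply the lognormal mean back-transform ``exp(m + v/2)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import DesignMatrix, ModelSpec, StatePanel, build_design
from .estimate import FitResult, fit_2sls


def back_transform(yhat_log: float | np.ndarray, var_log: float | np.ndarray):
    """Level forecast of a log-scale normal mean: ``exp(yhat + var/2)``."""
    var_log = np.asarray(var_log, dtype=float)
    if np.any(var_log < 0):
        raise ValueError("log-scale variance must be >= 0")
    out = np.exp(np.asarray(yhat_log, dtype=float) + var_log / 2.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class ForecastSet:
    """Out-of-sample forecasts with origins and horizons.

    ``entries`` columns: state, origin, target, horizon, yhat_log, se_log,
    y_obs_log, yhat_level, y_obs_level.  ``skipped`` records (state, origin,
    target, reason) for cells that could not be forecast.
    """

    entries: pd.DataFrame
    skipped: pd.DataFrame

    def __len__(self) -> int:
        return len(self.entries)

    def squared_log_errors(self) -> pd.Series:
        e = self.entries
        return pd.Series(
            ((e["yhat_log"] - e["y_obs_log"]) ** 2).to_numpy(),
            index=pd.MultiIndex.from_frame(e[["state", "target"]]),
        )

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


@dataclass
class ForecastMetrics:
    rmsfe: float                    # log scale
    mean_relative_bias_pct: float   # level scale, forecast-minus-observed
    correlation: float              # levels, pooled across state-target cells
    n: int
    per_year: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in dataclasses.asdict(self).items() if k != "per_year"}
        if self.per_year is not None:
            d["per_year"] = self.per_year.to_dict(orient="index")
        return d


def recursive_fit(panel: StatePanel, spec: ModelSpec, base_end: int,
                  final_end: int) -> list[FitResult]:
    """One fit per sample end-year from ``base_end`` through ``final_end``."""
    if final_end < base_end:
        raise ValueError("final_end must be >= base_end")
    fits = []
    for end in range(base_end, final_end + 1):
        try:
            fits.append(fit_2sls(build_design(panel, spec.with_(sample_end=end))))
        except Exception as exc:
            raise RuntimeError(f"recursive estimation failed for window ending {end}: {exc}") from exc
    return fits


def _predict_rows(fit: FitResult, rows: DesignMatrix, origin: int) -> tuple[list[dict], list[dict]]:
    entries, skipped = [], []
    sigma2 = fit.sigma ** 2
    for (state, target) in rows.y.index:
        x = rows.X.loc[(state, target)]
        group = rows.fe_groups.loc[(state, target)]
        try:
            yhat = fit.predict_row(x, group)
        except KeyError as exc:
            skipped.append({"state": state, "origin": origin, "target": target,
                            "reason": str(exc)})
            continue
        yobs = float(rows.y.loc[(state, target)])
        entries.append({
            "state": state, "origin": origin, "target": target,
            "horizon": target - origin,
            "yhat_log": yhat, "se_log": fit.sigma,
            "y_obs_log": yobs,
            "yhat_level": back_transform(yhat, sigma2),
            "y_obs_level": float(np.exp(yobs)),
        })
    return entries, skipped


_COLS = ["state", "origin", "target", "horizon", "yhat_log", "se_log",
         "y_obs_log", "yhat_level", "y_obs_level"]


def _make_set(entries: list[dict], skipped: list[dict]) -> ForecastSet:
    return ForecastSet(
        entries=pd.DataFrame(entries, columns=_COLS),
        skipped=pd.DataFrame(skipped, columns=["state", "origin", "target", "reason"]),
    )


def one_step_forecasts(fits: list[FitResult], panel: StatePanel) -> ForecastSet:
    """One forecast per state per target year, target = fit origin + 1.

    Each forecast uses the recursive fit whose sample ends at the origin and
    regressors dated at the origin (lag one), plus that state's fixed effect
    (the post-break effect when bridged and the target is past the break).
    """
    entries, skipped = [], []
    for fit in fits:
        origin = fit.spec.sample_end
        if origin is None:
            raise ValueError("recursive fits must carry sample_end as the origin year")
        target = origin + 1
        try:
            design = build_design(panel, fit.spec.with_(sample_end=target))
        except ValueError as exc:
            skipped.append({"state": None, "origin": origin, "target": target,
                            "reason": str(exc)})
            continue
        rows = design.rows_for_year(target)
        e, s = _predict_rows(fit, rows, origin)
        entries.extend(e)
        skipped.extend(s)
    return _make_set(entries, skipped)


def multi_step_forecasts(fit: FitResult, panel: StatePanel, horizon: int) -> ForecastSet:
    """Forecasts for origin+1 .. origin+horizon from the single fit at origin.

    Conditions on observed explanatory variables at each target-1; horizons
    whose explanatory path is unavailable are truncated and flagged.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    origin = fit.spec.sample_end
    if origin is None:
        raise ValueError("fit must carry sample_end as the origin year")
    last = panel.years[1]
    entries, skipped = [], []
    for target in range(origin + 1, origin + horizon + 1):
        if target > last:
            skipped.append({"state": None, "origin": origin, "target": target,
                            "reason": "explanatory path unavailable; truncated"})
            continue
        design = build_design(panel, fit.spec.with_(sample_end=target))
        rows = design.rows_for_year(target)
        e, s = _predict_rows(fit, rows, origin)
        entries.extend(e)
        skipped.extend(s)
    return _make_set(entries, skipped)


def forecast_metrics(fs: ForecastSet, per_year: bool = True) -> ForecastMetrics:
    """RMSFE (log scale), mean relative bias (%), forecast-observed correlation.

    ``bias = mean((forecast_level - observed_level) / observed_level) * 100``;
    correlation is computed on levels pooled over all state-target cells (it
    includes fixed-effect-driven cross-state variation, which inflates it).
    """
    e = fs.entries
    if e.empty:
        raise ValueError("empty forecast set")
    if e["y_obs_log"].isna().any():
        raise ValueError("observed values required for forecast metrics")
    err = e["yhat_log"] - e["y_obs_log"]
    rmsfe = float(np.sqrt(np.mean(err ** 2)))
    bias = float(np.mean((e["yhat_level"] - e["y_obs_level"]) / e["y_obs_level"]) * 100)
    if np.std(e["y_obs_level"]) > 0:
        if np.allclose(e["yhat_level"], e["y_obs_level"]):
            corr = 1.0
        else:
            corr = float(np.corrcoef(e["yhat_level"], e["y_obs_level"])[0, 1])
    else:
        corr = np.nan
    py = None
    if per_year:
        def _year_stats(g):
            return pd.Series({
                "rmsfe": np.sqrt(np.mean((g["yhat_log"] - g["y_obs_log"]) ** 2)),
                "bias_pct": np.mean((g["yhat_level"] - g["y_obs_level"]) / g["y_obs_level"]) * 100,
                "n": len(g),
            })
        py = e.groupby("target").apply(_year_stats, include_groups=False)
    return ForecastMetrics(rmsfe=rmsfe, mean_relative_bias_pct=bias,
                           correlation=corr, n=len(e), per_year=py)
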