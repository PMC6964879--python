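"""State-panel data model, CSV serialization, inflation adjustment, and design construction.

The unit of analysis is a long-format annual panel of US states (50 states plus
the District of Columbia, treated as 51 "states").  Every monetary, prevalence
and percentage field enters the regressions in natural logarithms, so the model
coefficients are elasticities.  This module owns the validated container
(:class:`StatePanel`), the declarative regression description
(:class:`ModelSpec`) and the construction of the lagged log-log design matrix
(:class:`DesignMatrix`) that the estimation and forecasting modules consume.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: The eight BEA Economic Region labels.
REGIONS = ("NE", "ME", "GL", "PL", "SE", "SW", "RM", "FW")

#: Variables eligible as cross-sectional (national-average) trend controls.
CS_CANDIDATES = ("hexp", "prev", "cons", "income", "elderly", "black", "hispanic")

#: Variables measured by the BRFSS telephone survey, affected by the 2011 redesign.
SURVEY_VARS = ("prev", "cons", "black", "hispanic")

#: Fields that enter regressions in logs and must therefore be strictly positive.
LOG_FIELDS = ("hexp", "prev", "cons", "income", "elderly", "black", "hispanic", "tax")

BASE_COLUMNS = ("state", "year", "region") + LOG_FIELDS + ("population",)

#: State postal code -> BEA Economic Region (New England, Mideast, Great Lakes,
#: Plains, Southeast, Southwest, Rocky Mountains, Far West).
BEA_REGION_OF_STATE = {
    "CT": "NE", "MA": "NE", "ME": "NE", "NH": "NE", "RI": "NE", "VT": "NE",
    "DE": "ME", "DC": "ME", "MD": "ME", "NJ": "ME", "NY": "ME", "PA": "ME",
    "IL": "GL", "IN": "GL", "MI": "GL", "OH": "GL", "WI": "GL",
    "IA": "PL", "KS": "PL", "MN": "PL", "MO": "PL", "NE": "PL", "ND": "PL", "SD": "PL",
    "AL": "SE", "AR": "SE", "FL": "SE", "GA": "SE", "KY": "SE", "LA": "SE",
    "MS": "SE", "NC": "SE", "SC": "SE", "TN": "SE", "VA": "SE", "WV": "SE",
    "AZ": "SW", "NM": "SW", "OK": "SW", "TX": "SW",
    "CO": "RM", "ID": "RM", "MT": "RM", "UT": "RM", "WY": "RM",
    "AK": "FW", "CA": "FW", "HI": "FW", "NV": "FW", "OR": "FW", "WA": "FW",
}


class PanelSchemaError(ValueError):
    """A mandatory column is missing or misnamed in an input file."""


class PanelValidationError(ValueError):
    """Panel contents violate an invariant; message lists offending cells."""


@dataclass
class StatePanel:
    """Long-format annual state panel: one row per (state, year).

    Parameters
    ----------
    data
        DataFrame with columns ``state, year, region, hexp, prev, cons, income,
        elderly, black, hispanic, tax, population`` plus any extra covariates.
        Missing cells are NaN (treated as missing completely at random).
    extra_covariates
        Names of additional state-level covariate columns carried in ``data``.
    """

    data: pd.DataFrame
    extra_covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data["year"] = self.data["year"].astype(int)
        self._validate()
        self.data = (
            self.data.sort_values(["state", "year"]).reset_index(drop=True)
        )

    # ------------------------------------------------------------------ #
    def _validate(self) -> None:
        missing = [c for c in BASE_COLUMNS if c not in self.data.columns]
        if missing:
            raise PanelSchemaError(f"missing mandatory columns: {missing}")
        for c in self.extra_covariates:
            if c not in self.data.columns:
                raise PanelSchemaError(f"missing extra covariate column: {c}")

        problems: list[str] = []
        bad_region = self.data.loc[~self.data["region"].isin(REGIONS)]
        for _, r in bad_region.iterrows():
            problems.append(f"({r['state']}, {r['year']}, region={r['region']!r}) not a BEA region label")
        multi = self.data.groupby("state")["region"].nunique()
        for st in multi.index[multi > 1]:
            problems.append(f"state {st} mapped to multiple regions")

        for fld in LOG_FIELDS + ("population",):
            vals = pd.to_numeric(self.data[fld], errors="coerce")
            bad = self.data.loc[vals.notna() & (vals <= 0)]
            for _, r in bad.iterrows():
                problems.append(f"({r['state']}, {r['year']}, {fld}={r[fld]}) must be strictly positive")

        if self.data.duplicated(["state", "year"]).any():
            dups = self.data.loc[self.data.duplicated(["state", "year"]), ["state", "year"]]
            for _, r in dups.iterrows():
                problems.append(f"duplicate row for ({r['state']}, {r['year']})")

        for st, g in self.data.groupby("state"):
            yrs = np.sort(g["year"].to_numpy())
            if len(yrs) and not np.array_equal(yrs, np.arange(yrs[0], yrs[-1] + 1)):
                problems.append(f"state {st}: years not contiguous ({yrs.min()}..{yrs.max()})")

        if problems:
            raise PanelValidationError("panel validation failed:\n  " + "\n  ".join(problems))

    # ------------------------------------------------------------------ #
    @property
    def states(self) -> list[str]:
        return sorted(self.data["state"].unique())

    @property
    def years(self) -> tuple[int, int]:
        return int(self.data["year"].min()), int(self.data["year"].max())

    @property
    def region_of(self) -> dict[str, str]:
        return dict(self.data.groupby("state")["region"].first())

    def to_csv(self, path) -> None:
        write_panel(self, path)


def write_panel(panel: StatePanel, path) -> None:
    """Serialize a panel to CSV (comma-separated, header, UTF-8, empty = missing)."""
    cols = list(BASE_COLUMNS) + [c for c in panel.extra_covariates]
    panel.data[cols].to_csv(path, index=False, encoding="utf-8")


def load_panel(path, schema: dict[str, str] | None = None,
               extra_covariates: tuple[str, ...] = ()) -> StatePanel:
    """Load and validate a long-format panel CSV.

    Parameters
    ----------
    path
        CSV file with one row per state-year.
    schema
        Optional mapping from the file's column names to the canonical names
        (e.g. ``{"fips": "state", "exp_pc": "hexp"}``).
    """
    df = pd.read_csv(path, encoding="utf-8")
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in BASE_COLUMNS if c not in df.columns]
    if missing:
        raise PanelSchemaError(
            f"missing mandatory columns after schema mapping: {missing}"
        )
    return StatePanel(df, extra_covariates=extra_covariates)


def deflate(nominal: pd.Series, index: pd.Series, base_year: int) -> pd.Series:
    """Convert a nominal series to base-year dollars with a price index.

    ``real_t = nominal_t * index_base / index_t``; ``nominal`` must be indexed
    by calendar year, ``index`` maps year -> price-index level.
    """
    index = pd.Series(index)
    if base_year not in index.index:
        raise ValueError(f"base year {base_year} not present in price index")
    if (index <= 0).any():
        raise ValueError("price index must be strictly positive")
    missing = [int(y) for y in nominal.index if y not in index.index]
    if missing:
        raise ValueError(f"years missing from price index: {missing}")
    return nominal * float(index.loc[base_year]) / index.reindex(nominal.index)


# ---------------------------------------------------------------------- #
# Model specification
# ---------------------------------------------------------------------- #

BRIDGE_MODES = ("none", "intercept_shift", "slope_shift", "both")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one regression specification.

    Defaults reproduce the preferred forecasting model: six state-specific
    regressors, region-specific tax terms, mean consumption instrumented by
    deeper lags of the smoking variables, and the cross-sectional national
    trends for age structure, Hispanic population share and healthcare
    expenditure.
    """

    state_vars: tuple[str, ...] = ("prev", "cons", "income", "elderly", "black", "hispanic")
    cs_averages: tuple[str, ...] = ("elderly", "hispanic", "hexp")
    tax_by_region: bool = True
    endogenous: tuple[str, ...] = ("cons",)
    instruments: tuple[tuple[str, int], ...] = (("prev", 2), ("prev", 3), ("cons", 3))
    lag: int = 1
    bridge_mode: str = "none"
    break_year: int = 2011
    sample_start: int | None = None
    sample_end: int | None = None
    extra_covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "state_vars", tuple(self.state_vars))
        object.__setattr__(self, "cs_averages", tuple(self.cs_averages))
        object.__setattr__(self, "endogenous", tuple(self.endogenous))
        object.__setattr__(self, "extra_covariates", tuple(self.extra_covariates))
        object.__setattr__(self, "instruments",
                           tuple((v, int(l)) for v, l in self.instruments))
        bad = set(self.cs_averages) - set(CS_CANDIDATES)
        if bad:
            raise ValueError(f"cross-sectional averages not among candidates: {sorted(bad)}")
        if len(set(self.cs_averages)) != len(self.cs_averages):
            raise ValueError("duplicate cross-sectional averages")
        if self.bridge_mode not in BRIDGE_MODES:
            raise ValueError(f"bridge_mode must be one of {BRIDGE_MODES}")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        for v, l in self.instruments:
            if l <= self.lag:
                raise ValueError(
                    f"instrument {v} lag {l} must be strictly deeper than regression lag {self.lag}"
                )
        bad_endog = set(self.endogenous) - set(self.state_vars)
        if bad_endog:
            raise ValueError(f"endogenous regressors not among state_vars: {sorted(bad_endog)}")

    @property
    def max_lag(self) -> int:
        """Deepest lag the design needs (regression lag or instrument lag)."""
        inst = max((l for _, l in self.instruments), default=0)
        return max(self.lag, inst)

    @property
    def instrument_names(self) -> tuple[str, ...]:
        return tuple(f"{v}_lag{l}" for v, l in self.instruments)

    @property
    def spec_id(self) -> str:
        """Short identifier used in loss tables and reports."""
        cs = "+".join(self.cs_averages) if self.cs_averages else "none"
        sid = f"cs[{cs}]|bridge[{self.bridge_mode}]"
        if self.sample_start is not None:
            sid += f"|from[{self.sample_start}]"
        return sid

    def with_(self, **kw) -> "ModelSpec":
        return replace(self, **kw)


# ---------------------------------------------------------------------- #
# Design matrix
# ---------------------------------------------------------------------- #


@dataclass
class DesignMatrix:
    """Aligned regression arrays for one specification.

    Rows are indexed by ``(state, year)`` where ``year`` is the response year
    *t*; regressor columns hold logs dated *t - lag*, instrument columns hold
    logs at deeper lags.  Listwise deletion has already been applied: no NaNs
    remain in any retained row.
    """

    y: pd.Series
    X: pd.DataFrame
    Z: pd.DataFrame
    endog: list[str]
    clusters: pd.Series
    fe_groups: pd.Series
    regions: pd.Series
    spec: ModelSpec
    absorbed: list[str] = field(default_factory=list)

    @property
    def nobs(self) -> int:
        return len(self.y)

    def rows_for_year(self, year: int) -> "DesignMatrix":
        mask = self.y.index.get_level_values("year") == year
        return DesignMatrix(
            y=self.y[mask], X=self.X[mask], Z=self.Z[mask], endog=list(self.endog),
            clusters=self.clusters[mask], fe_groups=self.fe_groups[mask],
            regions=self.regions[mask], spec=self.spec, absorbed=list(self.absorbed),
        )


def _fe_group_labels(states: pd.Series, years: pd.Series, spec: ModelSpec) -> pd.Series:
    if spec.bridge_mode in ("intercept_shift", "both"):
        post = years >= spec.break_year
        return states.where(~post, states + ":post")
    return states.copy()


def build_design(panel: StatePanel, spec: ModelSpec) -> DesignMatrix:
    """Construct the lagged log-log design matrix for one specification.

    Cross-sectional averages are unweighted means over all states observed in a
    year, computed on the raw scale, then logged and lagged.  State variables
    are logged then lagged.  Rows with any missing ingredient are dropped
    (listwise deletion, per the MCAR assumption).
    """
    df = panel.data.sort_values(["state", "year"]).reset_index(drop=True).copy()

    start = spec.sample_start if spec.sample_start is not None else int(df["year"].min())
    end = spec.sample_end if spec.sample_end is not None else int(df["year"].max())
    # A bridged spec on a window ending before the break simply has no
    # post-break rows and collapses to the unbridged design; recursive
    # (expanding-window) estimation through the break relies on this.
    if spec.bridge_mode != "none" and spec.break_year <= start + spec.max_lag:
        raise ValueError(
            f"bridge_mode={spec.bridge_mode!r} requires pre-break years inside "
            f"the sample window [{start}, {end}] (break {spec.break_year})"
        )

    vars_needed = set(spec.state_vars) | set(spec.extra_covariates) | {"hexp", "tax"}
    vars_needed |= {v for v, _ in spec.instruments}
    # cross-sectional raw-scale averages per year
    for v in spec.cs_averages:
        df[f"_csavg_{v}"] = df.groupby("year")[v].transform("mean")

    with np.errstate(divide="ignore", invalid="ignore"):
        for v in sorted(vars_needed):
            df[f"_ln_{v}"] = np.log(df[v].astype(float))
        for v in spec.cs_averages:
            df[f"_lnavg_{v}"] = np.log(df[f"_csavg_{v}"].astype(float))

    g = df.groupby("state", sort=False)
    out = pd.DataFrame({
        "state": df["state"], "year": df["year"], "region": df["region"],
        "_y": df["_ln_hexp"],
    })
    for v in spec.state_vars + spec.extra_covariates:
        out[v] = g[f"_ln_{v}"].shift(spec.lag)
    for v in spec.cs_averages:
        out[f"avg_{v}"] = g[f"_lnavg_{v}"].shift(spec.lag)
    ln_tax_lag = g["_ln_tax"].shift(spec.lag)
    if spec.tax_by_region:
        for r in REGIONS:
            out[f"tax_{r}"] = np.where(df["region"] == r, ln_tax_lag, 0.0)
            # keep NaN where the lagged tax itself is missing for rows of that region
            out.loc[(df["region"] == r) & ln_tax_lag.isna(), f"tax_{r}"] = np.nan
    else:
        out["tax"] = ln_tax_lag

    if spec.bridge_mode in ("slope_shift", "both"):
        post = (out["year"] >= spec.break_year).astype(float)
        for v in SURVEY_VARS:
            if v in spec.state_vars:
                out[f"{v}_post"] = post * out[v]
            if v in spec.cs_averages:
                out[f"avg_{v}_post"] = post * out[f"avg_{v}"]

    inst_cols = []
    for v, l in spec.instruments:
        name = f"{v}_lag{l}"
        out[name] = g[f"_ln_{v}"].shift(l)
        inst_cols.append(name)

    # sample window: response years, first max_lag years of the window excluded
    keep = (out["year"] >= start + spec.max_lag) & (out["year"] <= end)
    out = out.loc[keep]
    out = out.dropna(axis=0, how="any")
    if out.empty:
        raise ValueError("design matrix empty after listwise deletion")

    out = out.set_index(["state", "year"]).sort_index()
    idx = out.index
    states = pd.Series(idx.get_level_values("state"), index=idx)
    years = pd.Series(idx.get_level_values("year"), index=idx)

    x_cols = [c for c in out.columns if c not in ("_y", "region") and c not in inst_cols]
    return DesignMatrix(
        y=out["_y"].rename("ln_hexp"),
        X=out[x_cols],
        Z=out[inst_cols],
        endog=[e for e in spec.endogenous],
        clusters=states,
        fe_groups=_fe_group_labels(states, years, spec),
        regions=out["region"],
        spec=spec,
    )
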