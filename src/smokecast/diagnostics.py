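"""Cointegration and instrument-validity diagnostics.

Stationary regression residuals are evidence that the log-log expenditure
regression is cointegrating: a panel Phillips-Perron test is run per state and
combined across states Fisher-style.  Instrument diagnostics cover
under-identification (canonical-correlation LM), weak identification
(first-stage F against tabulated 2SLS relative-bias thresholds) and
over-identification (Sargan J on the residual-instrument moments).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.adfvalues import mackinnonp

from .panel import DesignMatrix
from .estimate import FitResult, fit_2sls, within_transform, _sandwich


# ---------------------------------------------------------------------- #
# Phillips-Perron panel unit-root test
# ---------------------------------------------------------------------- #


@dataclass
class UnitRootResult:
    per_state: pd.DataFrame          # columns: stat, pvalue
    combined_stat: float             # Fisher -2 sum(ln p)
    combined_pvalue: float
    dof: int
    lag_truncation: int
    excluded: list[str]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["per_state"] = self.per_state.to_dict(orient="index")
        return d


def _newey_west_lrv(u: np.ndarray, q: int) -> float:
    T = len(u)
    gamma0 = float(u @ u) / T
    lrv = gamma0
    for j in range(1, min(q, T - 1) + 1):
        w = 1.0 - j / (q + 1.0)
        lrv += 2.0 * w * float(u[j:] @ u[:-j]) / T
    return lrv


def phillips_perron(series: np.ndarray, trunc: int | None = None) -> tuple[float, float]:
    """Phillips-Perron Z-tau statistic (regression with constant) and p-value.

    The tau statistic from the AR(1) regression ``y_t = a + rho y_{t-1} + u_t``
    is corrected with the Newey-West long-run variance at truncation ``trunc``
    (default ``floor(4 (T/100)^{2/9})``); p-values are MacKinnon's asymptotic
    approximation for the Dickey-Fuller tau distribution with constant.
    """
    y = np.asarray(series, dtype=float)
    T = len(y) - 1
    if T < 4:
        raise ValueError("series too short for Phillips-Perron test")
    if trunc is None:
        trunc = int(np.floor(4.0 * (T / 100.0) ** (2.0 / 9.0)))
    ylag, ycur = y[:-1], y[1:]
    A = np.column_stack([np.ones(T), ylag])
    coef, *_ = np.linalg.lstsq(A, ycur, rcond=None)
    u = ycur - A @ coef
    dof = T - 2
    s2 = float(u @ u) / dof
    XtX_inv = np.linalg.inv(A.T @ A)
    se_rho = float(np.sqrt(s2 * XtX_inv[1, 1]))
    tau = (coef[1] - 1.0) / se_rho
    gamma0 = float(u @ u) / T
    lam = max(_newey_west_lrv(u, trunc), 1e-12)
    # Z_tau = sqrt(g0/lam) * tau - (lam - g0) / (2 sqrt(lam)) * T se_rho / s
    z_tau = (np.sqrt(gamma0 / lam) * tau
             - (lam - gamma0) / (2.0 * np.sqrt(lam)) * T * se_rho / np.sqrt(s2))
    pval = float(mackinnonp(z_tau, regression="c", N=1))
    return float(z_tau), pval


def pp_panel_unit_root(residuals: pd.Series | dict, lag_truncation: int | None = None,
                       min_obs: int = 8) -> UnitRootResult:
    """Fisher-combined Phillips-Perron test on per-state residual series.

    ``residuals`` is a Series indexed by (state, year) (e.g.
    ``FitResult.residuals``) or a mapping state -> series.  States with fewer
    than ``min_obs`` observations or zero variance are excluded and listed.
    Combined statistic: ``-2 sum ln p_i ~ chi2(2k)`` under the unit-root null.
    """
    if isinstance(residuals, pd.Series):
        groups = {s: g.sort_index().values for s, g in residuals.groupby(level=0)}
    else:
        groups = {s: np.asarray(v, dtype=float) for s, v in residuals.items()}

    rows, excluded = {}, []
    trunc_used = lag_truncation
    for st, series in groups.items():
        if len(series) < min_obs or np.std(series) <= 1e-14:
            excluded.append(str(st))
            continue
        stat, p = phillips_perron(series, trunc=lag_truncation)
        if trunc_used is None:
            T = len(series) - 1
            trunc_used = int(np.floor(4.0 * (T / 100.0) ** (2.0 / 9.0)))
        rows[st] = {"stat": stat, "pvalue": p}
    if not rows:
        raise ValueError("all residual series too short or degenerate")

    per_state = pd.DataFrame.from_dict(rows, orient="index")
    pvals = np.clip(per_state["pvalue"].values, 1e-300, 1.0)
    fisher = float(-2.0 * np.sum(np.log(pvals)))
    dof = 2 * len(per_state)
    return UnitRootResult(
        per_state=per_state,
        combined_stat=fisher,
        combined_pvalue=float(stats.chi2.sf(fisher, dof)),
        dof=dof,
        lag_truncation=int(trunc_used or 0),
        excluded=excluded,
    )


# ---------------------------------------------------------------------- #
# Instrument diagnostics
# ---------------------------------------------------------------------- #

#: Stock-Yogo critical values of the first-stage F for 2SLS relative bias,
#: one endogenous regressor, keyed by number of instruments.
_SY_BIAS = {
    3: [(0.05, 13.91), (0.10, 9.08), (0.20, 6.46), (0.30, 5.39)],
    4: [(0.05, 16.85), (0.10, 10.27), (0.20, 6.71), (0.30, 5.34)],
    5: [(0.05, 18.37), (0.10, 10.83), (0.20, 6.77), (0.30, 5.25)],
}


def _bias_category(F: float, L: int) -> str:
    table = _SY_BIAS.get(L)
    if table is None:
        return "<10%" if F > 10.0 else "unclassified"
    for level, crit in table:
        if F > crit:
            return f"<{int(level * 100)}%"
    return ">30%"


@dataclass
class IVDiagnostics:
    underid_stat: float
    underid_pvalue: float
    weak_F: float
    bias_category: str
    overid_J: float | None
    overid_pvalue: float | None
    overid_dof: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _partial_out(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Residuals of each column of A on B."""
    if B.size == 0:
        return A
    coef, *_ = np.linalg.lstsq(B, A, rcond=None)
    return A - B @ coef


def iv_diagnostics(design: DesignMatrix, fit: FitResult | None = None) -> IVDiagnostics:
    """Under-, weak- and over-identification statistics for the 2SLS design.

    * under-identification: Anderson canonical-correlation LM statistic,
      ``chi2(L - m + 1)`` under the null of no identification;
    * weak identification: cluster-robust first-stage F on the excluded
      instruments, classified against tabulated 2SLS relative-bias thresholds;
    * over-identification: Sargan ``N R^2`` of the 2SLS residuals on the full
      instrument set, ``chi2(L - m)``; reported as inapplicable (None) for a
      just-identified model.
    """
    if fit is None:
        fit = fit_2sls(design)
    wd = within_transform(design)
    endog = [e for e in wd.endog if e in wd.X.columns]
    if not endog:
        raise ValueError("design has no endogenous regressors")
    m = len(endog)
    Z = wd.Z.values
    L = Z.shape[1]
    if L < m:
        raise ValueError("under- or just-identified required: fewer instruments than endogenous")

    exog_cols = [c for c in wd.X.columns if c not in endog]
    Xex = wd.X[exog_cols].values
    E = wd.X[endog].values
    n = len(wd.y)

    Ep = _partial_out(E, Xex)
    Zp = _partial_out(Z, Xex)

    # canonical correlations between partialled endogenous block and instruments
    qe, _ = np.linalg.qr(Ep)
    qz, _ = np.linalg.qr(Zp)
    svals = np.linalg.svd(qe.T @ qz, compute_uv=False)
    cc_min = float(np.min(svals[:m]) ** 2)
    underid = n * cc_min
    underid_dof = L - m + 1
    underid_p = float(stats.chi2.sf(underid, underid_dof))

    weak_F = min(fs["F"] for fs in fit.first_stage.values()) if fit.first_stage else np.nan

    overid_dof = L - m
    if overid_dof > 0:
        u = wd.y.values - wd.X.values @ fit.beta.reindex(wd.X.columns).values
        W = np.column_stack([Xex, Z]) if exog_cols else Z
        coef, *_ = np.linalg.lstsq(W, u, rcond=None)
        uhat = W @ coef
        r2 = float(uhat @ uhat) / float(u @ u)
        J = n * r2
        J_p = float(stats.chi2.sf(J, overid_dof))
    else:
        J, J_p = None, None

    return IVDiagnostics(
        underid_stat=float(underid), underid_pvalue=underid_p,
        weak_F=float(weak_F), bias_category=_bias_category(float(weak_F), L),
        overid_J=J, overid_pvalue=J_p, overid_dof=overid_dof,
    )


# ---------------------------------------------------------------------- #
# Residual serial correlation
# ---------------------------------------------------------------------- #


@dataclass
class ResidualAutocorr:
    per_state: pd.Series
    mean: float
    min: float
    max: float

    def to_dict(self) -> dict:
        return {"per_state": self.per_state.to_dict(), "mean": self.mean,
                "min": self.min, "max": self.max}


def residual_autocorrelation(fit: FitResult | pd.Series) -> ResidualAutocorr:
    """Per-state lag-1 autocorrelation of regression residuals, with summary.

    Residuals are mean zero within each state by the fixed-effects property,
    so the lag-1 coefficient is estimated through the origin:
    ``sum_t e_t e_{t-1} / sum_t e_{t-1}^2``.
    """
    resid = fit.residuals if isinstance(fit, FitResult) else fit
    out = {}
    for st, g in resid.groupby(level=0):
        e = g.sort_index().values
        if len(e) < 3:
            continue
        denom = float(e[:-1] @ e[:-1])
        if denom <= 0:
            continue
        out[st] = float(e[1:] @ e[:-1]) / denom
    if not out:
        raise ValueError("no state has >= 3 residual observations")
    s = pd.Series(out, name="ar1")
    return ResidualAutocorr(per_state=s, mean=float(s.mean()),
                            min=float(s.min()), max=float(s.max()))
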