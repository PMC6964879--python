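"""Fixed-effects two-stage least squares with cluster-robust inference.

The estimator absorbs state-specific constants by within-demeaning (separately
before/after the survey break when an intercept-shift bridge is active),
replaces the mismeasured regressor(s) by first-stage fitted values, and reports
a sandwich covariance clustered by state.  Residuals and the regression sigma
always use the *original* (not fitted) endogenous columns, the standard 2SLS
convention.  Confidence intervals use normal critical values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .panel import DesignMatrix, ModelSpec, REGIONS

_Z975 = stats.norm.ppf(0.975)


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; message names collinear columns."""


def _collinear_columns(A: np.ndarray, names: list[str], tol: float = 1e-8) -> list[str]:
    """Name columns involved in rank deficiency via pivoted QR."""
    from scipy.linalg import qr

    _, R, piv = qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    thresh = tol * (diag[0] if diag.size else 1.0)
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < thresh]
    return bad


def _solve_ols(A: np.ndarray, b: np.ndarray, names: list[str]) -> np.ndarray:
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        raise RankDeficientError(
            f"rank-deficient design (rank {rank} < {A.shape[1]}); "
            f"collinear columns: {_collinear_columns(A, names)}"
        )
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    return coef


def within_transform(design: DesignMatrix, tol: float = 1e-10) -> DesignMatrix:
    """Demean response, regressors and instruments by fixed-effect group.

    Groups are states, or state x pre/post-break cells when the specification
    bridges the survey break with an intercept shift.  Columns that demean to
    (numerically) zero everywhere are absorbed by the fixed effects: they are
    removed from ``X`` and recorded in ``absorbed`` — never silently dropped.
    """
    counts = design.clusters.value_counts()
    if (counts < 2).any():
        small = list(counts.index[counts < 2])
        raise ValueError(f"states with fewer than 2 rows: {small}")
    # single-row fixed-effect cells (e.g. the first post-break year) demean to
    # zero and contribute nothing to the slopes, but their intercept is still
    # estimated; this is how expanding windows identify the break shift

    def demean(frame):
        return frame - frame.groupby(design.fe_groups).transform("mean")

    Xd = demean(design.X)
    yd = design.y - design.y.groupby(design.fe_groups).transform("mean")
    Zd = demean(design.Z)

    scale = design.X.abs().max().replace(0.0, 1.0)
    absorbed = [c for c in Xd.columns if (Xd[c].abs().max() <= tol * (1.0 + scale[c]))]
    Xd = Xd.drop(columns=absorbed)

    return DesignMatrix(
        y=yd, X=Xd, Z=Zd,
        endog=[e for e in design.endog if e not in absorbed],
        clusters=design.clusters, fe_groups=design.fe_groups,
        regions=design.regions, spec=design.spec,
        absorbed=list(design.absorbed) + absorbed,
    )


# ---------------------------------------------------------------------- #


@dataclass
class FitResult:
    """One fixed-effects (2SLS or OLS) estimation."""

    beta: pd.Series
    vcov: pd.DataFrame
    fixed_effects: pd.Series
    residuals: pd.Series
    sigma: float
    nobs: int
    n_clusters: int
    dof: int
    first_stage: dict
    absorbed: list[str]
    spec: ModelSpec

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov.values)), index=self.beta.index, name="se")

    @property
    def pvalues(self) -> pd.Series:
        z = self.beta / self.se
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.beta.index, name="p")

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        lo, hi = confidence_interval(self.beta.values, self.se.values, level)
        return pd.DataFrame({"low": lo, "high": hi}, index=self.beta.index)

    def predict_row(self, x: pd.Series, fe_group: str) -> float:
        """Linear prediction alpha_g + x'beta for one design row.

        Columns absent from ``beta`` (absorbed or never estimated, e.g.
        post-break slope terms at pre-break origins) contribute zero.
        Unknown fixed-effect groups fall back to the pre-break state effect.
        """
        fe = self.fixed_effects
        if fe_group not in fe.index:
            fe_group = fe_group.split(":")[0]
            if fe_group not in fe.index:
                raise KeyError(f"no fixed effect estimated for group {fe_group!r}")
        xb = float(sum(self.beta[c] * x[c] for c in self.beta.index))
        return float(fe[fe_group]) + xb

    def summary(self) -> str:
        """Structured text report: coefficient, cluster-robust SE, p-value."""
        lines = [f"{'variable':<16}{'coef':>12}{'cluster SE':>12}{'p':>10}"]
        for name in self.beta.index:
            lines.append(f"{name:<16}{self.beta[name]:>12.4g}{self.se[name]:>12.4g}"
                         f"{self.pvalues[name]:>10.3g}")
        lines.append(f"nobs={self.nobs}  clusters={self.n_clusters}  sigma={self.sigma:.4g}")
        if self.absorbed:
            lines.append(f"absorbed columns: {self.absorbed}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.to_dict(),
            "se": self.se.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "sigma": self.sigma,
            "nobs": self.nobs,
            "n_clusters": self.n_clusters,
            "dof": self.dof,
            "absorbed": list(self.absorbed),
            "first_stage": {k: (v.to_dict() if isinstance(v, pd.Series) else v)
                            for k, v in self.first_stage.items()},
            "spec_id": self.spec.spec_id if self.spec is not None else None,
        }


def _cluster_meat(X: np.ndarray, u: np.ndarray, clusters: np.ndarray) -> np.ndarray:
    Xu = X * u[:, None]
    frame = pd.DataFrame(Xu)
    sums = frame.groupby(pd.Series(clusters)).sum().values
    return sums.T @ sums


def _sandwich(Xhat: np.ndarray, u: np.ndarray, clusters: np.ndarray,
              small_sample: bool = True, k_absorbed: int = 0) -> np.ndarray:
    """Cluster sandwich with factor G/(G-1) * (N-1)/(N-K).

    K counts the slope coefficients plus any absorbed fixed-effect intercepts
    (``k_absorbed``), the dof accounting used by panel FE-IV software.
    """
    n, k = Xhat.shape
    groups = pd.unique(clusters)
    G = len(groups)
    if G < 2:
        raise ValueError("cluster-robust covariance requires >= 2 clusters")
    bread = np.linalg.inv(Xhat.T @ Xhat)
    meat = _cluster_meat(Xhat, u, clusters)
    V = bread @ meat @ bread
    if small_sample:
        V *= (G / (G - 1)) * ((n - 1) / (n - k - k_absorbed))
    return V


def fit_2sls(design: DesignMatrix, small_sample: bool = True) -> FitResult:
    """Fixed-effects 2SLS (or within-OLS when no endogenous regressors).

    First stage: each within-transformed endogenous column on the excluded
    instruments plus all exogenous columns (within-transformed).  Second stage:
    OLS of the demeaned response on the instrumented design.  Residuals, sigma
    and the cluster sandwich use the original endogenous columns.
    """
    wd = within_transform(design)
    y = wd.y.values
    X = wd.X.values
    names = list(wd.X.columns)
    n, k = X.shape
    endog = [e for e in wd.endog if e in wd.X.columns]
    clusters = wd.clusters.values
    G = len(pd.unique(clusters))

    first_stage: dict = {}
    Xhat = X.copy()
    if endog:
        Z = wd.Z.values
        if Z.shape[1] < len(endog):
            raise ValueError(
                f"order condition violated: {Z.shape[1]} instruments for {len(endog)} endogenous"
            )
        exog_idx = [i for i, c in enumerate(names) if c not in endog]
        W = np.column_stack([X[:, exog_idx], Z]) if exog_idx else Z
        w_names = [names[i] for i in exog_idx] + list(wd.Z.columns)
        for e in endog:
            j = names.index(e)
            coef = _solve_ols(W, X[:, j], w_names)
            fitted = W @ coef
            Xhat[:, j] = fitted
            fs_resid = X[:, j] - fitted
            # cluster-robust Wald F on the excluded-instrument coefficients
            L = Z.shape[1]
            Vw = _sandwich(W, fs_resid, clusters, small_sample=small_sample,
                           k_absorbed=design.fe_groups.nunique())
            sel = np.arange(len(w_names) - L, len(w_names))
            th = coef[sel]
            F = float(th @ np.linalg.solve(Vw[np.ix_(sel, sel)], th) / L)
            first_stage[e] = {
                "coef": pd.Series(coef, index=w_names),
                "F": F,
                "n_instruments": L,
            }

    beta = _solve_ols(Xhat, y, names)
    u = y - X @ beta            # original endogenous columns
    n_fe = design.fe_groups.nunique()
    dof = n - k - n_fe
    if dof <= 0:
        raise ValueError(f"non-positive residual dof ({dof})")
    sigma = float(np.sqrt(u @ u / dof))

    V = _sandwich(Xhat, u, clusters, small_sample=small_sample, k_absorbed=n_fe)

    # fixed effects on the original scale: group means of y - X beta
    xb_full = design.X[names].values @ beta
    resid_fe = pd.Series(design.y.values - xb_full, index=design.y.index)
    fe = resid_fe.groupby(design.fe_groups).mean()
    resid = resid_fe - fe.reindex(design.fe_groups.values).values

    return FitResult(
        beta=pd.Series(beta, index=names, name="beta"),
        vcov=pd.DataFrame(V, index=names, columns=names),
        fixed_effects=fe.rename("alpha"),
        residuals=resid.rename("resid"),
        sigma=sigma,
        nobs=n,
        n_clusters=G,
        dof=dof,
        first_stage=first_stage,
        absorbed=list(wd.absorbed),
        spec=design.spec,
    )


def cluster_robust_vcov(fit: FitResult, design: DesignMatrix,
                        small_sample: bool = True) -> pd.DataFrame:
    """Recompute the cluster-robust sandwich for ``fit`` on ``design``.

    Sandwich ``(X'X)^-1 (sum_g X_g' u_g u_g' X_g) (X'X)^-1`` over the
    within-transformed, instrumented design, clusters = states, with the
    small-sample factor ``G/(G-1) * (N-1)/(N-K)``.
    """
    wd = within_transform(design)
    names = list(fit.beta.index)
    X = wd.X[names].values
    endog = [e for e in wd.endog if e in names]
    Xhat = X.copy()
    if endog:
        exog_idx = [i for i, c in enumerate(names) if c not in endog]
        W = np.column_stack([X[:, exog_idx], wd.Z.values]) if exog_idx else wd.Z.values
        for e in endog:
            j = names.index(e)
            coef, *_ = np.linalg.lstsq(W, X[:, j], rcond=None)
            Xhat[:, j] = W @ coef
    u = wd.y.values - X @ fit.beta.values
    V = _sandwich(Xhat, u, wd.clusters.values, small_sample=small_sample,
                  k_absorbed=design.fe_groups.nunique())
    return pd.DataFrame(V, index=names, columns=names)


def confidence_interval(estimate, se, level: float = 0.95):
    """Normal-quantile confidence interval ``estimate ± z * se``."""
    estimate = np.asarray(estimate, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se < 0):
        raise ValueError("standard error must be >= 0")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = estimate - z * se, estimate + z * se
    if lo.ndim == 0:
        return float(lo), float(hi)
    return lo, hi


# ---------------------------------------------------------------------- #
# Panel R^2 statistics
# ---------------------------------------------------------------------- #


@dataclass
class R2Stats:
    within: float
    between: float
    total: float
    rho: float
    corr_u_xb: float
    rmse: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sq_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def panel_r2(fit: FitResult, design: DesignMatrix) -> R2Stats:
    """Within/between/total R², error-variance share rho, and corr(u, Xb).

    R² statistics are squared correlations between the linear score and the
    response (demeaned, group means, raw) as panel software conventionally
    reports them; ``rho = sigma_alpha^2 / (sigma_alpha^2 + sigma_e^2)``.
    """
    names = list(fit.beta.index)
    xb = pd.Series(design.X[names].values @ fit.beta.values, index=design.y.index)
    groups = design.fe_groups
    xb_w = xb - xb.groupby(groups).transform("mean")
    y_w = design.y - design.y.groupby(groups).transform("mean")
    # between/total scores include the estimated state effects, so an exact
    # fit scores 1 on all three statistics
    score_m = xb.groupby(groups).mean() + fit.fixed_effects.reindex(
        xb.groupby(groups).mean().index)
    y_m = design.y.groupby(groups).mean()

    # exact fits leave zero within-variation in the residual: report 1, not nan
    if np.allclose(y_w.values, xb_w.values, atol=1e-12):
        within = 1.0
    else:
        within = _sq_corr(xb_w.values, y_w.values)
    sig_a = float(fit.fixed_effects.std(ddof=1)) if len(fit.fixed_effects) > 1 else 0.0
    denom = sig_a ** 2 + fit.sigma ** 2
    rho = sig_a ** 2 / denom if denom > 0 else np.nan
    xb_m = xb.groupby(groups).mean()
    corr = (np.corrcoef(fit.fixed_effects.reindex(xb_m.index), xb_m)[0, 1]
            if len(xb_m) > 1 and np.std(xb_m) > 0 and np.std(fit.fixed_effects) > 0 else np.nan)
    return R2Stats(
        within=within,
        between=_sq_corr(score_m.values, y_m.values) if len(score_m) > 1 else np.nan,
        total=_sq_corr((xb + fit.fixed_effects.reindex(groups.values).values).values,
                       design.y.values),
        rho=rho,
        corr_u_xb=float(corr) if corr is not None else np.nan,
        rmse=fit.sigma,
    )


# ---------------------------------------------------------------------- #
# Regional heterogeneity
# ---------------------------------------------------------------------- #


@dataclass
class HeterogeneityResult:
    per_region: pd.DataFrame       # region x varied regressor elasticities
    f_stat: float
    p_value: float
    pooled_ssr: float
    regional_ssr: float
    groups: list[frozenset]        # sequential grouping of regions
    vary: tuple[str, ...]


def _within_ols_ssr(X: np.ndarray, y: np.ndarray, names: list[str]):
    beta = _solve_ols(X, y, names)
    u = y - X @ beta
    return beta, float(u @ u)


def _interacted(Xw: pd.DataFrame, regions: pd.Series, vary, groups: list[frozenset]):
    """Replace each varied column by one column per region group."""
    cols = {}
    names = []
    for c in Xw.columns:
        if c in vary:
            for grp in groups:
                label = f"{c}@{'+'.join(sorted(grp))}"
                cols[label] = Xw[c].values * regions.isin(grp).values
                names.append(label)
        else:
            cols[c] = Xw[c].values
            names.append(c)
    return pd.DataFrame(cols, index=Xw.index)[names]


def fit_regional(design: DesignMatrix, vary=("prev", "cons"),
                 alpha: float = 0.05) -> HeterogeneityResult:
    """Region-specific elasticities, homogeneity F-test, sequential grouping.

    The varied regressors are interacted with region indicators and the model
    re-estimated by within-OLS; the F statistic compares restricted (pooled)
    and unrestricted residual sums of squares.  Sequential grouping repeatedly
    merges the pair of region groups with the largest equality-test p-value
    while that p-value exceeds ``alpha``.
    """
    vary = tuple(vary)
    wd = within_transform(design)
    missing = [v for v in vary if v not in wd.X.columns]
    if missing:
        raise ValueError(f"varied regressors not in design: {missing}")
    present = sorted(design.regions.unique())
    reg_counts = design.regions.value_counts()
    if (reg_counts < len(vary) + 2).any():
        small = list(reg_counts.index[reg_counts < len(vary) + 2])
        raise ValueError(f"regions with too few observations: {small}")
    y = wd.y.values
    n = len(y)
    n_fe = design.fe_groups.nunique()

    _, ssr_pooled = _within_ols_ssr(wd.X.values, y, list(wd.X.columns))

    full_groups = [frozenset([r]) for r in present]
    Xu = _interacted(wd.X, wd.regions, vary, full_groups)
    beta_u, ssr_u = _within_ols_ssr(Xu.values, y, list(Xu.columns))
    k_u = Xu.shape[1]
    q = (len(present) - 1) * len(vary)
    dof_u = n - k_u - n_fe
    f_stat = ((ssr_pooled - ssr_u) / q) / (ssr_u / dof_u)
    p_value = float(stats.f.sf(f_stat, q, dof_u))

    beta_u = pd.Series(beta_u, index=Xu.columns)
    per_region = pd.DataFrame(
        {v: {r: beta_u[f"{v}@{r}"] for r in present} for v in vary}
    )

    # sequential merging of indistinguishable region groups
    groups = list(full_groups)
    while len(groups) > 1:
        Xg = _interacted(wd.X, wd.regions, vary, groups)
        beta_g, ssr_g = _within_ols_ssr(Xg.values, y, list(Xg.columns))
        dof_g = n - Xg.shape[1] - n_fe
        best_p, best_pair = -1.0, None
        for a, b in combinations(range(len(groups)), 2):
            merged = [g for i, g in enumerate(groups) if i not in (a, b)]
            merged.append(groups[a] | groups[b])
            Xm = _interacted(wd.X, wd.regions, vary, merged)
            _, ssr_m = _within_ols_ssr(Xm.values, y, list(Xm.columns))
            qm = len(vary)
            fm = ((ssr_m - ssr_g) / qm) / (ssr_g / dof_g)
            pm = float(stats.f.sf(max(fm, 0.0), qm, dof_g))
            if pm > best_p:
                best_p, best_pair = pm, (a, b)
        if best_p <= alpha:
            break
        a, b = best_pair
        merged_groups = [g for i, g in enumerate(groups) if i not in (a, b)]
        merged_groups.append(groups[a] | groups[b])
        groups = merged_groups

    return HeterogeneityResult(
        per_region=per_region, f_stat=float(f_stat), p_value=p_value,
        pooled_ssr=ssr_pooled, regional_ssr=ssr_u,
        groups=groups, vary=vary,
    )
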