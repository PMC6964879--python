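"""Specification search: enumeration, forecast loss, Model Confidence Set.

All candidate specifications are scored by one-step-ahead out-of-sample
squared log forecast errors on an identical set of (state, target-year) cells.
The Model Confidence Set (MCS) procedure then eliminates candidates that are
statistically inferior in mean loss at a chosen level, using a moving-block
bootstrap that resamples whole target-years so the cross-state dependence of
forecast errors is preserved.  The survey-break bridging mode is selected the
same way on the post-break window.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ModelSpec, StatePanel
from .forecasting import forecast_metrics, one_step_forecasts, recursive_fit

_EPS = 1e-14


def enumerate_cs_specs(candidates: list[str], base: ModelSpec) -> list[ModelSpec]:
    """One spec per subset of cross-sectional-average candidates (2^k specs).

    Deterministic binary-counter order: bit *i* of the subset mask toggles
    ``candidates[i]``; the empty subset comes first.
    """
    candidates = list(candidates)
    if len(set(candidates)) != len(candidates):
        raise ValueError("duplicate cross-sectional-average candidates")
    specs = []
    for mask in range(2 ** len(candidates)):
        subset = tuple(c for i, c in enumerate(candidates) if mask >> i & 1)
        specs.append(base.with_(cs_averages=subset))
    return specs


@dataclass
class LossTable:
    """Per-cell squared one-step log forecast errors for each candidate."""

    losses: pd.DataFrame             # index (state, target), one column per spec id
    specs: dict[str, ModelSpec]
    failed: dict[str, str] = field(default_factory=dict)

    @property
    def mean_loss(self) -> pd.Series:
        return self.losses.mean(axis=0)

    def rmsfe(self) -> pd.Series:
        return np.sqrt(self.mean_loss)

    def by_year(self) -> pd.DataFrame:
        """Mean loss per target year (rows) and candidate (columns)."""
        return self.losses.groupby(level="target").mean()


def evaluate_specs(panel: StatePanel, specs: list[ModelSpec], base_end: int,
                   eval_start: int, eval_end: int) -> LossTable:
    """Score each spec by recursive one-step forecasts over the window.

    Origins run from ``eval_start - 1`` to ``eval_end - 1`` with the base
    estimation sample ending at ``base_end`` (the first origin must be >=
    ``base_end``).  Cells any candidate cannot forecast are dropped for all
    candidates, so every loss column is computed on the identical cell set.
    Candidates that fail estimation are excluded and recorded with a warning.
    """
    if eval_start - 1 < base_end:
        raise ValueError("eval_start must be > base_end")
    columns: dict[str, pd.Series] = {}
    spec_map: dict[str, ModelSpec] = {}
    failed: dict[str, str] = {}
    for spec in specs:
        sid = spec.spec_id
        if sid in spec_map:
            raise ValueError(f"duplicate spec id {sid}")
        try:
            fits = recursive_fit(panel, spec, eval_start - 1, eval_end - 1)
            fs = one_step_forecasts(fits, panel)
            sq = fs.squared_log_errors()
        except Exception as exc:
            failed[sid] = str(exc)
            warnings.warn(f"spec {sid} failed estimation and is excluded: {exc}")
            continue
        columns[sid] = sq
        spec_map[sid] = spec
    if not columns:
        raise ValueError("all candidate specifications failed")
    losses = pd.DataFrame(columns).dropna(axis=0, how="any")
    losses.index = losses.index.set_names(["state", "target"])
    return LossTable(losses=losses, specs=spec_map, failed=failed)


# ---------------------------------------------------------------------- #
# Model Confidence Set
# ---------------------------------------------------------------------- #


@dataclass
class MCSResult:
    survivors: list[str]
    elimination_order: list[str]     # first eliminated first
    pvalues: pd.Series               # MCS p-value per candidate
    alpha: float
    reps: int
    block: int
    seed: int | None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pvalues"] = self.pvalues.to_dict()
        return d


def _moving_block_indices(T: int, block: int, reps: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Moving-block bootstrap index matrix (reps x T)."""
    block = max(1, min(block, T))
    n_blocks = int(np.ceil(T / block))
    starts = rng.integers(0, T - block + 1, size=(reps, n_blocks))
    idx = (starts[:, :, None] + np.arange(block)[None, None, :]).reshape(reps, -1)
    return idx[:, :T]


def model_confidence_set(losses: LossTable | pd.DataFrame, alpha: float = 0.05,
                         reps: int = 5000, block: int = 2,
                         seed: int | None = None,
                         statistic: str = "Tmax") -> MCSResult:
    """Hansen-style MCS over forecast-loss columns.

    Losses are aggregated to per-target-year means and bootstrapped by
    resampling whole years in moving blocks (cross-state dependence is kept
    inside each year's mean).  With ``statistic="Tmax"`` the test statistic is
    the largest studentized deviation of a candidate's mean loss from the
    current-set average; ``"range"`` uses the full pairwise max-t statistic
    (quadratic in the number of candidates).  Candidates are eliminated while
    equal predictive ability is rejected; each candidate's MCS p-value is the
    running maximum of elimination p-values, so survivor sets are nested in
    ``alpha``.  Exact ties (zero-variance loss differentials) are treated as
    indistinguishable.
    """
    frame = losses.losses if isinstance(losses, LossTable) else losses
    if frame.shape[1] < 1:
        raise ValueError("need at least one candidate")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    Y = frame.groupby(level="target").mean() if frame.index.nlevels > 1 else frame
    Y = Y.to_numpy(dtype=float)
    ids = list(frame.columns)
    T, M = Y.shape

    if M == 1:
        return MCSResult(survivors=ids, elimination_order=[],
                         pvalues=pd.Series({ids[0]: 1.0}), alpha=alpha,
                         reps=reps, block=block, seed=seed)

    rng = np.random.default_rng(seed)
    idx = _moving_block_indices(T, block, reps, rng)
    boot_means = Y[idx].mean(axis=1)            # reps x M
    zeta_full = boot_means - Y.mean(axis=0)     # centered bootstrap deviations

    # run the elimination sequence to completion; MCS p-values are the running
    # max of stage p-values, so the survivor set at any alpha is just
    # {p > alpha} and sets are nested across alpha by construction
    active = list(range(M))
    elim_order: list[str] = []
    stage_ps: list[float] = []
    pvals = np.ones(M)

    while len(active) > 1:
        mean_a = Y[:, active].mean(axis=0)
        zeta = zeta_full[:, active]
        if statistic == "Tmax":
            d = mean_a - mean_a.mean()
            zc = zeta - zeta.mean(axis=1, keepdims=True)
            var = (zc ** 2).mean(axis=0)
            sd = np.sqrt(np.maximum(var, _EPS))
            t_obs = np.where((var <= _EPS) & (np.abs(d) <= 1e-12), 0.0, d / sd)
            T_obs = float(np.max(t_obs))
            T_boot = np.max(np.abs(zc) / sd[None, :], axis=1)
            worst = int(np.argmax(t_obs))
        elif statistic == "range":
            d = mean_a[:, None] - mean_a[None, :]
            dz = zeta[:, :, None] - zeta[:, None, :]
            var = (dz ** 2).mean(axis=0)
            sd = np.sqrt(np.maximum(var, _EPS))
            t_mat = np.where((var <= _EPS) & (np.abs(d) <= 1e-12), 0.0, d / sd)
            T_obs = float(np.max(t_mat))
            T_boot = np.max(np.abs(dz) / sd[None, :, :], axis=(1, 2))
            worst = int(np.argmax(np.max(t_mat, axis=1)))
        else:
            raise ValueError("statistic must be 'Tmax' or 'range'")

        p = float(np.mean(T_boot >= T_obs - 1e-12))
        stage_ps.append(p)
        cand = active[worst]
        pvals[cand] = max(stage_ps)
        elim_order.append(ids[cand])
        active.remove(cand)

    pvals[active[0]] = 1.0  # final survivor is never eliminated
    pseries = pd.Series(pvals, index=ids, name="mcs_pvalue")
    survivors = [c for c in ids if pseries[c] > alpha]
    if not survivors:   # cannot happen (last p-value is 1); defensive
        survivors = [pseries.idxmax()]
    return MCSResult(survivors=survivors, elimination_order=elim_order,
                     pvalues=pseries, alpha=alpha, reps=reps, block=block, seed=seed)


def select_best(mcs: MCSResult, losses: LossTable) -> ModelSpec:
    """Surviving spec with minimal mean loss; ties go to fewer averages."""
    if not mcs.survivors:
        raise ValueError("survivor set is empty")
    mean = losses.mean_loss
    best, best_key = None, None
    for sid in mcs.survivors:
        if sid not in losses.specs:
            continue
        spec = losses.specs[sid]
        key = (round(float(mean[sid]), 15), len(spec.cs_averages))
        if best_key is None or key < best_key:
            best, best_key = spec, key
    return best


# ---------------------------------------------------------------------- #
# Bridging-mode selection
# ---------------------------------------------------------------------- #


@dataclass
class BridgeSelection:
    best_mode: str
    rmsfe: dict[str, float]
    failed: dict[str, str]
    collinearity: dict[str, float]   # condition number of the within design


def select_bridge(panel: StatePanel, spec: ModelSpec,
                  modes=("none", "intercept_shift", "slope_shift", "both"),
                  eval_start: int = 2011, eval_end: int = 2014) -> BridgeSelection:
    """Pick the survey-break bridging mode with lowest post-break RMSFE.

    Each mode is estimated recursively (origins ``eval_start-1`` to
    ``eval_end-1``) and scored by one-step RMSFE over the post-break window.
    Modes failing estimation are excluded with a warning; the condition number
    of each mode's within-transformed design (largest window) is reported so
    collinearity between shift columns and averages is visible.
    """
    if not (spec.break_year <= eval_start <= eval_end):
        raise ValueError("need break_year <= eval_start <= eval_end")
    from .estimate import within_transform
    from .panel import build_design

    rmsfes: dict[str, float] = {}
    failed: dict[str, str] = {}
    cond: dict[str, float] = {}
    for mode in modes:
        mspec = spec.with_(bridge_mode=mode)
        try:
            fits = recursive_fit(panel, mspec, eval_start - 1, eval_end - 1)
            fs = one_step_forecasts(fits, panel)
            rmsfes[mode] = forecast_metrics(fs, per_year=False).rmsfe
            wd = within_transform(build_design(panel, mspec.with_(sample_end=eval_end)))
            X = wd.X.values
            sv = np.linalg.svd(X / np.maximum(np.abs(X).max(axis=0), _EPS),
                               compute_uv=False)
            cond[mode] = float(sv[0] / max(sv[-1], _EPS))
        except Exception as exc:
            failed[mode] = str(exc)
            warnings.warn(f"bridge mode {mode!r} failed and is excluded: {exc}")
    if not rmsfes:
        raise ValueError("all bridging modes failed estimation")
    best = min(rmsfes, key=rmsfes.get)
    return BridgeSelection(best_mode=best, rmsfe=rmsfes, failed=failed,
                           collinearity=cond)
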