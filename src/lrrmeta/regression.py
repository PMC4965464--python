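"""Weighted meta-regression on the lnR scale with Knapp-Hartung inference.

Fits single- or multi-moderator mixed-effects models: REML between-study
variance, weighted least squares with weights 1/(V + tau2), coefficient
variances scaled by the Knapp-Hartung factor (weighted residual sum of
squares over k - p) and t-based tests.  Also provides the derived report
quantities: the raw average slope back-transformation, the R^2 analog,
incremental moderator tests on the complete-case subset, Cook's distance
influence screening, and weighted moderator correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    InsufficientDataError,
    InvalidValueError,
    RankDeficiencyError,
)
from .pooling import _split, estimate_tau2

__all__ = [
    "RegressionFit",
    "InfluenceReport",
    "fit_meta_regression",
    "average_raw_slope",
    "r2_analog",
    "incremental_moderator_test",
    "cooks_distance",
    "weighted_moderator_correlation",
]


@dataclass
class RegressionFit:
    """Coefficients on the lnR scale with Knapp-Hartung inference."""

    moderator_names: list[str]
    intercept_lnr: float
    slopes_lnr: dict[str, float]
    se: np.ndarray  # per coefficient, intercept first
    t_stat: np.ndarray
    p_value: np.ndarray
    tau2: float
    tau2_total: float
    r2_analog: float | None  # percent, or None when tau2_total == 0
    k: int
    i2: float
    p_hetero: float
    kh_scale: float
    beta: np.ndarray = field(repr=False, default=None)
    cov: np.ndarray = field(repr=False, default=None)

    @property
    def df_resid(self) -> int:
        return self.k - len(self.beta)


@dataclass
class InfluenceReport:
    study_ids: list[str]
    cooks_d: np.ndarray
    flagged: np.ndarray  # boolean, D > threshold
    threshold: float


def _design(moderators, names):
    """Build (X without intercept, names) from a dict, 2-D array or frame."""
    if isinstance(moderators, dict):
        names = list(moderators)
        X = np.column_stack([np.asarray(moderators[n], float) for n in names])
    elif isinstance(moderators, pd.DataFrame):
        names = list(moderators.columns)
        X = moderators.to_numpy(float)
    else:
        X = np.asarray(moderators, float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
    if np.isnan(X).any():
        raise InvalidValueError(
            "moderator matrix contains missing values; apply listwise deletion first"
        )
    return X, list(names)


def _check_rank(X_full: np.ndarray, names_full: list[str]) -> None:
    rank = np.linalg.matrix_rank(X_full)
    if rank >= X_full.shape[1]:
        return
    # Identify columns expressible as combinations of the preceding ones.
    bad = []
    for j in range(1, X_full.shape[1]):
        sub = X_full[:, :j]
        coef, *_ = np.linalg.lstsq(sub, X_full[:, j], rcond=None)
        resid = X_full[:, j] - sub @ coef
        scale = np.linalg.norm(X_full[:, j]) or 1.0
        if np.linalg.norm(resid) < 1e-8 * max(1.0, scale):
            bad.append(names_full[j])
    raise RankDeficiencyError(bad or names_full[1:])


def fit_meta_regression(effects, v=None, moderators=None, names=None) -> RegressionFit:
    """Mixed-effects meta-regression with REML tau2 and Knapp-Hartung tests.

    Parameters
    ----------
    effects, v
        Either a list of ``EffectSize`` objects, or an array of lnR values
        plus the aligned variance array.
    moderators
        dict name -> vector, DataFrame, or 2-D array of covariates (no
        intercept column; one is prepended).
    """
    y, v = _split(effects, v)
    if moderators is None:
        raise InvalidValueError("fit_meta_regression requires moderators")
    X0, mod_names = _design(moderators, names)
    if X0.shape[0] != y.size:
        raise InvalidValueError("moderators must align with effects")
    k = y.size
    p = X0.shape[1] + 1
    if k < p + 2:
        raise InsufficientDataError(
            f"need k >= number of coefficients + 2 ({p + 2}), got k = {k}"
        )
    X = np.column_stack([np.ones(k), X0])
    _check_rank(X, ["intercept", *mod_names])

    tau2 = estimate_tau2(y, v, X=X)
    w = 1.0 / (v + tau2)
    XtW = X.T * w
    M = XtW @ X
    Minv = np.linalg.inv(M)
    beta = Minv @ (XtW @ y)
    resid = y - X @ beta

    # Knapp-Hartung: scale the model-based covariance by the weighted
    # residual mean square and use a t reference with k - p df.
    kh_scale = float(np.sum(w * resid**2) / (k - p))
    cov = kh_scale * Minv
    se = np.sqrt(np.diag(cov))
    t_stat = beta / se
    p_value = 2.0 * stats.t.sf(np.abs(t_stat), k - p)

    # Residual heterogeneity about the fixed-effect regression.
    wf = 1.0 / v
    beta_f = np.linalg.solve((X.T * wf) @ X, (X.T * wf) @ y)
    q_e = float(np.sum(wf * (y - X @ beta_f) ** 2))
    df_e = k - p
    i2 = max(0.0, (q_e - df_e)) * 100.0 / q_e if q_e > 0 else 0.0
    p_hetero = float(stats.chi2.sf(q_e, df_e)) if df_e > 0 else 1.0

    tau2_total = estimate_tau2(y, v)  # moderator-free model, same subset
    r2 = r2_analog(tau2, tau2_total)

    return RegressionFit(
        moderator_names=mod_names,
        intercept_lnr=float(beta[0]),
        slopes_lnr={n: float(b) for n, b in zip(mod_names, beta[1:])},
        se=se,
        t_stat=t_stat,
        p_value=p_value,
        tau2=tau2,
        tau2_total=tau2_total,
        r2_analog=r2,
        k=k,
        i2=i2,
        p_hetero=p_hetero,
        kh_scale=kh_scale,
        beta=beta,
        cov=cov,
    )


def average_raw_slope(
    intercept_lnr: float, slope_lnr: float, min_x: float, max_x: float
) -> float:
    """Raw average slope over [min_x, max_x] on the response-ratio scale.

    [exp(slope * max_x + intercept) - exp(slope * min_x + intercept)]
    / (max_x - min_x).
    """
    if max_x <= min_x:
        raise InvalidValueError(
            f"degenerate moderator range: [{min_x}, {max_x}]"
        )
    return (
        math.exp(slope_lnr * max_x + intercept_lnr)
        - math.exp(slope_lnr * min_x + intercept_lnr)
    ) / (max_x - min_x)


def r2_analog(tau2_residual: float, tau2_total: float) -> float | None:
    """Percent of true (between-study) variance explained by the moderators.

    Undefined (``None``) when the moderator-free tau2 is 0; truncated to
    [0, 100] otherwise.
    """
    if tau2_total <= 0:
        return None
    raw = (tau2_total - tau2_residual) / tau2_total * 100.0
    return float(np.clip(raw, 0.0, 100.0))


def incremental_moderator_test(effects, v=None, moderators=None, target: str = "") -> float:
    """p-value for whether ``target`` explains variation beyond the others.

    Knapp-Hartung-adjusted F-type test of the target coefficient in the full
    model (F = t^2 with (1, k - p) df for a single column), on the subset
    with complete data for every moderator in the set.
    """
    if not isinstance(moderators, (dict, pd.DataFrame)):
        raise InvalidValueError("moderators must be a dict or DataFrame of columns")
    names = list(moderators)
    if target not in names:
        raise InvalidValueError(f"target {target!r} not among moderators {names}")
    fit = fit_meta_regression(effects, v, moderators)
    j = fit.moderator_names.index(target)
    f = fit.t_stat[j + 1] ** 2  # +1 skips the intercept
    return float(stats.f.sf(f, 1, fit.df_resid))


def cooks_distance(
    fit: RegressionFit,
    effects,
    v=None,
    moderators=None,
    study_ids=None,
    threshold: float | None = None,
) -> InfluenceReport:
    """Per-study Cook's D for a fitted weighted meta-regression.

    D_i = e_i^2 h_ii / (p * s^2 * (1 - h_ii)^2) with weighted residuals
    e_i = sqrt(w_i) (y_i - x_i beta), leverages from the weighted hat matrix
    and s^2 the Knapp-Hartung scale.  Studies with D above ``threshold``
    (default 4/k) are flagged.
    """
    y, v = _split(effects, v)
    X0, _ = _design(moderators, None)
    X = np.column_stack([np.ones(y.size), X0])
    w = 1.0 / (v + fit.tau2)
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    M = Xw.T @ Xw
    H_diag = np.einsum("ij,jk,ik->i", Xw, np.linalg.inv(M), Xw)
    e = sw * (y - X @ fit.beta)
    p = X.shape[1]
    s2 = fit.kh_scale
    # An (essentially) exact fit has no influential points: both e^2 and s2
    # are at rounding level and their ratio is noise.
    y_scale = float(np.mean(w * y**2)) or 1.0
    if s2 <= 1e-12 * y_scale:
        d = np.zeros_like(e)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = e**2 * H_diag / (p * s2 * (1.0 - H_diag) ** 2)
        d = np.where(np.isfinite(d), d, np.inf)
    if threshold is None:
        threshold = 4.0 / y.size
    ids = (
        [str(s) for s in study_ids]
        if study_ids is not None
        else [str(i) for i in range(y.size)]
    )
    return InfluenceReport(
        study_ids=ids,
        cooks_d=d,
        flagged=d > threshold,
        threshold=threshold,
    )


def weighted_moderator_correlation(
    moderator_df: pd.DataFrame,
    weights,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Weighted Pearson correlations among moderators, pairwise-complete.

    Parameters
    ----------
    moderator_df
        One column per moderator, one row per study; NaN marks missing.
    weights
        Meta-analytic weights, aligned with rows (typically 1/(V + tau2)
        from the intercept-only model).

    Returns
    -------
    (r, p, stars)
        Correlation, two-sided p-value, and significance-star frames.
        Cells with fewer than 3 complete pairs are NaN / blank.
    """
    w_all = np.asarray(weights, float)
    cols = list(moderator_df.columns)
    n = len(cols)
    r_mat = np.full((n, n), np.nan)
    p_mat = np.full((n, n), np.nan)
    for i in range(n):
        r_mat[i, i] = 1.0
        p_mat[i, i] = 0.0
        for j in range(i + 1, n):
            x = moderator_df[cols[i]].to_numpy(float)
            z = moderator_df[cols[j]].to_numpy(float)
            mask = np.isfinite(x) & np.isfinite(z) & np.isfinite(w_all)
            if mask.sum() < 3:
                continue
            xw, zw, w = x[mask], z[mask], w_all[mask]
            wsum = w.sum()
            xc = xw - np.sum(w * xw) / wsum
            zc = zw - np.sum(w * zw) / wsum
            denom = math.sqrt(np.sum(w * xc**2) * np.sum(w * zc**2))
            if denom == 0:
                continue
            r = float(np.sum(w * xc * zc) / denom)
            r = float(np.clip(r, -1.0, 1.0))
            m = int(mask.sum())
            if abs(r) < 1.0:
                t = r * math.sqrt((m - 2) / (1.0 - r**2))
                p = float(2.0 * stats.t.sf(abs(t), m - 2))
            else:
                p = 0.0
            r_mat[i, j] = r_mat[j, i] = r
            p_mat[i, j] = p_mat[j, i] = p

    def star(p):
        if not np.isfinite(p):
            return ""
        if p < 0.001:
            return "***"
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return ""

    r_df = pd.DataFrame(r_mat, index=cols, columns=cols)
    p_df = pd.DataFrame(p_mat, index=cols, columns=cols)
    stars = p_df.map(star)
    return r_df, p_df, stars
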