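"""Random-effects pooling: REML tau^2, summary effects, heterogeneity, subgroups.

All estimators work on the lnR scale with known within-study variances.
``estimate_tau2`` is a Fisher-scoring REML solver that also accepts a fixed
design matrix, so the same engine serves plain pooling (intercept-only),
mixed-effects subgroup models (level indicators) and meta-regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .effects import percent_change as _percent_change
from .exceptions import ConvergenceError, InsufficientDataError, InvalidValueError

__all__ = [
    "SummaryEffect",
    "HeterogeneityStats",
    "SubgroupResult",
    "estimate_tau2",
    "restricted_loglik",
    "pool_effects",
    "heterogeneity",
    "subgroup_analysis",
    "chronology_bin",
    "CHRONOLOGY_BINS",
]

#: Seven closed 5-year publication periods.
CHRONOLOGY_BINS = [
    (1980, 1984),
    (1985, 1989),
    (1990, 1994),
    (1995, 1999),
    (2000, 2004),
    (2005, 2009),
    (2010, 2014),
]


@dataclass
class SummaryEffect:
    """Pooled lnR with normal-theory confidence interval."""

    mu_hat: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    k: int
    percent_change: float


@dataclass
class HeterogeneityStats:
    q_total: float
    df: int
    tau2: float
    i2: float  # percent, in [0, 100)
    p_hetero: float


@dataclass
class SubgroupResult:
    moderator_name: str
    q_between: float
    df_between: int
    p_between: float
    levels: dict[str, SummaryEffect] = field(default_factory=dict)
    common_tau2: float = 0.0
    i2_within: float = 0.0
    p_hetero_within: float = 1.0


def _split(effects, v=None):
    """Accept a list of EffectSize objects or parallel (y, v) arrays."""
    if v is None:
        y = np.asarray([e.lnr for e in effects], dtype=float)
        v = np.asarray([e.variance for e in effects], dtype=float)
    else:
        y = np.asarray(effects, dtype=float)
        v = np.asarray(v, dtype=float)
    if y.shape != v.shape or y.ndim != 1:
        raise InvalidValueError("lnr and variance arrays must be 1-D and aligned")
    if np.any(v <= 0):
        raise InvalidValueError("all within-study variances must be > 0")
    return y, v


def restricted_loglik(tau2: float, y, v, X=None) -> float:
    """Restricted log-likelihood of tau2 given effects and a fixed design."""
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    if X is None:
        X = np.ones((y.size, 1))
    w = 1.0 / (v + tau2)
    XtW = X.T * w
    M = XtW @ X
    beta = np.linalg.solve(M, XtW @ y)
    resid = y - X @ beta
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        return -np.inf
    return -0.5 * (np.sum(np.log(v + tau2)) + logdet + np.sum(w * resid**2))


def _reml_score_info(tau2: float, y, v, X):
    """Score and expected information of the restricted likelihood in tau2."""
    w = 1.0 / (v + tau2)
    XtW = X.T * w
    M = XtW @ X
    A = np.linalg.solve(M, XtW)  # p x k
    beta = A @ y
    resid = y - X @ beta
    py = w * resid  # P y (P = W - W X (X'WX)^-1 X'W)
    # tr(P) = sum(w) - tr((X'WX)^-1 X'W^2 X)
    tr_p = np.sum(w) - np.trace(A * w @ X)
    # tr(P^2) = sum(w^2) - 2 tr((X'WX)^-1 X'W^3 X) + tr(((X'WX)^-1 X'W^2 X)^2)
    B = A * w @ X  # (X'WX)^-1 X'W^2 X
    tr_p2 = np.sum(w**2) - 2.0 * np.trace(A * w**2 @ X) + np.trace(B @ B)
    score = -0.5 * (tr_p - py @ py)
    info = 0.5 * tr_p2
    return score, info


def _dl_start(y, v, X) -> float:
    """Generalized DerSimonian-Laird estimate used to initialize Fisher scoring."""
    w = 1.0 / v
    XtW = X.T * w
    M = XtW @ X
    A = np.linalg.solve(M, XtW)
    resid = y - X @ (A @ y)
    q = np.sum(w * resid**2)
    k, p = X.shape
    c = np.sum(w) - np.trace(A * w @ X)
    if c <= 0:
        return 0.0
    return max(0.0, (q - (k - p)) / c)


def estimate_tau2(
    effects,
    v=None,
    X=None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> float:
    """REML estimate of the between-study variance, truncated at 0.

    Fisher scoring on the restricted likelihood, with step halving when a
    step would decrease the likelihood.  Convergence is declared when
    successive iterates differ by less than ``tol``.

    Raises
    ------
    ConvergenceError
        After ``max_iter`` iterations without convergence; carries the last
        iterate in ``last_iterate``.
    """
    y, v = _split(effects, v)
    k = y.size
    if X is None:
        X = np.ones((k, 1))
    else:
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
    if k < X.shape[1] + 1:
        raise InsufficientDataError(
            f"need at least {X.shape[1] + 1} effects to estimate tau2, got {k}"
        )
    tau2 = _dl_start(y, v, X)
    lo, hi = 0.0, np.inf  # bracket on the score's sign change
    for _ in range(max_iter):
        score, info = _reml_score_info(tau2, y, v, X)
        if tau2 == 0.0 and score <= 0:
            return 0.0  # boundary solution
        if score > 0:
            lo = max(lo, tau2)
        else:
            hi = min(hi, tau2)
        if info > 0:
            cand = tau2 + score / info
        else:
            cand = tau2 * 2.0 + 1e-3 if score > 0 else tau2 / 2.0
        cand = max(cand, 0.0)
        # Fisher scoring can overshoot or oscillate when the expected
        # information misjudges the curvature; once the root is bracketed,
        # fall back to bisection for any step that is not clearly shrinking
        # the bracket.
        if np.isfinite(hi) and (
            not (lo <= cand <= hi) or abs(cand - tau2) > 0.5 * (hi - lo)
        ):
            cand = 0.5 * (lo + hi)
        if abs(cand - tau2) < tol:
            return cand
        tau2 = cand
    raise ConvergenceError(
        f"REML did not converge within {max_iter} iterations",
        last_iterate=tau2,
    )


def pool_effects(effects, v=None, tau2: float = 0.0, ci_level: float = 0.95) -> SummaryEffect:
    """Inverse-variance weighted summary effect with weights 1/(V + tau2).

    Confidence interval and p-value use the normal reference distribution
    (the small-sample t adjustment belongs to the regression setting).
    """
    y, v = _split(effects, v)
    if y.size == 0:
        raise InsufficientDataError("cannot pool an empty effect list")
    if tau2 < 0:
        raise InvalidValueError(f"tau2 must be >= 0, got {tau2}")
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    p = float(2.0 * stats.norm.sf(abs(mu / se)))
    return SummaryEffect(
        mu_hat=mu,
        se=se,
        ci_low=mu - z * se,
        ci_high=mu + z * se,
        p_value=p,
        k=int(y.size),
        percent_change=_percent_change(mu),
    )


def _i2_from_q(q: float, df: int) -> float:
    if q <= 0:
        return 0.0
    return max(0.0, (q - df)) * 100.0 / q


def heterogeneity(effects, v=None) -> HeterogeneityStats:
    """Q / I^2 / p_hetero with fixed-effect weights, plus the REML tau2.

    I^2 = (Q_total - df) x 100 / Q_total, truncated at 0; p_hetero from the
    chi-square distribution with k - 1 degrees of freedom.
    """
    y, v = _split(effects, v)
    k = y.size
    if k < 2:
        raise InsufficientDataError("heterogeneity needs at least 2 effects")
    w = 1.0 / v
    mu_fixed = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu_fixed) ** 2))
    df = k - 1
    return HeterogeneityStats(
        q_total=q,
        df=df,
        tau2=estimate_tau2(y, v),
        i2=_i2_from_q(q, df),
        p_hetero=float(stats.chi2.sf(q, df)),
    )


def subgroup_analysis(effects, v=None, labels=None, moderator_name: str = "subgroup") -> SubgroupResult:
    """Mixed-effects categorical analysis with a common among-study variance.

    The common tau2 is the REML estimate under a fixed-level-effects design
    (each level its own mean).  Per-level summaries reuse that tau2;
    Q_between tests the weighted dispersion of level means around the grand
    mean against chi-square with (levels - 1) degrees of freedom.
    """
    y, v = _split(effects, v)
    if labels is None:
        raise InvalidValueError("subgroup_analysis requires level labels")
    labels = np.asarray(labels)
    if labels.shape != y.shape:
        raise InvalidValueError("labels must align with effects")
    level_names = [str(l) for l in np.unique(labels)]
    if len(level_names) < 2:
        raise InvalidValueError("need at least 2 subgroup levels")
    counts = {name: int(np.sum(labels.astype(str) == name)) for name in level_names}
    empty = [name for name, c in counts.items() if c == 0]
    if empty:
        raise InvalidValueError(f"subgroup levels with zero studies: {empty}")

    # Fixed level effects: one indicator column per level, no intercept.
    X = (labels.astype(str)[:, None] == np.array(level_names)[None, :]).astype(float)
    tau2 = estimate_tau2(y, v, X=X)

    w = 1.0 / (v + tau2)
    levels: dict[str, SummaryEffect] = {}
    level_means = np.empty(len(level_names))
    level_weights = np.empty(len(level_names))
    q_within_fixed = 0.0
    for i, name in enumerate(level_names):
        mask = labels.astype(str) == name
        levels[name] = pool_effects(y[mask], v[mask], tau2)
        level_means[i] = np.sum(w[mask] * y[mask]) / np.sum(w[mask])
        level_weights[i] = np.sum(w[mask])
        wf = 1.0 / v[mask]
        mu_f = np.sum(wf * y[mask]) / np.sum(wf)
        q_within_fixed += float(np.sum(wf * (y[mask] - mu_f) ** 2))

    grand = np.sum(level_weights * level_means) / np.sum(level_weights)
    q_between = float(np.sum(level_weights * (level_means - grand) ** 2))
    df_between = len(level_names) - 1
    df_within = y.size - len(level_names)
    return SubgroupResult(
        moderator_name=moderator_name,
        q_between=q_between,
        df_between=df_between,
        p_between=float(stats.chi2.sf(q_between, df_between)),
        levels=levels,
        common_tau2=tau2,
        i2_within=_i2_from_q(q_within_fixed, df_within),
        p_hetero_within=float(stats.chi2.sf(q_within_fixed, df_within))
        if df_within > 0
        else 1.0,
    )


def chronology_bin(year: int) -> str:
    """Map a publication year to its closed 5-year period label."""
    year = int(year)
    for lo, hi in CHRONOLOGY_BINS:
        if lo <= year <= hi:
            return f"{lo}-{hi}"
    raise InvalidValueError(
        f"year {year} outside the supported span "
        f"[{CHRONOLOGY_BINS[0][0]}, {CHRONOLOGY_BINS[-1][1]}]"
    )
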