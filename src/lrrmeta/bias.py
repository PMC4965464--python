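"""Publication-bias diagnostics and leave-one-out sensitivity analysis."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError
from .pooling import SummaryEffect, _split, estimate_tau2, pool_effects

__all__ = ["FunnelPoint", "SensitivityTrace", "begg_mazumdar", "funnel_data", "leave_one_out"]


@dataclass
class FunnelPoint:
    study_id: str
    lnr: float
    se: float


@dataclass
class SensitivityTrace:
    """Leave-one-out refits of the summary effect, on the ratio scale."""

    table: pd.DataFrame  # omitted_study, mu_hat, ratio, ci_low, ci_high, pct_change
    full: SummaryEffect
    max_abs_change: float  # largest |percent change of the summary ratio|
    most_influential_study: str


def begg_mazumdar(effects, v=None) -> tuple[float, float]:
    """Begg-Mazumdar rank correlation test for funnel asymmetry.

    Kendall's tau (tie-corrected) between the variance-stabilized deviates
    (fixed-effect-centered lnR divided by the conditional standard error)
    and the within-study variances, with the normal-approximation p-value.
    A tau near 0 indicates no tendency for effects to grow as studies shrink.
    """
    y, v = _split(effects, v)
    if y.size < 3:
        raise InsufficientDataError("Begg-Mazumdar needs at least 3 effects")
    w = 1.0 / v
    mu_fixed = np.sum(w * y) / np.sum(w)
    v_star = v - 1.0 / np.sum(w)
    v_star = np.maximum(v_star, 1e-30)
    deviates = (y - mu_fixed) / np.sqrt(v_star)
    res = stats.kendalltau(deviates, v)
    return float(res.statistic), float(res.pvalue)


def funnel_data(effects, v=None, study_ids=None) -> list[FunnelPoint]:
    """One (lnr, se) point per study, ordered by standard error."""
    y, v = _split(effects, v)
    if study_ids is None:
        study_ids = [str(i) for i in range(y.size)]
    points = [
        FunnelPoint(study_id=str(s), lnr=float(a), se=float(math.sqrt(b)))
        for s, a, b in zip(study_ids, y, v)
    ]
    return sorted(points, key=lambda pt: pt.se)


def leave_one_out(effects, v=None, study_ids=None) -> SensitivityTrace:
    """Recompute tau2 and the summary effect omitting each study in turn.

    Changes are reported on the response-ratio scale (exp of the pooled lnR)
    as percent deviations from the full-data summary ratio.
    """
    y, v = _split(effects, v)
    k = y.size
    if k < 2:
        raise InsufficientDataError("leave-one-out needs at least 2 effects")
    if study_ids is None:
        study_ids = [str(i) for i in range(k)]
    tau2_full = estimate_tau2(y, v) if k >= 2 else 0.0
    full = pool_effects(y, v, tau2_full)
    full_ratio = math.exp(full.mu_hat)

    rows = []
    for i in range(k):
        mask = np.ones(k, bool)
        mask[i] = False
        yi, vi = y[mask], v[mask]
        tau2_i = estimate_tau2(yi, vi) if yi.size >= 2 else 0.0
        summ = pool_effects(yi, vi, tau2_i)
        ratio = math.exp(summ.mu_hat)
        rows.append(
            {
                "omitted_study": str(study_ids[i]),
                "mu_hat": summ.mu_hat,
                "ratio": ratio,
                "ci_low": math.exp(summ.ci_low),
                "ci_high": math.exp(summ.ci_high),
                "pct_change_from_full": (ratio - full_ratio) / full_ratio * 100.0,
            }
        )
    table = pd.DataFrame(rows)
    idx = int(table["pct_change_from_full"].abs().idxmax())
    return SensitivityTrace(
        table=table,
        full=full,
        max_abs_change=float(table["pct_change_from_full"].abs().max()),
        most_influential_study=str(table.loc[idx, "omitted_study"]),
    )
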