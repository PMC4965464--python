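"""Per-study effect sizes for paired-treatment response-ratio meta-analysis.

A study contributes the natural-log response ratio of a treatment mean over
its paired control mean.  When dispersion measures are unreported, studies
are weighted by a variance built from sample sizes alone; repeated
measurements within a study (time-points, light levels) are averaged into a
single synthetic score whose variance accounts for the correlation among
time-points.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import (
    InsufficientDataError,
    InvalidValueError,
    UnusableStudyError,
)

__all__ = [
    "Outcome",
    "Dispersion",
    "ModeratorSet",
    "GasExchangeSeries",
    "StudyRecord",
    "EffectSize",
    "compute_lnr",
    "percent_change",
    "floor_adjust",
    "nonparametric_variance",
    "timepoint_variance",
    "aggregate_timepoints",
    "resolve_sample_size",
    "colonization_from_range",
    "estimate_timepoint_correlation",
    "DEFAULT_TIMEPOINT_CORRELATION",
    "DEFAULT_FLOOR_FRACTION",
]

#: Correlation among time-points applied to every study unless overridden.
DEFAULT_TIMEPOINT_CORRELATION = 0.1

#: Values below this fraction of a study's maximum are raised to the floor.
DEFAULT_FLOOR_FRACTION = 0.01


class Outcome(str, enum.Enum):
    """Leaf gas-exchange outcome measured by a study."""

    CER = "CER"  # carbon exchange rate (photosynthesis)
    GS = "GS"  # stomatal conductance
    E = "E"  # transpiration rate


class Dispersion(str, enum.Enum):
    """What dispersion information a study reported alongside its means."""

    NONE = "none"
    LSD_OR_SE = "lsd_or_se"
    FULL = "full"


@dataclass
class ModeratorSet:
    """Quantitative study-level covariates; ``None`` marks a missing value.

    The three ``*_es`` fields are themselves treatment/control response
    ratios (strictly positive); ``colonization_pct`` is on the 0-100 scale.
    """

    colonization_pct: float | None = None
    shoot_dw_es: float | None = None
    leaf_p_es: float | None = None
    nm_leaf_np: float | None = None
    leaf_np_es: float | None = None

    def __post_init__(self) -> None:
        if self.colonization_pct is not None and not (
            0.0 <= self.colonization_pct <= 100.0
        ):
            raise InvalidValueError(
                f"colonization_pct must lie in [0, 100], got {self.colonization_pct}"
            )
        for name in ("shoot_dw_es", "leaf_p_es", "nm_leaf_np", "leaf_np_es"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise InvalidValueError(f"{name} must be > 0 when present, got {value}")

    def as_dict(self) -> dict[str, float | None]:
        return {
            "colonization_pct": self.colonization_pct,
            "shoot_dw_es": self.shoot_dw_es,
            "leaf_p_es": self.leaf_p_es,
            "nm_leaf_np": self.nm_leaf_np,
            "leaf_np_es": self.leaf_np_es,
        }


@dataclass
class GasExchangeSeries:
    """Paired treatment/control means for one outcome, over >= 1 time-points.

    ``time_points`` holds ``(am_mean, nm_mean, label)`` triples in measurement
    order.  Means must be strictly positive once the floor adjustment has been
    applied.
    """

    outcome: Outcome
    time_points: list[tuple[float, float, str]]
    units: str = ""

    def __post_init__(self) -> None:
        if not self.time_points:
            raise InvalidValueError("a series needs at least one time-point")
        self.outcome = Outcome(self.outcome)

    @property
    def m(self) -> int:
        return len(self.time_points)

    def values(self) -> list[float]:
        """All treatment and control means, in time-point order."""
        out: list[float] = []
        for am, nm, _ in self.time_points:
            out.extend((am, nm))
        return out


@dataclass
class StudyRecord:
    """One literature study: series per outcome plus moderators and metadata."""

    study_id: str
    article_id: str
    series: dict[Outcome, GasExchangeSeries]
    n_am: int | None = None
    n_nm: int | None = None
    dispersion_reported: Dispersion = Dispersion.NONE
    moderators: ModeratorSet = field(default_factory=ModeratorSet)
    stress: str = "unstressed"
    year: int | None = None

    def __post_init__(self) -> None:
        self.dispersion_reported = Dispersion(self.dispersion_reported)
        if self.stress not in ("stressed", "unstressed"):
            raise InvalidValueError(
                f"stress must be 'stressed' or 'unstressed', got {self.stress!r}"
            )
        for n in (self.n_am, self.n_nm):
            if n is not None and n < 1:
                raise InvalidValueError(f"sample sizes must be >= 1, got {n}")

    def resolved_sample_sizes(self) -> tuple[int, int]:
        return (
            resolve_sample_size(self.n_am, self.dispersion_reported),
            resolve_sample_size(self.n_nm, self.dispersion_reported),
        )


@dataclass
class EffectSize:
    """A study-level lnR with its variance and time-point provenance."""

    study_id: str
    outcome: Outcome
    lnr: float
    variance: float
    m: int = 1
    weight: float | None = None  # assigned at model-fit time as 1/(V + tau2)

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise InvalidValueError(
                f"effect-size variance must be > 0 (study {self.study_id})"
            )
        if self.m < 1:
            raise InvalidValueError("m must be >= 1")


def compute_lnr(am_mean: float, nm_mean: float, study_id: str | None = None) -> float:
    """Natural-log response ratio ln(am_mean / nm_mean).

    Both means must be strictly positive (the floor adjustment handles zeros
    beforehand).  Antisymmetric: swapping the arguments flips the sign.
    """
    if am_mean <= 0 or nm_mean <= 0:
        where = f" in study {study_id}" if study_id else ""
        raise InvalidValueError(
            f"means must be strictly positive{where}: got ({am_mean}, {nm_mean})"
        )
    return math.log(am_mean / nm_mean)


def percent_change(lnr: float) -> float:
    """Back-transform an lnR to the raw percent change, (exp(lnr) - 1) * 100."""
    return (math.exp(lnr) - 1.0) * 100.0


def floor_adjust(
    values: Sequence[float],
    floor_fraction: float = DEFAULT_FLOOR_FRACTION,
    study_id: str | None = None,
) -> np.ndarray:
    """Floor near-zero measurements at ``floor_fraction`` of the study maximum.

    Negative values are first equated to 0; any value below
    ``floor_fraction * max(values)`` is then raised to exactly that floor.
    The maximum is unchanged, so the operation is idempotent.

    Raises
    ------
    UnusableStudyError
        If no value is strictly positive, the study cannot enter a ratio
        analysis at all.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidValueError("floor_adjust needs a non-empty value list")
    arr = np.where(arr < 0, 0.0, arr)
    top = float(arr.max())
    if top <= 0:
        where = f"study {study_id}" if study_id else "study"
        raise UnusableStudyError(
            f"{where} has no positive measurement; unusable for ratio analysis"
        )
    floor = floor_fraction * top
    return np.where(arr < floor, floor, arr)


def nonparametric_variance(n_am: int, n_nm: int) -> float:
    """Within-study lnR variance from sample sizes alone: (n1 + n2)/(n1 * n2)."""
    if n_am < 1 or n_nm < 1:
        raise InvalidValueError(
            f"sample sizes must be >= 1, got ({n_am}, {n_nm})"
        )
    return (n_am + n_nm) / (n_am * n_nm)


def timepoint_variance(v: float, m: int, r: float) -> float:
    """Variance of the mean of ``m`` correlated time-points: v(1 + (m-1)r)/m."""
    if v <= 0:
        raise InvalidValueError(f"base variance must be > 0, got {v}")
    if m < 1:
        raise InvalidValueError(f"m must be >= 1, got {m}")
    if not 0.0 <= r <= 1.0:
        raise InvalidValueError(f"time-point correlation must lie in [0, 1], got {r}")
    return v * (1.0 + (m - 1) * r) / m


def aggregate_timepoints(
    series: GasExchangeSeries,
    n_am: int,
    n_nm: int,
    r: float = DEFAULT_TIMEPOINT_CORRELATION,
    study_id: str = "",
) -> EffectSize:
    """Collapse a multi-time-point series into one synthetic effect size.

    The lnR is the arithmetic mean of the per-time-point lnR values; the
    variance applies the correlated-time-point formula to the sample-size
    variance.  Assumes the series is already floor-adjusted.
    """
    lnrs = [compute_lnr(am, nm, study_id=study_id) for am, nm, _ in series.time_points]
    v = nonparametric_variance(n_am, n_nm)
    return EffectSize(
        study_id=study_id,
        outcome=series.outcome,
        lnr=float(np.mean(lnrs)),
        variance=timepoint_variance(v, series.m, r),
        m=series.m,
    )


def resolve_sample_size(
    reported_n: int | tuple[int, int] | None,
    dispersion_reported: Dispersion | str = Dispersion.NONE,
) -> int:
    """Resolve a reported sample size to the value used for weighting.

    A range resolves to its smallest value.  A missing sample size resolves
    conservatively: to 2 when an LSD or standard error was at least reported,
    otherwise to 1.
    """
    dispersion = Dispersion(dispersion_reported)
    if reported_n is None:
        return 2 if dispersion is Dispersion.LSD_OR_SE else 1
    if isinstance(reported_n, (tuple, list)):
        n = int(min(reported_n))
    else:
        n = int(reported_n)
    if n < 1:
        raise InvalidValueError(f"reported sample size must be >= 1, got {n}")
    return n


def colonization_from_range(lo: float, hi: float) -> float | None:
    """Midpoint of a reported colonization range, if the range is narrow.

    Only ranges spanning <= 25 percentage points are resolved to their
    midpoint; wider ranges return ``None`` and are flagged for manual entry.
    """
    if not (0.0 <= lo <= hi <= 100.0):
        raise InvalidValueError(
            f"colonization range must satisfy 0 <= lo <= hi <= 100, got ({lo}, {hi})"
        )
    if hi - lo > 25.0:
        return None
    return (lo + hi) / 2.0


def estimate_timepoint_correlation(replicate_series: np.ndarray) -> float:
    """Average pairwise Pearson correlation across time-points.

    Parameters
    ----------
    replicate_series
        2-D array of shape (experimental units, time-points): repeated
        measurements on the same units.

    Returns
    -------
    float
        Mean of the upper-triangle pairwise correlations, truncated to [0, 1].
    """
    data = np.asarray(replicate_series, dtype=float)
    if data.ndim != 2 or data.shape[0] < 3 or data.shape[1] < 2:
        raise InsufficientDataError(
            "need >= 3 experimental units and >= 2 time-points, got shape "
            f"{data.shape}"
        )
    corr = np.corrcoef(data, rowvar=False)
    iu = np.triu_indices_from(corr, k=1)
    pairwise = corr[iu]
    if np.any(~np.isfinite(pairwise)):
        raise InsufficientDataError(
            "a time-point has zero variance across units; correlation undefined"
        )
    return float(np.clip(pairwise.mean(), 0.0, 1.0))
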