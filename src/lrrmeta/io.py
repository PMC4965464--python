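"""Study-table I/O and the table -> effect-size pipeline.

The study table is delimited text with one row per (study x outcome x
time-point).  Missing values are empty fields.  ``build_effect_table``
collapses it to one effect size per (study, outcome) applying, in order:
the per-study floor adjustment, sample-size resolution, per-time-point lnR,
time-point averaging, and the correlated-time-point variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import (
    DEFAULT_FLOOR_FRACTION,
    DEFAULT_TIMEPOINT_CORRELATION,
    Dispersion,
)
from .exceptions import InvalidValueError

logger = logging.getLogger(__name__)

#: Quantitative regression moderators, in report order.
MODERATORS = [
    "colonization_pct",
    "shoot_dw_es",
    "leaf_p_es",
    "nm_leaf_np",
    "leaf_np_es",
]

STUDY_TABLE_COLUMNS = [
    "study_id",
    "article_id",
    "outcome",
    "timepoint_label",
    "am_mean",
    "nm_mean",
    "n_am",
    "n_nm",
    "dispersion_reported",
    *MODERATORS,
    "stress",
    "year",
]

EFFECT_TABLE_COLUMNS = ["study_id", "outcome", "lnr", "variance", "m"]

_VALID_OUTCOMES = {"CER", "GS", "E"}
_VALID_STRESS = {"stressed", "unstressed"}


@dataclass
class PipelineLog:
    """Bookkeeping emitted by :func:`build_effect_table`."""

    n_rows: int = 0
    n_effects: int = 0
    unusable_studies: list[str] = field(default_factory=list)
    floored_values: int = 0
    imputed_n1: int = 0
    imputed_n2: int = 0


def read_study_table(path) -> pd.DataFrame:
    """Read and validate a study-table CSV."""
    df = pd.read_csv(path, dtype={"study_id": str, "article_id": str})
    missing = [c for c in STUDY_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidValueError(f"study table missing columns: {missing}")
    bad_outcome = set(df["outcome"].dropna()) - _VALID_OUTCOMES
    if bad_outcome:
        raise InvalidValueError(f"unknown outcome values: {sorted(bad_outcome)}")
    bad_stress = set(df["stress"].dropna()) - _VALID_STRESS
    if bad_stress:
        raise InvalidValueError(f"unknown stress values: {sorted(bad_stress)}")
    return df


def write_study_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def write_effect_table(df: pd.DataFrame, path) -> None:
    """Emit the normalized per-study effect-size table."""
    cols = [c for c in df.columns if c in EFFECT_TABLE_COLUMNS]
    df[cols].to_csv(path, index=False, float_format="%.6f")


def _resolve_n_column(n: pd.Series, dispersion: pd.Series, log: PipelineLog) -> pd.Series:
    """Vectorized sample-size resolution with imputation counting."""
    out = n.astype(float).copy()
    missing = out.isna()
    se_given = dispersion.eq(Dispersion.LSD_OR_SE.value)
    out[missing & se_given] = 2
    out[missing & ~se_given] = 1
    log.imputed_n2 += int((missing & se_given).sum())
    log.imputed_n1 += int((missing & ~se_given).sum())
    if (out < 1).any():
        bad = n[out < 1].index.tolist()
        raise InvalidValueError(f"sample sizes < 1 at rows {bad}")
    return out


def build_effect_table(
    study_df: pd.DataFrame,
    r: float = DEFAULT_TIMEPOINT_CORRELATION,
    floor_fraction: float = DEFAULT_FLOOR_FRACTION,
) -> tuple[pd.DataFrame, PipelineLog]:
    """Collapse a study table into one row per (study, outcome).

    Returns a frame with ``study_id, outcome, lnr, variance, m`` plus the
    moderator, stress and year columns carried along for downstream analyses,
    and a :class:`PipelineLog` recording exclusions and imputations.

    Studies whose measurements are all <= 0 for an outcome are dropped (they
    cannot form a ratio) and listed in the log.
    """
    if not 0.0 <= r <= 1.0:
        raise InvalidValueError(f"time-point correlation must lie in [0, 1], got {r}")
    log = PipelineLog(n_rows=len(study_df))
    if study_df.empty:
        empty = pd.DataFrame(
            columns=EFFECT_TABLE_COLUMNS + MODERATORS + ["stress", "year"]
        )
        return empty, log

    df = study_df.copy()
    df["am_mean"] = pd.to_numeric(df["am_mean"], errors="coerce")
    df["nm_mean"] = pd.to_numeric(df["nm_mean"], errors="coerce")
    if df[["am_mean", "nm_mean"]].isna().any().any():
        bad = df.index[df[["am_mean", "nm_mean"]].isna().any(axis=1)].tolist()
        raise InvalidValueError(f"non-numeric or missing means at rows {bad}")

    key = ["study_id", "outcome"]
    # Floor adjustment: per (study, outcome), across all treatment and
    # control values of all time-points.
    df[["am_mean", "nm_mean"]] = df[["am_mean", "nm_mean"]].clip(lower=0.0)
    gmax = (
        df[["am_mean", "nm_mean"]]
        .max(axis=1)
        .groupby([df["study_id"], df["outcome"]])
        .transform("max")
    )
    usable = gmax > 0
    if (~usable).any():
        dropped = df.loc[~usable, key].drop_duplicates()
        log.unusable_studies = sorted(
            f"{s}:{o}" for s, o in dropped.itertuples(index=False)
        )
        logger.warning(
            "dropping %d study/outcome groups with no positive value: %s",
            len(log.unusable_studies),
            log.unusable_studies,
        )
        df = df[usable]
        gmax = gmax[usable]
    if df.empty:
        empty = pd.DataFrame(
            columns=EFFECT_TABLE_COLUMNS + MODERATORS + ["stress", "year"]
        )
        return empty, log

    floor = floor_fraction * gmax
    before = df[["am_mean", "nm_mean"]].to_numpy()
    df["am_mean"] = np.maximum(df["am_mean"], floor)
    df["nm_mean"] = np.maximum(df["nm_mean"], floor)
    log.floored_values = int((before < df[["am_mean", "nm_mean"]].to_numpy()).sum())

    df["n_am_resolved"] = _resolve_n_column(df["n_am"], df["dispersion_reported"], log)
    df["n_nm_resolved"] = _resolve_n_column(df["n_nm"], df["dispersion_reported"], log)
    df["lnr_tp"] = np.log(df["am_mean"].to_numpy() / df["nm_mean"].to_numpy())

    grouped = df.groupby(key, sort=True)
    out = grouped.agg(
        lnr=("lnr_tp", "mean"),
        m=("lnr_tp", "size"),
        n_am=("n_am_resolved", "first"),
        n_nm=("n_nm_resolved", "first"),
        **{c: (c, "first") for c in MODERATORS},
        stress=("stress", "first"),
        year=("year", "first"),
    ).reset_index()

    v = (out["n_am"] + out["n_nm"]) / (out["n_am"] * out["n_nm"])
    out["variance"] = v * (1.0 + (out["m"] - 1) * r) / out["m"]
    log.n_effects = len(out)
    cols = EFFECT_TABLE_COLUMNS + ["n_am", "n_nm"] + MODERATORS + ["stress", "year"]
    return out[cols], log
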