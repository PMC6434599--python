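"""Cytokine-table preprocessing and cohort inclusion rules.

Multiplex bead-array measurements come in duplicate wells with per-analyte
detection limits.  The preparation pipeline is fixed and order-sensitive:

    average duplicates -> censor against LLD/ULD -> log10 transform

Values below the lower limit of detection (LLD) are assigned LLD/2; values
above the upper limit (ULD) are assigned ULD + 1000 (on the analyte's native
concentration scale, whatever its units).  Censoring is applied exactly once,
to the replicate mean, and censored cells are flagged so a repeated pass is a
no-op.  Detectability (raw mean at or above the LLD) is kept as a separate
binary endpoint for over-detection-limit frequency comparisons.

The luteal-phase inclusion rule for control subjects requires the plasma
progesterone concentration at the study visit to be at least twice the value
measured two weeks earlier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LutealRecord",
    "average_duplicates",
    "censor_impute",
    "log10_transform",
    "detectability",
    "luteal_inclusion",
    "prepare_analytes",
]

ULD_EXCESS = 1000.0  # added to the ULD for over-range samples, native units


@dataclass
class LutealRecord:
    """Paired progesterone measurements used for luteal-phase confirmation."""

    subject_id: str
    progesterone_study_visit: float
    progesterone_prior_visit: float
    days_since_menses: int | None = None

    def __post_init__(self) -> None:
        if self.progesterone_study_visit <= 0 or self.progesterone_prior_visit <= 0:
            raise ValueError("progesterone concentrations must be > 0")


def average_duplicates(replicates: Sequence[float]) -> float:
    """Arithmetic mean of the replicate wells (the value used downstream)."""
    if len(replicates) == 0:
        raise ValueError("no replicate values")
    return float(np.mean(replicates))


def censor_impute(value: float, lld: float, uld: float) -> float:
    """Detection-limit assignment: < LLD -> LLD/2; > ULD -> ULD + 1000."""
    if lld >= uld:
        raise ValueError(f"LLD ({lld}) must be < ULD ({uld})")
    if not math.isfinite(value):
        raise ValueError("value must be finite")
    if value < lld:
        return lld / 2.0
    if value > uld:
        return uld + ULD_EXCESS
    return float(value)


def log10_transform(value: float) -> float:
    if not value > 0:
        raise ValueError(f"log10 requires a positive value (got {value})")
    return float(np.log10(value))


def detectability(value: float, lld: float) -> bool:
    """Detectable iff the raw mean reaches the lower detection limit.

    The boundary (value exactly at the LLD) counts as detectable, consistent
    with the censoring rule's strict '<' for below-limit assignment.
    """
    return bool(value >= lld)


def luteal_inclusion(rec: LutealRecord, ratio_min: float = 2.0) -> bool:
    """Control-subject inclusion: progesterone ratio study:prior >= ratio_min."""
    if rec.progesterone_prior_visit == 0:
        raise ValueError("prior-visit progesterone is zero; ratio undefined")
    return (rec.progesterone_study_visit / rec.progesterone_prior_visit) >= ratio_min


def prepare_analytes(
    table: pd.DataFrame, limits: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Run the fixed pipeline over a long-format analyte table.

    ``table`` needs columns ``sample_id, group, analyte`` plus replicate
    columns ``rep1, rep2, ...`` (any number >= 1), and either ``lld``/``uld``
    columns or a separate ``limits`` frame (``analyte, lld, uld``).

    Adds: ``mean_value`` (replicate mean), ``censored_value``,
    ``censor_flag`` ('low' | 'high' | '' — marks cells already censored so
    the rule is never applied twice), ``log10_value`` and ``detectable``.
    Idempotent: running it on its own output changes nothing.
    """
    df = table.copy()
    if limits is not None:
        lim = limits.set_index("analyte")
        df = df.drop(columns=[c for c in ("lld", "uld") if c in df], errors="ignore")
        df["lld"] = df["analyte"].map(lim["lld"])
        df["uld"] = df["analyte"].map(lim["uld"])
    if df["lld"].isna().any() or df["uld"].isna().any():
        missing = sorted(df.loc[df["lld"].isna() | df["uld"].isna(), "analyte"].unique())
        raise ValueError(f"no detection limits for analytes: {missing}")
    bad = df.loc[df["lld"] >= df["uld"], "analyte"].unique()
    if len(bad):
        raise ValueError(f"LLD >= ULD for analytes: {sorted(bad)}")

    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if rep_cols:
        df["mean_value"] = df[rep_cols].mean(axis=1)
    elif "mean_value" not in df:
        raise ValueError("need replicate columns rep1.. or a mean_value column")

    already = df["censor_flag"].fillna("").astype(str) if "censor_flag" in df else pd.Series("", index=df.index)
    low = (df["mean_value"] < df["lld"]) & (already == "")
    high = (df["mean_value"] > df["uld"]) & (already == "")
    df["censored_value"] = df["mean_value"].where(~low, df["lld"] / 2.0)
    df["censored_value"] = df["censored_value"].where(~high, df["uld"] + ULD_EXCESS)
    if "censor_flag" in df:
        # already-flagged cells keep their censored value untouched
        df.loc[already != "", "censored_value"] = table.loc[already != "", "censored_value"]
    df["censor_flag"] = np.select([low, high], ["low", "high"], default="")
    if "censor_flag" in table.columns:
        df.loc[already != "", "censor_flag"] = already[already != ""]

    if (df["censored_value"] <= 0).any():
        raise ValueError("non-positive censored value; cannot log10 transform")
    df["log10_value"] = np.log10(df["censored_value"])
    df["detectable"] = df["mean_value"] >= df["lld"]
    return df
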