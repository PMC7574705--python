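"""Cohort ingestion: side selection, derived indices, eligibility filters.

Reads the wide per-participant cohort format produced by
:mod:`leanbone.simulate` (or equivalently structured real exports), applies
the side-selection rule (left side by default, contralateral side when a
prosthesis/fracture flag is set), derives the body-composition indices used
by every downstream analysis (LM, LMI = LM/height^2, LM/BMI, and their
appendicular aggregates), and applies the eligibility rules: exclusion of
glucocorticoid users and complete-case filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import COVARIATE_COLUMNS, LIMBS, VISITS, read_cohort_csv

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisDataset",
    "IngestLog",
    "EmptyDatasetError",
    "select_side",
    "derive_indices",
    "exclude_glucocorticoid",
    "complete_case_filter",
    "ingest_cohort",
    "REGIONS",
    "METRICS",
    "MODEL_COVARIATES",
    "analysis_columns",
]

REGIONS = ("leg", "arm", "app")
METRICS = ("LM", "LMI", "LM_BMI", "BMD")

#: covariates entering the panel models (glucocorticoid use is an exclusion
#: rule, not a covariate; ethnicity is carried but not modelled)
MODEL_COVARIATES = (
    "age",
    "height",
    "weight",
    "smoking",
    "alcohol",
    "diabetes",
    "walking",
    "grip",
    "arthritis",
    "fracture40",
    "hospitalization",
)


class EmptyDatasetError(ValueError):
    """Every row was removed by an eligibility filter."""


@dataclass
class IngestLog:
    """Row counts at each ingestion stage."""

    records_read: int = 0
    glucocorticoid_excluded: int = 0
    incomplete_excluded: int = 0
    retained: int = 0
    side_substitutions: int = 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"read={self.records_read} glucocorticoid={self.glucocorticoid_excluded} "
            f"incomplete={self.incomplete_excluded} retained={self.retained} "
            f"side_substitutions={self.side_substitutions}"
        )


@dataclass
class AnalysisDataset:
    """Side-resolved, index-derived, complete-case analysis table."""

    data: pd.DataFrame
    log: IngestLog = field(default_factory=IngestLog)

    def __len__(self) -> int:
        return len(self.data)


def analysis_columns(
    regions=REGIONS, metrics=METRICS, visits=VISITS
) -> list[str]:
    return [f"{v}_{r}_{m}" for v in visits for r in regions for m in metrics]


def select_side(df: pd.DataFrame, limb: str, visit: str) -> pd.DataFrame:
    """Resolve one limb/visit to a single side per participant.

    The left side is used unless its exclusion flag (prosthesis/fracture)
    is set, in which case the contralateral side is carried forward.  If
    the chosen side's values are missing but the other side is present and
    unflagged, the other side is used.  Rows with no usable side come back
    as NaN and are removed later by the complete-case filter.

    Returns columns ``LM``, ``BMD`` and ``side`` ('L', 'R' or '' when
    unresolved).
    """
    if limb not in LIMBS:
        raise ValueError(f"unknown limb {limb!r}")
    n = len(df)

    def grab(side: str, metric: str) -> np.ndarray:
        col = f"{visit}_{side}_{limb}_{metric}"
        if col in df.columns:
            return df[col].to_numpy(float)
        return np.full(n, np.nan)

    def flag(side: str) -> np.ndarray:
        col = f"{visit}_{side}_{limb}_flag"
        if col in df.columns:
            return df[col].fillna(0).to_numpy() > 0
        return np.zeros(n, bool)

    lm = {s: grab(s, "LM") for s in ("L", "R")}
    bmd = {s: grab(s, "BMD") for s in ("L", "R")}
    flagged = {s: flag(s) for s in ("L", "R")}
    usable = {
        s: ~flagged[s] & np.isfinite(lm[s]) & np.isfinite(bmd[s]) for s in ("L", "R")
    }
    if not (usable["L"] | usable["R"]).any() and n > 0:
        logger.warning("%s %s: no usable side for any participant", visit, limb)
    take_left = usable["L"] & ~flagged["L"]
    take_right = ~take_left & usable["R"]
    out = pd.DataFrame(index=df.index)
    out["LM"] = np.where(take_left, lm["L"], np.where(take_right, lm["R"], np.nan))
    out["BMD"] = np.where(take_left, bmd["L"], np.where(take_right, bmd["R"], np.nan))
    out["side"] = np.where(take_left, "L", np.where(take_right, "R", ""))
    return out


def derive_indices(
    lm_leg: float,
    lm_arm: float,
    bmd_leg: float,
    bmd_arm: float,
    height_cm: float,
    bmi: float,
) -> dict[str, float]:
    """Region-level composition indices from single-side limb measures.

    LMI is lean mass over height squared (kg/m^2, height supplied in cm);
    LM/BMI is lean mass over body-mass index.  Appendicular lean mass
    doubles the single carried side (ALM = 2 * (leg + arm)); appendicular
    BMD is the mean of the two regional densities.
    """
    if height_cm <= 0:
        raise ValueError("height_cm must be > 0")
    if bmi <= 0:
        raise ValueError("bmi must be > 0")
    h2 = (height_cm / 100.0) ** 2
    alm = 2.0 * (lm_leg + lm_arm)
    return {
        "leg_LM": lm_leg,
        "leg_LMI": lm_leg / h2,
        "leg_LM_BMI": lm_leg / bmi,
        "leg_BMD": bmd_leg,
        "arm_LM": lm_arm,
        "arm_LMI": lm_arm / h2,
        "arm_LM_BMI": lm_arm / bmi,
        "arm_BMD": bmd_arm,
        "app_LM": alm,
        "app_LMI": alm / h2,
        "app_LM_BMI": alm / bmi,
        "app_BMD": (bmd_leg + bmd_arm) / 2.0,
    }


def _derive_frame(df: pd.DataFrame, log: IngestLog) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    out["pid"] = df["pid"] if "pid" in df.columns else np.arange(1, len(df) + 1)
    for c in COVARIATE_COLUMNS:
        if c in df.columns:
            out[c] = df[c]
    for v in VISITS:
        height = df[f"{v}_height"].to_numpy(float)
        bmi = df[f"{v}_BMI"].to_numpy(float)
        with np.errstate(invalid="ignore"):
            bad = (height <= 0) | (bmi <= 0)
        if bad.any():
            raise ValueError(
                f"nonpositive height/BMI at {v} for rows {list(df.index[bad][:5])}"
            )
        out[f"{v}_height"] = height
        out[f"{v}_weight"] = df[f"{v}_weight"].to_numpy(float)
        out[f"{v}_BMI"] = bmi
        leg = select_side(df, "leg", v)
        arm = select_side(df, "arm", v)
        log.side_substitutions += int((leg["side"] == "R").sum() + (arm["side"] == "R").sum())
        h2 = (height / 100.0) ** 2
        alm = 2.0 * (leg["LM"].to_numpy() + arm["LM"].to_numpy())
        for region, lm, bmd in (
            ("leg", leg["LM"].to_numpy(), leg["BMD"].to_numpy()),
            ("arm", arm["LM"].to_numpy(), arm["BMD"].to_numpy()),
            ("app", alm, (leg["BMD"].to_numpy() + arm["BMD"].to_numpy()) / 2.0),
        ):
            out[f"{v}_{region}_LM"] = lm
            out[f"{v}_{region}_LMI"] = lm / h2
            out[f"{v}_{region}_LM_BMI"] = lm / bmi
            out[f"{v}_{region}_BMD"] = bmd
    return out


def exclude_glucocorticoid(df: pd.DataFrame, log: IngestLog | None = None) -> pd.DataFrame:
    """Drop participants reporting glucocorticoid use (counted, logged)."""
    if "glucocorticoid" not in df.columns:
        raise ValueError("dataset has no 'glucocorticoid' flag column")
    mask = df["glucocorticoid"].fillna(0).astype(float) > 0
    n_excl = int(mask.sum())
    if log is not None:
        log.glucocorticoid_excluded = n_excl
    if n_excl:
        logger.info("excluding %d glucocorticoid user(s)", n_excl)
    out = df.loc[~mask]
    if out.empty:
        raise EmptyDatasetError("all rows excluded by the glucocorticoid rule")
    return out


def complete_case_filter(
    df: pd.DataFrame,
    required: list[str],
    log: IngestLog | None = None,
) -> pd.DataFrame:
    """Retain rows with every required variable present; log the counts."""
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"required variables absent from dataset: {missing_cols}")
    ok = df[required].notna().all(axis=1)
    n_dropped = int((~ok).sum())
    if log is not None:
        log.incomplete_excluded = n_dropped
        log.retained = int(ok.sum())
    out = df.loc[ok]
    if out.empty:
        raise EmptyDatasetError(
            f"no rows with complete data on the {len(required)} required variables"
        )
    return out


def ingest_cohort(
    source,
    required: list[str] | None = None,
) -> AnalysisDataset:
    """Full ingestion pipeline: read -> exclude -> side-resolve -> derive -> filter.

    ``source`` is a cohort DataFrame or a CSV path.  ``required`` defaults
    to every derived analysis column at all three visits plus the model
    covariates.
    """
    df = read_cohort_csv(source) if not isinstance(source, pd.DataFrame) else source
    log = IngestLog(records_read=len(df))
    df = exclude_glucocorticoid(df, log)
    derived = _derive_frame(df, log)
    if required is None:
        # height/weight covariates refer to baseline values
        derived = derived.assign(height=derived["V0_height"], weight=derived["V0_weight"])
        required = analysis_columns() + [c for c in MODEL_COVARIATES if c in derived.columns]
    else:
        if "height" in required and "height" not in derived.columns:
            derived = derived.assign(height=derived["V0_height"], weight=derived["V0_weight"])
    filtered = complete_case_filter(derived, required, log)
    return AnalysisDataset(data=filtered.reset_index(drop=True), log=log)
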