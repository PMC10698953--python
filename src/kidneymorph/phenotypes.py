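"""Phenotype engineering: CKD-EPI eGFR, disease flags, covariate recoding, and
the cohort quality-control cascade.

The eGFR is the 2009 CKD-EPI creatinine equation,

    eGFR = 141 * min(Scr/kappa, 1)^alpha * max(Scr/kappa, 1)^-1.209
           * 0.993^Age * [1.018 if female] * [1.159 if black]

with kappa = 0.7 (F) / 0.9 (M) and alpha = -0.329 (F) / -0.411 (M), Scr in
mg/dL.  CKD is eGFR < 60 ml/min/1.73 m^2 or a diagnosis code; hypertension is
medication, diagnosis, or blood pressure >= 140/90 mmHg.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "egfr_ckd_epi",
    "convert_creatinine",
    "classify_ckd",
    "classify_hypertension",
    "code_covariates",
    "qc_filter",
    "UMOL_PER_MGDL",
]

UMOL_PER_MGDL = 88.42  # creatinine: 1 mg/dL = 88.42 umol/L


def egfr_ckd_epi(scr_mg_dl, age_years, female, black=False):
    """CKD-EPI 2009 estimated glomerular filtration rate (ml/min/1.73 m^2).

    Vectorised over all arguments; continuous at Scr = kappa because both
    power terms equal 1 there.
    """
    scr = np.asarray(scr_mg_dl, float)
    age = np.asarray(age_years, float)
    female = np.asarray(female, bool)
    black = np.asarray(black, bool)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be positive")
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    ratio = scr / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993**age
        * np.where(female, 1.018, 1.0)
        * np.where(black, 1.159, 1.0)
    )
    return egfr if egfr.ndim else float(egfr)


def convert_creatinine(value, unit: str):
    """Convert serum creatinine to mg/dL from an explicit unit tag.

    The unit is never guessed — a silent umol/mg mix-up would shift eGFR by
    orders of magnitude.
    """
    value = np.asarray(value, float)
    if unit == "umol_L":
        out = value / UMOL_PER_MGDL
    elif unit == "mg_dL":
        out = value
    else:
        raise ValueError(f"unknown creatinine unit {unit!r} (use 'umol_L' or 'mg_dL')")
    return out if out.ndim else float(out)


def classify_ckd(egfr, diagnosis_code_flag):
    """CKD flag: eGFR strictly below 60 ml/min/1.73 m^2 OR a diagnosis code."""
    egfr = np.asarray(egfr, float)
    code = np.asarray(diagnosis_code_flag, bool)
    out = ((egfr < 60.0) | code).astype(int)
    return out if out.ndim else int(out)


def classify_hypertension(medication_flag, diagnosis_flag, sbp, dbp):
    """Hypertension: medication OR diagnosis OR SBP >= 140 OR DBP >= 90 mmHg."""
    med = np.asarray(medication_flag, bool)
    dia = np.asarray(diagnosis_flag, bool)
    sbp = np.asarray(sbp, float)
    dbp = np.asarray(dbp, float)
    out = (med | dia | (sbp >= 140.0) | (dbp >= 90.0)).astype(int)
    return out if out.ndim else int(out)


def code_covariates(raw: pd.DataFrame) -> pd.DataFrame:
    """Recode questionnaire-style columns to the model's 0/1 and ratio forms.

    - alcohol_frequency: 1 for "Daily or almost daily", else 0
    - smoking_status: 1 for "Current", 0 for "Previous"/"Never"
    - ethnicity: 0 for "White", 1 for any other background
    - whr = waist / hip where circumferences are present
    """
    out = raw.copy()
    if "alcohol_frequency" in out:
        out["alcohol_daily"] = (
            out["alcohol_frequency"].astype(str).str.strip() == "Daily or almost daily"
        ).astype(int)
    if "smoking_status" in out:
        out["smoker_current"] = (
            out["smoking_status"].astype(str).str.strip() == "Current"
        ).astype(int)
    if "ethnicity" in out:
        out["ethnicity_nonwhite"] = (
            out["ethnicity"].astype(str).str.strip() != "White"
        ).astype(int)
    if "waist_cm" in out and "hip_cm" in out:
        out["whr"] = out["waist_cm"].astype(float) / out["hip_cm"].astype(float)
    return out


def qc_filter(
    cohort: pd.DataFrame,
    covariate_columns: list[str],
    volume_columns: list[str] = ("kidney_volume_left_ml", "kidney_volume_right_ml"),
    min_volume_ml: float = 30.0,
    s2s: np.ndarray | None = None,
    outlier_quantiles: tuple[float, float] = (0.001, 0.999),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Quality-control cascade.

    Order matters for the exclusion tally: (1) rows missing any required
    covariate, then (2) among the remainder, rows where either kidney volume
    is below ``min_volume_ml`` — one under-covered kidney excludes the
    participant even if the other kidney has full coverage.  S2S values
    outside the extreme quantiles only set an ``s2s_outlier`` flag; they are
    never excluded.  Returns (kept rows, tally).
    """
    volume_columns = [c for c in volume_columns if c in cohort.columns]
    missing = cohort[covariate_columns].isna().any(axis=1)
    remainder = cohort.loc[~missing]
    low = pd.Series(False, index=remainder.index)
    for c in volume_columns:
        low |= remainder[c] < min_volume_ml
    kept = remainder.loc[~low].copy()
    tally = {
        "missing_covariates": int(missing.sum()),
        "low_volume": int(low.sum()),
        "kept": len(kept),
        "input": len(cohort),
    }
    kept["s2s_outlier"] = 0
    if s2s is not None:
        lo, hi = np.quantile(s2s, outlier_quantiles)
        row_flag = ((s2s < lo) | (s2s > hi)).any(axis=1)
        flags = pd.Series(row_flag, index=cohort.index[: len(row_flag)])
        kept["s2s_outlier"] = flags.reindex(kept.index).fillna(False).astype(int)
    return kept, tally
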