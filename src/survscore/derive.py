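"""Metabolic-syndrome classification and derived blood-count ratios.

Component definitions (all thresholds inclusive except the strict HDLC cut):

* obesity:        BMI >= 25 kg/m^2
* hyperglycemia:  fasting glucose >= 6.1 mmol/L, or 2-h glucose >= 7.8 mmol/L,
                  or previously diagnosed diabetes
* hypertension:   SBP >= 140 or DBP >= 90 mm Hg, or antihypertensive therapy
* dyslipidemia:   triglycerides >= 1.7 mmol/L, or HDLC < 0.9 (male) /
                  < 1.0 (female) mmol/L

Metabolic syndrome = at least three positive components.  A missing 2-h
glucose is treated as non-qualifying (it is one arm of an "or"), never as a
missing-data error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingDataError

__all__ = [
    "MetabolicProfile",
    "MetabolicStatus",
    "BloodRatios",
    "classify_metabolic",
    "derive_ratios",
    "add_metabolic_columns",
    "add_ratio_columns",
    "add_derived_columns",
]

BMI_CUT = 25.0
FBG_CUT = 6.1
G2H_CUT = 7.8
SBP_CUT = 140.0
DBP_CUT = 90.0
TG_CUT = 1.7
HDLC_CUT = {"male": 0.9, "female": 1.0}


@dataclass(frozen=True)
class MetabolicProfile:
    bmi: float
    fasting_glucose: float
    sbp: float
    dbp: float
    triglycerides: float
    hdlc: float
    sex: str
    glucose_2h: float | None = None
    diabetes_diagnosed: bool = False
    antihypertensive: bool = False


@dataclass(frozen=True)
class MetabolicStatus:
    obesity: bool
    hyperglycemia: bool
    hypertension: bool
    dyslipidemia: bool

    @property
    def n_components(self) -> int:
        return int(self.obesity) + int(self.hyperglycemia) + int(self.hypertension) + int(self.dyslipidemia)

    @property
    def metsyn(self) -> bool:
        return self.n_components >= 3


@dataclass(frozen=True)
class BloodRatios:
    """Derived blood-count ratios; an undefined ratio (zero denominator) is None."""

    nlr: float | None
    plr: float | None
    lmr: float | None
    mrr: float | None


def _require(profile: MetabolicProfile, name: str) -> float:
    value = getattr(profile, name)
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise MissingDataError(f"required measurement missing: {name!r}")
    return value


def classify_metabolic(profile: MetabolicProfile) -> MetabolicStatus:
    """Classify one subject's metabolic-syndrome components."""
    if profile.sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {profile.sex!r}")
    bmi = _require(profile, "bmi")
    fbg = _require(profile, "fasting_glucose")
    sbp = _require(profile, "sbp")
    dbp = _require(profile, "dbp")
    tg = _require(profile, "triglycerides")
    hdlc = _require(profile, "hdlc")
    g2h = profile.glucose_2h
    g2h_high = g2h is not None and not math.isnan(g2h) and g2h >= G2H_CUT
    return MetabolicStatus(
        obesity=bmi >= BMI_CUT,
        hyperglycemia=fbg >= FBG_CUT or g2h_high or bool(profile.diabetes_diagnosed),
        hypertension=sbp >= SBP_CUT or dbp >= DBP_CUT or bool(profile.antihypertensive),
        dyslipidemia=tg >= TG_CUT or hdlc < HDLC_CUT[profile.sex],
    )


def derive_ratios(neutrophil: float, lymphocyte: float, monocyte: float,
                  platelet: float, rbc: float) -> BloodRatios:
    """NLR, PLR, LMR, MRR; a ratio with a zero denominator comes back None."""
    for name, v in [("neutrophil", neutrophil), ("lymphocyte", lymphocyte),
                    ("monocyte", monocyte), ("platelet", platelet), ("rbc", rbc)]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return BloodRatios(
        nlr=neutrophil / lymphocyte if lymphocyte > 0 else None,
        plr=platelet / lymphocyte if lymphocyte > 0 else None,
        lmr=lymphocyte / monocyte if monocyte > 0 else None,
        mrr=monocyte / rbc if rbc > 0 else None,
    )


_REQUIRED_METABOLIC = ["bmi", "fasting_glucose", "sbp", "dbp", "triglycerides", "hdlc", "sex"]


def add_metabolic_columns(cohort: pd.DataFrame, missing: str = "raise") -> pd.DataFrame:
    """Vectorized metabolic classification over a cohort table.

    Adds obesity, hyperglycemia, hypertension, dyslipidemia, n_components and
    metabolic_syndrome columns (0/1 ints).  ``missing`` policy for required
    measurements: ``"raise"`` (default, complete-case contract — errors naming
    the first incomplete field) or ``"drop"`` (incomplete rows removed).
    """
    df = cohort.copy()
    if len(df) == 0:
        for col in ("obesity", "hyperglycemia", "hypertension", "dyslipidemia",
                    "n_components", "metabolic_syndrome"):
            df[col] = pd.Series(dtype=int)
        return df
    for col in _REQUIRED_METABOLIC:
        if col not in df.columns:
            raise MissingDataError(f"required column missing: {col!r}")
        bad = df[col].isna()
        if bad.any():
            if missing == "raise":
                raise MissingDataError(
                    f"required measurement missing: {col!r} "
                    f"({int(bad.sum())} subjects, first id "
                    f"{df.loc[bad, 'id'].iloc[0] if 'id' in df else bad.idxmax()})"
                )
            if missing == "drop":
                df = df.loc[~bad]
            else:
                raise ValueError(f"unknown missing policy: {missing!r}")

    male = df["sex"] == "male"
    g2h = df["glucose_2h"] if "glucose_2h" in df else pd.Series(np.nan, index=df.index)
    diab = df.get("diabetes_diagnosed", pd.Series(0, index=df.index)).fillna(0).astype(bool)
    anti = df.get("antihypertensive", pd.Series(0, index=df.index)).fillna(0).astype(bool)

    obesity = df["bmi"] >= BMI_CUT
    hyperglycemia = (df["fasting_glucose"] >= FBG_CUT) | (g2h.fillna(-np.inf) >= G2H_CUT) | diab
    hypertension = (df["sbp"] >= SBP_CUT) | (df["dbp"] >= DBP_CUT) | anti
    hdlc_thr = np.where(male, HDLC_CUT["male"], HDLC_CUT["female"])
    dyslipidemia = (df["triglycerides"] >= TG_CUT) | (df["hdlc"] < hdlc_thr)

    df["obesity"] = obesity.astype(int)
    df["hyperglycemia"] = hyperglycemia.astype(int)
    df["hypertension"] = hypertension.astype(int)
    df["dyslipidemia"] = dyslipidemia.astype(int)
    df["n_components"] = (df["obesity"] + df["hyperglycemia"]
                          + df["hypertension"] + df["dyslipidemia"])
    df["metabolic_syndrome"] = (df["n_components"] >= 3).astype(int)
    return df


def add_ratio_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add nlr, plr, lmr, mrr columns (NaN where the denominator is zero)."""
    df = cohort.copy()
    if len(df) == 0:
        for col in ("nlr", "plr", "lmr", "mrr"):
            df[col] = pd.Series(dtype=float)
        return df
    with np.errstate(divide="ignore", invalid="ignore"):
        lymph = df["lymphocyte"].to_numpy(float)
        mono = df["monocyte"].to_numpy(float)
        rbc = df["rbc"].to_numpy(float)
        df["nlr"] = np.where(lymph > 0, df["neutrophil"] / lymph, np.nan)
        df["plr"] = np.where(lymph > 0, df["platelet"] / lymph, np.nan)
        df["lmr"] = np.where(mono > 0, lymph / mono, np.nan)
        df["mrr"] = np.where(rbc > 0, mono / rbc, np.nan)
    return df


def add_derived_columns(cohort: pd.DataFrame, missing: str = "raise") -> pd.DataFrame:
    """Metabolic classification plus blood ratios in one pass."""
    return add_ratio_columns(add_metabolic_columns(cohort, missing=missing))
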