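"""Cohort table schema: canonical column names, coded levels and validation.

The same flat table is the currency of every stage of the pipeline.  The
authoritative column dictionary ships as ``data/cohort_schema.tsv``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import SchemaError

#: canonical column order of a raw cohort table
COHORT_COLUMNS = [
    "id",
    "age",
    "sex",
    "drinking",
    "family_history",
    "bmi",
    "fasting_glucose",
    "glucose_2h",
    "diabetes_diagnosed",
    "sbp",
    "dbp",
    "antihypertensive",
    "triglycerides",
    "hdlc",
    "neutrophil",
    "lymphocyte",
    "monocyte",
    "eosinophil",
    "basophil",
    "wbc",
    "rbc",
    "hemoglobin",
    "rdw",
    "platelet",
    "tnm_stage",
    "invasion_depth",
    "n_category",
    "distant_metastasis",
    "lauren_type",
    "embolus",
    "tumor_size",
    "n_positive_nodes",
    "smoking",
    "time_months",
    "event",
]

#: columns added by :mod:`survscore.derive`
DERIVED_COLUMNS = [
    "obesity",
    "hyperglycemia",
    "hypertension",
    "dyslipidemia",
    "n_components",
    "metabolic_syndrome",
    "nlr",
    "plr",
    "lmr",
    "mrr",
]

#: coded levels of the categorical columns
CATEGORICAL_LEVELS = {
    "sex": ["male", "female"],
    "tnm_stage": ["I/II", "III/IV"],
    "invasion_depth": ["T1/T2", "T3/T4"],
    "n_category": ["N0", "N1", "N2", "N3"],
    "lauren_type": ["intestinal", "diffuse"],
    "smoking": ["never", "ever"],
}

#: 0/1 flag columns
FLAG_COLUMNS = [
    "drinking",
    "family_history",
    "diabetes_diagnosed",
    "antihypertensive",
    "distant_metastasis",
    "embolus",
    "event",
]


def schema_table() -> pd.DataFrame:
    """Return the shipped column dictionary as a data frame."""
    with resources.files("survscore").joinpath("data/cohort_schema.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def validate_cohort(df: pd.DataFrame, required: list[str] | None = None) -> None:
    """Validate a cohort table against the schema.

    Raises :class:`SchemaError` naming the first offending column.
    """
    required = COHORT_COLUMNS if required is None else required
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    if len(df) == 0:
        return
    for col, levels in CATEGORICAL_LEVELS.items():
        if col in df.columns:
            bad = set(df[col].dropna().unique()) - set(levels)
            if bad:
                raise SchemaError(f"column {col!r} has unknown levels: {sorted(bad)}")
    for col in FLAG_COLUMNS:
        if col in df.columns:
            vals = set(pd.unique(df[col].dropna()))
            if not vals <= {0, 1, 0.0, 1.0, True, False}:
                raise SchemaError(f"flag column {col!r} must be coded 0/1")
    if "time_months" in df.columns and (df["time_months"] <= 0).any():
        raise SchemaError("column 'time_months' must be strictly positive")


def read_cohort_csv(path, validate: bool = True) -> pd.DataFrame:
    """Read a cohort CSV (``#`` comment lines allowed) and optionally validate."""
    df = pd.read_csv(path, comment="#")
    if validate:
        validate_cohort(df, required=[c for c in COHORT_COLUMNS if c in df.columns])
    return df
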