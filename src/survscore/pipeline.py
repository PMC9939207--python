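"""Configuration-driven orchestration: simulate/load -> derive -> match ->
interaction -> score -> validate, with reproducible file outputs.

All outputs are deterministic functions of the configuration (explicit seeds
everywhere); every output table carries the config hash and seeds in ``#``
header lines, and JSON outputs carry them under ``"_meta"``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._schema import read_cohort_csv, validate_cohort
from .config import read_kv_config
from .derive import add_derived_columns
from .errors import ConfigError, SchemaError
from .interaction import additive_measures, joint_hrs, stratum_hrs, z_interaction
from .propensity import balance_smd, encode_treatment, fit_propensity, match_nearest
from .scoring import (build_score_table, categorize, group_by_quantiles,
                      score_mortality_hr, total_scores, tree_cutoffs)
from .simulate import SimConfig, generate_cohort
from .validation import (ValidationReport, cv_auroc, hosmer_lemeshow,
                         logistic_recalibration)

__all__ = ["AnalysisConfig", "run_pipeline"]

#: factors entering the default score (categorical / flag / tree-cut continuous)
DEFAULT_FACTORS = [
    "tnm_stage", "invasion_depth", "n_category", "distant_metastasis",
    "lauren_type", "embolus", "tumor_size", "n_positive_nodes", "wbc",
    "hemoglobin", "nlr", "plr", "metabolic_syndrome",
]
CATEGORICAL_FACTORS = {"tnm_stage", "invasion_depth", "n_category", "lauren_type"}
FLAG_FACTORS = {"distant_metastasis", "embolus", "metabolic_syndrome"}
#: Table-2-style stratified covariates reported in the interaction output
DEFAULT_STRATIFIED = ["metabolic_syndrome", "hyperglycemia", "hypertension",
                      "obesity", "dyslipidemia"]


@dataclass
class AnalysisConfig:
    input_csv: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    adjust: list = field(default_factory=lambda: ["age", "male", "drinking", "bmi", "family_history"])
    missing_policy: str = "raise"
    caliper: float | None = 0.2
    match_seed: int = 0
    factors: list = field(default_factory=lambda: list(DEFAULT_FACTORS))
    horizon: float = 173.0
    tree_max_leaves: int = 3
    tree_min_leaf: int = 20
    tree_alpha: float = 0.05
    tree_max_candidates: int | None = 128
    quantile_probs: tuple = (0.25, 0.75)
    score_on: str = "matched"  # or "full"
    cv_k: int = 10
    cv_seed: int = 0
    n_boot: int = 2000
    out_dir: str = "survscore_out"

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        raw = read_kv_config(path)
        sim_kwargs = {}
        kwargs = {}
        known = {f.name for f in fields(cls)}
        for key, val in raw.items():
            if key.startswith("sim."):
                sim_kwargs[key[4:]] = val
            elif key in known:
                kwargs[key] = val
            else:
                raise ConfigError(f"unknown configuration key: {key!r}")
        if "factors" in kwargs and isinstance(kwargs["factors"], str):
            kwargs["factors"] = [kwargs["factors"]]
        if "adjust" in kwargs and isinstance(kwargs["adjust"], str):
            kwargs["adjust"] = [kwargs["adjust"]]
        if "quantile_probs" in kwargs:
            kwargs["quantile_probs"] = tuple(kwargs["quantile_probs"])
        cfg = cls(**kwargs)
        if sim_kwargs:
            cfg.sim = SimConfig(**sim_kwargs)
        return cfg

    def echo(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "sim":
                for sf in fields(SimConfig):
                    lines.append(f"sim.{sf.name} = {getattr(v, sf.name)}")
            elif isinstance(v, (list, tuple)):
                lines.append(f"{f.name} = {','.join(str(i) for i in v)}")
            else:
                lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    def sha256(self) -> str:
        return hashlib.sha256(self.echo().encode()).hexdigest()[:16]


def _prepare_cohort(config: AnalysisConfig) -> pd.DataFrame:
    if config.input_csv is not None:
        cohort = read_cohort_csv(config.input_csv, validate=False)
        validate_cohort(cohort, required=["id", "age", "sex", "smoking",
                                          "time_months", "event"])
    else:
        cohort = generate_cohort(config.sim)
    cohort = add_derived_columns(cohort, missing=config.missing_policy)
    cohort["male"] = (cohort["sex"] == "male").astype(int)
    cohort["smoke"] = encode_treatment(cohort["smoking"])
    return cohort


def _factor_labels(df: pd.DataFrame, factors: list, cutoffs: dict) -> pd.DataFrame:
    """One label column per factor, aligned with ``df``."""
    out = {}
    for f in factors:
        if f in CATEGORICAL_FACTORS:
            out[f] = df[f].astype(str)
        elif f in FLAG_FACTORS:
            out[f] = df[f].map({0: "no", 1: "yes"}).astype(str)
        else:
            out[f] = categorize(df[f].to_numpy(float), cutoffs[f]).set_axis(df.index)
    return pd.DataFrame(out, index=df.index)


def _score_builder(config: AnalysisConfig):
    """Return builder(train) -> scorer(test) re-running the full construction."""

    def builder(train: pd.DataFrame):
        cutoffs = {
            f: tree_cutoffs(train["time_months"], train["event"],
                            train[f].to_numpy(float), variable=f,
                            max_leaves=config.tree_max_leaves,
                            min_leaf=config.tree_min_leaf,
                            alpha=config.tree_alpha,
                            max_candidates=config.tree_max_candidates)
            for f in config.factors
            if f not in CATEGORICAL_FACTORS and f not in FLAG_FACTORS
        }
        labels = _factor_labels(train, config.factors, cutoffs)
        table = build_score_table(train, {f: labels[f] for f in config.factors},
                                  horizon=config.horizon)
        fallback = {f: int(round(sub["score"].mean()))
                    for f, sub in table.table.groupby("factor")}

        def scorer(test: pd.DataFrame) -> np.ndarray:
            lab = _factor_labels(test, config.factors, cutoffs)
            total = np.zeros(len(test), dtype=int)
            for f in table.factors:
                scores = table.scores_for(f)
                # unseen category falls back to the factor's mean score
                mapped = lab[f].astype(str).map(scores).astype(float)
                total += mapped.fillna(fallback[f]).astype(int).to_numpy()
            return total

        return scorer, table, cutoffs

    return builder


def _write_table(df: pd.DataFrame, path: Path, meta: dict, sep: str = ",") -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep=sep, index=False)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the full analysis; writes the report bundle to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"version": __version__, "config_sha256": config.sha256(),
            "sim_seed": config.sim.seed, "match_seed": config.match_seed,
            "cv_seed": config.cv_seed}
    log_lines = [f"survscore {__version__}", f"config sha256 {config.sha256()}",
                 "--- configuration echo ---", config.echo().rstrip()]

    # stage: cohort -----------------------------------------------------------
    cohort = _prepare_cohort(config)
    log_lines.append(f"cohort: n={len(cohort)}, events={int(cohort['event'].sum())}")

    # stage: matching ---------------------------------------------------------
    model = fit_propensity(cohort, ["age", "male", "drinking", "bmi", "family_history"],
                           treatment="smoking")
    pairs = match_nearest(model, caliper=config.caliper, seed=config.match_seed)
    balance = balance_smd(cohort, pairs, ["age", "male", "drinking", "bmi", "family_history"])
    _write_table(pairs.to_frame(), out / "matched_pairs.csv", meta)
    _write_table(balance, out / "balance.tsv", meta, sep="\t")
    matched = cohort[cohort["id"].isin(pairs.matched_ids())].copy()
    log_lines.append(f"matching: pairs={len(pairs.pairs)}, "
                     f"unmatched_treated={len(pairs.unmatched_treated)}")

    analysis = matched if config.score_on == "matched" else cohort

    # stage: stratified + additive interaction --------------------------------
    strat_block = {}
    for cov in DEFAULT_STRATIFIED:
        try:
            rows = stratum_hrs(analysis, cov, "smoking", adjust=config.adjust)
            z, p = z_interaction(rows["ever"]["adjusted"]["beta"], rows["ever"]["adjusted"]["se"],
                                 rows["never"]["adjusted"]["beta"], rows["never"]["adjusted"]["se"])
            strat_block[cov] = {"strata": rows, "z_interaction": z, "p_interaction": p}
        except Exception as exc:  # degenerate stratum: report, keep the bundle
            strat_block[cov] = {"error": f"{type(exc).__name__}: {exc}"}
    joint = joint_hrs(analysis, "smoke", "metabolic_syndrome", adjust=config.adjust)
    add = additive_measures(joint)
    interaction_report = {
        "_meta": meta,
        "stratified": strat_block,
        "joint_cells": {
            "ref_00": {"cases": joint.counts[(0, 0)][0], "total": joint.counts[(0, 0)][1],
                       "hr": 1.0},
            "smoke_only_10": {"cases": joint.counts[(1, 0)][0],
                              "total": joint.counts[(1, 0)][1], "hr_ci": joint.hr10},
            "metsyn_only_01": {"cases": joint.counts[(0, 1)][0],
                               "total": joint.counts[(0, 1)][1], "hr_ci": joint.hr01},
            "both_11": {"cases": joint.counts[(1, 1)][0],
                        "total": joint.counts[(1, 1)][1], "hr_ci": joint.hr11},
        },
        "additive": {"reri": add.reri, "reri_ci": add.reri_ci,
                     "ap": add.ap, "ap_ci": add.ap_ci,
                     "si": None if not add.si_defined else add.si,
                     "si_ci": add.si_ci},
    }
    (out / "interaction.json").write_text(json.dumps(interaction_report, indent=2,
                                                     default=float))
    log_lines.append(f"interaction: RERI={add.reri:.3f}, AP={add.ap:.3f}")

    # stage: scoring ----------------------------------------------------------
    builder = _score_builder(config)
    scorer, table, cutoffs = builder(analysis)
    T = pd.Series(scorer(analysis), index=analysis.index)
    group, bounds = group_by_quantiles(T, config.quantile_probs)
    hrres = score_mortality_hr(analysis, T, adjust=config.adjust,
                               probs=config.quantile_probs)
    table.to_tsv(out / "score_table.tsv",
                 header_lines=[f"{k}={v}" for k, v in meta.items()]
                 + [f"horizon={config.horizon}"])
    scored = analysis.copy()
    scored["total_score"] = T
    scored["score_group"] = group
    _write_table(scored, out / "scored_cohort.csv", meta)
    log_lines.append(f"scoring: T range {int(T.min())}-{int(T.max())}, "
                     f"group bounds {bounds}, "
                     f"per-unit HR {hrres['per_unit']['hr_ci'][0]:.3f}")

    # stage: validation -------------------------------------------------------
    probs = logistic_recalibration(T.to_numpy(), scored["event"].to_numpy())
    hl_chi2, hl_p = hosmer_lemeshow(scored["event"].to_numpy(), probs)
    n_bins = int(pd.qcut(probs, 10, labels=False, duplicates="drop").max()) + 1

    def cv_builder(train):
        scorer, _, _ = builder(train)
        return scorer

    pooled, ci, per_fold = cv_auroc(analysis, cv_builder, k=config.cv_k,
                                    seed=config.cv_seed, n_boot=config.n_boot,
                                    higher_is_event=False)
    report = ValidationReport(hl_chi2=hl_chi2, hl_df=n_bins - 2, hl_p=hl_p,
                              auroc=pooled, auroc_ci=ci, fold_aurocs=per_fold,
                              k=config.cv_k, seed=config.cv_seed)
    payload = report.to_dict()
    payload["_meta"] = meta
    payload["score_hr"] = {
        "per_unit": {"hr_ci": hrres["per_unit"]["hr_ci"], "p": hrres["per_unit"]["p"]},
        "group2": hrres["group2"], "group3": hrres["group3"],
        "group_bounds": list(bounds),
    }
    (out / "validation.json").write_text(json.dumps(payload, indent=2, default=float))
    log_lines.append(f"validation: HL p={hl_p:.3f}, CV AUROC={pooled:.3f}")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return {
        "cohort": cohort, "matched": matched, "pairs": pairs, "balance": balance,
        "interaction": interaction_report, "score_table": table, "total_score": T,
        "groups": group, "score_hr": hrres, "validation": payload,
    }
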