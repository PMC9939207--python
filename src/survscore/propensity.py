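"""Exposure propensity model, greedy 1:1 nearest-neighbor matching and
standardized-mean-difference balance diagnostics.

Matching operates on the logit of the fitted propensity score, without
replacement, with treated subjects processed in a seed-shuffled order.  The
default caliper is 0.2 SD of the logit (pass ``caliper=None`` to disable);
distance ties are broken by the lower control id so results are fully
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glm import fit_logistic
from .errors import EstimationError, SeparationError

__all__ = ["PropensityModel", "MatchedPairs", "fit_propensity", "match_nearest", "balance_smd"]

#: covariates of the default exposure model
DEFAULT_COVARIATES = ["age", "male", "drinking", "bmi", "family_history"]


@dataclass
class PropensityModel:
    covariates: list
    coef: pd.Series  # intercept + one per covariate, log-odds scale
    fitted: pd.Series  # P(treated | x), indexed like the cohort
    treatment: pd.Series  # 0/1, same index
    ids: pd.Series
    converged: bool

    @property
    def logit(self) -> pd.Series:
        p = self.fitted.clip(1e-12, 1 - 1e-12)
        return np.log(p / (1 - p))


@dataclass
class MatchedPairs:
    pairs: list  # [(treated id, control id), ...]
    unmatched_treated: list
    unmatched_control: list
    caliper: float | None  # in SD-of-logit multiples
    seed: int

    def matched_ids(self) -> list:
        return [i for pair in self.pairs for i in pair]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["treated_id", "control_id"])


def encode_treatment(series: pd.Series) -> np.ndarray:
    """Map a treatment column to 0/1 ('never'/'ever' accepted for smoking)."""
    vals = pd.unique(series.dropna())
    if set(vals) <= {0, 1, 0.0, 1.0, True, False}:
        return np.asarray(series).astype(int)
    if set(vals) <= {"never", "ever"}:
        return (series == "ever").astype(int).to_numpy()
    raise EstimationError(f"treatment column is not binary: levels {sorted(map(str, vals))}")


def fit_propensity(cohort: pd.DataFrame, covariates: list[str],
                   treatment: str = "smoking") -> PropensityModel:
    """Maximum-likelihood logistic propensity model for the exposure."""
    y = encode_treatment(cohort[treatment])
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise EstimationError("need at least 2 subjects per exposure level")
    Xc = cohort[covariates].to_numpy(float)
    if np.isnan(Xc).any():
        bad = [c for c in covariates if cohort[c].isna().any()]
        raise EstimationError(f"covariates with missing values: {bad}")
    # complete-separation scan: a covariate whose ranges do not overlap
    for j, c in enumerate(covariates):
        x1, x0 = Xc[y == 1, j], Xc[y == 0, j]
        if x1.min() > x0.max() or x0.min() > x1.max():
            raise SeparationError(f"complete separation on covariate {c!r}")
    X = np.column_stack([np.ones(len(y)), Xc])
    beta, mu, converged = fit_logistic(X, y)
    coef = pd.Series(beta, index=["intercept"] + list(covariates))
    ids = cohort["id"] if "id" in cohort else pd.Series(cohort.index, index=cohort.index)
    return PropensityModel(covariates=list(covariates), coef=coef,
                           fitted=pd.Series(mu, index=cohort.index),
                           treatment=pd.Series(y, index=cohort.index),
                           ids=ids, converged=converged)


def match_nearest(model: PropensityModel, caliper: float | None = 0.2,
                  seed: int = 0) -> MatchedPairs:
    """Greedy 1:1 nearest-neighbor matching on the logit of the score.

    Without replacement; treated subjects processed in seed-shuffled order;
    exact distance ties broken by the lower control id; pairs farther apart
    than ``caliper`` SD-of-logit are discarded (``caliper=None`` disables).
    """
    logit = model.logit.to_numpy()
    treated = model.treatment.to_numpy() == 1
    ids = np.asarray(model.ids)
    if treated.all() or (~treated).all():
        raise EstimationError("both exposure groups must be non-empty")
    sd = float(np.std(logit, ddof=1))
    max_dist = np.inf if caliper is None else caliper * sd

    t_idx = np.flatnonzero(treated)
    c_idx = np.flatnonzero(~treated)
    rng = np.random.default_rng(seed)
    t_idx = t_idx[rng.permutation(t_idx.size)]

    c_logit = logit[c_idx]
    c_ids = ids[c_idx]
    available = np.ones(c_idx.size, dtype=bool)
    pairs = []
    unmatched_treated = []
    for ti in t_idx:
        if not available.any():
            unmatched_treated.append(ids[ti])
            continue
        dist = np.abs(c_logit - logit[ti])
        dist = np.where(available, dist, np.inf)
        best = dist.min()
        if best > max_dist:
            unmatched_treated.append(ids[ti])
            continue
        cand = np.flatnonzero(dist <= best + 1e-12)
        pick = cand[np.argmin(c_ids[cand])]
        available[pick] = False
        pairs.append((ids[ti], c_ids[pick]))
    if not pairs:
        warnings.warn("no matched pairs produced")
    return MatchedPairs(pairs=pairs, unmatched_treated=unmatched_treated,
                        unmatched_control=list(c_ids[available]),
                        caliper=caliper, seed=seed)


def _smd(x1: np.ndarray, x0: np.ndarray) -> float:
    vals = set(np.unique(np.concatenate([x1, x0])).tolist())
    if vals <= {0.0, 1.0}:
        p1, p0 = x1.mean(), x0.mean()
        pooled = (p1 * (1 - p1) + p0 * (1 - p0)) / 2.0
        if pooled == 0:
            return 0.0 if p1 == p0 else np.inf
        return abs(p1 - p0) / np.sqrt(pooled)
    m1, m0 = x1.mean(), x0.mean()
    pooled = (x1.var(ddof=1) + x0.var(ddof=1)) / 2.0
    if pooled == 0:
        return 0.0 if m1 == m0 else np.inf
    return abs(m1 - m0) / np.sqrt(pooled)


def balance_smd(cohort: pd.DataFrame, pairs: MatchedPairs,
                covariates: list[str], treatment: str = "smoking") -> pd.DataFrame:
    """Standardized mean differences before and after matching, per covariate."""
    y = encode_treatment(cohort[treatment])
    id_col = cohort["id"] if "id" in cohort else pd.Series(cohort.index, index=cohort.index)
    matched = id_col.isin(pairs.matched_ids()).to_numpy()
    rows = []
    for c in covariates:
        x = cohort[c].to_numpy(float)
        rows.append({
            "covariate": c,
            "smd_before": _smd(x[y == 1], x[y == 0]),
            "smd_after": _smd(x[matched & (y == 1)], x[matched & (y == 0)]),
        })
    return pd.DataFrame(rows)
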