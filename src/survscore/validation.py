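"""Calibration and discrimination of the total risk score.

Hosmer-Lemeshow is applied to a binary outcome (death during follow-up)
against predicted probabilities — for the pipeline these come from a
logistic recalibration of the total score.  Discrimination is the rank-based
(Mann-Whitney, midranks) AUROC, cross-validated by re-running the entire
score construction on each training fold and pooling held-out pairs; the CI
is a percentile bootstrap of the pooled pairs.

Score orientation: the total score is protective (higher score = lower
predicted mortality), so AUROC helpers take a ``higher_is_event`` flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import fit_logistic
from .errors import EstimationError

__all__ = ["ValidationReport", "hosmer_lemeshow", "auroc", "cv_auroc",
           "logistic_recalibration", "stratified_folds", "harrell_c"]


@dataclass
class ValidationReport:
    hl_chi2: float
    hl_df: int
    hl_p: float
    auroc: float
    auroc_ci: tuple
    fold_aurocs: list
    k: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "hosmer_lemeshow": {"chi2": self.hl_chi2, "df": self.hl_df, "p": self.hl_p},
            "cv_auroc": {"estimate": self.auroc, "ci95": list(self.auroc_ci),
                         "per_fold": list(self.fold_aurocs), "k": self.k,
                         "seed": self.seed},
        }


def hosmer_lemeshow(events, probs, g: int = 10) -> tuple[float, float]:
    """Hosmer-Lemeshow chi-square over ``g`` equal-count probability bins.

    chi2 = sum (O - E)^2 / (E (1 - E/n_bin)), df = bins - 2.  Fewer than
    ``g`` distinct probabilities leads to merged bins (with a warning) and an
    adjusted df.
    """
    events = np.asarray(events, int)
    probs = np.asarray(probs, float)
    if np.any((probs <= 0) | (probs >= 1)):
        raise EstimationError("probabilities must lie strictly in (0, 1)")
    if events.size < g:
        raise EstimationError("need at least g subjects")
    bins = pd.qcut(probs, g, labels=False, duplicates="drop")
    n_bins = int(bins.max()) + 1
    if n_bins < g:
        warnings.warn(f"merged to {n_bins} bins (ties in predicted probabilities)")
    if n_bins < 2:
        raise EstimationError("fewer than 2 distinct bins; test undefined")
    chi2 = 0.0
    for b in range(n_bins):
        mask = bins == b
        nb = int(mask.sum())
        O = float(events[mask].sum())
        E = float(probs[mask].sum())
        denom = E * (1.0 - E / nb)
        if denom <= 0:
            if O != E:
                return float("inf"), 0.0
            continue
        chi2 += (O - E) ** 2 / denom
    df = n_bins - 2
    if df < 1:
        warnings.warn("fewer than 3 bins: chi-square reported, p undefined")
        return float(chi2), float("nan")
    return float(chi2), float(stats.chi2.sf(chi2, df))


def auroc(scores, labels, higher_is_event: bool = True) -> float:
    """Rank-based AUROC with midranks for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise EstimationError("both outcome classes must be present")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return float(auc if higher_is_event else 1.0 - auc)


def stratified_folds(labels, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic event-stratified k-fold index partition."""
    labels = np.asarray(labels, int)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(idx.size)]
        for i, ix in enumerate(idx):
            folds[i % k].append(int(ix))
    return [np.array(sorted(f), dtype=int) for f in folds]


def cv_auroc(cohort: pd.DataFrame, builder, k: int = 10, seed: int = 0,
             n_boot: int = 2000, higher_is_event: bool = False,
             event_col: str = "event") -> tuple[float, tuple, list]:
    """Pooled k-fold cross-validated AUROC of a score-building procedure.

    ``builder(train_df)`` must return a callable mapping a held-out data
    frame to a score vector; the whole construction (cut-offs, score table)
    is re-run per fold.  Returns (pooled AUROC, bootstrap 95% CI, per-fold
    AUROCs).  Outcome = event during follow-up, censoring time ignored.
    """
    labels = np.asarray(cohort[event_col], int)
    if labels.sum() < k:
        raise EstimationError("not enough events for event-stratified folds")
    folds = stratified_folds(labels, k, seed)
    pooled_scores = np.empty(len(cohort))
    fold_aucs = []
    for fold in folds:
        mask = np.zeros(len(cohort), dtype=bool)
        mask[fold] = True
        scorer = builder(cohort.iloc[~mask])
        s = np.asarray(scorer(cohort.iloc[mask]), float)
        pooled_scores[mask] = s
        fold_aucs.append(auroc(s, labels[mask], higher_is_event=higher_is_event))
    pooled = auroc(pooled_scores, labels, higher_is_event=higher_is_event)
    rng = np.random.default_rng(seed)
    n = len(cohort)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        lab = labels[idx]
        if lab.sum() == 0 or lab.sum() == n:
            continue
        boots.append(auroc(pooled_scores[idx], lab, higher_is_event=higher_is_event))
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return float(pooled), ci, fold_aucs


def logistic_recalibration(scores, events) -> np.ndarray:
    """Predicted event probabilities from a univariate logistic fit of the
    binary outcome on the score (used upstream of Hosmer-Lemeshow)."""
    scores = np.asarray(scores, float)
    X = np.column_stack([np.ones(scores.size), scores])
    _, mu, _ = fit_logistic(X, np.asarray(events, float))
    return mu


def harrell_c(times, events, scores, higher_is_event: bool = True) -> float:
    """Auxiliary concordance index over usable pairs (censoring-aware)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    scores = np.asarray(scores, float)
    if not higher_is_event:
        scores = -scores
    conc = ties = usable = 0
    ev_idx = np.flatnonzero(events == 1)
    for i in ev_idx:
        later = times > times[i]
        usable += int(later.sum())
        conc += int((scores[i] > scores[later]).sum())
        ties += int((scores[i] == scores[later]).sum())
    if usable == 0:
        raise EstimationError("no usable pairs")
    return (conc + 0.5 * ties) / usable
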