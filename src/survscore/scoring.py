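"""Survival-rate-based prognostic risk score.

Construction: continuous factors are categorized at survival-tree cut-offs
(recursive binary partitioning on the two-sample log-rank statistic); each
factor-category is scored as its Kaplan-Meier survival percent at a fixed
horizon (default 173 months) divided by 10 and rounded half-up to an integer;
per-subject total score T sums the factor scores; subjects are stratified at
the 25th/75th T quantiles into three groups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimationError
from .survival import fit_cox, hr_ci, cox_p, km_estimate, logrank, survival_at

__all__ = [
    "CutoffSpec",
    "ScoreTable",
    "tree_cutoffs",
    "categorize",
    "assign_score",
    "build_score_table",
    "total_score",
    "total_scores",
    "group_by_quantiles",
    "score_mortality_hr",
]

DEFAULT_HORIZON = 173.0


@dataclass
class CutoffSpec:
    """Ordered cut points for one continuous variable plus per-split log-rank
    statistics ``(cut, chi2, p)`` in the order the splits were accepted."""

    variable: str
    cuts: list
    labels: list
    split_stats: list = field(default_factory=list)

    def __post_init__(self):
        if sorted(self.cuts) != list(self.cuts):
            raise ValueError("cut points must be strictly increasing")


@dataclass
class ScoreTable:
    """Per factor-category n, survival percent at the horizon, integer score."""

    table: pd.DataFrame  # columns: factor, category, n, survival_pct, score
    horizon: float
    factors: list

    def scores_for(self, factor: str) -> dict:
        sub = self.table[self.table["factor"] == factor]
        return dict(zip(sub["category"], sub["score"]))

    def min_total(self) -> int:
        return int(self.table.groupby("factor")["score"].min().sum())

    def max_total(self) -> int:
        return int(self.table.groupby("factor")["score"].max().sum())

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def _labels_from_cuts(cuts: list[float]) -> list[str]:
    if not cuts:
        return ["all"]
    labels = [f"<={cuts[0]:g}"]
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        labels.append(f"({lo:g},{hi:g}]")
    labels.append(f">{cuts[-1]:g}")
    return labels


def _best_split(times, events, x, min_leaf, max_candidates=None):
    """Best log-rank split of one node.

    Returns (cut, chi2, p, n_candidates) or None; ``n_candidates`` counts the
    admissible cut points actually evaluated (used for the maximal-selection
    correction).
    """
    xs = np.unique(x)
    if xs.size < 2:
        return None
    mids = (xs[:-1] + xs[1:]) / 2.0
    if max_candidates is not None and mids.size > max_candidates:
        take = np.unique(np.linspace(0, mids.size - 1, max_candidates).astype(int))
        mids = mids[take]
    best = None
    n_cand = 0
    for c in mids:
        left = x <= c
        nl = int(left.sum())
        if nl < min_leaf or x.size - nl < min_leaf:
            continue
        if events[left].sum() + events[~left].sum() == 0:
            continue
        n_cand += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chi2, p = logrank(times[left], events[left], times[~left], events[~left])
        if best is None or chi2 > best[1]:
            best = (float(c), chi2, p)
    return None if best is None else best + (n_cand,)


def tree_cutoffs(times, events, x, variable: str = "x", max_leaves: int = 3,
                 min_leaf: int = 20, alpha: float = 0.05,
                 max_candidates: int | None = None,
                 p_adjust: str = "sidak") -> CutoffSpec:
    """Survival-tree cut-offs for one continuous variable.

    Candidate splits are midpoints between sorted distinct values; the split
    maximizing the two-sample log-rank chi-square (both children >=
    ``min_leaf``) is accepted when its p-value is <= ``alpha``.  Because the
    maximum is taken over many candidate cut points, the p-value is, by
    default, Sidak-adjusted for the number of admissible candidates
    (``p_adjust="none"`` restores the raw log-rank p).  Nodes are expanded
    best-first until ``max_leaves`` or no admissible split remains.
    All-identical ``x`` yields a single category with no cuts.
    """
    if p_adjust not in ("sidak", "none"):
        raise ValueError("p_adjust must be 'sidak' or 'none'")
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    if np.isnan(x).any():
        raise EstimationError(f"variable {variable!r} has missing values")
    if x.size < 2 * min_leaf:
        raise EstimationError(f"need at least {2 * min_leaf} subjects to split")

    stats_accepted: list = []
    cuts: list[float] = []
    # leaves as boolean masks
    leaves = [np.ones(x.size, dtype=bool)]
    while len(leaves) < max_leaves:
        candidates = []
        for li, mask in enumerate(leaves):
            res = _best_split(times[mask], events[mask], x[mask], min_leaf, max_candidates)
            if res is None:
                continue
            cut, chi2, p, n_cand = res
            if p_adjust == "sidak":
                # p of the maximum over n_cand (correlated) candidates
                p = float(-np.expm1(n_cand * np.log1p(-min(p, 1.0 - 1e-16))))
            if p <= alpha:
                candidates.append((li, cut, chi2, p))
        if not candidates:
            break
        li, cut, chi2, p = max(candidates, key=lambda c: c[2])
        mask = leaves.pop(li)
        leaves.append(mask & (x <= cut))
        leaves.append(mask & (x > cut))
        cuts.append(cut)
        stats_accepted.append((cut, chi2, p))
    cuts = sorted(cuts)
    return CutoffSpec(variable=variable, cuts=cuts,
                      labels=_labels_from_cuts(cuts), split_stats=stats_accepted)


def categorize(x, spec: CutoffSpec) -> pd.Series:
    """Map continuous values to the spec's category labels."""
    x = np.asarray(x, float)
    bins = np.searchsorted(np.asarray(spec.cuts, float), x, side="left")
    return pd.Series(pd.Categorical.from_codes(bins, categories=spec.labels))


def assign_score(survival_percent: float) -> int:
    """Integer score = survival percent / 10, rounded half-up; range 0-10."""
    if not 0.0 <= survival_percent <= 100.0:
        raise ValueError(f"survival percent out of [0, 100]: {survival_percent}")
    return int(math.floor(survival_percent / 10.0 + 0.5))


def build_score_table(cohort: pd.DataFrame, factors: dict,
                      horizon: float = DEFAULT_HORIZON,
                      time_col: str = "time_months",
                      event_col: str = "event") -> ScoreTable:
    """Assemble the per-category score table.

    ``factors`` maps factor name -> label series aligned with ``cohort``
    (categorical series keep their declared category order).  Every category
    must be non-empty.
    """
    rows = []
    for factor, labels in factors.items():
        if isinstance(labels, pd.Series):
            labels = labels.set_axis(cohort.index)  # keeps categorical dtype
        else:
            labels = pd.Series(labels, index=cohort.index)
        if isinstance(labels.dtype, pd.CategoricalDtype):
            cats = list(labels.cat.categories)
        else:
            cats = sorted(labels.dropna().unique().tolist())
        for cat in cats:
            mask = (labels == cat).to_numpy()
            if mask.sum() == 0:
                raise EstimationError(f"factor {factor!r} category {cat!r} is empty")
            km = km_estimate(cohort.loc[mask, time_col], cohort.loc[mask, event_col])
            pct = survival_at(km, horizon)
            rows.append({"factor": factor, "category": cat, "n": int(mask.sum()),
                         "survival_pct": pct, "score": assign_score(pct)})
    return ScoreTable(table=pd.DataFrame(rows), horizon=horizon,
                      factors=list(factors.keys()))


def total_score(subject_categories: dict, table: ScoreTable) -> int:
    """Sum the per-factor scores matching one subject's categories."""
    total = 0
    for factor in table.factors:
        if factor not in subject_categories:
            raise KeyError(f"subject has no category for factor {factor!r}")
        scores = table.scores_for(factor)
        cat = subject_categories[factor]
        if cat not in scores:
            raise KeyError(f"unmatched category {cat!r} for factor {factor!r}")
        total += int(scores[cat])
    return total


def total_scores(categories: pd.DataFrame, table: ScoreTable) -> pd.Series:
    """Vectorized total score; ``categories`` has one column per factor."""
    total = pd.Series(0, index=categories.index)
    for factor in table.factors:
        scores = table.scores_for(factor)
        col = categories[factor]
        mapped = col.map(scores)
        if mapped.isna().any():
            bad = col[mapped.isna()].iloc[0]
            raise KeyError(f"unmatched category {bad!r} for factor {factor!r}")
        total = total + mapped.astype(int)
    return total


def group_by_quantiles(T, probs: tuple = (0.25, 0.75)) -> tuple[pd.Series, tuple]:
    """Three-way stratification of total scores at empirical quantiles.

    Linear-interpolation quantiles (numpy default).  Group 1: T < q_low;
    group 2: q_low <= T < q_high; group 3: T >= q_high.  All-identical T
    collapses to a single group with a warning.
    """
    T = pd.Series(T)
    q_low, q_high = (float(q) for q in np.quantile(T.to_numpy(float), probs))
    if T.nunique() == 1:
        warnings.warn("all total scores identical; a single group results")
    group = pd.Series(2, index=T.index)
    group[T < q_low] = 1
    group[T >= q_high] = 3
    return group, (q_low, q_high)


def score_mortality_hr(cohort: pd.DataFrame, T, adjust: list[str] | None = None,
                       probs: tuple = (0.25, 0.75),
                       time_col: str = "time_months", event_col: str = "event") -> dict:
    """Cox risk estimates for the total score: per-unit HR and group HRs vs
    the lowest-score group."""
    adjust = adjust or []
    T = pd.Series(np.asarray(T, float), index=cohort.index)
    adj = [cohort[c].to_numpy(float) for c in adjust]
    fit_lin = fit_cox(cohort[time_col], cohort[event_col],
                      np.column_stack([T.to_numpy()] + adj),
                      names=["total_score"] + list(adjust))
    group, bounds = group_by_quantiles(T, probs)
    # empty quantile groups (possible for very discrete T) yield constant
    # dummies; only non-degenerate groups enter the fit
    dummies = {f"group{g}": (group == g).astype(float)
               for g in (2, 3) if (group == g).any() and not (group == g).all()}
    out = {
        "per_unit": {"hr_ci": hr_ci(fit_lin, "total_score"),
                     "p": cox_p(fit_lin, "total_score"), "fit": fit_lin},
        "group2": None,
        "group3": None,
        "group_bounds": bounds,
        "groups": group,
        "fit_groups": None,
    }
    if dummies:
        names = list(dummies)
        fit_grp = fit_cox(cohort[time_col], cohort[event_col],
                          np.column_stack(list(dummies.values()) + adj),
                          names=names + list(adjust))
        out["fit_groups"] = fit_grp
        for name in names:
            out[name] = {"hr_ci": hr_ci(fit_grp, name), "p": cox_p(fit_grp, name)}
    return out
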