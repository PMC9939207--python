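"""Stratified hazard ratios, the between-stratum Z-test and additive-interaction
decomposition (RERI / AP / SI) with delta-method confidence intervals.

The joint-exposure model codes the four cells of two binary exposures with
three dummies against the double-unexposed reference; RERI, AP and SI follow
from the three cell hazard ratios by their defining identities, and their
intervals propagate the 3x3 coefficient covariance through the gradient of
each measure (SI on the log scale).  A nonparametric bootstrap is available
as an alternative interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError
from .survival import Z95, CoxFit, cox_p, fit_cox, hr_ci

__all__ = [
    "JointExposureResult",
    "AdditiveInteraction",
    "stratum_hrs",
    "z_interaction",
    "joint_hrs",
    "additive_measures",
    "bootstrap_additive",
]


@dataclass
class JointExposureResult:
    """Cell hazard ratios for exposures (a, b) vs the (0, 0) reference.

    ``beta``/``cov`` are ordered (a-only, b-only, both) = (10, 01, 11).
    """

    hr10: tuple[float, float, float]
    hr01: tuple[float, float, float]
    hr11: tuple[float, float, float]
    beta: np.ndarray
    cov: np.ndarray
    counts: dict
    fit: CoxFit


@dataclass
class AdditiveInteraction:
    reri: float
    ap: float
    si: float  # nan when undefined
    reri_ci: tuple[float, float] | None = None
    ap_ci: tuple[float, float] | None = None
    si_ci: tuple[float, float] | None = None

    @property
    def si_defined(self) -> bool:
        return not math.isnan(self.si)


def _as_binary(series: pd.Series, name: str) -> np.ndarray:
    vals = np.asarray(series)
    uniq = set(pd.unique(series).tolist())
    if uniq <= {0, 1, 0.0, 1.0, True, False}:
        return vals.astype(int)
    raise EstimationError(f"column {name!r} must be binary 0/1")


def stratum_hrs(cohort: pd.DataFrame, covariate: str, stratifier: str,
                adjust: list[str] | None = None,
                time_col: str = "time_months", event_col: str = "event") -> dict:
    """Per-stratum unadjusted and adjusted Cox HRs for ``covariate``.

    Returns ``{stratum: {"unadjusted": row, "adjusted": row}}`` where each row
    holds (hr, lo, hi, beta, se, p).  Requires >= 2 strata, each with >= 1
    event.
    """
    adjust = adjust or []
    levels = list(pd.unique(cohort[stratifier].dropna()))
    if len(levels) < 2:
        raise EstimationError(f"stratifier {stratifier!r} has a single stratum")
    out = {}
    for lev in levels:
        sub = cohort[cohort[stratifier] == lev]
        if len(sub) == 0 or sub[event_col].sum() < 1:
            raise EstimationError(f"stratum {stratifier}={lev!r} has no events")
        rows = {}
        for label, cols in (("unadjusted", [covariate]), ("adjusted", [covariate] + adjust)):
            fit = fit_cox(sub[time_col], sub[event_col], sub[cols].to_numpy(float), names=cols)
            hr, lo, hi = hr_ci(fit, covariate)
            j = fit.names.index(covariate)
            rows[label] = {
                "hr": hr, "lo": lo, "hi": hi,
                "beta": float(fit.beta[j]), "se": float(fit.se[j]),
                "p": cox_p(fit, covariate),
            }
        out[lev] = rows
    return out


def z_interaction(beta1: float, se1: float, beta2: float, se2: float) -> tuple[float, float]:
    """Z-test comparing two independent log-HRs; returns (z, two-sided p)."""
    if se1 <= 0 or se2 <= 0:
        raise EstimationError("standard errors must be > 0")
    z = (beta1 - beta2) / math.sqrt(se1**2 + se2**2)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def joint_hrs(cohort: pd.DataFrame, exposure_a: str, exposure_b: str,
              adjust: list[str] | None = None,
              time_col: str = "time_months", event_col: str = "event") -> JointExposureResult:
    """Single Cox fit with dummies for the three non-reference exposure cells."""
    adjust = adjust or []
    a = _as_binary(cohort[exposure_a], exposure_a)
    b = _as_binary(cohort[exposure_b], exposure_b)
    counts = {}
    for ca in (0, 1):
        for cb in (0, 1):
            mask = (a == ca) & (b == cb)
            if mask.sum() == 0:
                raise EstimationError(f"empty exposure cell ({exposure_a}={ca}, {exposure_b}={cb})")
            counts[(ca, cb)] = (int(cohort.loc[mask, event_col].sum()), int(mask.sum()))
    if counts[(0, 0)][0] < 1:
        raise EstimationError("reference cell has no events")
    d10 = ((a == 1) & (b == 0)).astype(float)
    d01 = ((a == 0) & (b == 1)).astype(float)
    d11 = ((a == 1) & (b == 1)).astype(float)
    names = ["cell_10", "cell_01", "cell_11"] + list(adjust)
    X = np.column_stack([d10, d01, d11] + [cohort[c].to_numpy(float) for c in adjust])
    fit = fit_cox(cohort[time_col], cohort[event_col], X, names=names)
    return JointExposureResult(
        hr10=hr_ci(fit, "cell_10"),
        hr01=hr_ci(fit, "cell_01"),
        hr11=hr_ci(fit, "cell_11"),
        beta=fit.beta[:3].copy(),
        cov=fit.cov[:3, :3].copy(),
        counts=counts,
        fit=fit,
    )


def _point_measures(h10: float, h01: float, h11: float) -> tuple[float, float, float]:
    reri = h11 - h10 - h01 + 1.0
    ap = reri / h11
    denom = (h10 - 1.0) + (h01 - 1.0)
    si = (h11 - 1.0) / denom if denom > 0 else math.nan
    return reri, ap, si


def additive_measures(joint=None, *, hr10: float | None = None, hr01: float | None = None,
                      hr11: float | None = None) -> AdditiveInteraction:
    """RERI, AP and SI with 95% delta-method CIs.

    Accepts either a :class:`JointExposureResult` (CIs from its coefficient
    covariance) or three plain hazard ratios via keywords (point estimates
    only).  SI and its CI are flagged undefined (nan/None) when the excess-risk
    denominator is <= 0; RERI and AP are always returned.
    """
    if joint is None:
        if None in (hr10, hr01, hr11):
            raise ValueError("provide a JointExposureResult or all three hazard ratios")
        reri, ap, si = _point_measures(hr10, hr01, hr11)
        return AdditiveInteraction(reri=reri, ap=ap, si=si)

    b10, b01, b11 = joint.beta
    h10, h01, h11 = math.exp(b10), math.exp(b01), math.exp(b11)
    reri, ap, si = _point_measures(h10, h01, h11)
    cov = joint.cov  # ordered (10, 01, 11)

    g_reri = np.array([-h10, -h01, h11])
    var_reri = float(g_reri @ cov @ g_reri)
    reri_ci = (reri - Z95 * math.sqrt(var_reri), reri + Z95 * math.sqrt(var_reri))

    g_ap = np.array([-h10 / h11, -h01 / h11, (h10 + h01 - 1.0) / h11])
    var_ap = float(g_ap @ cov @ g_ap)
    ap_ci = (ap - Z95 * math.sqrt(var_ap), ap + Z95 * math.sqrt(var_ap))

    denom = (h10 - 1.0) + (h01 - 1.0)
    if denom > 0 and h11 > 1.0:
        # CI for log SI = log(h11 - 1) - log(h10 + h01 - 2)
        g_lsi = np.array([-h10 / denom, -h01 / denom, h11 / (h11 - 1.0)])
        var_lsi = float(g_lsi @ cov @ g_lsi)
        half = Z95 * math.sqrt(var_lsi)
        si_ci = (si * math.exp(-half), si * math.exp(half))
    else:
        si_ci = None
    return AdditiveInteraction(reri=reri, ap=ap, si=si,
                               reri_ci=reri_ci, ap_ci=ap_ci, si_ci=si_ci)


def bootstrap_additive(cohort: pd.DataFrame, exposure_a: str, exposure_b: str,
                       adjust: list[str] | None = None, n_boot: int = 500,
                       seed: int = 0, time_col: str = "time_months",
                       event_col: str = "event") -> dict:
    """Percentile bootstrap CIs for RERI / AP / SI (resampling subjects)."""
    rng = np.random.default_rng(seed)
    n = len(cohort)
    reris, aps, sis = [], [], []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        sample = cohort.iloc[idx]
        try:
            j = joint_hrs(sample, exposure_a, exposure_b, adjust,
                          time_col=time_col, event_col=event_col)
        except EstimationError:
            continue
        h = (j.hr10[0], j.hr01[0], j.hr11[0])
        reri, ap, si = _point_measures(*h)
        reris.append(reri)
        aps.append(ap)
        if not math.isnan(si):
            sis.append(si)
    def ci(v):
        return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))) if v else None
    return {"reri_ci": ci(reris), "ap_ci": ci(aps), "si_ci": ci(sis),
            "n_effective": len(reris)}
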