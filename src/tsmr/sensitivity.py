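"""Sensitivity analyses: heterogeneity, pleiotropy, leave-one-out,
multiple-testing adjustment, and the advisory method-selection rule.

Cochran's Q is always computed around the fixed-effect IVW estimate (the
standard definition), whatever IVW variant the main table reports.  The
heterogeneity flag is the union of two criteria — Q-test p < alpha or
I^2 > 50% — each also reported separately.  The method recommendation
(IVW vs MR-Egger when the Egger intercept indicates directional
pleiotropy) is advisory output only; all five estimates are always
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimators import IVW_MRE, MREstimate, _ratio_arrays, egger, ivw
from .harmonize import HarmonizedDataset

I2_THRESHOLD = 50.0  # percent


@dataclass(frozen=True)
class HeterogeneityResult:
    Q: float
    df: int
    pvalue: float
    i2: float  # percent in [0, 100]


@dataclass(frozen=True)
class PleiotropyResult:
    intercept: float
    se: float
    pvalue: float


@dataclass(frozen=True)
class LeaveOneOutEntry:
    excluded: str
    beta: float
    se: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class LeaveOneOutSeries:
    entries: tuple[LeaveOneOutEntry, ...]
    full: MREstimate
    unstable: bool


@dataclass
class SensitivityReport:
    heterogeneity: HeterogeneityResult
    pleiotropy: PleiotropyResult
    loo: LeaveOneOutSeries
    recommended_method: str
    heterogeneity_flag: bool
    adjusted_pvalues: tuple[float, ...] = ()


def cochran_q(data: HarmonizedDataset) -> HeterogeneityResult:
    """Cochran's Q across per-SNP Wald ratios, with I^2 = max(0, (Q-df)/Q)·100."""
    r, w = _ratio_arrays(data)
    n = len(r)
    if n < 2:
        raise ValueError("Cochran's Q requires >= 2 instruments")
    beta_fixed = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - beta_fixed) ** 2))
    df = n - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityResult(Q=q, df=df, pvalue=p, i2=i2)


def egger_intercept_test(data: HarmonizedDataset) -> PleiotropyResult:
    """Directional-pleiotropy test: the MR-Egger intercept against t(n-2)."""
    est = egger(data)
    return PleiotropyResult(
        intercept=est.extra["intercept"],
        se=est.extra["intercept_se"],
        pvalue=est.extra["intercept_pvalue"],
    )


def leave_one_out(data: HarmonizedDataset, model: str = IVW_MRE) -> LeaveOneOutSeries:
    """Re-estimate IVW with each SNP excluded in turn.

    The series is flagged unstable when any reduced-data CI excludes the
    full estimate, or when dropping one SNP flips the sign of a full
    estimate whose CI excludes zero.
    """
    if len(data) < 3:
        raise ValueError("leave-one-out requires >= 3 instruments")
    full = ivw(data, model=model)
    entries = []
    unstable = False
    full_sig = not (full.ci_low <= 0.0 <= full.ci_high)
    for snp in data.snp_ids:
        est = ivw(data.drop(snp), model=model)
        entries.append(
            LeaveOneOutEntry(snp, est.beta, est.se, est.ci_low, est.ci_high)
        )
        if not (est.ci_low <= full.beta <= est.ci_high):
            unstable = True
        if full_sig and np.sign(est.beta) != np.sign(full.beta):
            unstable = True
    return LeaveOneOutSeries(tuple(entries), full, unstable)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_method(
    het: HeterogeneityResult, pleio: PleiotropyResult, alpha: float = 0.05
) -> str:
    """Advisory rule: MR-Egger when directional pleiotropy is detected,
    IVW otherwise (random-effects IVW flagged separately under
    heterogeneity)."""
    return "MR-Egger" if pleio.pvalue < alpha else "IVW"


def heterogeneity_flag(het: HeterogeneityResult, alpha: float = 0.05) -> bool:
    """Union flag: Q-test p < alpha or I^2 above the 50% threshold."""
    return het.pvalue < alpha or het.i2 > I2_THRESHOLD


def sensitivity_report(
    data: HarmonizedDataset,
    alpha: float = 0.05,
    ivw_model: str = IVW_MRE,
) -> SensitivityReport:
    """Run the full sensitivity suite on one harmonized dataset."""
    het = cochran_q(data)
    pleio = egger_intercept_test(data)
    loo = leave_one_out(data, model=ivw_model)
    return SensitivityReport(
        heterogeneity=het,
        pleiotropy=pleio,
        loo=loo,
        recommended_method=select_method(het, pleio, alpha),
        heterogeneity_flag=heterogeneity_flag(het, alpha),
    )
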