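"""Causal-effect estimators for two-sample MR.

All five estimators consume a :class:`~tsmr.harmonize.HarmonizedDataset`
and return an :class:`MREstimate` (effect in SD outcome per SD exposure).

Per-SNP Wald ratios use the first-order standard error se_out/|beta_exp|
(the exposure-side uncertainty is ignored; the F > 10 instrument filter
bounds the resulting weak-instrument bias).  Inverse-variance weights are
1/ratio_se^2 throughout.

* IVW: weighted average of ratios; the default multiplicative
  random-effects model inflates the fixed-effect standard error by
  max(1, sqrt(Q/(n-1))) so confidence intervals never shrink below the
  fixed-effect ones under heterogeneity.
* MR-Egger: weighted regression of outcome on exposure effects with a free
  intercept after orienting every exposure effect positive; slope and
  intercept are tested against t(n-2).
* Weighted median: weight-interpolated median of the ratio distribution;
  standard error by parametric bootstrap.
* Simple/weighted mode: the maximizer of a Gaussian-kernel-smoothed ratio
  density (modified Silverman bandwidth scaled by ``phi``); standard error
  by parametric bootstrap.

Stochastic estimators draw from a deterministic substream derived from
(method name, seed), so results are bit-reproducible and adding one method
never perturbs another's numbers.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .harmonize import HarmonizedDataset, HarmonizedPair

log = logging.getLogger(__name__)

Z975 = 1.959964  # 97.5% standard-normal quantile, as conventionally printed

IVW_FIXED = "fixed"
IVW_MRE = "multiplicative-random"


@dataclass(frozen=True)
class WaldRatio:
    """Per-SNP causal estimate beta_out/beta_exp with first-order se."""

    snp_id: str
    ratio: float
    ratio_se: float

    @property
    def weight(self) -> float:
        return 1.0 / self.ratio_se**2


@dataclass(frozen=True)
class MREstimate:
    """One estimator's result — one row of a summary table."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int
    extra: dict = field(default_factory=dict)


def _rng(seed: int | None, method: str) -> np.random.Generator:
    """Deterministic per-method substream of the pipeline-level seed."""
    return np.random.default_rng([zlib.crc32(method.encode()), 0 if seed is None else seed])


def wald_ratio(pair: HarmonizedPair) -> WaldRatio:
    """Single-SNP ratio estimate.  Requires beta_exp != 0."""
    if pair.beta_exp == 0:
        raise ValueError(f"{pair.snp_id}: beta_exp is zero; Wald ratio undefined")
    return WaldRatio(
        snp_id=pair.snp_id,
        ratio=pair.beta_out / pair.beta_exp,
        ratio_se=pair.se_out / abs(pair.beta_exp),
    )


def wald_ratios(data: HarmonizedDataset) -> list[WaldRatio]:
    """Per-SNP ratios; pairs with beta_exp = 0 are excluded with a warning."""
    out = []
    for p in data:
        if p.beta_exp == 0:
            log.warning("%s: beta_exp = 0, excluded from ratio-based estimators", p.snp_id)
            continue
        out.append(wald_ratio(p))
    return out


def _ratio_arrays(data: HarmonizedDataset):
    ratios = wald_ratios(data)
    r = np.array([w.ratio for w in ratios])
    w = np.array([w.weight for w in ratios])
    return r, w


def _normal_pvalue(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def confidence_interval(
    beta: float,
    se: float,
    level: float = 0.95,
    dist: str = "normal",
    df: int | None = None,
) -> tuple[float, float]:
    """Symmetric interval beta ± q·se, q the (1+level)/2 quantile.

    ``dist`` is ``"normal"`` or ``"t"`` (the latter requires ``df``).
    """
    if se < 0:
        raise ValueError("se must be >= 0")
    q = (1.0 + level) / 2.0
    if dist == "normal":
        quant = Z975 if level == 0.95 else float(stats.norm.ppf(q))
    elif dist == "t":
        if df is None:
            raise ValueError("t interval requires df")
        quant = float(stats.t.ppf(q, df))
    else:
        raise ValueError(f"unknown dist {dist!r}")
    return beta - quant * se, beta + quant * se


def ivw(data: HarmonizedDataset, model: str = IVW_MRE) -> MREstimate:
    """Inverse-variance-weighted average of Wald ratios.

    Equivalent to weighted least squares of beta_out on beta_exp through
    the origin with weights 1/se_out^2.  ``model`` selects the
    fixed-effect standard error (sum of weights)^{-1/2} or the
    multiplicative random-effects inflation max(1, sqrt(Q/(n-1))).
    """
    if model not in (IVW_FIXED, IVW_MRE):
        raise ValueError(f"unknown IVW model {model!r}")
    r, w = _ratio_arrays(data)
    n = len(r)
    if n == 0:
        raise ValueError("no usable pairs for IVW")
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q_stat = float(np.sum(w * (r - beta) ** 2))
    scale = max(1.0, np.sqrt(q_stat / (n - 1))) if n > 1 else 1.0
    se = se_fixed * scale if model == IVW_MRE else se_fixed
    lo, hi = confidence_interval(beta, se)
    return MREstimate(
        method="Inverse variance weighted",
        beta=beta,
        se=se,
        ci_low=lo,
        ci_high=hi,
        pvalue=_normal_pvalue(beta, se),
        n_snp=n,
        extra={"model": model, "Q": q_stat, "se_fixed": se_fixed},
    )


def _oriented(data: HarmonizedDataset):
    """Orient pairs so every exposure effect is positive (Egger convention)."""
    bx, by = data.beta_exp, data.beta_out
    sgn = np.where(bx < 0, -1.0, 1.0)
    return bx * sgn, by * sgn, data.se_out


def egger(data: HarmonizedDataset) -> MREstimate:
    """MR-Egger regression: slope = causal effect, free intercept =
    directional-pleiotropy estimate; t inference with n-2 df.

    The residual scale is floored at 1 (multiplicative random effects), so
    an under-dispersed fit cannot shrink the standard errors.
    """
    n = len(data)
    if n < 3:
        raise ValueError("insufficient instruments for Egger (need >= 3)")
    bx, by, se_out = _oriented(data)
    X = sm.add_constant(bx, has_constant="add")
    fit = sm.WLS(by, X, weights=1.0 / se_out**2).fit()
    scale_floor = min(1.0, float(np.sqrt(fit.scale))) if fit.scale > 0 else 1.0
    se_int, se_slope = (float(s) / scale_floor for s in fit.bse)
    intercept, slope = (float(b) for b in fit.params)
    df = n - 2

    def t_p(b, s):
        if s == 0:
            return 0.0 if b != 0 else 1.0
        return float(2.0 * stats.t.sf(abs(b) / s, df))

    lo, hi = confidence_interval(slope, se_slope, dist="t", df=df)
    return MREstimate(
        method="MR Egger",
        beta=slope,
        se=se_slope,
        ci_low=lo,
        ci_high=hi,
        pvalue=t_p(slope, se_slope),
        n_snp=n,
        extra={
            "intercept": intercept,
            "intercept_se": se_int,
            "intercept_pvalue": t_p(intercept, se_int),
            "df": df,
        },
    )


def t_pvalue(beta: float, se: float, df: int) -> float:
    """Two-sided p-value for beta/se against Student's t with ``df`` df."""
    if se <= 0:
        raise ValueError("se must be > 0")
    return float(2.0 * stats.t.sf(abs(beta) / se, df))


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weight-interpolated median of the ratio distribution.

    Sort ratios ascending; at sorted position j the normalized cumulative
    weight is S_j = (sum_{k<=j} w_k - w_j/2) / sum(w); the estimate is the
    linear interpolation of the sorted ratios at S = 0.5.
    """
    order = np.argsort(ratios)
    r, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def _bootstrap_se(data: HarmonizedDataset, point_fn, n_boot: int,
                  rng: np.random.Generator) -> float:
    """Parametric bootstrap: redraw both betas from their sampling
    distributions, recompute the point estimate, take the SD."""
    bx, sx = data.beta_exp, data.se_exp
    by, sy = data.beta_out, data.se_out
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        ok = bxb != 0
        r = byb[ok] / bxb[ok]
        w = (np.abs(bxb[ok]) / sy[ok]) ** 2
        est[b] = point_fn(r, w)
    return float(np.std(est, ddof=1))


def weighted_median(
    data: HarmonizedDataset,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median estimator — consistent when valid instruments carry
    at least half of the inverse-variance weight.

    Standard error by parametric bootstrap (``n_boot`` replicates); set
    ``n_boot=0`` to skip it (se/CI/p become NaN).
    """
    n = len(data)
    if n < 3:
        raise ValueError("weighted median requires >= 3 instruments")
    r, w = _ratio_arrays(data)
    beta = weighted_median_point(r, w)
    if n_boot > 0:
        se = _bootstrap_se(data, weighted_median_point, n_boot,
                           _rng(seed, "weighted median"))
        lo, hi = confidence_interval(beta, se)
        p = _normal_pvalue(beta, se)
    else:
        se = lo = hi = p = float("nan")
    return MREstimate("Weighted median", beta, se, lo, hi, p, n,
                      extra={"n_boot": n_boot})


def mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float = 1.0) -> float:
    """Maximizer of the kernel-smoothed weighted ratio density.

    Bandwidth: modified Silverman rule 0.9·min(sd, MAD)·n^(-1/5) scaled by
    ``phi`` (MAD on the normal-consistent scale; falls back to the sd term
    when the MAD degenerates to zero).
    """
    r = np.asarray(ratios, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.ptp(r) == 0:
        return float(r[0])
    sd = float(np.std(r, ddof=1))
    mad = float(stats.median_abs_deviation(r, scale="normal"))
    s = 0.9 * min(sd, mad) * len(r) ** (-0.2)
    if s <= 0:
        s = 0.9 * sd * len(r) ** (-0.2)
    h = phi * s
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 512)
    dens = (w[:, None] * stats.norm.pdf(grid[None, :], r[:, None], h)).sum(axis=0)
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    data: HarmonizedDataset,
    weighted: bool = False,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Mode-based estimator: simple (unit weights) or weighted (IVW weights).

    Consistent when the largest homogeneous cluster of instruments is
    valid, even if they are a minority.  Standard error by parametric
    bootstrap; ``n_boot=0`` skips it.
    """
    n = len(data)
    if n < 3:
        raise ValueError("mode estimator requires >= 3 instruments")
    method = "Weighted mode" if weighted else "Simple mode"
    r, w = _ratio_arrays(data)

    def point(rr, ww):
        return mode_point(rr, ww if weighted else np.ones_like(rr), phi)

    beta = point(r, w)
    if n_boot > 0:
        se = _bootstrap_se(data, point, n_boot, _rng(seed, method))
        lo, hi = confidence_interval(beta, se)
        p = _normal_pvalue(beta, se)
    else:
        se = lo = hi = p = float("nan")
    return MREstimate(method, beta, se, lo, hi, p, n,
                      extra={"phi": phi, "n_boot": n_boot})


def all_estimates(
    data: HarmonizedDataset,
    ivw_model: str = IVW_MRE,
    n_boot: int = 1000,
    phi: float = 1.0,
    seed: int | None = None,
) -> list[MREstimate]:
    """The five standard estimators in conventional reporting order."""
    return [
        egger(data),
        weighted_median(data, n_boot=n_boot, seed=seed),
        ivw(data, model=ivw_model),
        mode_estimate(data, weighted=False, phi=phi, n_boot=n_boot, seed=seed),
        mode_estimate(data, weighted=True, phi=phi, n_boot=n_boot, seed=seed),
    ]
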