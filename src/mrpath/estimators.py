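"""Two-sample MR estimators on harmonized summary statistics.

All estimators consume a :class:`~mrpath.instruments.HarmonizedSet` (or a
DataFrame with its columns) holding per-SNP exposure/outcome effects aligned
to a common effect allele, and return :class:`MREstimate` objects.

Implemented methods
-------------------
* Wald ratio — the per-SNP building block, by/bx with first-order se |sy/bx|.
* IVW — inverse-variance-weighted meta-analysis of Wald ratios, equivalently a
  zero-intercept weighted regression of by on bx with weights 1/sy^2.  The
  fixed-effects se is sqrt(1/sum(w bx^2)); the multiplicative random-effects
  se inflates it by sqrt(max(1, Q/(k-1))) and never shrinks below it.  With
  ``model="auto"`` the model follows Cochran's Q: random effects iff the
  heterogeneity p-value falls below the switch threshold (0.05).
* MR-Egger — weighted regression with an intercept after orienting all
  exposure effects positive; the intercept estimates average directional
  pleiotropy; t inference on k-2 df.
* Weighted median — consistent when at least half the weight comes from valid
  instruments; se by parametric bootstrap.
* Cochran's Q — heterogeneity of the per-SNP estimates and the fixed/random
  model choice driven by it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EstimationError

__all__ = [
    "MREstimate",
    "HeterogeneityResult",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "cochran_q",
]

Z95 = 1.959964  # two-sided 95% normal quantile, fixed by convention


@dataclass
class MREstimate:
    """A causal-effect estimate with normal-theory 95% CI and OR scale."""

    method: str
    beta: float
    se: float
    p: float
    n_snp: int
    ci_low: float = field(default=math.nan)
    ci_high: float = field(default=math.nan)
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if math.isnan(self.ci_low):
            self.ci_low = self.beta - Z95 * self.se
        if math.isnan(self.ci_high):
            self.ci_high = self.beta + Z95 * self.se

    @property
    def or_point(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    def to_row(self) -> dict:
        low, high = self.or_ci
        return {
            "method": self.method,
            "nsnp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "OR": self.or_point,
            "or_ci_low": low,
            "or_ci_high": high,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            **{k: v for k, v in self.extras.items() if np.isscalar(v)},
        }


@dataclass
class HeterogeneityResult:
    """Cochran's Q heterogeneity test and the model it selects."""

    q: float
    df: int
    p: float
    selected_model: str  # "fixed" | "random"
    note: str = ""

    @property
    def is_na(self) -> bool:
        return math.isnan(self.q)


def _arrays(h):
    """Extract (bx, sx, by, sy) from a HarmonizedSet, DataFrame or tuple."""
    if hasattr(h, "arrays"):
        return h.arrays()
    if isinstance(h, pd.DataFrame):
        return (
            h["beta_exposure"].to_numpy(float),
            h["se_exposure"].to_numpy(float),
            h["beta_outcome"].to_numpy(float),
            h["se_outcome"].to_numpy(float),
        )
    bx, sx, by, sy = h
    return (np.asarray(bx, float), np.asarray(sx, float),
            np.asarray(by, float), np.asarray(sy, float))


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def wald_ratio(bx, sx, by, sy, second_order: bool = False):
    """Per-SNP Wald ratio by/bx with delta-method standard error.

    First order: se = |sy/bx|.  With ``second_order=True`` the term
    propagating the exposure-side noise is added:
    se = sqrt(sy^2/bx^2 + by^2 sx^2 / bx^4).
    """
    bx = np.asarray(bx, float)
    if np.any(bx == 0):
        raise ValueError("wald_ratio undefined for bx = 0")
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    ratio = by / bx
    if second_order:
        sx = np.asarray(sx, float)
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = np.abs(sy / bx)
    if ratio.ndim == 0:
        return float(ratio), float(se)
    return ratio, se


def _ivw_sums(bx, by, sy):
    w = 1.0 / sy**2
    s_xy = float(np.sum(w * bx * by))
    s_xx = float(np.sum(w * bx * bx))
    return w, s_xy, s_xx


def cochran_q(h, beta: float | None = None,
              model_switch_alpha: float = 0.05) -> HeterogeneityResult:
    """Cochran's Q for the harmonized set around a pooled estimate.

    When ``beta`` is omitted the fixed-effects IVW estimate is used.  With a
    single SNP the statistic is undefined and an NA result is returned.
    """
    bx, _, by, sy = _arrays(h)
    k = len(bx)
    if k < 2:
        return HeterogeneityResult(
            q=math.nan, df=0, p=math.nan, selected_model="fixed",
            note="Q undefined for fewer than 2 SNPs",
        )
    w, s_xy, s_xx = _ivw_sums(bx, by, sy)
    if beta is None:
        beta = s_xy / s_xx
    q = float(np.sum(w * (by - beta * bx) ** 2))
    p = float(stats.chi2.sf(q, k - 1))
    model = "random" if p < model_switch_alpha else "fixed"
    return HeterogeneityResult(q=q, df=k - 1, p=p, selected_model=model)


def ivw(h, model: str = "auto",
        model_switch_alpha: float = 0.05) -> tuple[MREstimate, HeterogeneityResult]:
    """Inverse-variance-weighted estimate with Q-driven model choice.

    ``model`` is one of ``fixed``, ``random``, ``auto``; ``auto`` uses the
    random-effects (multiplicative overdispersion) se iff Cochran's Q has
    p < ``model_switch_alpha``.  A single instrument degrades to its Wald
    ratio, noted in ``extras``.
    """
    if model not in ("fixed", "random", "auto"):
        raise EstimationError(f"unknown IVW model {model!r}")
    bx, sx, by, sy = _arrays(h)
    k = len(bx)
    if k < 1:
        raise EstimationError("IVW requires at least 1 SNP")
    if k == 1:
        ratio, se = wald_ratio(bx[0], sx[0], by[0], sy[0])
        het = cochran_q(h, model_switch_alpha=model_switch_alpha)
        est = MREstimate(
            method="Wald ratio", beta=float(ratio), se=float(se),
            p=_normal_p(ratio, se), n_snp=1,
            extras={"model": "fixed", "note": "single SNP: IVW degraded to Wald ratio"},
        )
        return est, het

    w, s_xy, s_xx = _ivw_sums(bx, by, sy)
    beta = s_xy / s_xx
    fixed_se = math.sqrt(1.0 / s_xx)
    het = cochran_q(h, beta=beta, model_switch_alpha=model_switch_alpha)
    inflation = math.sqrt(max(1.0, het.q / (k - 1)))
    chosen = het.selected_model if model == "auto" else model
    se = fixed_se * inflation if chosen == "random" else fixed_se
    est = MREstimate(
        method="IVW", beta=beta, se=se, p=_normal_p(beta, se), n_snp=k,
        extras={"model": chosen, "fixed_se": fixed_se, "q": het.q, "q_p": het.p},
    )
    return est, het


def mr_egger(h) -> MREstimate:
    """MR-Egger regression: weighted slope + pleiotropy intercept.

    Exposure effects are oriented non-negative (flipping the outcome effect in
    tandem) so the intercept is interpretable as average directional
    pleiotropy.  Inference uses the t distribution on k-2 df with the residual
    variance estimate floored at 1 (multiplicative overdispersion, never
    deflating below the homogeneous-model se).
    """
    bx, sx, by, sy = _arrays(h)
    k = len(bx)
    if k < 3:
        raise EstimationError(f"MR-Egger requires at least 3 SNPs, got {k}")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx = bx * sign
    by = by * sign
    w = 1.0 / sy**2

    # weighted normal equations for by ~ intercept + slope * bx
    sw = float(np.sum(w))
    swx = float(np.sum(w * bx))
    swxx = float(np.sum(w * bx * bx))
    swy = float(np.sum(w * by))
    swxy = float(np.sum(w * bx * by))
    det = sw * swxx - swx**2
    if det <= 0:
        raise EstimationError("MR-Egger design is singular (no spread in bx)")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det

    resid = by - intercept - slope * bx
    sigma2 = max(1.0, float(np.sum(w * resid**2)) / (k - 2))
    se_slope = math.sqrt(sigma2 * sw / det)
    se_intercept = math.sqrt(sigma2 * swxx / det)
    t = stats.t(df=k - 2)
    p_slope = float(2.0 * t.sf(abs(slope / se_slope)))
    p_intercept = float(2.0 * t.sf(abs(intercept / se_intercept)))
    tq = float(t.ppf(0.975))
    return MREstimate(
        method="MR-Egger", beta=slope, se=se_slope, p=p_slope, n_snp=k,
        ci_low=slope - tq * se_slope, ci_high=slope + tq * se_slope,
        extras={
            "intercept": intercept,
            "intercept_se": se_intercept,
            "intercept_p": p_intercept,
            "sigma2": sigma2,
        },
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by midpoint cumulative-weight linear interpolation."""
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] < 0.5:
        return float(r[-1])
    below = int(np.max(np.nonzero(cum < 0.5)[0]))
    frac = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
    return float(r[below] + (r[below + 1] - r[below]) * frac)


def weighted_median(h, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap standard error.

    Per-SNP ratios by/bx are weighted by inverse ratio variance (first-order:
    (bx/sy)^2); the point estimate interpolates the weighted cumulative
    distribution at 0.5.  The se is the sd of the statistic over ``n_boot``
    parametric resamples bx* ~ N(bx, sx), by* ~ N(by, sy) — deterministic
    given ``seed``.
    """
    bx, sx, by, sy = _arrays(h)
    k = len(bx)
    if k < 3:
        raise EstimationError(f"weighted median requires at least 3 SNPs, got {k}")
    if n_boot < 2:
        raise EstimationError("n_boot must be >= 2")
    ratios = by / bx
    weights = (bx / sy) ** 2
    point = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, k))
    by_star = rng.normal(by, sy, size=(n_boot, k))
    boot = np.empty(n_boot)
    for i in range(n_boot):
        r = by_star[i] / bx_star[i]
        w = (bx_star[i] / sy) ** 2
        boot[i] = _weighted_median_point(r, w)
    se = float(np.std(boot, ddof=1))
    return MREstimate(
        method="Weighted median", beta=point, se=se, p=_normal_p(point, se),
        n_snp=k, extras={"n_boot": n_boot, "seed": seed, "se_method": "parametric bootstrap"},
    )
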