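"""Robustness suite: MR-PRESSO, leave-one-out, Steiger directionality, diagnostics.

MR-PRESSO follows the residual-sum-and-outlier recipe: the observed weighted
RSS around leave-one-out IVW fits is ranked against a parametric null
simulated from the fitted model (global test); each SNP's observed residual is
ranked against its own simulated residual distribution (outlier test,
Bonferroni-adjusted); and the shift in the IVW slope after removing flagged
SNPs is compared against removals of random same-size subsets (distortion
test).

The Steiger test compares the variance the instruments explain in the
exposure versus the outcome (per-SNP r^2 ~ z^2/(z^2+N)) via Fisher
z-transforms: a causal interpretation in the forward direction requires the
instruments to explain more of the exposure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, _arrays, ivw
from .exceptions import DataError, EstimationError, PressoNotApplicableError

__all__ = [
    "PressoResult",
    "SteigerResult",
    "mr_presso",
    "leave_one_out",
    "steiger",
    "steiger_filter",
    "export_diagnostics",
]


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss: float
    global_p: float
    outlier_p: pd.Series           # per-SNP simulation p-values (indexed by SNP)
    outliers: list[str]            # flagged SNP ids (Bonferroni at outlier_alpha)
    distortion_p: float            # NaN when no outlier was flagged
    corrected_estimate: MREstimate | None
    n_sim: int
    seed: int
    extras: dict = field(default_factory=dict)


@dataclass
class SteigerResult:
    """Directionality test: do the instruments explain more of the exposure?"""

    r2_exposure: float
    r2_outcome: float
    direction: str                 # "forward" | "reverse"
    p: float
    note: str = ""

    @property
    def passes_gate(self) -> bool:
        """Reverse-causality gate: forward direction with p <= 0.05."""
        return self.direction == "forward" and self.p <= 0.05



def _frame(h) -> pd.DataFrame | None:
    """The underlying harmonized DataFrame, when there is one."""
    if hasattr(h, "table"):
        return h.table
    if isinstance(h, pd.DataFrame):
        return h
    return None


def _snp_names(h, k) -> list[str]:
    f = _frame(h)
    if f is not None and "SNP" in f.columns:
        return f["SNP"].tolist()
    return [f"snp{i}" for i in range(k)]

def _loo_betas(bx, by, w):
    """Leave-one-out IVW slopes via sum updates (vectorized over omitted SNP)."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx * bx)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


def mr_presso(h, n_sim: int = 1000, outlier_alpha: float = 0.05,
              seed: int = 0) -> PressoResult:
    """MR-PRESSO residual-sum-and-outlier test.

    Requires at least 4 instruments and ``n_sim >= 100`` simulations; fully
    deterministic given ``seed``.  Flagged outliers are removed from the
    corrected IVW estimate; the distortion p-value compares the induced slope
    shift with removals of random subsets of the same size.
    """
    bx, sx, by, sy = _arrays(h)
    k = len(bx)
    if k < 4:
        raise PressoNotApplicableError(f"MR-PRESSO requires at least 4 SNPs, got {k}")
    if n_sim < 100:
        raise EstimationError("n_sim must be >= 100")
    snps = _snp_names(h, k)
    w = 1.0 / sy**2

    beta_loo = _loo_betas(bx, by, w)
    resid_obs = by - beta_loo * bx
    rss_obs = float(np.sum(w * resid_obs**2))

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_sim, k))
    by_star = rng.normal(beta_loo * bx, sy, size=(n_sim, k))
    w_row = w[None, :]
    s_xy = np.sum(w_row * bx_star * by_star, axis=1, keepdims=True)
    s_xx = np.sum(w_row * bx_star * bx_star, axis=1, keepdims=True)
    beta_loo_star = (s_xy - w_row * bx_star * by_star) / (s_xx - w_row * bx_star**2)
    resid_star = by_star - beta_loo_star * bx_star
    wres_star = w_row * resid_star**2
    rss_star = np.sum(wres_star, axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))

    wres_obs = w * resid_obs**2
    outlier_p = (1 + np.sum(wres_star >= wres_obs[None, :], axis=0)) / (n_sim + 1)
    outlier_p = pd.Series(outlier_p, index=snps, name="outlier_p")
    flagged_mask = outlier_p.to_numpy() < outlier_alpha / k  # Bonferroni
    outliers = [s for s, f in zip(snps, flagged_mask) if f]

    corrected = None
    distortion_p = math.nan
    extras: dict = {}
    if outliers and k - len(outliers) >= 2:
        keep = ~flagged_mask
        full_est, _ = ivw((bx, sx, by, sy), model="fixed")
        corrected, _ = ivw((bx[keep], sx[keep], by[keep], sy[keep]), model="fixed")
        if corrected.beta != 0:
            d_obs = (corrected.beta - full_est.beta) / abs(corrected.beta)
            n_rand = n_sim
            m = len(outliers)
            # vectorized IVW slopes after removing random same-size subsets
            contrib_xy, contrib_xx = w * bx * by, w * bx * bx
            tot_xy, tot_xx = float(np.sum(contrib_xy)), float(np.sum(contrib_xx))
            drops = np.stack([rng.choice(k, size=m, replace=False) for _ in range(n_rand)])
            sub_beta = (tot_xy - np.take(contrib_xy, drops).sum(axis=1)) / (
                tot_xx - np.take(contrib_xx, drops).sum(axis=1)
            )
            d_rand = (sub_beta - full_est.beta) / np.abs(sub_beta)
            distortion_p = float((1 + np.sum(np.abs(d_rand) >= abs(d_obs))) / (n_rand + 1))
            extras["distortion_coefficient"] = d_obs
    elif outliers:
        extras["note"] = "too few SNPs remain after outlier removal for a corrected estimate"

    return PressoResult(
        global_rss=rss_obs, global_p=global_p, outlier_p=outlier_p,
        outliers=outliers, distortion_p=distortion_p,
        corrected_estimate=corrected, n_sim=n_sim, seed=seed, extras=extras,
    )


def leave_one_out(h, significance_alpha: float = 0.05) -> pd.DataFrame | None:
    """Per-SNP-removed IVW estimates (fixed model), plus the all-SNP row.

    Returns a table with one row per omitted SNP and a final ``ALL`` row;
    ``sign_change`` / ``significance_change`` flag omissions that alter the
    estimate's sign or its significance at ``significance_alpha``.  Returns
    None (with a warning) for fewer than 3 SNPs.
    """
    bx, sx, by, sy = _arrays(h)
    k = len(bx)
    if k < 3:
        warnings.warn("leave-one-out requires at least 3 SNPs; returning None")
        return None
    snps = _snp_names(h, k)
    full, _ = ivw((bx, sx, by, sy), model="fixed")
    rows = []
    for j in range(k):
        mask = np.ones(k, dtype=bool)
        mask[j] = False
        est, _ = ivw((bx[mask], sx[mask], by[mask], sy[mask]), model="fixed")
        rows.append(
            {
                "snp_omitted": snps[j],
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "p": est.p,
                "sign_change": bool(np.sign(est.beta) != np.sign(full.beta)),
                "significance_change": bool(
                    (est.p < significance_alpha) != (full.p < significance_alpha)
                ),
            }
        )
    rows.append(
        {
            "snp_omitted": "ALL",
            "beta": full.beta,
            "se": full.se,
            "ci_low": full.ci_low,
            "ci_high": full.ci_high,
            "p": full.p,
            "sign_change": False,
            "significance_change": False,
        }
    )
    return pd.DataFrame(rows)


def _sum_r2(beta, se, n):
    z2 = (np.asarray(beta) / np.asarray(se)) ** 2
    return float(np.sum(z2 / (z2 + np.asarray(n))))


def steiger(h, n_exposure=None, n_outcome=None) -> SteigerResult:
    """Steiger directionality test on the harmonized instrument set.

    Per-SNP variance explained is approximated as z^2/(z^2+N) and summed per
    trait; the difference of Fisher z-transformed multiple correlations is
    tested with a two-sample z-test.  Sample sizes default to the harmonized
    table's N columns.
    """
    bx, sx, by, sy = _arrays(h)
    if len(bx) < 1:
        raise EstimationError("Steiger test requires at least 1 SNP")
    if n_exposure is None or n_outcome is None:
        f = _frame(h)
        if f is not None and {"n_exposure", "n_outcome"} <= set(f.columns):
            n_exp_arr = f["n_exposure"].to_numpy(float)
            n_out_arr = f["n_outcome"].to_numpy(float)
        else:
            raise DataError(
                "Steiger test needs sample sizes: pass n_exposure/n_outcome or use a "
                "HarmonizedSet carrying N columns"
            )
    else:
        n_exp_arr = np.full(len(bx), float(n_exposure))
        n_out_arr = np.full(len(bx), float(n_outcome))
    n_exp, n_out = float(np.mean(n_exp_arr)), float(np.mean(n_out_arr))
    if n_exp < 10 or n_out < 10:
        raise DataError("Steiger test requires sample sizes >= 10")

    r2_x = min(_sum_r2(bx, sx, n_exp_arr), 1.0 - 1e-12)
    r2_y = min(_sum_r2(by, sy, n_out_arr), 1.0 - 1e-12)
    z_x = np.arctanh(math.sqrt(r2_x))
    z_y = np.arctanh(math.sqrt(r2_y))
    se_diff = math.sqrt(1.0 / (n_exp - 3.0) + 1.0 / (n_out - 3.0))
    z = (z_x - z_y) / se_diff
    p = float(2.0 * stats.norm.sf(abs(z)))
    note = ""
    if r2_x == r2_y:
        direction = "forward"
        note = "r2 tie broken to forward"
        warnings.warn("Steiger r2 values exactly equal; direction tie broken to forward")
    else:
        direction = "forward" if r2_x > r2_y else "reverse"
    return SteigerResult(r2_exposure=r2_x, r2_outcome=r2_y, direction=direction,
                         p=p, note=note)


def steiger_filter(h, keep_equal: bool = True):
    """Optional per-SNP Steiger filter: keep instruments explaining more of the exposure.

    Returns a new HarmonizedSet-like table restricted to SNPs whose per-SNP
    r^2 in the exposure exceeds (or ties, when ``keep_equal``) that in the
    outcome.
    """
    if not (hasattr(h, "table") and {"n_exposure", "n_outcome"} <= set(h.table.columns)):
        raise DataError("steiger_filter requires a HarmonizedSet with N columns")
    t = h.table
    zx2 = (t["beta_exposure"] / t["se_exposure"]) ** 2
    zy2 = (t["beta_outcome"] / t["se_outcome"]) ** 2
    r2x = zx2 / (zx2 + t["n_exposure"])
    r2y = zy2 / (zy2 + t["n_outcome"])
    keep = (r2x >= r2y) if keep_equal else (r2x > r2y)
    out = type(h)(table=t[keep].reset_index(drop=True), audit=h.audit,
                  exposure=h.exposure, outcome=h.outcome)
    return out


def export_diagnostics(h, estimates: list[MREstimate] | None = None) -> dict[str, pd.DataFrame]:
    """Per-SNP data tables behind scatter and funnel plots (no rendering).

    ``scatter``: bx, by and their se's plus one column of fitted slopes per
    estimate; ``funnel``: per-SNP Wald ratio against its precision 1/se.
    """
    bx, sx, by, sy = _arrays(h)
    snps = _snp_names(h, len(bx))
    scatter = pd.DataFrame(
        {
            "SNP": snps,
            "beta_exposure": bx,
            "se_exposure": sx,
            "beta_outcome": by,
            "se_outcome": sy,
        }
    )
    with np.errstate(divide="ignore"):
        ratio = np.where(bx != 0, by / bx, np.nan)
        se_ratio = np.where(bx != 0, np.abs(sy / bx), np.nan)
    funnel = pd.DataFrame(
        {
            "SNP": snps,
            "ratio": ratio,
            "se_ratio": se_ratio,
            "precision": np.where(se_ratio > 0, 1.0 / se_ratio, np.nan),
        }
    )
    if estimates:
        for est in estimates:
            col = est.method.lower().replace(" ", "_").replace("-", "_")
            scatter[f"slope_{col}"] = est.beta
            if "intercept" in est.extras:
                scatter[f"intercept_{col}"] = est.extras["intercept"]
    return {"scatter": scatter, "funnel": funnel}
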