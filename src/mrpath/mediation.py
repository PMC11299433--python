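"""Two-step mediation analysis on GWAS summary statistics.

The total causal effect beta of the exposure on the outcome is estimated by
univariable MR; the two steps estimate beta1 (exposure -> mediator, using the
exposure's instruments) and beta2 (mediator -> outcome, using the mediator's
own instruments at a relaxed significance threshold).  The mediated proportion
is 100 * beta1*beta2 / beta with a first-order delta-method confidence
interval treating the three estimates as independent (they come from
non-overlapping samples):

    var(prop) ~ (b2/b)^2 se1^2 + (b1/b)^2 se2^2 + (b1 b2 / b^2)^2 se_b^2

Mediator screening keeps a candidate iff both legs reach IVW p < 0.05 and
neither leg shows Steiger evidence of reverse causation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, Z95, ivw
from .exceptions import MRPathError, NoInstrumentsError
from .instruments import harmonize, select_instruments
from .sensitivity import SteigerResult, steiger

__all__ = [
    "MediationConfig",
    "MediationResult",
    "mediated_proportion",
    "delta_ci",
    "run_mediation",
    "screen_mediators",
]

DELTA_VARIANT = "first-order delta, independent estimates"


@dataclass(frozen=True)
class MediationConfig:
    """Thresholds and options for the two-step analysis."""

    p_exposure: float = 5e-8       # instrument threshold for exposure legs
    p_mediator: float = 5e-6       # relaxed threshold for mediator instruments
    f_min: float = 10.0
    r2_max: float = 0.001
    window_kb: float = 10_000.0
    model_switch_alpha: float = 0.05
    screen_alpha: float = 0.05     # per-leg IVW significance for screening
    apply_steiger_gate: bool = True
    multiple_testing: str | None = None  # None | "bonferroni" | "fdr"
    seed: int = 0


@dataclass
class MediationResult:
    """One mediation pathway: total effect, step effects, mediated proportion."""

    exposure: str
    mediator: str
    outcome: str
    total: MREstimate              # beta  (exposure -> outcome)
    leg1: MREstimate               # beta1 (exposure -> mediator)
    leg2: MREstimate               # beta2 (mediator -> outcome)
    proportion: float              # percent
    proportion_ci: tuple[float, float]
    steiger_total: SteigerResult | None = None
    steiger_leg1: SteigerResult | None = None
    steiger_leg2: SteigerResult | None = None
    ci_variant: str = DELTA_VARIANT
    extras: dict = field(default_factory=dict)

    @property
    def indirect(self) -> float:
        return self.leg1.beta * self.leg2.beta

    def to_row(self) -> dict:
        """Serialize as a mediation-table row (point estimates with 95% CIs)."""
        return {
            "exposure": self.exposure,
            "mediator": self.mediator,
            "outcome": self.outcome,
            "beta_total": self.total.beta,
            "beta_total_ci_low": self.total.ci_low,
            "beta_total_ci_high": self.total.ci_high,
            "beta1": self.leg1.beta,
            "beta1_ci_low": self.leg1.ci_low,
            "beta1_ci_high": self.leg1.ci_high,
            "beta2": self.leg2.beta,
            "beta2_ci_low": self.leg2.ci_low,
            "beta2_ci_high": self.leg2.ci_high,
            "indirect": self.indirect,
            "proportion_pct": self.proportion,
            "proportion_ci_low": self.proportion_ci[0],
            "proportion_ci_high": self.proportion_ci[1],
            "ci_variant": self.ci_variant,
        }


def mediated_proportion(beta_total: float, beta1: float, beta2: float) -> float:
    """Mediated proportion in percent: 100 * (beta1*beta2) / beta_total.

    Negative proportions are legal (an indirect path opposing the total
    effect).  Undefined for beta_total = 0.
    """
    if beta_total == 0:
        raise ValueError("mediated proportion undefined for beta_total = 0")
    return 100.0 * (beta1 * beta2) / beta_total


def delta_ci(beta1: float, se1: float, beta2: float, se2: float,
             beta_total: float, se_total: float,
             level: float = 0.95) -> tuple[float, float]:
    """First-order delta-method CI for the mediated proportion (percent).

    Propagates var(beta1), var(beta2), var(beta_total) through
    f = beta1*beta2/beta_total assuming independent estimates.  With all ses
    zero the interval collapses to the point estimate.
    """
    if beta_total == 0:
        raise ValueError("mediated proportion undefined for beta_total = 0")
    if min(se1, se2, se_total) < 0:
        raise ValueError("standard errors must be >= 0")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    prop = mediated_proportion(beta_total, beta1, beta2)
    var = (
        (beta2 / beta_total) ** 2 * se1**2
        + (beta1 / beta_total) ** 2 * se2**2
        + (beta1 * beta2 / beta_total**2) ** 2 * se_total**2
    )
    z = Z95 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2.0))
    half = 100.0 * z * math.sqrt(var)
    return prop - half, prop + half


def _uvmr_leg(exposure_df, outcome_df, p_threshold, cfg: MediationConfig,
              trait: str, seed_offset: int = 0):
    """One UVMR leg: select -> harmonize -> Q-driven IVW (+Steiger)."""
    inst = select_instruments(
        exposure_df, p_threshold=p_threshold, f_min=cfg.f_min,
        r2_max=cfg.r2_max, window_kb=cfg.window_kb, trait=trait,
    )
    h = harmonize(inst, outcome_df, exposure_label=trait)
    if h.n_snp == 0:
        raise NoInstrumentsError(trait, f"no harmonizable instruments for {trait!r}")
    est, het = ivw(h, model="auto", model_switch_alpha=cfg.model_switch_alpha)
    st = steiger(h)
    return est, het, st, h


def run_mediation(
    exposure_df: pd.DataFrame,
    mediator_df: pd.DataFrame,
    outcome_df: pd.DataFrame,
    config: MediationConfig | None = None,
    exposure: str = "exposure",
    mediator: str = "mediator",
    outcome: str = "outcome",
) -> MediationResult:
    """Full two-step mediation for one exposure/mediator/outcome triple.

    beta comes from the exposure->outcome UVMR (Q-driven fixed/random IVW),
    beta1 from exposure->mediator with the same instruments, beta2 from
    mediator->outcome with the mediator's instruments at the relaxed
    threshold; the mediated proportion and its delta-method CI are assembled
    from the three legs.
    """
    cfg = config or MediationConfig()
    total, _, st_total, _ = _uvmr_leg(exposure_df, outcome_df, cfg.p_exposure, cfg, exposure)
    leg1, _, st1, _ = _uvmr_leg(exposure_df, mediator_df, cfg.p_exposure, cfg, exposure)
    leg2, _, st2, _ = _uvmr_leg(mediator_df, outcome_df, cfg.p_mediator, cfg, mediator)

    prop = mediated_proportion(total.beta, leg1.beta, leg2.beta)
    ci = delta_ci(leg1.beta, leg1.se, leg2.beta, leg2.se, total.beta, total.se)
    return MediationResult(
        exposure=exposure, mediator=mediator, outcome=outcome,
        total=total, leg1=leg1, leg2=leg2,
        proportion=prop, proportion_ci=ci,
        steiger_total=st_total, steiger_leg1=st1, steiger_leg2=st2,
    )


def _adjust(pvals: np.ndarray, method: str | None) -> np.ndarray:
    if method is None:
        return pvals
    m = len(pvals)
    if method == "bonferroni":
        return np.minimum(pvals * m, 1.0)
    if method == "fdr":  # Benjamini-Hochberg
        order = np.argsort(pvals)
        ranked = pvals[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown multiple-testing method {method!r}")


def screen_mediators(
    exposure_df: pd.DataFrame,
    panel: dict[str, pd.DataFrame],
    outcome_df: pd.DataFrame,
    config: MediationConfig | None = None,
    exposure: str = "exposure",
    outcome: str = "outcome",
) -> tuple[list[MediationResult], pd.DataFrame]:
    """Screen a mediator panel for candidates carrying part of the effect.

    For every panel trait, leg 1 (exposure -> mediator) and leg 2
    (mediator -> outcome, relaxed instrument threshold) are estimated by IVW;
    a mediator survives iff both legs have p < ``screen_alpha`` and both pass
    the Steiger reverse-causality gate.  Survivors (full MediationResults,
    ordered by leg-2 p) are returned together with a long-format audit table
    over the whole panel — the per-mediator leg-1 estimates behind a panel
    heatmap.
    """
    cfg = config or MediationConfig()
    audit_rows = []
    legs: dict[str, dict] = {}
    for name, med_df in panel.items():
        rec: dict = {"mediator": name}
        try:
            leg1, _, st1, _ = _uvmr_leg(exposure_df, med_df, cfg.p_exposure, cfg, exposure)
            rec.update(leg1=leg1, steiger1=st1)
            audit_rows.append(
                {
                    "exposure": exposure,
                    "mediator": name,
                    "beta": leg1.beta,
                    "se": leg1.se,
                    "p": leg1.p,
                    "nsnp": leg1.n_snp,
                    "status": "ok",
                }
            )
        except MRPathError as exc:
            audit_rows.append(
                {
                    "exposure": exposure,
                    "mediator": name,
                    "beta": math.nan,
                    "se": math.nan,
                    "p": math.nan,
                    "nsnp": 0,
                    "status": f"skipped: {exc}",
                }
            )
            continue
        try:
            leg2, _, st2, _ = _uvmr_leg(med_df, outcome_df, cfg.p_mediator, cfg, name)
            rec.update(leg2=leg2, steiger2=st2)
        except MRPathError as exc:
            audit_rows[-1]["status"] = f"leg2 skipped: {exc}"
            continue
        legs[name] = rec

    raw_p1 = np.array([legs[n]["leg1"].p for n in legs]) if legs else np.empty(0)
    raw_p2 = np.array([legs[n]["leg2"].p for n in legs]) if legs else np.empty(0)
    adj_p1 = _adjust(raw_p1, cfg.multiple_testing)
    adj_p2 = _adjust(raw_p2, cfg.multiple_testing)

    survivors = []
    for i, name in enumerate(legs):
        rec = legs[name]
        ok = adj_p1[i] < cfg.screen_alpha and adj_p2[i] < cfg.screen_alpha
        if cfg.apply_steiger_gate:
            ok = ok and rec["steiger1"].passes_gate and rec["steiger2"].passes_gate
        if not ok:
            continue
        try:
            res = run_mediation(
                exposure_df, panel[name], outcome_df, cfg,
                exposure=exposure, mediator=name, outcome=outcome,
            )
        except MRPathError:
            continue
        survivors.append(res)
    survivors.sort(key=lambda r: r.leg2.p)
    audit = pd.DataFrame(
        audit_rows,
        columns=["exposure", "mediator", "beta", "se", "p", "nsnp", "status"],
    )
    return survivors, audit
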