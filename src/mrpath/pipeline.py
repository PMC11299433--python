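"""Two-phase orchestration: a UVMR screen, then mediation over a panel.

Phase 1 runs, for every exposure x outcome pair: instrument selection,
harmonization, Cochran's Q with the Q-driven fixed/random IVW model choice,
MR-Egger and weighted median, the sensitivity suite (PRESSO, leave-one-out,
Steiger), and — when Steiger suggests reverse causation — an automatic
reverse-direction UVMR.  Pairs with IVW p < 0.05, forward Steiger direction
and no significant reverse signal are phase-2 eligible.

Phase 2 screens the mediator panel for each eligible pair and emits one
mediation row per surviving mediator.

Everything is a pure function of (config, master seed): per-stage seeds are
derived deterministically from the master seed and stage name, so any stage
can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import ivw, mr_egger, weighted_median
from .exceptions import ConfigurationError, MRPathError
from .instruments import harmonize, select_instruments
from .io import read_sumstats
from .mediation import MediationConfig, screen_mediators
from .sensitivity import export_diagnostics, leave_one_out, mr_presso, steiger

logger = logging.getLogger("mrpath")

__all__ = ["TraitSpec", "RunConfig", "run_phase1", "run_phase2", "run_all", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed: sha256(master || stage) mod 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class TraitSpec:
    """One registry entry: where a trait's summary statistics live."""

    label: str
    path: str
    n: int | None = None
    trait_type: str = "binary"  # binary | continuous


@dataclass
class RunConfig:
    """Run-level configuration for the two-phase analysis."""

    traits: dict[str, TraitSpec]
    exposures: list[str]
    outcomes: list[str]
    mediators: list[str] = field(default_factory=list)
    p_exposure: float = 5e-8
    p_exposure_relaxed: float = 5e-6   # fallback when no instruments at p_exposure
    p_mediator: float = 5e-6
    f_min: float = 10.0
    r2_max: float = 0.001
    window_kb: float = 10_000.0
    model_switch_alpha: float = 0.05
    screen_alpha: float = 0.05
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    output_dir: str = "mrpath_run"

    def validate(self) -> "RunConfig":
        labels = set(self.traits)
        for role, names in (("exposures", self.exposures),
                            ("outcomes", self.outcomes),
                            ("mediators", self.mediators)):
            unknown = [n for n in names if n not in labels]
            if unknown:
                raise ConfigurationError(role, f"unknown trait labels {unknown}")
        for thr in ("p_exposure", "p_exposure_relaxed", "p_mediator"):
            v = getattr(self, thr)
            if not 0 < v <= 1:
                raise ConfigurationError(thr, "must lie in (0, 1]")
        if self.n_sim < 100:
            raise ConfigurationError("n_sim", "must be >= 100")
        if self.n_boot < 2:
            raise ConfigurationError("n_boot", "must be >= 2")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError("config", f"{path} is not a mapping")
        base = os.path.dirname(os.path.abspath(path))
        traits = {}
        for label, spec in raw.get("traits", {}).items():
            p = spec["path"]
            if not os.path.isabs(p):
                p = os.path.join(base, p)
            traits[label] = TraitSpec(
                label=label, path=p, n=spec.get("n"),
                trait_type=spec.get("type", "binary"),
            )
        thresholds = raw.get("thresholds", {})
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in raw.items()
                  if k in known and k not in ("traits",)}
        kwargs.update({k: v for k, v in thresholds.items() if k in known})
        cfg = cls(traits=traits, **kwargs)
        return cfg.validate()

    def mediation_config(self) -> MediationConfig:
        return MediationConfig(
            p_exposure=self.p_exposure,
            p_mediator=self.p_mediator,
            f_min=self.f_min,
            r2_max=self.r2_max,
            window_kb=self.window_kb,
            model_switch_alpha=self.model_switch_alpha,
            screen_alpha=self.screen_alpha,
            seed=stage_seed(self.seed, "mediation"),
        )


def _load(cfg: RunConfig, label: str) -> pd.DataFrame:
    return read_sumstats(cfg.traits[label].path, name=label)


def _select_with_fallback(cfg: RunConfig, df, label):
    """Select at the primary threshold, relaxing once if nothing survives."""
    from .exceptions import NoInstrumentsError

    try:
        return select_instruments(
            df, p_threshold=cfg.p_exposure, f_min=cfg.f_min,
            r2_max=cfg.r2_max, window_kb=cfg.window_kb, trait=label,
        )
    except NoInstrumentsError:
        logger.info("trait %s: relaxing instrument threshold to %g",
                    label, cfg.p_exposure_relaxed)
        return select_instruments(
            df, p_threshold=cfg.p_exposure_relaxed, f_min=cfg.f_min,
            r2_max=cfg.r2_max, window_kb=cfg.window_kb, trait=label,
        )


def _estimate_to_dict(est) -> dict:
    d = est.to_row()
    d["ci_low"], d["ci_high"] = est.ci_low, est.ci_high
    return d


def _analyse_pair(cfg: RunConfig, exp_label: str, out_label: str,
                  exp_df, out_df) -> dict:
    """Full UVMR + sensitivity analysis for one exposure->outcome pair."""
    inst = _select_with_fallback(cfg, exp_df, exp_label)
    h = harmonize(inst, out_df, exposure_label=exp_label, outcome_label=out_label)
    if h.n_snp == 0:
        raise MRPathError(f"{exp_label}->{out_label}: no harmonizable instruments")

    est_ivw, het = ivw(h, model="auto", model_switch_alpha=cfg.model_switch_alpha)
    estimates = {"IVW": est_ivw}
    if h.n_snp >= 3:
        estimates["MR-Egger"] = mr_egger(h)
        estimates["Weighted median"] = weighted_median(
            h, n_boot=cfg.n_boot,
            seed=stage_seed(cfg.seed, f"wm:{exp_label}:{out_label}"),
        )

    result: dict = {
        "exposure": exp_label,
        "outcome": out_label,
        "n_snp": h.n_snp,
        "instrument_provenance": inst.provenance,
        "estimates": {k: _estimate_to_dict(v) for k, v in estimates.items()},
        "heterogeneity": {
            "q": het.q, "df": het.df, "p": het.p, "selected_model": het.selected_model,
        },
    }

    st = steiger(h)
    result["steiger"] = {
        "r2_exposure": st.r2_exposure, "r2_outcome": st.r2_outcome,
        "direction": st.direction, "p": st.p,
    }
    if h.n_snp >= 4:
        presso = mr_presso(
            h, n_sim=cfg.n_sim,
            seed=stage_seed(cfg.seed, f"presso:{exp_label}:{out_label}"),
        )
        result["presso"] = {
            "global_rss": presso.global_rss,
            "global_p": presso.global_p,
            "outliers": presso.outliers,
            "distortion_p": None if math.isnan(presso.distortion_p) else presso.distortion_p,
            "corrected_beta": None if presso.corrected_estimate is None
            else presso.corrected_estimate.beta,
        }
    else:
        result["presso"] = {"status": "not applicable (fewer than 4 SNPs)"}
    loo = leave_one_out(h)
    if loo is not None:
        result["loo_flags"] = {
            "sign_change": loo["sign_change"].any().item(),
            "significance_change": loo["significance_change"].any().item(),
        }
        result["_loo_table"] = loo
    result["_harmonized"] = h
    result["_estimates_obj"] = estimates

    # reverse-direction UVMR when Steiger suggests reverse causation
    reverse_triggered = st.p > 0.05 or st.direction == "reverse"
    result["reverse_mr"] = None
    reverse_significant = False
    if reverse_triggered:
        try:
            rev_inst = _select_with_fallback(cfg, out_df, out_label)
            rev_h = harmonize(rev_inst, exp_df, exposure_label=out_label,
                              outcome_label=exp_label)
            if rev_h.n_snp >= 1:
                rev_est, _ = ivw(rev_h, model="auto",
                                 model_switch_alpha=cfg.model_switch_alpha)
                reverse_significant = rev_est.p < 0.05
                result["reverse_mr"] = {
                    "beta": rev_est.beta, "se": rev_est.se, "p": rev_est.p,
                    "n_snp": rev_est.n_snp, "significant": reverse_significant,
                }
        except MRPathError as exc:
            result["reverse_mr"] = {"status": f"skipped: {exc}"}

    result["phase2_eligible"] = bool(
        est_ivw.p < 0.05 and st.direction == "forward" and not reverse_significant
    )
    return result


def run_phase1(config: RunConfig) -> dict:
    """UVMR screen over every exposure x outcome pair (phase 1)."""
    cfg = config.validate()
    pairs = []
    for out_label in cfg.outcomes:
        out_df = _load(cfg, out_label)
        for exp_label in cfg.exposures:
            exp_df = _load(cfg, exp_label)
            try:
                pairs.append(_analyse_pair(cfg, exp_label, out_label, exp_df, out_df))
            except MRPathError as exc:
                logger.warning("pair %s->%s skipped: %s", exp_label, out_label, exc)
                pairs.append(
                    {
                        "exposure": exp_label,
                        "outcome": out_label,
                        "skip_reason": str(exc),
                        "phase2_eligible": False,
                    }
                )
    return {"phase": 1, "pairs": pairs, "seed": cfg.seed}


def run_phase2(config: RunConfig, phase1_report: dict) -> dict:
    """Mediator screen + mediation rows for every phase-2-eligible pair."""
    cfg = config.validate()
    med_cfg = cfg.mediation_config()
    panel = {m: _load(cfg, m) for m in cfg.mediators}
    mediation_rows, screens = [], []
    for pair in phase1_report["pairs"]:
        if not pair.get("phase2_eligible"):
            continue
        exp_label, out_label = pair["exposure"], pair["outcome"]
        exp_df, out_df = _load(cfg, exp_label), _load(cfg, out_label)
        survivors, audit = screen_mediators(
            exp_df, panel, out_df, med_cfg, exposure=exp_label, outcome=out_label
        )
        audit = audit.assign(outcome=out_label)
        screens.append(audit)
        mediation_rows.extend(r.to_row() for r in survivors)
    return {
        "phase": 2,
        "mediation_rows": mediation_rows,
        "screen_audit": (
            pd.concat(screens, ignore_index=True) if screens else pd.DataFrame(
                columns=["exposure", "mediator", "beta", "se", "p", "nsnp",
                         "status", "outcome"]
            )
        ),
        "seed": cfg.seed,
    }


def _uvmr_table(phase1: dict) -> pd.DataFrame:
    rows = []
    for pair in phase1["pairs"]:
        if "skip_reason" in pair:
            continue
        for method, est in pair["estimates"].items():
            rows.append(
                {
                    "exposure": pair["exposure"],
                    "outcome": pair["outcome"],
                    "method": method,
                    "nsnp": est["nsnp"],
                    "beta": est["beta"],
                    "se": est["se"],
                    "OR": est["OR"],
                    "or_ci_low": est["or_ci_low"],
                    "or_ci_high": est["or_ci_high"],
                    "p": est["p"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["exposure", "outcome", "method", "nsnp", "beta", "se",
                 "OR", "or_ci_low", "or_ci_high", "p"],
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items() if not str(k).startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def run_all(config: RunConfig, write: bool = True) -> dict:
    """Both phases end to end; optionally write the run directory.

    Outputs under ``config.output_dir``: uvmr.tsv, sensitivity.json,
    mediation.tsv, diagnostics/<pair>.tsv and provenance.json.  Byte-identical
    across runs with the same (config, seed).
    """
    cfg = config.validate()
    phase1 = run_phase1(cfg)
    phase2 = run_phase2(cfg, phase1)
    report = {"phase1": phase1, "phase2": phase2}
    if not write:
        return report

    outdir = cfg.output_dir
    os.makedirs(outdir, exist_ok=True)
    _uvmr_table(phase1).to_csv(os.path.join(outdir, "uvmr.tsv"), sep="\t", index=False)

    sens = []
    for pair in phase1["pairs"]:
        if "skip_reason" in pair:
            sens.append(_jsonable(pair))
            continue
        sens.append(_jsonable(pair))
    with open(os.path.join(outdir, "sensitivity.json"), "w") as fh:
        json.dump(sens, fh, indent=1, sort_keys=True)
        fh.write("\n")

    med_df = pd.DataFrame(phase2["mediation_rows"])
    med_cols = [
        "exposure", "mediator", "outcome",
        "beta_total", "beta_total_ci_low", "beta_total_ci_high",
        "beta1", "beta1_ci_low", "beta1_ci_high",
        "beta2", "beta2_ci_low", "beta2_ci_high",
        "indirect", "proportion_pct", "proportion_ci_low", "proportion_ci_high",
        "ci_variant",
    ]
    if med_df.empty:
        med_df = pd.DataFrame(columns=med_cols)
    med_df.loc[:, med_cols].to_csv(os.path.join(outdir, "mediation.tsv"),
                                   sep="\t", index=False)
    phase2["screen_audit"].to_csv(os.path.join(outdir, "screen_audit.tsv"),
                                  sep="\t", index=False)

    diag_dir = os.path.join(outdir, "diagnostics")
    os.makedirs(diag_dir, exist_ok=True)
    for pair in phase1["pairs"]:
        if "_harmonized" not in pair:
            continue
        tag = f"{pair['exposure']}__{pair['outcome']}"
        tables = export_diagnostics(pair["_harmonized"],
                                    list(pair["_estimates_obj"].values()))
        for kind, df in tables.items():
            df.to_csv(os.path.join(diag_dir, f"{tag}.{kind}.tsv"),
                      sep="\t", index=False)
        if "_loo_table" in pair:
            pair["_loo_table"].to_csv(os.path.join(diag_dir, f"{tag}.loo.tsv"),
                                      sep="\t", index=False)

    provenance = {
        "package": "mrpath",
        "version": __version__,
        "seed": cfg.seed,
        "config": _jsonable(
            {
                **{k: v for k, v in dataclasses.asdict(cfg).items() if k != "traits"},
                "traits": {k: dataclasses.asdict(v) for k, v in cfg.traits.items()},
            }
        ),
        "stage_seeds": {
            "mediation": stage_seed(cfg.seed, "mediation"),
        },
    }
    with open(os.path.join(outdir, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


def write_demo(directory, seed: int = 0, n_snps: int = 60,
               n_mediator_snps: int = 40) -> str:
    """Write a self-contained demo study (data + config.yaml); returns config path.

    The demo registry holds one causal exposure (true effect 0.1, 20% of it
    mediated), one null exposure, one outcome, the true mediator and two null
    mediators, all simulated from one shared SNP panel.
    """
    from .simulate import SimConfig, simulate_study

    cfg = SimConfig(
        n_snps=n_snps, n_mediator_snps=n_mediator_snps,
        beta_total=0.1, beta_x_to_m=0.4, beta_m_to_y=0.05,
        seed=seed,
    )
    tables, truths = simulate_study(cfg, n_null_mediators=2, null_exposure=True)
    os.makedirs(directory, exist_ok=True)
    registry = {}
    for name, df in tables.items():
        path = os.path.join(directory, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False)
        registry[name] = {
            "path": f"{name}.tsv",
            "n": int(df["N"].iloc[0]),
            "type": "continuous",
        }
    demo = {
        "traits": registry,
        "exposures": ["exposure", "null_exposure"],
        "outcomes": ["outcome"],
        "mediators": ["mediator", "null_mediator1", "null_mediator2"],
        "seed": seed,
        "n_boot": 200,
        "n_sim": 200,
        "output_dir": os.path.join(directory, "run"),
    }
    config_path = os.path.join(directory, "config.yaml")
    with open(config_path, "w") as fh:
        yaml.safe_dump(demo, fh, sort_keys=True)
    return config_path
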