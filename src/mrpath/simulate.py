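"""Synthetic GWAS summary statistics with a known causal structure.

The generator emulates the two-sample MR setting: per-SNP effects on an
exposure, a mediator causally downstream of the exposure, and an outcome that
receives both a direct and a mediated effect, with optional balanced or
directional horizontal pleiotropy contaminating a configurable fraction of
instruments.

Model
-----
For SNP *j* with minor-allele frequency :math:`p_j`:

* true exposure effect  :math:`\\gamma_j = |z_j|`, :math:`z_j \\sim N(0, \\sigma_\\gamma^2)`
  — effects are reported for the exposure-increasing allele, which is
  without loss of generality for a GWAS;
* true mediator effect  :math:`\\mu_j = \\beta_1 \\gamma_j + \\delta_j` where
  :math:`\\delta_j` is a mediator-specific (pQTL-like) effect carried by a
  separate block of SNPs;
* true outcome effect   :math:`\\Gamma_j = \\beta_{dir} \\gamma_j + \\beta_2 \\mu_j + \\alpha_j`
  with :math:`\\beta_{dir} = \\beta - \\beta_1\\beta_2` and :math:`\\alpha_j`
  the horizontal-pleiotropy effect (zero for valid instruments).

Each trait's table adds independent estimation noise with the standard error
of a standardized-trait GWAS, :math:`se \\approx 1/\\sqrt{2 p (1-p) N}`
(multiplied by :math:`1/\\sqrt{\\phi(1-\\phi)}` for a case-control trait with
case fraction :math:`\\phi`, on the log-odds scale), so the two samples are
non-overlapping by construction.  P-values follow the normal approximation.
Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .io import SUMSTAT_COLUMNS, validate_sumstats, write_keyvalues, write_sumstats

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_pair",
    "simulate_mediation_triple",
    "simulate_study",
    "write_fixture",
]

# ordered non-palindromic allele pairs; palindromic pairs kept separate so a
# configurable fraction of A/T & C/G SNPs can exercise harmonization
_NONPALINDROMIC = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

# default inter-SNP spacing (bp), deliberately wider than the 10,000 kb clump
# window so unlinked simulated SNPs are never window-mates
_POS_SPACING = 20_000_000


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters of a synthetic GWAS study.

    Defaults describe the study conditions emulated throughout: biobank-scale
    exposure and outcome GWAS, a pQTL-scale mediator GWAS, per-SNP exposure
    effects of complex-trait size, and no pleiotropy unless asked for.
    """

    n_snps: int = 100
    n_exposure: int = 200_000
    n_mediator: int = 30_000
    n_outcome: int = 200_000
    beta_total: float = 0.1
    beta_x_to_m: float = 0.2
    beta_m_to_y: float = 0.05
    gamma_var: float = 9e-4           # sd 0.03 per SNP on the exposure
    pleiotropy_mode: str = "none"     # none | balanced | directional
    pleiotropy_var: float = 1e-4
    pleiotropy_mean: float = 0.0
    frac_invalid: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    # mediator-specific instrument block (cis-pQTL-like effects)
    n_mediator_snps: int = 100
    mediator_gamma_var: float = 0.0225  # sd 0.15 per SNP on the mediator
    palindromic_frac: float = 0.0
    # case fractions: None = continuous standardized trait, else log-odds scale
    case_fraction_exposure: float | None = None
    case_fraction_outcome: float | None = None
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_snps < 1:
            raise ConfigurationError("n_snps", "must be >= 1")
        for fld in ("n_exposure", "n_mediator", "n_outcome"):
            if getattr(self, fld) < 2:
                raise ConfigurationError(fld, "sample size must be >= 2")
        if not 0.0 <= self.frac_invalid <= 1.0:
            raise ConfigurationError("frac_invalid", "must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range", "must lie within (0, 0.5]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigurationError("pleiotropy_mode", "must be none|balanced|directional")
        if self.pleiotropy_mode == "balanced" and self.pleiotropy_mean != 0.0:
            raise ConfigurationError("pleiotropy_mean", "must be 0 when pleiotropy_mode=balanced")
        if self.gamma_var <= 0:
            raise ConfigurationError("gamma_var", "must be > 0")
        if self.pleiotropy_var < 0:
            raise ConfigurationError("pleiotropy_var", "must be >= 0")
        if not 0.0 <= self.palindromic_frac <= 1.0:
            raise ConfigurationError("palindromic_frac", "must lie in [0, 1]")
        if self.n_mediator_snps < 0:
            raise ConfigurationError("n_mediator_snps", "must be >= 0")
        for fld in ("case_fraction_exposure", "case_fraction_outcome"):
            cf = getattr(self, fld)
            if cf is not None and not 0.0 < cf < 1.0:
                raise ConfigurationError(fld, "case fraction must lie in (0, 1)")
        return self


@dataclass
class SimTruth:
    """The generating truth of one simulated dataset (oracle for recovery tests)."""

    beta_total: float
    beta1: float | None = None
    beta2: float | None = None
    direct_effect: float | None = None
    gamma: np.ndarray = field(default_factory=lambda: np.empty(0))
    alpha: np.ndarray = field(default_factory=lambda: np.empty(0))
    delta: np.ndarray | None = None
    invalid: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    snp: list[str] = field(default_factory=list)

    @property
    def mediated_proportion(self) -> float | None:
        """True mediated proportion beta1*beta2/beta_total, as a fraction."""
        if self.beta1 is None or self.beta2 is None:
            return None
        return self.beta1 * self.beta2 / self.beta_total

    def to_mapping(self) -> dict:
        out = {
            "beta_total": self.beta_total,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "direct_effect": self.direct_effect,
            "mediated_proportion": self.mediated_proportion,
            "snp": self.snp,
            "gamma": self.gamma,
            "alpha": self.alpha,
            "invalid": self.invalid.astype(int),
        }
        if self.delta is not None:
            out["delta"] = self.delta
        return out


def _se_standardized(maf: np.ndarray, n: int, case_fraction: float | None) -> np.ndarray:
    """GWAS standard error for a standardized (or log-odds) trait."""
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    if case_fraction is not None:
        se /= np.sqrt(case_fraction * (1.0 - case_fraction))
    return se


def _pvalue(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    # P must live in (0, 1]; the normal sf can underflow to exactly 0
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _alleles(rng: np.random.Generator, n: int, palindromic_frac: float):
    pal = rng.random(n) < palindromic_frac
    idx_np = rng.integers(0, len(_NONPALINDROMIC), size=n)
    idx_p = rng.integers(0, len(_PALINDROMIC), size=n)
    ea, oa = [], []
    for j in range(n):
        a, b = _PALINDROMIC[idx_p[j]] if pal[j] else _NONPALINDROMIC[idx_np[j]]
        ea.append(a)
        oa.append(b)
    return ea, oa


def _draw_pleiotropy(rng, cfg: SimConfig, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP direct-to-outcome effects alpha and the invalid mask."""
    alpha = np.zeros(n)
    invalid = np.zeros(n, dtype=bool)
    if cfg.pleiotropy_mode == "none" or cfg.frac_invalid == 0.0:
        return alpha, invalid
    n_invalid = int(round(cfg.frac_invalid * n))
    which = rng.choice(n, size=n_invalid, replace=False)
    invalid[which] = True
    mean = cfg.pleiotropy_mean if cfg.pleiotropy_mode == "directional" else 0.0
    alpha[which] = rng.normal(mean, np.sqrt(cfg.pleiotropy_var), size=n_invalid)
    return alpha, invalid


def _table(snp, chrom, pos, ea, oa, eaf, beta, se, n) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "SNP": snp,
            "CHR": chrom,
            "POS": pos,
            "EA": ea,
            "OA": oa,
            "EAF": eaf,
            "BETA": beta,
            "SE": se,
            "P": _pvalue(np.asarray(beta), np.asarray(se)),
            "N": n,
        }
    )
    return validate_sumstats(df, "simulated")


def _base_variants(rng, cfg: SimConfig, n: int):
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n)
    snp = [f"rs{j + 1}" for j in range(n)]
    chrom = ["1"] * n
    pos = [(j + 1) * _POS_SPACING for j in range(n)]
    ea, oa = _alleles(rng, n, cfg.palindromic_frac)
    return snp, chrom, pos, ea, oa, maf


def simulate_pair(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate an exposure/outcome summary-statistic pair.

    Returns (exposure table, outcome table, truth).  Per SNP j the exposure
    effect is gamma_j and the outcome effect beta_total*gamma_j + alpha_j;
    both tables add independent estimation noise consistent with their sample
    sizes and MAF (the two GWAS samples do not overlap).
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    snp, chrom, pos, ea, oa, maf = _base_variants(rng, cfg, n)

    gamma = np.abs(rng.normal(0.0, np.sqrt(cfg.gamma_var), size=n))
    alpha, invalid = _draw_pleiotropy(rng, cfg, n)
    Gamma = cfg.beta_total * gamma + alpha

    se_x = _se_standardized(maf, cfg.n_exposure, cfg.case_fraction_exposure)
    se_y = _se_standardized(maf, cfg.n_outcome, cfg.case_fraction_outcome)
    bx = gamma + rng.normal(0.0, se_x)
    by = Gamma + rng.normal(0.0, se_y)

    exposure = _table(snp, chrom, pos, ea, oa, maf, bx, se_x, cfg.n_exposure)
    outcome = _table(snp, chrom, pos, ea, oa, maf, by, se_y, cfg.n_outcome)
    truth = SimTruth(
        beta_total=cfg.beta_total,
        direct_effect=cfg.beta_total,
        gamma=gamma,
        alpha=alpha,
        invalid=invalid,
        snp=snp,
    )
    return exposure, outcome, truth


def simulate_mediation_triple(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate an exposure/mediator/outcome triple with a known mediated path.

    The SNP panel is the union of an exposure-instrument block (gamma != 0)
    and a mediator-specific block (delta != 0, pQTL-like); all three tables
    cover every SNP.  The outcome receives direct_effect*gamma_j +
    beta_m_to_y*mu_j + alpha_j where mu_j is the true mediator effect.
    """
    cfg = config.validate()
    if cfg.beta_total == 0.0 and cfg.beta_x_to_m * cfg.beta_m_to_y != 0.0:
        raise ConfigurationError(
            "beta_total", "mediated proportion undefined: beta_total = 0 with a nonzero indirect path"
        )
    beta1, beta2 = cfg.beta_x_to_m, cfg.beta_m_to_y
    direct = cfg.beta_total - beta1 * beta2

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps + cfg.n_mediator_snps
    snp, chrom, pos, ea, oa, maf = _base_variants(rng, cfg, n)

    gamma = np.zeros(n)
    delta = np.zeros(n)
    gamma[: cfg.n_snps] = np.abs(rng.normal(0.0, np.sqrt(cfg.gamma_var), size=cfg.n_snps))
    delta[cfg.n_snps:] = np.abs(
        rng.normal(0.0, np.sqrt(cfg.mediator_gamma_var), size=cfg.n_mediator_snps)
    )
    alpha, invalid = _draw_pleiotropy(rng, cfg, n)

    mu = beta1 * gamma + delta
    Gamma = direct * gamma + beta2 * mu + alpha

    se_x = _se_standardized(maf, cfg.n_exposure, cfg.case_fraction_exposure)
    se_m = _se_standardized(maf, cfg.n_mediator, None)
    se_y = _se_standardized(maf, cfg.n_outcome, cfg.case_fraction_outcome)
    bx = gamma + rng.normal(0.0, se_x)
    bm = mu + rng.normal(0.0, se_m)
    by = Gamma + rng.normal(0.0, se_y)

    exposure = _table(snp, chrom, pos, ea, oa, maf, bx, se_x, cfg.n_exposure)
    mediator = _table(snp, chrom, pos, ea, oa, maf, bm, se_m, cfg.n_mediator)
    outcome = _table(snp, chrom, pos, ea, oa, maf, by, se_y, cfg.n_outcome)
    truth = SimTruth(
        beta_total=cfg.beta_total,
        beta1=beta1,
        beta2=beta2,
        direct_effect=direct,
        gamma=gamma,
        alpha=alpha,
        delta=delta,
        invalid=invalid,
        snp=snp,
    )
    return exposure, mediator, outcome, truth


def simulate_study(
    config: SimConfig,
    n_null_mediators: int = 2,
    null_exposure: bool = True,
) -> tuple[dict[str, pd.DataFrame], dict[str, SimTruth]]:
    """Simulate a small multi-trait registry sharing one SNP panel.

    Produces a causal exposure -> mediator -> outcome triple plus, optionally,
    a null exposure (beta_total = 0, its own instrument block) and null
    mediators (pQTL blocks with no effect on the outcome).  Used by the demo
    configuration and the end-to-end pipeline tests.
    """
    cfg = config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 9151]))
    beta1, beta2 = cfg.beta_x_to_m, cfg.beta_m_to_y
    direct = cfg.beta_total - beta1 * beta2

    n_blocks = 1 + (1 if null_exposure else 0) + 1 + n_null_mediators
    n = cfg.n_snps * (1 if null_exposure else 0) + cfg.n_snps \
        + cfg.n_mediator_snps * (1 + n_null_mediators)
    snp, chrom, pos, ea, oa, maf = _base_variants(rng, cfg, n)

    # block layout: [exposure | null exposure? | mediator | null mediators...]
    blocks: dict[str, slice] = {}
    start = 0
    blocks["EXP"] = slice(start, start + cfg.n_snps)
    start += cfg.n_snps
    if null_exposure:
        blocks["EXP_NULL"] = slice(start, start + cfg.n_snps)
        start += cfg.n_snps
    blocks["MED"] = slice(start, start + cfg.n_mediator_snps)
    start += cfg.n_mediator_snps
    for i in range(n_null_mediators):
        blocks[f"MED_NULL{i + 1}"] = slice(start, start + cfg.n_mediator_snps)
        start += cfg.n_mediator_snps

    def block_effects(key, var):
        eff = np.zeros(n)
        sl = blocks[key]
        eff[sl] = np.abs(rng.normal(0.0, np.sqrt(var), size=sl.stop - sl.start))
        return eff

    gamma = block_effects("EXP", cfg.gamma_var)
    gamma_null = block_effects("EXP_NULL", cfg.gamma_var) if null_exposure else None
    delta = block_effects("MED", cfg.mediator_gamma_var)
    deltas_null = [
        block_effects(f"MED_NULL{i + 1}", cfg.mediator_gamma_var)
        for i in range(n_null_mediators)
    ]

    mu = beta1 * gamma + delta
    Gamma = direct * gamma + beta2 * mu  # null mediators do not touch the outcome

    def noisy_table(true_eff, n_sample, case_fraction=None):
        se = _se_standardized(maf, n_sample, case_fraction)
        b = true_eff + rng.normal(0.0, se)
        return _table(snp, chrom, pos, ea, oa, maf, b, se, n_sample)

    tables = {
        "exposure": noisy_table(gamma, cfg.n_exposure, cfg.case_fraction_exposure),
        "mediator": noisy_table(mu, cfg.n_mediator),
        "outcome": noisy_table(Gamma, cfg.n_outcome, cfg.case_fraction_outcome),
    }
    truths = {
        "exposure": SimTruth(
            beta_total=cfg.beta_total, beta1=beta1, beta2=beta2,
            direct_effect=direct, gamma=gamma, alpha=np.zeros(n),
            delta=delta, invalid=np.zeros(n, dtype=bool), snp=snp,
        )
    }
    if null_exposure:
        tables["null_exposure"] = noisy_table(gamma_null, cfg.n_exposure,
                                              cfg.case_fraction_exposure)
        truths["null_exposure"] = SimTruth(
            beta_total=0.0, gamma=gamma_null, alpha=np.zeros(n),
            invalid=np.zeros(n, dtype=bool), snp=snp,
        )
    for i, d in enumerate(deltas_null):
        tables[f"null_mediator{i + 1}"] = noisy_table(d, cfg.n_mediator)
    assert len(blocks) == n_blocks
    return tables, truths


def write_fixture(tables: dict[str, pd.DataFrame], directory,
                  truth: SimTruth | None = None) -> dict[str, str]:
    """Write a dict of summary-stat tables (and optional truth sidecar) as TSVs."""
    os.makedirs(directory, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        paths[name] = write_sumstats(df, os.path.join(directory, f"{name}.tsv"))
    if truth is not None:
        paths["truth"] = write_keyvalues(
            truth.to_mapping(), os.path.join(directory, "truth.txt")
        )
    return paths
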