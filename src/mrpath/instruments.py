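"""Instrument selection and allele harmonization.

Selection follows the conventional two-sample MR recipe: keep SNPs below a
genome-wide significance threshold (5e-8 by default, relaxed to 5e-6 for
traits or mediator panels that would otherwise yield no instruments), prune to
approximate pairwise independence by greedy LD clumping (r^2 < 0.001 within a
10,000 kb window by default), and drop weak instruments with F = beta^2/se^2
not exceeding 10.

Harmonization expresses the outcome association on the exposure's effect
allele: swapped alleles flip the sign of BETA (and reflect EAF), strand flips
are resolved through allele complements, and palindromic (A/T, C/G) SNPs whose
allele frequency cannot settle the strand are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError, NoInstrumentsError
from .io import validate_sumstats

__all__ = [
    "compute_f",
    "select_instruments",
    "harmonize",
    "InstrumentSet",
    "HarmonizedSet",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class InstrumentSet:
    """Selected instruments for one trait: table rows plus an F column and provenance."""

    table: pd.DataFrame            # SUMSTAT columns + "F"
    trait: str = ""
    provenance: dict = field(default_factory=dict)

    @property
    def n_snp(self) -> int:
        return len(self.table)


@dataclass
class HarmonizedSet:
    """Exposure/outcome effects aligned to the exposure's effect allele.

    ``table`` columns: SNP, beta_exposure, se_exposure, beta_outcome,
    se_outcome, eaf_exposure, eaf_outcome, n_exposure, n_outcome.
    ``audit`` records the action taken for every exposure SNP
    (kept / flipped / dropped-*).
    """

    table: pd.DataFrame
    audit: pd.DataFrame
    exposure: str = ""
    outcome: str = ""

    @property
    def n_snp(self) -> int:
        return len(self.table)

    def arrays(self):
        t = self.table
        return (
            t["beta_exposure"].to_numpy(float),
            t["se_exposure"].to_numpy(float),
            t["beta_outcome"].to_numpy(float),
            t["se_outcome"].to_numpy(float),
        )


def compute_f(beta, se):
    """Instrument-strength F statistic, F = beta^2 / se^2 (vectorized)."""
    se_arr = np.asarray(se, dtype=float)
    if np.any(se_arr <= 0):
        raise ValueError("se must be > 0 to compute an F statistic")
    return np.asarray(beta, dtype=float) ** 2 / se_arr**2


def _greedy_clump(df: pd.DataFrame, ld: dict | None, r2_max: float,
                  window_kb: float) -> pd.DataFrame:
    """Greedy clumping by ascending P (ties by SNP id).

    A candidate is kept iff, for every already-kept SNP on the same chromosome
    within window_kb, the pairwise r^2 is known and below r2_max.  Without LD
    information, window-mates are conservatively clumped away; SNPs on
    different chromosomes or beyond the window are treated as independent.
    """
    order = df.sort_values(["P", "SNP"], kind="mergesort")
    window_bp = window_kb * 1000.0
    kept_idx: list = []
    kept_chr: list[str] = []
    kept_pos: list[float] = []
    kept_snp: list[str] = []
    for idx, row in order.iterrows():
        ok = True
        for c, p, s in zip(kept_chr, kept_pos, kept_snp):
            if row["CHR"] != c or abs(row["POS"] - p) > window_bp:
                continue
            r2 = None if ld is None else ld.get(frozenset((row["SNP"], s)))
            if r2 is None or r2 >= r2_max:
                ok = False
                break
        if ok:
            kept_idx.append(idx)
            kept_chr.append(row["CHR"])
            kept_pos.append(row["POS"])
            kept_snp.append(row["SNP"])
    return order.loc[kept_idx]


def select_instruments(
    stats: pd.DataFrame,
    p_threshold: float = 5e-8,
    f_min: float = 10.0,
    ld: dict | None = None,
    r2_max: float = 0.001,
    window_kb: float = 10_000.0,
    trait: str = "",
) -> InstrumentSet:
    """Select genetic instruments from one trait's summary statistics.

    Pipeline: P < p_threshold (a threshold >= 1 disables the p filter), greedy
    LD clumping, then F > f_min.  Raises :class:`NoInstrumentsError` carrying
    the trait name when nothing survives, so callers may relax the threshold.
    """
    if not 0.0 < p_threshold:
        raise ConfigurationError("p_threshold", "must be positive")
    if f_min < 0:
        raise ConfigurationError("f_min", "must be >= 0")
    if not 0.0 <= r2_max <= 1.0:
        raise ConfigurationError("r2_max", "must lie in [0, 1]")
    if window_kb < 0:
        raise ConfigurationError("window_kb", "must be >= 0")
    df = validate_sumstats(stats, name=trait or "stats")

    sig = df if p_threshold >= 1.0 else df[df["P"] < p_threshold]
    clumped = _greedy_clump(sig, ld, r2_max, window_kb)
    clumped = clumped.assign(F=compute_f(clumped["BETA"], clumped["SE"]))
    strong = clumped[clumped["F"] > f_min]
    if strong.empty:
        raise NoInstrumentsError(
            trait,
            f"no instruments for trait {trait!r} at p<{p_threshold:g}, F>{f_min:g} "
            f"({len(sig)} significant, {len(clumped)} after clumping)",
        )
    provenance = {
        "p_threshold": p_threshold,
        "f_min": f_min,
        "r2_max": r2_max,
        "window_kb": window_kb,
        "n_input": len(df),
        "n_significant": len(sig),
        "n_clumped": len(clumped),
        "n_final": len(strong),
    }
    return InstrumentSet(table=strong.reset_index(drop=True), trait=trait,
                         provenance=provenance)


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def harmonize(
    exposure: InstrumentSet | pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_eaf_band: float = 0.08,
    exposure_label: str = "",
    outcome_label: str = "",
) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect allele.

    Per shared SNP: identical allele pairs are kept; swapped pairs flip the
    outcome BETA and reflect EAF; strand mismatches are resolved through
    complements; palindromic SNPs are oriented by which side of 0.5 the allele
    frequencies fall on, and dropped when EAF is missing or within
    ``palindrome_eaf_band`` of 0.5 in either study; incompatible allele pairs
    are dropped.  Every action is recorded in the audit table.
    """
    exp_df = exposure.table if isinstance(exposure, InstrumentSet) else exposure
    exp_df = validate_sumstats(exp_df, "exposure")
    out_df = validate_sumstats(outcome, "outcome")
    if out_df["SNP"].duplicated().any():  # validate_sumstats already enforces this
        raise DataError("outcome: duplicated SNP ids")
    out_by_snp = out_df.set_index("SNP")

    rows, audit = [], []

    def log(snp, action, reason):
        audit.append({"SNP": snp, "action": action, "reason": reason})

    for _, e in exp_df.iterrows():
        snp = e["SNP"]
        if snp not in out_by_snp.index:
            log(snp, "dropped-missing", "absent from outcome table")
            continue
        o = out_by_snp.loc[snp]
        ea_e, oa_e = e["EA"], e["OA"]
        ea_o, oa_o = o["EA"], o["OA"]
        bad = [a for a in (ea_e, oa_e, ea_o, oa_o) if a not in _COMPLEMENT]
        if bad:
            log(snp, "dropped-incompatible", f"non-ACGT allele {bad[0]!r}")
            continue
        b_out, eaf_out = float(o["BETA"]), float(o["EAF"]) if pd.notna(o["EAF"]) else np.nan

        if _is_palindromic(ea_e, oa_e):
            if {ea_o, oa_o} != {ea_e, oa_e}:
                log(snp, "dropped-incompatible", "palindromic exposure, allele mismatch")
                continue
            eaf_e = float(e["EAF"]) if pd.notna(e["EAF"]) else np.nan
            if (
                np.isnan(eaf_e)
                or np.isnan(eaf_out)
                or abs(eaf_e - 0.5) <= palindrome_eaf_band
                or abs(eaf_out - 0.5) <= palindrome_eaf_band
            ):
                log(snp, "dropped-palindromic", "EAF missing or too close to 0.5")
                continue
            # orient by frequency: same side of 0.5 -> same allele is the effect allele
            if (eaf_e - 0.5) * (eaf_out - 0.5) < 0:
                b_out, eaf_out = -b_out, 1.0 - eaf_out
                action = "flipped"
            else:
                action = "kept"
        else:
            if (ea_o, oa_o) == (ea_e, oa_e):
                action = "kept"
            elif (ea_o, oa_o) == (oa_e, ea_e):
                b_out, eaf_out = -b_out, 1.0 - eaf_out
                action = "flipped"
            elif (_COMPLEMENT[ea_o], _COMPLEMENT[oa_o]) == (ea_e, oa_e):
                action = "kept"  # strand flip only
            elif (_COMPLEMENT[ea_o], _COMPLEMENT[oa_o]) == (oa_e, ea_e):
                b_out, eaf_out = -b_out, 1.0 - eaf_out
                action = "flipped"
            else:
                log(snp, "dropped-incompatible", f"alleles {ea_e}/{oa_e} vs {ea_o}/{oa_o}")
                continue

        log(snp, action, "aligned to exposure effect allele")
        rows.append(
            {
                "SNP": snp,
                "beta_exposure": float(e["BETA"]),
                "se_exposure": float(e["SE"]),
                "beta_outcome": b_out,
                "se_outcome": float(o["SE"]),
                "eaf_exposure": float(e["EAF"]) if pd.notna(e["EAF"]) else np.nan,
                "eaf_outcome": eaf_out,
                "n_exposure": int(e["N"]),
                "n_outcome": int(o["N"]),
            }
        )

    cols = [
        "SNP", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome",
        "eaf_exposure", "eaf_outcome", "n_exposure", "n_outcome",
    ]
    table = pd.DataFrame(rows, columns=cols)
    audit_df = pd.DataFrame(audit, columns=["SNP", "action", "reason"])
    return HarmonizedSet(table=table, audit=audit_df,
                         exposure=exposure_label, outcome=outcome_label)
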