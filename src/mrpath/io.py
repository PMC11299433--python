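"""Reading, writing and validating GWAS summary-statistic tables.

The universal on-disk format is a tab-delimited file with a fixed header::

    SNP  CHR  POS  EA  OA  EAF  BETA  SE  P  N

POS is 1-based, EA is the effect allele, BETA/SE are on the log-odds scale for
case-control traits and the SD scale for continuous traits.  EAF may be empty
(missing).  All tables used anywhere in the package pass through
:func:`validate_sumstats`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DataError

SUMSTAT_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

_DTYPES = {
    "SNP": str,
    "CHR": str,
    "POS": np.int64,
    "EA": str,
    "OA": str,
    "EAF": float,
    "BETA": float,
    "SE": float,
    "P": float,
    "N": np.int64,
}


def validate_sumstats(df: pd.DataFrame, name: str = "table") -> pd.DataFrame:
    """Validate (and dtype-coerce) a summary-statistics table.

    Raises :class:`DataError` naming the first violated constraint.  Returns a
    copy with canonical column order and dtypes.
    """
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{name}: missing required columns {missing}")
    out = df.loc[:, SUMSTAT_COLUMNS].copy()
    for col, dt in _DTYPES.items():
        try:
            out[col] = out[col].astype(dt)
        except (TypeError, ValueError) as exc:  # pragma: no cover - message path
            raise DataError(f"{name}: column {col} not coercible to {dt}: {exc}") from exc
    if out["SNP"].duplicated().any():
        dups = out.loc[out["SNP"].duplicated(), "SNP"].head(3).tolist()
        raise DataError(f"{name}: duplicated SNP ids, e.g. {dups}")
    if (out["SE"] <= 0).any():
        raise DataError(f"{name}: SE must be > 0")
    if ((out["P"] <= 0) | (out["P"] > 1)).any():
        raise DataError(f"{name}: P must lie in (0, 1]")
    if (out["EA"] == out["OA"]).any():
        raise DataError(f"{name}: EA must differ from OA")
    eaf = out["EAF"]
    bad_eaf = eaf.notna() & ((eaf < 0) | (eaf > 1))
    if bad_eaf.any():
        raise DataError(f"{name}: EAF must lie in [0, 1] or be missing")
    return out.reset_index(drop=True)


def read_sumstats(path, name: str | None = None) -> pd.DataFrame:
    """Read and validate a tab-delimited summary-statistics file."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "EA": str, "OA": str})
    return validate_sumstats(df, name or str(path))


def write_sumstats(df: pd.DataFrame, path) -> str:
    """Write a validated table as TSV (round-trips through read_sumstats)."""
    validate_sumstats(df).to_csv(path, sep="\t", index=False)
    return str(path)


def read_ld(path) -> dict[frozenset, float]:
    """Read a 3-column LD file (SNP_A, SNP_B, R2) into a symmetric lookup."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP_A": str, "SNP_B": str})
    for col in ("SNP_A", "SNP_B", "R2"):
        if col not in df.columns:
            raise DataError(f"LD file {path}: missing column {col}")
    return {
        frozenset((a, b)): float(r2)
        for a, b, r2 in zip(df["SNP_A"], df["SNP_B"], df["R2"])
    }


def write_ld(ld: dict, path) -> str:
    rows = sorted((tuple(sorted(k)), v) for k, v in ld.items())
    df = pd.DataFrame(
        [(a, b, r2) for (a, b), r2 in rows], columns=["SNP_A", "SNP_B", "R2"]
    )
    df.to_csv(path, sep="\t", index=False)
    return str(path)


def write_keyvalues(mapping: dict, path) -> str:
    """Serialize a flat mapping as ``key = value`` lines (arrays comma-joined)."""
    with open(path, "w") as fh:
        for key in sorted(mapping):
            val = mapping[key]
            if isinstance(val, (list, tuple, np.ndarray)):
                val = ",".join(repr(x) for x in np.asarray(val).tolist())
            fh.write(f"{key} = {val}\n")
    return str(path)


def read_keyvalues(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            out[key.strip()] = val.strip()
    return out
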