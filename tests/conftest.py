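"""Shared fixtures: small simulated datasets and harmonized-array helpers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrpath import SimConfig, simulate_pair

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_table(snp, beta, se, p=None, chrom=None, pos=None, ea=None, oa=None,
               eaf=None, n=10_000):
    """Build a minimal valid summary-statistics table."""
    from scipy import stats

    k = len(snp)
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if p is None:
        p = np.clip(2 * stats.norm.sf(np.abs(beta) / se), np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "SNP": snp,
            "CHR": chrom if chrom is not None else ["1"] * k,
            "POS": pos if pos is not None else [(i + 1) * 20_000_000 for i in range(k)],
            "EA": ea if ea is not None else ["A"] * k,
            "OA": oa if oa is not None else ["G"] * k,
            "EAF": eaf if eaf is not None else [0.3] * k,
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": n,
        }
    )


def tables_to_harmonized(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Pair two same-panel tables into a harmonized frame (alleles already aligned)."""
    return pd.DataFrame(
        {
            "SNP": exposure["SNP"].to_numpy(),
            "beta_exposure": exposure["BETA"].to_numpy(float),
            "se_exposure": exposure["SE"].to_numpy(float),
            "beta_outcome": outcome["BETA"].to_numpy(float),
            "se_outcome": outcome["SE"].to_numpy(float),
            "n_exposure": exposure["N"].to_numpy(),
            "n_outcome": outcome["N"].to_numpy(),
        }
    )


@pytest.fixture(scope="session")
def clean_pair():
    """A strong-instrument exposure/outcome pair with true effect 0.1."""
    cfg = SimConfig(n_snps=50, beta_total=0.1, n_exposure=500_000,
                    n_outcome=500_000, seed=11)
    exp, out, truth = simulate_pair(cfg)
    return exp, out, truth


@pytest.fixture(scope="session")
def clean_harmonized(clean_pair):
    exp, out, _ = clean_pair
    return tables_to_harmonized(exp, out)
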