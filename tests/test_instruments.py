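"""Instrument selection, clumping and harmonization rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrpath import compute_f, harmonize, select_instruments
from mrpath.exceptions import DataError, NoInstrumentsError
from tests.conftest import make_table


class TestComputeF:
    @pytest.mark.parametrize(
        "beta, se, expected",
        [(0.1, 0.01, 100.0), (0.0, 0.1, 0.0), (0.02, 0.0089, 0.0004 / 0.00007921)],
    )
    def test_direct_arithmetic(self, beta, se, expected):
        assert compute_f(beta, se) == pytest.approx(expected)

    def test_weak_instrument_below_ten(self):
        assert compute_f(0.02, 0.0089) < 10

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            compute_f(0.1, 0.0)


class TestSelectInstruments:
    @pytest.fixture()
    def toy(self):
        return make_table(
            snp=["rs1", "rs2", "rs3", "rs4"],
            beta=[0.5, 0.5, 0.5, 0.5],
            se=[0.05, 0.05, 0.05, 0.05],
            p=[1e-9, 4e-8, 1e-7, 1e-5],
        )

    def test_genomewide_threshold_keeps_two(self, toy):
        assert select_instruments(toy, p_threshold=5e-8).n_snp == 2

    def test_relaxed_threshold_keeps_three(self, toy):
        """At the relaxed 5e-6 threshold the 1e-5 SNP stays excluded."""
        inst = select_instruments(toy, p_threshold=5e-6)
        assert inst.n_snp == 3
        assert "rs4" not in set(inst.table["SNP"])

    def test_weak_f_removed(self):
        # rs2 significant but F = 9 < 10
        tbl = make_table(
            snp=["rs1", "rs2"], beta=[0.5, 0.03], se=[0.05, 0.01], p=[1e-9, 1e-9]
        )
        inst = select_instruments(tbl, p_threshold=5e-8, f_min=10)
        assert set(inst.table["SNP"]) == {"rs1"}

    def test_strict_f_inequality(self):
        # F exactly at the cutoff does not "exceed" it
        from mrpath import compute_f

        tbl = make_table(snp=["rs1"], beta=[0.03], se=[0.01], p=[1e-9])
        f_exact = float(compute_f(0.03, 0.01))
        with pytest.raises(NoInstrumentsError):
            select_instruments(tbl, p_threshold=5e-8, f_min=f_exact)

    def test_no_instruments_error_carries_trait(self):
        tbl = make_table(snp=["rs1"], beta=[0.5], se=[0.05], p=[0.5])
        with pytest.raises(NoInstrumentsError) as err:
            select_instruments(tbl, trait="myexposure")
        assert err.value.trait == "myexposure"

    def test_identity_in_the_limit(self, toy):
        """p_threshold = 1, no LD, f_min = 0 returns the full table."""
        inst = select_instruments(toy, p_threshold=1.0, f_min=0.0)
        assert set(inst.table["SNP"]) == set(toy["SNP"])

    def test_windowmates_without_ld_conservatively_clumped(self):
        tbl = make_table(
            snp=["rs1", "rs2", "rs3"],
            beta=[0.5] * 3, se=[0.05] * 3, p=[1e-9, 1e-8, 1e-7],
            pos=[1_000_000, 2_000_000, 500_000_000],
        )
        inst = select_instruments(tbl, p_threshold=5e-6)
        # rs2 is within 10,000 kb of the better rs1 and has no LD data
        assert list(inst.table["SNP"]) == ["rs1", "rs3"]

    def test_ld_matrix_resolves_windowmates(self):
        tbl = make_table(
            snp=["rs1", "rs2", "rs3"],
            beta=[0.5] * 3, se=[0.05] * 3, p=[1e-9, 1e-8, 1e-7],
            pos=[1_000_000, 2_000_000, 3_000_000],
        )
        ld = {
            frozenset(("rs1", "rs2")): 0.0005,  # independent
            frozenset(("rs1", "rs3")): 0.5,     # linked to rs1
            frozenset(("rs2", "rs3")): 0.0,
        }
        inst = select_instruments(tbl, p_threshold=5e-6, ld=ld, r2_max=0.001)
        assert list(inst.table["SNP"]) == ["rs1", "rs2"]

    def test_different_chromosomes_independent(self):
        tbl = make_table(
            snp=["rs1", "rs2"], beta=[0.5] * 2, se=[0.05] * 2, p=[1e-9, 1e-8],
            chrom=["1", "2"], pos=[1_000_000, 1_000_000],
        )
        assert select_instruments(tbl, p_threshold=5e-6).n_snp == 2

    @given(perm=st.permutations(range(4)))
    def test_clump_invariant_to_row_order(self, perm):
        tbl = make_table(
            snp=["rs1", "rs2", "rs3", "rs4"],
            beta=[0.5] * 4, se=[0.05] * 4,
            p=[1e-9, 1e-8, 1e-7, 1e-9],  # tie between rs1 and rs4
            pos=[1_000_000, 2_000_000, 500_000_000, 1_500_000],
        )
        shuffled = tbl.iloc[list(perm)].reset_index(drop=True)
        kept = list(select_instruments(shuffled, p_threshold=5e-6).table["SNP"])
        assert kept == ["rs1", "rs3"]  # rs1 beats rs4 on the id tiebreak


class TestHarmonize:
    def _pair(self, ea_o, oa_o, beta_o=0.2, eaf_e=0.3, eaf_o=0.3):
        exp = make_table(snp=["rs1"], beta=[0.5], se=[0.05], p=[1e-9],
                         ea=["A"], oa=["G"], eaf=[eaf_e])
        out = make_table(snp=["rs1"], beta=[beta_o], se=[0.05],
                         ea=[ea_o], oa=[oa_o], eaf=[eaf_o])
        return exp, out

    def test_identical_alleles_kept_unchanged(self):
        h = harmonize(*self._pair("A", "G"))
        assert h.n_snp == 1
        assert h.table.loc[0, "beta_outcome"] == 0.2
        assert list(h.audit["action"]) == ["kept"]

    def test_swapped_alleles_flip_beta_and_eaf(self):
        h = harmonize(*self._pair("G", "A", beta_o=0.2, eaf_o=0.7))
        assert h.table.loc[0, "beta_outcome"] == -0.2
        assert h.table.loc[0, "eaf_outcome"] == pytest.approx(0.3)
        assert list(h.audit["action"]) == ["flipped"]

    def test_strand_flip_resolved_by_complement(self):
        h = harmonize(*self._pair("T", "C"))  # complement of A/G
        assert h.table.loc[0, "beta_outcome"] == 0.2

    def test_strand_flip_plus_swap(self):
        h = harmonize(*self._pair("C", "T"))
        assert h.table.loc[0, "beta_outcome"] == -0.2

    def test_incompatible_alleles_dropped(self):
        h = harmonize(*self._pair("A", "C"))
        assert h.n_snp == 0
        assert list(h.audit["action"]) == ["dropped-incompatible"]

    def test_missing_snp_dropped(self):
        exp = make_table(snp=["rs1"], beta=[0.5], se=[0.05], p=[1e-9])
        out = make_table(snp=["rs2"], beta=[0.2], se=[0.05])
        h = harmonize(exp, out)
        assert h.n_snp == 0
        assert list(h.audit["action"]) == ["dropped-missing"]

    def test_ambiguous_palindromic_dropped(self):
        exp = make_table(snp=["rs1"], beta=[0.5], se=[0.05], p=[1e-9],
                         ea=["A"], oa=["T"], eaf=[0.50])
        out = make_table(snp=["rs1"], beta=[0.2], se=[0.05],
                         ea=["A"], oa=["T"], eaf=[0.50])
        h = harmonize(exp, out)
        assert h.n_snp == 0
        assert list(h.audit["action"]) == ["dropped-palindromic"]

    def test_informative_palindromic_oriented_by_frequency(self):
        exp = make_table(snp=["rs1"], beta=[0.5], se=[0.05], p=[1e-9],
                         ea=["A"], oa=["T"], eaf=[0.1])
        out_same = make_table(snp=["rs1"], beta=[0.2], se=[0.05],
                              ea=["A"], oa=["T"], eaf=[0.12])
        out_opp = make_table(snp=["rs1"], beta=[0.2], se=[0.05],
                             ea=["A"], oa=["T"], eaf=[0.88])
        assert harmonize(exp, out_same).table.loc[0, "beta_outcome"] == 0.2
        assert harmonize(exp, out_opp).table.loc[0, "beta_outcome"] == -0.2

    def test_duplicated_outcome_snp_rejected(self):
        exp = make_table(snp=["rs1"], beta=[0.5], se=[0.05], p=[1e-9])
        out = pd.concat([make_table(snp=["rs1"], beta=[0.2], se=[0.05])] * 2,
                        ignore_index=True)
        with pytest.raises(DataError):
            harmonize(exp, out)

    def test_idempotent_on_aligned_pair(self):
        """Harmonizing an already-aligned pair changes nothing."""
        exp = make_table(snp=["rs1", "rs2"], beta=[0.5, 0.4], se=[0.05, 0.05],
                         p=[1e-9, 1e-9], ea=["A", "C"], oa=["G", "T"])
        out = make_table(snp=["rs1", "rs2"], beta=[0.2, -0.1], se=[0.05, 0.06],
                         ea=["A", "C"], oa=["G", "T"])
        h1 = harmonize(exp, out)
        h2 = harmonize(exp, out)
        pd.testing.assert_frame_equal(h1.table, h2.table)
        assert (h1.audit["action"] == "kept").all()
        assert np.array_equal(h1.table["beta_outcome"], out["BETA"])

    def test_row_count_bounded_by_inputs(self, clean_pair):
        exp, out, _ = clean_pair
        h = harmonize(exp, out)
        assert h.n_snp <= min(len(exp), len(out))
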