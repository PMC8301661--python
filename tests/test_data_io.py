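"""Harmonization, instrument selection and greedy LD clumping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrprofile import harmonize, ld_clump, select_instruments
from mrprofile.data_io import combined_selection_p

from .conftest import make_trait_table, study_from_arrays


def _three_tables(snp_ids, betas, effect=None, other=None, sel_pval=1e-10):
    effect = effect or ["A"] * len(snp_ids)
    other = other or ["G"] * len(snp_ids)
    out = make_trait_table(snp_ids, effect, other, betas)
    exp = make_trait_table(snp_ids, effect, other, betas)
    sel = make_trait_table(snp_ids, effect, other, betas, pval=sel_pval)
    return out, [exp], [sel]


class TestHarmonize:
    def test_allele_flip_negates_and_preserves_magnitude(self):
        out, exps, sels = _three_tables(["rs1"], [0.4])
        # exposure table reports the opposite effect allele
        exps[0].loc[0, ["effect_allele", "other_allele"]] = ["G", "A"]
        study = harmonize(out, exps, sels)
        rec = study.records[0]
        assert rec.gamma_hat[0] == pytest.approx(-0.4)
        assert rec.Gamma_hat == pytest.approx(0.4)
        assert abs(rec.gamma_hat[0]) == abs(rec.Gamma_hat)

    def test_palindromic_snps_removed(self):
        out, exps, sels = _three_tables(
            ["rs1", "rs2", "rs3"], [0.1, 0.2, 0.3],
            effect=["A", "A", "G"], other=["G", "T", "C"])
        study = harmonize(out, exps, sels)
        assert study.snp_ids == ["rs1"]  # A/T and G/C dropped

    def test_twelve_snp_fixture_keeps_nine(self):
        # 12 SNPs: 2 strand-ambiguous, 1 absent from the outcome table -> 9
        ids = [f"rs{i}" for i in range(1, 13)]
        effect = ["A"] * 10 + ["A", "G"]
        other = ["G"] * 10 + ["T", "C"]
        betas = np.linspace(0.1, 1.2, 12)
        out = make_trait_table(ids[:-1][:11], effect[:11], other[:11], betas[:11])
        out = out[out.SNP != "rs6"]  # missing from the outcome table
        exp = make_trait_table(ids, effect, other, betas)
        sel = make_trait_table(ids, effect, other, betas)
        study = harmonize(out, [exp], [sel])
        assert study.n_snps == 9

    def test_duplicated_id_is_hard_error_naming_it(self):
        out, exps, sels = _three_tables(["rs1", "rs1"], [0.1, 0.2])
        with pytest.raises(ValueError, match="rs1"):
            harmonize(out, exps, sels)

    def test_empty_intersection_is_hard_error(self):
        out, _, _ = _three_tables(["rs1"], [0.1])
        exp, sel = _three_tables(["rs2"], [0.1])[1:]
        with pytest.raises(ValueError, match="no SNP"):
            harmonize(out, exp, sel)

    def test_harmonization_is_involutive(self):
        out, exps, sels = _three_tables(
            ["rs1", "rs2", "rs3"], [0.1, -0.2, 0.3], sel_pval=0.4)
        exps[0].loc[1, ["effect_allele", "other_allele"]] = ["G", "A"]
        exps[0].loc[1, "beta"] = 0.2  # flipped sign, same SNP
        study = harmonize(out, exps, sels)
        study2 = harmonize(*study.to_tables())
        assert study2.snp_ids == study.snp_ids
        np.testing.assert_allclose(study2.gamma, study.gamma)
        np.testing.assert_allclose(study2.Gamma, study.Gamma)
        np.testing.assert_allclose(study2.sel_pvalues, study.sel_pvalues)


class TestSelectInstruments:
    def test_single_exposure_direct_rule(self):
        study = study_from_arrays([0.1], 0.01, [[0.1]], 0.01, sel_p=[[1e-9]])
        assert select_instruments(study, 1e-8) == ["rs0"]

    def test_bonferroni_combination_two_exposures(self):
        study = study_from_arrays([0.1], 0.01, [[5e-1, 5e-1]], 0.01,
                                  sel_p=[[5e-9, 0.3]])
        # combined p = 2 * 5e-9 = 1e-8, boundary inclusive
        assert select_instruments(study, 1e-8) == ["rs0"]
        assert select_instruments(study, 9e-9) == []

    def test_fixture_count_matches_hand_enumeration(self):
        pairs = [(1e-9, 0.5), (1e-6, 1e-6), (4e-6, 0.9), (6e-6, 0.9),
                 (0.2, 0.3), (1e-3, 1e-3), (5e-6, 5e-6), (0.9, 1e-7),
                 (1e-4, 1e-4), (0.49, 0.51)]
        # combined = 2*min: 2e-9, 2e-6, 8e-6, 1.2e-5, 0.4, 2e-3, 1e-5,
        #            2e-7, 2e-4, 0.98 -> at 1e-5: four pass (2e-9, 2e-6,
        #            8e-6, 2e-7) plus 1e-5 itself -> 5
        study = study_from_arrays(np.zeros(10), 0.01,
                                  np.full((10, 2), 0.1), 0.01, sel_p=pairs)
        assert len(select_instruments(study, 1e-5)) == 5

    def test_combined_p_capped_at_one(self):
        assert combined_selection_p(np.array([[0.8, 0.9, 0.7]]))[0] == 1.0

    @settings(deadline=None, derandomize=True)
    @given(st.floats(1e-8, 0.5), st.floats(1e-8, 0.5))
    def test_monotone_in_threshold(self, thr_a, thr_b):
        rng = np.random.default_rng(0)
        study = study_from_arrays(
            np.zeros(30), 0.01, rng.normal(size=(30, 1)), 0.01,
            sel_p=rng.uniform(0, 1, (30, 1)))
        lo, hi = sorted([thr_a, thr_b])
        assert set(select_instruments(study, lo)) <= \
            set(select_instruments(study, hi))


def _brute_force_clump(candidates, pvals, r2, threshold):
    """Definitional oracle: plain scanning loops, no sort machinery."""
    alive = list(candidates)
    kept = []
    while alive:
        best = alive[0]
        for s in alive[1:]:
            if (pvals[s], s) < (pvals[best], best):
                best = s
        kept.append(best)
        alive = [s for s in alive if s != best
                 and r2.loc[best, s] <= threshold]
    return kept


class TestLDClump:
    def _toy(self):
        ids = [f"s{i}" for i in range(6)]
        r2 = np.array([
            [1.0, 0.9, 0.0, 0.0, 0.2, 0.0],
            [0.9, 1.0, 0.0, 0.5, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0, 0.8, 0.0],
            [0.0, 0.5, 0.0, 1.0, 0.0, 0.0],
            [0.2, 0.0, 0.8, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, 0.0, 1.0],
        ])
        mat = pd.DataFrame(r2, index=ids, columns=ids)
        pvals = dict(zip(ids, [1e-8, 1e-10, 1e-6, 1e-4, 1e-9, 0.5]))
        return ids, pvals, mat

    def test_all_independent_keeps_everything(self):
        ids, pvals, mat = self._toy()
        eye = pd.DataFrame(np.eye(6), index=ids, columns=ids)
        assert set(ld_clump(ids, pvals, eye, 0.1)) == set(ids)

    def test_perfect_ld_keeps_most_significant_only(self):
        ids = ["a", "b"]
        mat = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=ids, columns=ids)
        assert ld_clump(ids, {"a": 1e-10, "b": 1e-9}, mat, 0.1) == ["a"]

    def test_matches_brute_force_oracle_on_toy(self):
        ids, pvals, mat = self._toy()
        for thr in (0.001, 0.1, 0.3, 0.6):
            assert ld_clump(ids, pvals, mat, thr) == \
                _brute_force_clump(ids, pvals, mat, thr)

    def test_output_pairwise_independent_at_cutoff(self, rng):
        ids = [f"s{i}" for i in range(12)]
        raw = rng.uniform(0, 1, (12, 12))
        r2 = (raw + raw.T) / 2
        np.fill_diagonal(r2, 1.0)
        mat = pd.DataFrame(r2, index=ids, columns=ids)
        pvals = dict(zip(ids, rng.uniform(0, 1, 12)))
        kept = ld_clump(ids, pvals, mat, 0.4)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert mat.loc[a, b] <= 0.4

    def test_missing_r2_entry_is_hard_error(self):
        mat = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        with pytest.raises(KeyError, match="b"):
            ld_clump(["a", "b"], {"a": 0.1, "b": 0.2}, mat, 0.1)
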