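"""Normalisation, fold changes, NB Wald test, BH and GSZ."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import bh_bruteforce, gsz_permutation_z
from telomaint.diffexpr import (CountMatrix, normalize_counts, fold_changes,
                                nb_wald_test, benjamini_hochberg, gene_scores,
                                gsz_from_scores, gsz_score, builtin_gene_sets)
from telomaint.synth_data import ExpressionDesign, simulate_count_matrix


def _cm(counts: np.ndarray, groups: dict) -> CountMatrix:
    genes = [f"g{i}" for i in range(counts.shape[0])]
    samples = list(groups)
    df = pd.DataFrame(counts, index=genes, columns=samples)
    return CountMatrix(df, pd.Series(groups), "reference")


class TestNormalization:
    def test_identical_samples_unit_factors(self):
        c = np.array([[10, 10], [50, 50], [7, 7]])
        sf, norm = normalize_counts(_cm(c, {"a": "reference", "b": "reference"}))
        assert np.allclose(sf, 1.0)
        assert np.allclose(norm, c)

    def test_doubled_sample_factors_one_to_two(self):
        rng = np.random.default_rng(0)
        a = rng.integers(5, 500, size=30)
        c = np.column_stack([a, 2 * a])
        sf, _ = normalize_counts(_cm(c, {"a": "reference", "b": "reference"}))
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_invariant_to_gene_permutation(self):
        rng = np.random.default_rng(1)
        c = rng.integers(1, 300, size=(40, 3))
        m = _cm(c, {"a": "reference", "b": "reference", "c": "reference"})
        sf1, _ = normalize_counts(m)
        perm = rng.permutation(40)
        m2 = CountMatrix(m.counts.iloc[perm], m.groups, "reference")
        sf2, _ = normalize_counts(m2)
        assert np.allclose(sf1, sf2)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_counts(_cm(np.zeros((3, 2), dtype=int),
                                 {"a": "reference", "b": "reference"}))


class TestFoldChanges:
    def test_sample_equal_to_reference_mean_gives_unity(self):
        c = np.array([[10, 10, 10], [40, 40, 40]])
        m = _cm(c, {"a": "reference", "b": "reference", "t": "tumor"})
        fc = fold_changes(m)
        assert np.allclose(fc["t"], 1.0)

    def test_doubled_gene_without_pseudocount(self):
        # majority of genes unchanged, so size factors are exactly 1
        c = np.array([[10, 20], [30, 30], [70, 70], [50, 50]])
        m = _cm(c, {"a": "reference", "t": "tumor"})
        fc = fold_changes(m, pseudocount=0.0)
        assert fc.loc["g0", "t"] == pytest.approx(2.0)

    def test_all_zero_gene_positive_via_pseudocount(self):
        c = np.array([[0, 0], [10, 10]])
        m = _cm(c, {"a": "reference", "t": "tumor"})
        fc = fold_changes(m, pseudocount=1.0)
        assert (fc.to_numpy() > 0).all()
        assert fc.loc["g0", "t"] == pytest.approx(1.0)

    def test_missing_reference_group_rejected(self):
        c = np.array([[1, 2]])
        with pytest.raises(ValueError):
            fold_changes(_cm(c, {"a": "reference", "b": "tumor"}), "mucosa")


class TestWald:
    def test_single_sample_group_rejected(self):
        c = np.abs(np.random.default_rng(0).integers(1, 50, size=(10, 3)))
        m = _cm(c, {"a": "reference", "b": "reference", "t": "tumor"})
        with pytest.raises(ValueError, match=">= 2 samples"):
            nb_wald_test(m, "tumor")

    def test_relabeling_invariance(self, null_count_matrix):
        """Permuting samples jointly with their labels leaves results
        unchanged."""
        m, _ = null_count_matrix
        res1 = nb_wald_test(m, "tumor")
        rng = np.random.default_rng(3)
        perm = rng.permutation(m.counts.columns)
        m2 = CountMatrix(m.counts[perm], m.groups[perm], "reference")
        res2 = nb_wald_test(m2, "tumor")
        pd.testing.assert_frame_equal(res1.table, res2.table,
                                      rtol=1e-6, atol=1e-8)

    def test_planted_fold_change_recovered(self):
        genes = [f"GENE{i:05d}" for i in range(400)]
        planted = {g: {"tumor": 1.0} for g in genes[:30]}
        design = ExpressionDesign(n_genes=400,
                                  group_sizes={"reference": 30, "tumor": 30},
                                  planted_log2fc=planted, nb_dispersion=0.02,
                                  seed=21)
        counts, groups, _ = simulate_count_matrix(design)
        res = nb_wald_test(CountMatrix(counts, groups, "reference"), "tumor")
        est = res.table.loc[genes[:30], "log2fc"]
        assert est.median() == pytest.approx(1.0, abs=0.1)
        assert (res.table.loc[genes[:30], "padj"] < 0.05).mean() > 0.9

    def test_power_increases_with_effect_size(self):
        """Wald power grows monotonically over a planted |log2FC| grid."""
        genes = [f"GENE{i:05d}" for i in range(300)]
        powers = []
        for lfc in (0.25, 0.5, 1.0):
            planted = {g: {"tumor": lfc} for g in genes[:60]}
            design = ExpressionDesign(n_genes=300,
                                      group_sizes={"reference": 12, "tumor": 12},
                                      planted_log2fc=planted, nb_dispersion=0.05,
                                      seed=31)
            counts, groups, _ = simulate_count_matrix(design)
            res = nb_wald_test(CountMatrix(counts, groups, "reference"), "tumor")
            powers.append((res.table.loc[genes[:60], "pvalue"] < 0.05).mean())
        assert powers[0] < powers[1] < powers[2]

    def test_adjusted_p_at_least_raw_p(self, null_count_matrix):
        m, _ = null_count_matrix
        t = nb_wald_test(m, "tumor").table.dropna()
        assert (t["padj"] >= t["pvalue"] - 1e-12).all()


class TestBH:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    def test_matches_bruteforce_stepup(self, pvals):
        assert np.allclose(benjamini_hochberg(pvals), bh_bruteforce(pvals))


class TestGSZ:
    def test_all_equal_scores_give_zero(self):
        scores = pd.DataFrame(np.ones((20, 4)),
                              index=[f"g{i}" for i in range(20)])
        prof = gsz_from_scores(scores, {"s": ["g0", "g1", "g2"]})
        assert np.allclose(prof.scores, 0.0)

    def test_full_gene_set_gives_zero(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(rng.normal(size=(15, 3)),
                              index=[f"g{i}" for i in range(15)])
        prof = gsz_from_scores(scores, {"all": [f"g{i}" for i in range(15)]})
        assert np.allclose(prof.scores, 0.0)

    def test_empty_intersection_rejected(self):
        scores = pd.DataFrame(np.ones((5, 2)), index=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError, match="no genes"):
            gsz_from_scores(scores, {"s": ["absent"]})

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(4)
        scores = pd.DataFrame(rng.normal(size=(30, 5)),
                              index=[f"g{i}" for i in range(30)])
        sets = {"s": ["g3", "g7", "g11", "g19"]}
        a = gsz_from_scores(scores, sets).scores
        b = gsz_from_scores(scores.sample(frac=1, random_state=1), sets).scores
        assert np.allclose(a, b)

    def test_complement_has_opposite_sign_with_sample_centering(self):
        rng = np.random.default_rng(5)
        norm = pd.DataFrame(rng.lognormal(3, 1, size=(40, 6)),
                            index=[f"g{i}" for i in range(40)])
        scores = gene_scores(norm, center="sample")
        genes = list(norm.index)
        a = gsz_from_scores(scores, {"s": genes[:10]}).scores["s"]
        b = gsz_from_scores(scores, {"c": genes[10:]}).scores["c"]
        assert np.allclose(a, -b)

    def test_matches_permutation_oracle(self):
        """Analytic finite-population z agrees with a 1e5-draw random-set
        permutation z on a 200-gene fixture."""
        rng = np.random.default_rng(6)
        scores = pd.DataFrame(rng.normal(size=(200, 1)),
                              index=[f"g{i}" for i in range(200)])
        members = [f"g{i}" for i in range(0, 100, 10)]      # k = 10
        analytic = gsz_from_scores(scores, {"s": members}).scores.iloc[0, 0]
        x = scores.iloc[:, 0].to_numpy()
        t_obs = scores.loc[members, 0].sum()
        perm = gsz_permutation_z(x, k=10, t_obs=t_obs, n_draws=100_000, seed=1)
        assert analytic == pytest.approx(perm, abs=0.1)

    def test_builtin_gene_sets_load(self):
        sets = builtin_gene_sets()
        for name in ("extension of telomeres", "telomere maintenance",
                     "ALT genes", "mismatch repair", "regulation of apoptosis",
                     "cell cycle"):
            assert name in sets
            assert len(sets[name]) >= 10
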