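import numpy as np
import pytest

import pairphy as pp
from pairphy import ColumnKind

from _oracles import enumeration_loglik
from conftest import random_state6_model


def _random_coded(rng, model, names, n_cols, gap_prob=0.1):
    """Random coded columns (mixed blocks) for oracle comparisons."""
    kinds, rows = [], ["" for _ in names]
    nu = model.alphabet.n_unpaired
    for _ in range(n_cols):
        paired = rng.random() < 0.5
        kinds.append(ColumnKind.PAIRED if paired else ColumnKind.UNPAIRED)
        lo, hi = (nu, model.alphabet.size) if paired else (0, nu)
        for i in range(len(names)):
            if rng.random() < gap_prob:
                ch = "-"
            else:
                ch = model.alphabet.symbols[rng.integers(lo, hi)]
            rows[i] += ch
    return pp.CodedAlignment(list(names), rows, kinds, model.alphabet)


class TestSiteLogLikelihoods:
    def test_two_taxon_closed_form(self):
        m = pp.jc_model()
        tree = pp.tree_from_newick("(a:0.04,b:0.06);")
        coded = pp.CodedAlignment(["a", "b"], ["A", "A"],
                                  [ColumnKind.UNPAIRED], m.alphabet)
        fit = pp.site_log_likelihoods(tree, coded, m)
        p_ii = 0.25 + 0.75 * np.exp(-4 * 0.1 / 3)
        assert fit.total_lnl == pytest.approx(np.log(0.25 * p_ii), abs=1e-9)

    def test_all_missing_column_contributes_zero(self):
        m = pp.jc_model()
        tree = pp.tree_from_newick("(a:0.1,b:0.1);")
        coded = pp.CodedAlignment(["a", "b"], ["-A", "-A"],
                                  [ColumnKind.UNPAIRED] * 2, m.alphabet)
        fit = pp.site_log_likelihoods(tree, coded, m)
        assert fit.site_lnl[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_on_four_taxa(self, rng):
        m = random_state6_model(rng)
        tree = pp.tree_from_newick("((a:0.1,b:0.23):0.15,(c:0.3,d:0.08):0.02);")
        coded = _random_coded(rng, m, "abcd", 50)
        fit = pp.site_log_likelihoods(tree, coded, m)
        assert fit.total_lnl == pytest.approx(
            enumeration_loglik(tree, coded, m), abs=1e-10
        )

    def test_total_is_sum_of_site_lnl(self, rng):
        m = random_state6_model(rng)
        tree = pp.tree_from_newick("((a:0.1,b:0.2):0.1,c:0.3,d:0.15);")
        coded = _random_coded(rng, m, "abcd", 80)
        fit = pp.site_log_likelihoods(tree, coded, m, pp.RateModel(0.1, 0.8))
        assert fit.total_lnl == pytest.approx(fit.site_lnl.sum(), abs=1e-9)
        assert np.isfinite(fit.site_lnl).all()

    def test_invariant_under_rerooting(self, rng):
        m = random_state6_model(rng)
        tree = pp.tree_from_newick(
            "((a:0.1,b:0.2):0.12,(c:0.3,d:0.15):0.07,e:0.2);"
        )
        coded = _random_coded(rng, m, "abcde", 60)
        base = pp.site_log_likelihoods(tree, coded, m).total_lnl
        tree2 = pp.tree_from_newick(
            "((a:0.1,b:0.2):0.12,(c:0.3,d:0.15):0.07,e:0.2);"
        )
        node = [n for n in tree2.leaf_node_iter() if n.taxon.label == "c"][0]
        tree2.reroot_at_edge(node.edge, update_bipartitions=False,
                             length1=0.1, length2=0.2)
        rerooted = pp.site_log_likelihoods(tree2, coded, m).total_lnl
        assert rerooted == pytest.approx(base, abs=1e-9)

    def test_gamma_limit_equals_homogeneous(self, rng):
        m = random_state6_model(rng)
        tree = pp.tree_from_newick("((a:0.1,b:0.2):0.1,c:0.3,d:0.15);")
        coded = _random_coded(rng, m, "abcd", 40)
        homog = pp.site_log_likelihoods(tree, coded, m).total_lnl
        limit = pp.site_log_likelihoods(
            tree, coded, m, pp.RateModel(p_inv=0.0, alpha=1e6)
        ).total_lnl
        assert limit == pytest.approx(homog, abs=1e-3)

    def test_leaf_without_sequence_rejected(self, rng):
        m = random_state6_model(rng)
        tree = pp.tree_from_newick("((a:0.1,b:0.2):0.1,(c:0.3,x:0.1):0.05);")
        coded = _random_coded(rng, m, "abcd", 10)
        with pytest.raises(pp.PairphyError, match="x"):
            pp.site_log_likelihoods(tree, coded, m)


class TestAic:
    def test_arithmetic(self):
        assert pp.aic(-100.0, 10) == 220.0
        assert pp.aic(-50.0, 0) == 100.0

    def test_monotone_in_lnl(self):
        assert pp.aic(-90.0, 5) < pp.aic(-100.0, 5)


class TestNjTree:
    def test_three_taxon_symmetry(self, rng):
        # identical pairwise distances resolve to equal branch lengths
        m = pp.jc_model()
        coded = pp.CodedAlignment(
            ["a", "b", "c"],
            ["AAAACCCCGG", "AAAACCCCGG", "AAAACCCCGG"],
            [ColumnKind.UNPAIRED] * 10, m.alphabet,
        )
        tree = pp.nj_tree(coded, m)
        lengths = [e.length for e in tree.preorder_edge_iter()
                   if e.length is not None]
        assert all(l == pytest.approx(0.0, abs=1e-9) for l in lengths)

    def test_identical_sequences_have_zero_distance(self, rng):
        m = random_state6_model(rng)
        coded = _random_coded(rng, m, "ab", 30, gap_prob=0.0)
        coded2 = pp.CodedAlignment(["a", "b"], [coded.rows[0], coded.rows[0]],
                                   coded.column_kind, m.alphabet)
        assert pp.ml_pairwise_distance(coded2, "a", "b", m) == 0.0

    def test_recovers_simulated_topology(self):
        m = pp.default_stem_model()
        tree = pp.yule_tree(8, seed=17, mean_root_to_tip=0.4)
        sim = pp.simulate_coded(tree, m, n_columns=2000, seed=23)
        nj = pp.nj_tree(sim, m)
        assert pp.rf_distance(nj, tree) == 0

    def test_too_few_sequences_rejected(self, rng):
        m = random_state6_model(rng)
        with pytest.raises(pp.PairphyError):
            pp.nj_tree(_random_coded(rng, m, "ab", 10), m)


class TestOptimizeBranchLengths:
    def test_recovers_simulated_two_taxon_distance(self):
        m = pp.default_stem_model()
        tree = pp.tree_from_newick("(a:0.2,b:0.1);")
        truth = pp.tree_from_newick("(a:0.15,b:0.15);")
        sim = pp.simulate_coded(truth, m, n_columns=10000, seed=31)
        tree, lnl = pp.optimize_branch_lengths(tree, sim, m)
        total = sum(e.length for e in tree.preorder_edge_iter()
                    if e.length is not None)
        assert total == pytest.approx(0.3, abs=0.03)

    def test_lnl_never_decreases(self, rng):
        m = random_state6_model(rng)
        truth = pp.yule_tree(6, seed=41, mean_root_to_tip=0.5)
        sim = pp.simulate_coded(truth, m, n_columns=300, seed=43)
        before = pp.site_log_likelihoods(truth, sim, m).total_lnl
        _, after = pp.optimize_branch_lengths(truth, sim, m)
        assert after >= before - 1e-9

    def test_identical_sequences_shrink_branches(self):
        m = pp.jc_model()
        tree = pp.tree_from_newick("((a:0.3,b:0.2):0.1,c:0.2,d:0.4);")
        coded = pp.CodedAlignment(
            list("abcd"), ["ACGA"] * 4, [ColumnKind.UNPAIRED] * 4, m.alphabet
        )
        tree, _ = pp.optimize_branch_lengths(tree, coded, m)
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                assert e.length <= 1e-6


class TestCompareFit:
    def test_self_comparison_is_zero_and_antisymmetric(self, rng):
        m = random_state6_model(rng)
        tree = pp.yule_tree(5, seed=51)
        sim = pp.simulate_coded(tree, m, n_columns=200, seed=53)
        m2 = random_state6_model(rng)
        df = pp.compare_fit(
            [("a", m, pp.RateModel()), ("b", m2, pp.RateModel())],
            [(tree, sim)],
        )
        ab = df[(df.model_a == "a") & (df.model_b == "b")].iloc[0]
        ba = df[(df.model_a == "b") & (df.model_b == "a")].iloc[0]
        assert ab.mean_site_lnl_diff == pytest.approx(-ba.mean_site_lnl_diff)
        same = pp.compare_fit(
            [("a", m, pp.RateModel()), ("also_a", m, pp.RateModel())],
            [(tree, sim)],
        )
        assert (same.mean_site_lnl_diff == 0).all()

    def test_generating_model_beats_perturbed_copy(self, rng):
        m = random_state6_model(rng)
        tree = pp.yule_tree(8, seed=61, mean_root_to_tip=0.5)
        sim = pp.simulate_coded(tree, m, n_columns=3000, seed=63)
        S = m.S.copy()
        pert = rng.lognormal(0.0, 0.8, size=S.shape)
        S = S * (pert + pert.T) / 2
        m_bad = pp.build_model(m.alphabet, m.pi, S)
        tree, _ = pp.optimize_branch_lengths(tree, sim, m)
        df = pp.compare_fit(
            [("true", m, pp.RateModel()), ("perturbed", m_bad, pp.RateModel())],
            [(tree, sim)],
        )
        row = df[(df.model_a == "true") & (df.model_b == "perturbed")].iloc[0]
        assert row.mean_site_lnl_diff > 0
        assert row.mean_site_aic_diff < 0

    def test_alphabet_mismatch_rejected(self, rng):
        m6 = random_state6_model(rng)
        m16 = pp.default_stem_model()
        tree = pp.yule_tree(4, seed=71)
        sim = pp.simulate_coded(tree, m16, n_columns=20, seed=73)
        with pytest.raises(pp.PairphyError, match="alphabet"):
            pp.compare_fit(
                [("a", m6, pp.RateModel()), ("b", m6, pp.RateModel())],
                [(tree, sim)],
            )
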