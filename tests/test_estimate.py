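import numpy as np
import pytest
from scipy.stats import pearsonr

import pairphy as pp
from pairphy import ColumnKind, SplitConfig, SplitMode

from conftest import random_state6_model


def _within_block_upper(model):
    k, nu = model.alphabet.size, model.alphabet.n_unpaired
    iu = np.triu_indices(k, 1)
    within = ((iu[0] < nu) & (iu[1] < nu)) | ((iu[0] >= nu) & (iu[1] >= nu))
    return model.S[iu][within]


def _simulate(model, n_taxa, n_columns, seed, frac_paired=0.6):
    tree = pp.yule_tree(n_taxa, seed=seed, mean_root_to_tip=0.5)
    n_paired = int(n_columns * frac_paired)
    kinds = [ColumnKind.UNPAIRED] * (n_columns - n_paired) \
        + [ColumnKind.PAIRED] * n_paired
    return pp.simulate_coded(tree, model, n_columns=n_columns,
                             column_kinds=kinds, seed=seed + 1)


class TestSplitTaxa:
    def _coded(self, rng, n):
        m = pp.default_stem_model()
        tree = pp.yule_tree(n, seed=int(rng.integers(2**31)))
        return pp.simulate_coded(tree, m, n_columns=50, seed=5)

    def test_random_even_chunks(self, rng):
        coded = self._coded(rng, 32)
        subsets = pp.split_taxa(coded, SplitConfig(SplitMode.RANDOM, k=16, seed=3))
        assert sorted(s.n_sequences for s in subsets) == [16, 16]
        names = [n for s in subsets for n in s.names]
        assert sorted(names) == sorted(coded.names)

    def test_random_remainder_merged(self, rng):
        coded = self._coded(rng, 29)
        subsets = pp.split_taxa(coded, SplitConfig(SplitMode.RANDOM, k=8, seed=3))
        assert sorted(s.n_sequences for s in subsets) == [8, 8, 13]

    def test_random_is_seed_deterministic(self, rng):
        coded = self._coded(rng, 20)
        a = pp.split_taxa(coded, SplitConfig(SplitMode.RANDOM, k=8, seed=9))
        b = pp.split_taxa(coded, SplitConfig(SplitMode.RANDOM, k=8, seed=9))
        assert [s.names for s in a] == [s.names for s in b]

    def test_tree_based_keeps_clades_together(self):
        # two well-separated 10-taxon clades must not be split across subsets
        m = pp.default_stem_model()
        left = pp.yule_tree(10, seed=1, mean_root_to_tip=0.15)
        right = pp.yule_tree(10, seed=2, mean_root_to_tip=0.15)
        import dendropy
        taxa = dendropy.TaxonNamespace(
            [f"L{i}" for i in range(10)] + [f"R{i}" for i in range(10)]
        )
        tree = dendropy.Tree(taxon_namespace=taxa)
        for prefix, sub in (("L", left), ("R", right)):
            clone = sub.clone(depth=1)
            for lf in clone.leaf_node_iter():
                lf.taxon = taxa.get_taxon(prefix + lf.taxon.label[1:])
            clone.seed_node.edge.length = 0.5  # clear but unsaturated stem
            tree.seed_node.add_child(clone.seed_node)
        sim = pp.simulate_coded(tree, m, n_columns=2000, seed=7)
        subsets = pp.split_taxa(
            sim, SplitConfig(SplitMode.TREE_BASED, k=16), guide_model=m
        )
        for s in subsets:
            prefixes = {n[0] for n in s.names}
            assert len(prefixes) == 1

    def test_too_small_k_rejected(self):
        with pytest.raises(pp.PairphyError):
            SplitConfig(SplitMode.RANDOM, k=3)


class TestHoldoutSplit:
    def test_shapes_and_disjointness(self, rng):
        m = pp.default_stem_model()
        tree = pp.yule_tree(12, seed=3)
        coded = pp.simulate_coded(tree, m, n_columns=30, seed=5)
        train, test = pp.holdout_split(coded, n_test=3, seed=7)
        assert train.n_sequences == 9 and test.n_sequences == 3
        assert not set(train.names) & set(test.names)
        assert sorted(train.names + test.names) == sorted(coded.names)


class TestEstimateEmpiricalModel:
    def test_recovers_known_exchangeabilities(self, rng):
        true = random_state6_model(np.random.default_rng(77))
        sim = _simulate(true, n_taxa=12, n_columns=2000, seed=80)
        res = pp.estimate_empirical_model([sim], pp.flat_model(pp.STATE6),
                                          tol=0.1, max_iter=4)
        r, _ = pearsonr(_within_block_upper(true), _within_block_upper(res.model))
        assert r >= 0.9
        assert res.iterations >= 1

    def test_lnl_trace_monotone(self, rng):
        true = random_state6_model(np.random.default_rng(99))
        sim = _simulate(true, n_taxa=8, n_columns=500, seed=100)
        res = pp.estimate_empirical_model([sim], pp.flat_model(pp.STATE6),
                                          tol=0.01, max_iter=4)
        assert all(b >= a - 1e-6 for a, b in zip(res.lnl_trace, res.lnl_trace[1:]))

    def test_frequencies_equal_observed_counts(self, rng):
        true = random_state6_model(np.random.default_rng(55))
        sim = _simulate(true, n_taxa=8, n_columns=400, seed=56)
        res = pp.estimate_empirical_model([sim], pp.flat_model(pp.STATE6),
                                          max_iter=1)
        assert np.allclose(res.model.pi, pp.observed_frequencies([sim]), atol=1e-9)

    def test_degenerate_subset_rejected(self):
        coded = pp.CodedAlignment(
            list("abcd"), ["AFQ"] * 4,
            [ColumnKind.UNPAIRED, ColumnKind.PAIRED, ColumnKind.PAIRED],
            pp.STATE16,
        )
        with pytest.raises(pp.PairphyError, match="identical"):
            pp.estimate_empirical_model([coded], pp.flat_model(pp.STATE16))

    def test_equivariant_under_state_relabeling(self):
        # permuting the paired-block states permutes the estimate identically
        true = random_state6_model(np.random.default_rng(7))
        sim = _simulate(true, n_taxa=8, n_columns=800, seed=8)
        res = pp.estimate_empirical_model([sim], pp.flat_model(pp.STATE6),
                                          max_iter=2)
        perm = {"F": "I", "I": "F"}  # swap the GC and CG pair symbols
        rows = ["".join(perm.get(c, c) for c in r) for r in sim.rows]
        sim_perm = pp.CodedAlignment(sim.names, rows, sim.column_kind, sim.alphabet)
        res_perm = pp.estimate_empirical_model([sim_perm], pp.flat_model(pp.STATE6),
                                               max_iter=2)
        a = pp.STATE6
        i, j = a.index("F"), a.index("I")
        order = list(range(a.size))
        order[i], order[j] = j, i
        permuted_S = res.model.S[np.ix_(order, order)]
        assert np.allclose(permuted_S, res_perm.model.S, rtol=0.05, atol=1e-3)


class TestCompareModelParameters:
    def test_self_correlation_is_one(self, rng):
        m = random_state6_model(rng)
        rep = pp.compare_model_parameters(m, m)
        assert rep["freq_r"] == pytest.approx(1.0)
        assert rep["exch_r"] == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        m = random_state6_model(rng)
        scaled = pp.build_model(m.alphabet, m.pi, 3.5 * m.S)
        rep = pp.compare_model_parameters(m, scaled)
        assert rep["exch_r"] == pytest.approx(1.0)
        assert abs(rep["paired_t"]) < 1e-8

    def test_replicate_estimates_correlate(self):
        true = random_state6_model(np.random.default_rng(123))
        reps = []
        for seed in (200, 300):
            sim = _simulate(true, n_taxa=10, n_columns=2000, seed=seed)
            reps.append(
                pp.estimate_empirical_model([sim], pp.flat_model(pp.STATE6),
                                            max_iter=3).model
            )
        rep = pp.compare_model_parameters(*reps)
        assert rep["exch_r"] >= 0.9

    def test_alphabet_mismatch_rejected(self, rng):
        with pytest.raises(pp.PairphyError):
            pp.compare_model_parameters(
                random_state6_model(rng), pp.default_stem_model()
            )


class TestExpandCollapsedModel:
    def test_block_shapes_and_frequency_mass(self):
        m7 = pp.flat_model(pp.STATE7)
        m16 = pp.expand_collapsed_model(m7)
        assert m16.alphabet.id == "STATE16"
        from pairphy.recode import MISMATCH_SYMBOLS
        mm_mass = sum(m16.pi[m16.alphabet.index(s)] for s in MISMATCH_SYMBOLS)
        assert mm_mass == pytest.approx(m7.pi[m7.alphabet.index("M")], abs=1e-9)
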