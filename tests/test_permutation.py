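import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qtltree.bmg_tree import build_tree
from qtltree.disjoint_scan import best_disjoint
from qtltree.genotype_io import BMGMatrix
from qtltree.node_stats import TraitVector, compute_node_stats
from qtltree.permutation import (TreeScorer, bonferroni_threshold,
                                 permutation_test, scan_genes,
                                 stratified_permutation, write_scan_tsv)
from qtltree.synthetic_data import SimulationConfig, simulate

from conftest import random_bmg


class TestStratifiedPermutation:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_within_stratum_multisets_preserved(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        values = rng.normal(size=n)
        strata = rng.choice(["a", "b", "c"], size=n)
        out = stratified_permutation(values, strata, rng)
        for lab in "abc":
            idx = strata == lab
            assert sorted(out[idx]) == sorted(values[idx])

    def test_singleton_strata_are_fixed_points(self):
        rng = np.random.default_rng(0)
        values = np.arange(6, dtype=float)
        strata = [f"s{i}" for i in range(6)]
        for _ in range(10):
            assert np.array_equal(stratified_permutation(values, strata, rng), values)

    def test_one_stratum_is_uniform_shuffle(self):
        rng = np.random.default_rng(1)
        values = np.arange(5, dtype=float)
        out = stratified_permutation(values, ["x"] * 5, rng)
        assert sorted(out) == sorted(values)

    def test_two_by_two_strata_reach_all_four_arrangements(self):
        # strata {0,1} and {2,3}: exactly 2! * 2! = 4 composite permutations
        rng = np.random.default_rng(2)
        values = np.array([1.0, 2.0, 3.0, 4.0])
        strata = ["a", "a", "b", "b"]
        seen = {tuple(stratified_permutation(values, strata, rng)) for _ in range(300)}
        assert seen == {(1, 2, 3, 4), (2, 1, 3, 4), (1, 2, 4, 3), (2, 1, 4, 3)}


class TestVectorizedScorer:
    """The batched engine must agree with the per-node/per-tree reference path."""

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_scan_matches_slow_reference(self, seed):
        rng = np.random.default_rng(seed)
        b = random_bmg(rng, n_individuals=25)
        tree = build_tree(b)
        tv = TraitVector.from_values(rng.normal(size=25))
        k = 4
        traits = np.stack([rng.permutation(tv.values) for _ in range(8)])
        fast = TreeScorer(tree).scan(traits, tv.mean, tv.sd, k)
        for r in range(traits.shape[0]):
            tv_r = TraitVector(values=traits[r], mean=tv.mean, sd=tv.sd)
            stats = compute_node_stats(tree, tv_r, "square")
            slow = best_disjoint(tree, {s.node_id: s.score for s in stats}, k)
            assert np.allclose(fast[r], slow.S, rtol=1e-9, atol=1e-9)


class TestPermutationTest:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.b = random_bmg(rng, n_individuals=30, n_sites=4)
        self.tree = build_tree(self.b)
        self.rng = rng

    def test_constant_within_strata_gives_p_one(self):
        strata = np.array(["a"] * 15 + ["b"] * 15)
        trait = np.where(strata == "a", 1.0, 5.0)
        res = permutation_test(self.tree, trait, strata=strata, k=3, n_reps=50, seed=0)
        assert np.all(res.p_values == 1.0)

    def test_minimum_p_is_one_over_reps_plus_one(self):
        # a signal so strong no replicate reaches it: p = 1/(n_reps + 1)
        carrier = self.b.codes[:, 0] == 1
        trait = np.where(carrier, 100.0, 0.0) + self.rng.normal(size=30)
        res = permutation_test(self.tree, trait, k=2, n_reps=19, seed=1)
        assert res.p_values[0] == pytest.approx(1.0 / 20.0)
        assert np.all(res.p_values > 0)

    def test_deterministic_given_seed(self):
        trait = self.rng.normal(size=30)
        a = permutation_test(self.tree, trait, k=3, n_reps=99, seed=5)
        b = permutation_test(self.tree, trait, k=3, n_reps=99, seed=5)
        assert np.array_equal(a.p_values, b.p_values)
        assert np.array_equal(a.observed.S, b.observed.S)

    def test_batching_does_not_change_pvalues(self):
        trait = self.rng.normal(size=30)
        a = permutation_test(self.tree, trait, k=2, n_reps=100, seed=7, batch_size=7)
        b = permutation_test(self.tree, trait, k=2, n_reps=100, seed=7, batch_size=100)
        assert np.array_equal(a.p_values, b.p_values)

    def test_reps_validation(self):
        with pytest.raises(ValueError, match="n_reps"):
            permutation_test(self.tree, np.arange(30, dtype=float), n_reps=0)


@pytest.fixture(scope="module")
def dataset():
    return simulate(SimulationConfig(n_populations=2, n_per_population=40,
                                     n_genes=4, sites_per_gene=5, seed=11))


class TestScanGenes:

    def test_bit_identical_output(self, dataset, tmp_path):
        kwargs = dict(trait_name="Q1", k=3, n_reps=99, seed=42)
        df1 = scan_genes(dataset.genotypes, dataset.phenotypes, **kwargs)
        df2 = scan_genes(dataset.genotypes, dataset.phenotypes, **kwargs)
        pd.testing.assert_frame_equal(df1, df2)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_scan_tsv(df1, p1, 42)
        write_scan_tsv(df2, p2, 42)
        assert p1.read_bytes() == p2.read_bytes()

    def test_gene_order_independence(self, dataset):
        genes = dataset.genotypes.genes()
        kwargs = dict(trait_name="Q1", k=2, n_reps=49, seed=3)
        fwd = scan_genes(dataset.genotypes, dataset.phenotypes, genes=genes, **kwargs)
        rev = scan_genes(dataset.genotypes, dataset.phenotypes, genes=genes[::-1], **kwargs)
        rev = rev.iloc[::-1].reset_index(drop=True)
        pd.testing.assert_frame_equal(fwd, rev)

    def test_degenerate_gene_flagged(self, dataset):
        g = dataset.genotypes
        g2 = type(g)(counts=np.zeros_like(g.counts), site_ids=g.site_ids,
                     site_positions=g.site_positions, site_genes=g.site_genes,
                     individual_ids=g.individual_ids,
                     individual_population=g.individual_population)
        df = scan_genes(g2, dataset.phenotypes, trait_name="Q1", k=2, n_reps=9, seed=0)
        assert df["degenerate"].all()
        assert (df["p_2"] == 1.0).all() and (df["S_2"] == 0.0).all()


@pytest.mark.parametrize("alpha,n,expected", [
    (0.05, 1, 0.05),
    (0.05, 1000, 5e-5),
    (0.05, 3205, 0.05 / 3205),  # = 1.56e-5
])
def test_bonferroni_threshold(alpha, n, expected):
    assert bonferroni_threshold(alpha, n) == pytest.approx(expected, rel=1e-12)


def test_bonferroni_validation():
    with pytest.raises(ValueError):
        bonferroni_threshold(1.5, 10)
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)
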