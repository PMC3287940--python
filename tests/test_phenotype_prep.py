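import numpy as np
import pandas as pd
import pytest

from qtltree.genotype_io import MISSING
from qtltree.phenotype_prep import (individual_heterozygosity, pc_loadings,
                                    refit_selected, residualize)
from qtltree.synthetic_data import SimulationConfig, simulate

from conftest import make_matrix


class TestHeterozygosity:
    @pytest.mark.parametrize("counts,expected", [
        ([[0, 0, 0, 0]], 0.0),
        ([[1, 1, 1, 1]], 1.0),
        ([[0, 1, 2, 1]], 0.5),
    ])
    def test_fraction_of_het_sites(self, counts, expected):
        g = make_matrix(counts + [[0, 0, 0, 0]])
        assert individual_heterozygosity(g)[0] == pytest.approx(expected)

    def test_missing_sites_excluded(self):
        g = make_matrix([[1, MISSING, 0], [0, 0, 0]])
        assert individual_heterozygosity(g)[0] == pytest.approx(0.5)

    def test_all_missing_flagged_nan(self):
        g = make_matrix([[MISSING, MISSING], [0, 1]])
        het = individual_heterozygosity(g)
        assert np.isnan(het[0]) and het[1] == pytest.approx(0.5)


class TestPCLoadings:
    def test_separates_divergent_populations(self):
        from sklearn.metrics import silhouette_score
        d = simulate(SimulationConfig(n_populations=2, n_per_population=60,
                                      n_genes=40, fst=0.25, seed=5))
        scores, frac = pc_loadings(d.genotypes, n_components=4)
        labels = d.genotypes.individual_population
        assert silhouette_score(scores[:, :2], labels) > 0
        assert np.all(frac >= 0) and frac.sum() <= 1.0 + 1e-12

    def test_duplicate_individuals_identical_scores(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 3, size=(10, 30))
        counts[3] = counts[7]
        g = make_matrix(counts)
        scores, _ = pc_loadings(g, n_components=3)
        assert np.allclose(scores[3], scores[7], atol=1e-9)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(1)
        g = make_matrix(rng.integers(0, 3, size=(15, 20)))
        s1, _ = pc_loadings(g, n_components=3)
        s2, _ = pc_loadings(g, n_components=3)
        assert np.array_equal(s1, s2)
        for c in range(3):
            assert s1[np.argmax(np.abs(s1[:, c])), c] > 0

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pc_loadings(make_matrix(np.ones((8, 5))), n_components=2)


def _covariates(rng, n):
    return pd.DataFrame({
        "Age": rng.normal(45, 12, n),
        "Sex": rng.binomial(1, 0.5, n).astype(float),
        "Smoke": rng.binomial(1, 0.25, n).astype(float),
    })


class TestResidualize:
    def test_recovers_planted_age_effect(self):
        rng = np.random.default_rng(10)
        cand = _covariates(rng, 500)
        y = 2.0 * cand["Age"].to_numpy() + rng.normal(0, 5, 500)
        derived = residualize(y, cand)
        assert derived.retained_terms == ["Age"]
        assert derived.coefficients["Age"] == pytest.approx(2.0, abs=0.1)

    def test_pure_noise_mostly_intercept_only(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cand = _covariates(rng, 300)
            derived = residualize(rng.normal(size=300), cand)
            hits += derived.retained_terms == []
        assert hits >= 15  # BIC is consistent: null model wins most seeds

    def test_residuals_standardized_and_orthogonal(self):
        rng = np.random.default_rng(3)
        cand = _covariates(rng, 400)
        y = 0.5 * cand["Age"].to_numpy() + 2 * cand["Smoke"].to_numpy() \
            + rng.normal(0, 3, 400)
        derived = residualize(y, cand)
        v = derived.values
        assert abs(v.mean()) < 1e-9 and v.std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        for term in derived.retained_terms:
            x = cand[term].to_numpy() - cand[term].mean()
            assert abs(v @ x) / len(v) < 1e-8

    def test_candidate_order_invariance(self):
        rng = np.random.default_rng(4)
        cand = _covariates(rng, 300)
        y = cand["Age"].to_numpy() * 0.3 + rng.normal(0, 2, 300)
        a = residualize(y, cand)
        b = residualize(y, cand[["Smoke", "Sex", "Age"]])
        assert sorted(a.retained_terms) == sorted(b.retained_terms)
        assert np.allclose(a.values, b.values)

    def test_aliased_candidates_dropped(self):
        rng = np.random.default_rng(5)
        cand = _covariates(rng, 200)
        cand["Age2"] = cand["Age"] * 2.0  # collinear
        cand["Const"] = 1.0
        derived = residualize(cand["Age"].to_numpy() + rng.normal(size=200), cand)
        assert "Age2" not in derived.retained_terms
        assert "Const" not in derived.retained_terms

    def test_insufficient_data_rejected(self):
        rng = np.random.default_rng(6)
        cand = _covariates(rng, 4)
        with pytest.raises(ValueError, match="insufficient"):
            residualize(np.arange(4, dtype=float), cand)


class TestRefitSelected:
    def test_identity_on_selection_data(self):
        rng = np.random.default_rng(7)
        cand = _covariates(rng, 300)
        y = cand["Age"].to_numpy() * 1.5 + rng.normal(0, 4, 300)
        derived = residualize(y, cand)
        refit = refit_selected(derived, y, cand)
        assert np.allclose(refit.values, derived.values, atol=1e-10)

    def test_zero_terms_reduces_to_standardized_trait(self):
        rng = np.random.default_rng(8)
        cand = _covariates(rng, 100)
        derived = residualize(rng.normal(size=100), cand)
        if derived.retained_terms:  # rare under pure noise; skip-free guard
            derived.retained_terms = []
        y2 = rng.normal(2.0, 3.0, 100)
        refit = refit_selected(derived, y2, cand)
        assert np.allclose(refit.values, (y2 - y2.mean()) / y2.std(ddof=1))

    def test_replicate_recovers_noise_scale(self):
        rng = np.random.default_rng(9)
        cand = _covariates(rng, 800)
        sigma = 3.0
        y = 2.0 * cand["Age"].to_numpy() + rng.normal(0, sigma, 800)
        derived = residualize(y, cand)
        cand2 = _covariates(rng, 800)
        y2 = 2.0 * cand2["Age"].to_numpy() + rng.normal(0, sigma, 800)
        refit = refit_selected(derived, y2, cand2)
        assert refit.residual_sd == pytest.approx(sigma, rel=0.1)

    def test_missing_terms_rejected(self):
        rng = np.random.default_rng(12)
        cand = _covariates(rng, 300)
        derived = residualize(cand["Age"].to_numpy() * 2 + rng.normal(size=300), cand)
        with pytest.raises(ValueError, match="lacks retained"):
            refit_selected(derived, np.arange(300, dtype=float),
                           cand.drop(columns=derived.retained_terms))


def test_pc_residualization_removes_heterozygosity_confound():
    """Planted trait-heterozygosity correlation shrinks toward 0 after
    residualizing on PC loadings (raw ~0.2 -> residual ~0)."""
    # enough sites (~1000) that the heterozygosity axis is estimable by PCA
    cfg = SimulationConfig(n_populations=2, n_per_population=150, n_genes=150,
                           gamma_het=0.25, het_dropout_max=0.9, seed=13)
    d = simulate(cfg)
    het = individual_heterozygosity(d.genotypes)
    trait = d.phenotypes.trait("Q1")
    raw_r = np.corrcoef(trait, het)[0, 1]
    scores, _ = pc_loadings(d.genotypes, n_components=6)
    cand = d.phenotypes.data[["Age", "Sex", "Smoke"]].copy()
    for c in range(6):
        cand[f"PC{c + 1}"] = scores[:, c]
    derived = residualize(trait, cand)
    resid_r = np.corrcoef(derived.values, het)[0, 1]
    assert abs(raw_r) > 0.12
    assert abs(resid_r) < 0.5 * abs(raw_r)
    assert abs(resid_r) < 0.08
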