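import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from canopygen.quantgen import (GeneticCorrelationEstimate, MixedModelSpec,
                                RandomEffect, VarianceComponents,
                                breeding_values, fit_reml, fit_reml_genomic,
                                genetic_correlation_pedigree,
                                genetic_correlation_snp,
                                heritability_pedigree, heritability_snp,
                                incidence, reml_loglik, summarize_traits)
from canopygen.simulate import SimulationConfig, TraitModel, simulate_genetics


def _balanced_oneway(nf=20, npf=10, s2f=1.0, s2e=4.0, seed=7):
    rng = np.random.default_rng(seed)
    fam = np.repeat(np.arange(nf), npf)
    y = (np.repeat(rng.normal(0, np.sqrt(s2f), nf), npf)
         + rng.normal(0, np.sqrt(s2e), nf * npf))
    re = incidence(fam)
    re.name = "family"
    return y, np.ones((nf * npf, 1)), [re], fam


class TestREML:
    def test_matches_anova_on_balanced_design(self):
        y, X, random, fam = _balanced_oneway()
        fit = fit_reml(MixedModelSpec(y, X, random))
        nf, npf = 20, 10
        ybar = y.reshape(nf, npf).mean(1)
        msb = npf * ((ybar - y.mean()) ** 2).sum() / (nf - 1)
        msw = ((y.reshape(nf, npf) - ybar[:, None]) ** 2).sum() / (nf * (npf - 1))
        assert fit.vc.components["family"] == pytest.approx((msb - msw) / npf,
                                                            abs=1e-6)
        assert fit.vc.sigma2_e == pytest.approx(msw, abs=1e-6)

    def test_beats_variance_grid_on_tiny_unbalanced_data(self):
        rng = np.random.default_rng(3)
        fam = np.array([0]*3 + [1]*7 + [2]*5 + [3]*9 + [4]*6)  # n=30
        y = rng.normal(0, 1, 30) + np.array([0.9, -0.4, 0.1, 0.7, -1.1])[fam]
        X = np.ones((30, 1))
        re = incidence(fam)
        re.name = "family"
        fit = fit_reml(MixedModelSpec(y, X, [re]))
        best_grid = -np.inf
        for s2f in np.linspace(0.01, 3.0, 50):
            for s2e in np.linspace(0.05, 3.0, 50):
                ll = reml_loglik(y, X, [re], {"family": s2f}, s2e)
                best_grid = max(best_grid, ll)
        assert fit.vc.loglik >= best_grid - 1e-3

    def test_zero_family_variance_hits_boundary(self):
        rng = np.random.default_rng(2)
        fam = np.repeat(np.arange(10), 8)
        y = rng.normal(0, 1, 80)  # no family signal
        re = incidence(fam)
        re.name = "family"
        fit = fit_reml(MixedModelSpec(y, np.ones((80, 1)), [re]))
        assert fit.vc.components["family"] == 0.0
        assert fit.vc.boundary["family"]

    def test_missing_phenotypes_dropped_with_count(self):
        y, X, random, _ = _balanced_oneway()
        y[:5] = np.nan
        fit = fit_reml(MixedModelSpec(y, X, random))
        assert fit.n_dropped == 5

    def test_genomic_eigendecomposition_equals_direct(self, halfsib_dataset):
        from canopygen.gwas import qc_filter, yang_kinship
        geno, _ = qc_filter(halfsib_dataset.genotypes)
        K, _ = yang_kinship(geno)
        y = halfsib_dataset.phenotypes["trait"].to_numpy()
        X = np.ones((len(y), 1))
        fit_e, _ = fit_reml_genomic(y, X, K)
        fit_d = fit_reml(MixedModelSpec(y, X, [RandomEffect("g", K=K)]),
                         kind="genomic")
        assert fit_e.vc.components["g"] == pytest.approx(
            fit_d.vc.components["g"], abs=1e-6)
        assert fit_e.vc.sigma2_e == pytest.approx(fit_d.vc.sigma2_e, abs=1e-6)
        assert fit_e.vc.loglik == pytest.approx(fit_d.vc.loglik, abs=1e-6)


class TestHeritability:
    @pytest.mark.parametrize("comps,expected,warns", [
        ((1.0, 0.5, 3.5), 0.5, False),
        ((0.0, 0.5, 3.5), 0.0, False),
        ((2.0, 0.0, 2.0), 1.25, True),
    ])
    def test_pedigree_plugin(self, comps, expected, warns):
        s2f, s2b, s2e = comps
        vc = VarianceComponents("pedigree", {"family": s2f, "block": s2b},
                                s2e, 0.0)
        if warns:
            with pytest.warns(UserWarning):
                est = heritability_pedigree(vc)
        else:
            est = heritability_pedigree(vc)
        assert est.h2 == pytest.approx(expected)
        assert est.warning == warns

    def test_snp_plugin(self):
        vc = VarianceComponents("genomic", {"g": 1.0}, 4.0, 0.0)
        assert heritability_snp(vc).h2 == pytest.approx(0.5)
        vc0 = VarianceComponents("genomic", {"g": 0.0}, 4.0, 0.0)
        assert heritability_snp(vc0).h2 == 0.0

    def test_kind_mismatch_rejected(self):
        vc = VarianceComponents("genomic", {"g": 1.0}, 4.0, 0.0)
        with pytest.raises(ValueError):
            heritability_pedigree(vc)


class TestGeneticCorrelation:
    def test_duplicated_trait_gives_unity(self):
        sim = simulate_genetics(SimulationConfig(
            n_families=10, trees_per_family=10, n_sites=1, n_snps=5,
            traits=[TraitModel(sigma2_f=0.5, sigma2_b=0.1, sigma2_e=0.5)],
            seed=21))
        df = sim.design.merge(sim.phenotypes, on="individual_id")
        y = df["trait"].to_numpy()
        X = np.ones((len(y), 1))
        rb = incidence(df["block_id"]); rb.name = "block"
        rf = incidence(df["family_id"]); rf.name = "family"
        est = genetic_correlation_pedigree(y, y, X, [rb, rf])
        assert est.r_g == pytest.approx(1.0, abs=1e-4)

    def test_printed_denominator_variant(self):
        """The sum-denominator variant rescales the product form by
        sqrt(v_i v_j) / sqrt(v_i + v_j)."""
        sim = simulate_genetics(SimulationConfig(
            n_families=10, trees_per_family=10, n_sites=1, n_snps=5,
            traits=[TraitModel(name="a", sigma2_f=0.5, sigma2_b=0.1,
                               sigma2_e=0.5),
                    TraitModel(name="b", sigma2_f=0.5, sigma2_b=0.1,
                               sigma2_e=0.5)],
            family_corr=np.array([[1, 0.6], [0.6, 1]]), seed=22))
        df = sim.design.merge(sim.phenotypes, on="individual_id")
        X = np.ones((len(df), 1))
        rb = incidence(df["block_id"]); rb.name = "block"
        rf = incidence(df["family_id"]); rf.name = "family"
        std = genetic_correlation_pedigree(df["a"].to_numpy(),
                                           df["b"].to_numpy(), X, [rb, rf])
        printed = genetic_correlation_pedigree(
            df["a"].to_numpy(), df["b"].to_numpy(), X, [rb, rf],
            printed_denominator=True)
        vi = std.components["var_f_i"]
        vj = std.components["var_f_j"]
        assert printed.r_g == pytest.approx(
            std.r_g * np.sqrt(vi * vj) / np.sqrt(vi + vj), rel=1e-9)

    @pytest.mark.parametrize("truth,lo,hi", [(0.0, -0.15, 0.15),
                                             (0.8, 0.65, 0.95)])
    def test_family_correlation_recovered(self, truth, lo, hi):
        """Mean estimate across replicates tracks the planted family-effect
        correlation."""
        ests = []
        for rep in range(15):
            tm = [TraitModel(name="a", sigma2_f=0.2, sigma2_b=0.1,
                             sigma2_e=0.7),
                  TraitModel(name="b", sigma2_f=0.2, sigma2_b=0.1,
                             sigma2_e=0.7)]
            sim = simulate_genetics(SimulationConfig(
                n_families=20, trees_per_family=10, n_sites=2, n_snps=4,
                traits=tm, family_corr=np.array([[1, truth], [truth, 1]]),
                seed=4000 + rep))
            df = sim.design.merge(sim.phenotypes, on="individual_id")
            X = np.column_stack([np.ones(len(df)),
                                 (df["site_id"] == "site1").to_numpy(float)])
            rb = incidence(df["block_id"]); rb.name = "block"
            rf = incidence(df["family_id"]); rf.name = "family"
            ests.append(genetic_correlation_pedigree(
                df["a"].to_numpy(), df["b"].to_numpy(), X, [rb, rf]).r_g)
        assert lo <= np.mean(ests) <= hi

    @pytest.mark.parametrize("bi,bj,expected", [
        ((1, 2, 3), (1, 2, 3), 1.0),
        ((1, 0), (0, 1), 0.0),
        ((1, 1), (1, -1), 0.0),
    ])
    def test_snp_effect_correlation_examples(self, bi, bj, expected):
        est = genetic_correlation_snp(np.array(bi, float), np.array(bj, float))
        assert est.r_g == pytest.approx(expected, abs=1e-12)

    def test_snp_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            genetic_correlation_snp(np.zeros(3), np.ones(3))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_snp_estimator_bounded_by_cauchy_schwarz(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(2, 50)
        bi = rng.normal(0, 1, m)
        bj = rng.normal(0, 1, m)
        r = genetic_correlation_snp(bi, bj).r_g
        assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12


@pytest.fixture(scope="module")
def two_site_sim():
    return simulate_genetics(SimulationConfig(
        n_families=15, trees_per_family=10, n_sites=2, n_snps=5,
        traits=[TraitModel(name="T", sigma2_f=0.4, sigma2_b=0.1,
                           sigma2_e=0.5, sigma2_fs=0.1)], seed=31))


class TestBreedingValues:

    def test_standardized_scores_and_structure(self, two_site_sim):
        bv = breeding_values(two_site_sim.phenotypes, two_site_sim.design,
                             ["T"])
        for (_, _), grp in bv.groupby(["trait", "site"]):
            assert grp["BV_std"].mean() == pytest.approx(0.0, abs=1e-9)
            assert grp["BV_std"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(bv["BV"], bv["G"] + bv["GxE"])

    def test_single_site_bv_equals_g(self):
        sim = simulate_genetics(SimulationConfig(
            n_families=10, trees_per_family=10, n_sites=1, n_snps=5,
            traits=[TraitModel(name="T", sigma2_f=0.4, sigma2_b=0.1,
                               sigma2_e=0.5)], seed=32))
        bv = breeding_values(sim.phenotypes, sim.design, ["T"])
        assert (bv["GxE"] == 0).all()
        assert np.allclose(bv["BV"], bv["G"])

    def test_family_ranking_recovered(self):
        """BLUP family ranking tracks the planted family effects."""
        from scipy.stats import spearmanr
        sim = simulate_genetics(SimulationConfig(
            n_families=20, trees_per_family=20, n_sites=1, n_snps=5,
            traits=[TraitModel(name="T", sigma2_f=0.2, sigma2_b=0.1,
                               sigma2_e=0.7)], seed=33))
        bv = breeding_values(sim.phenotypes, sim.design, ["T"])
        g = bv.drop_duplicates("family").set_index("family")["G"]
        truth = sim.truth["family_effects"]["T"]
        fams = [f"fam{f:02d}" for f in range(20)]
        rho = spearmanr(g.loc[fams].to_numpy(), truth).statistic
        assert rho >= 0.7


class TestSummarizeTraits:
    def test_correlation_and_pca_structure(self, rng):
        n = 50
        base = rng.normal(0, 1, n)
        df = pd.DataFrame({
            "CA": base + rng.normal(0, 0.1, n),
            "CBH": rng.normal(0, 1, n),
            "CL": base * 2 + rng.normal(0, 0.1, n),
            "CV": base + rng.normal(0, 0.2, n),
            "CW": rng.normal(0, 1, n),
            "CWH": rng.normal(0, 1, n),
            "H": base + rng.normal(0, 0.3, n),
        })
        out = summarize_traits(df)
        corr = out["correlation"]
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)
        assert corr.loc["CA", "CL"] > 0.9
        assert out["pca_variance_fraction"].sum() == pytest.approx(1.0)

    def test_constant_trait_flagged(self, rng):
        df = pd.DataFrame({"CA": rng.normal(0, 1, 10),
                           "H": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            out = summarize_traits(df, trait_cols=["CA", "H"])
        assert out["constant_traits"] == ["H"]

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            summarize_traits(pd.DataFrame({"CA": [1.0, 2.0], "H": [1.0, 2.0]}),
                             trait_cols=["CA", "H"])
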