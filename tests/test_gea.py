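"""Tests of the GEA scans: Mahalanobis outliers, LFMM, gradient forest,
consensus and matched random sets."""

import numpy as np
import pytest
from scipy import stats

import yewoffset as yo
from yewoffset.gea import (
    LFMM,
    GradientForest,
    TurnoverFunction,
    consensus_candidates,
    genomic_inflation_factor,
    gf_importance,
    matched_random_set,
    rda_outliers,
    snp_maf,
)
from yewoffset.ordination import RDA


class TestRdaOutliers:
    def test_displaced_snp_always_flagged(self, rng):
        n_pop, n_snp = 30, 300
        X = rng.normal(0, 1, (n_pop, 2))
        Y = rng.uniform(0.2, 0.8, (n_pop, n_snp))
        # make one SNP strongly climate-driven
        Y[:, 0] = 0.5 + 0.4 * np.tanh(2 * X[:, 0])
        res = RDA(Y, X).fit()
        tab = rda_outliers(res, K=2, fdr=0.10)
        assert tab.iloc[0]["candidate"]
        assert tab.iloc[0]["D2"] == tab["D2"].max()

    def test_gif_of_chisq_draws_near_one(self, rng):
        d2 = stats.chi2.rvs(2, size=20000, random_state=rng.integers(2**31))
        assert genomic_inflation_factor(d2, 2) == pytest.approx(1.0, abs=0.05)

    def test_null_false_positive_control(self):
        """Without adaptive loci, flagged fractions stay near the FDR level."""
        hits = []
        for seed in range(20):
            ds = yo.simulate_landscape(yo.LandscapeConfig(
                n_pops=25, n_ind_per_pop=12, n_snps=500, frac_adaptive=0.0,
                missing_rate=0.0, seed=300 + seed))
            freqs = yo.population_allele_freqs(ds.genotypes)
            res = RDA(freqs.freqs, ds.reference_climate.values).fit()
            tab = rda_outliers(res, K=2, fdr=0.10)
            hits.append(tab["candidate"].mean())
        assert np.mean(hits) < 0.12

    def test_k_validation(self, rda_results):
        with pytest.raises(ValueError):
            rda_outliers(rda_results, K=0)
        with pytest.raises(ValueError):
            rda_outliers(rda_results, K=99)


class TestLFMM:
    def test_k_zero_reduces_to_ols(self, rng):
        n, p, m = 20, 2, 30
        X = rng.normal(0, 1, (n, p))
        Y = rng.uniform(0, 1, (n, m))
        res = LFMM(Y, X, K_latent=0).fit()
        # per-SNP OLS oracle via statsmodels
        import statsmodels.api as sm

        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        D = sm.add_constant(Z)
        for j in range(0, m, 7):
            fit = sm.OLS(Y[:, j] - Y[:, j].mean(), D).fit()
            np.testing.assert_allclose(res.effects[:, j], fit.params[1:], atol=1e-8)
            np.testing.assert_allclose(res.tstats[:, j], fit.tvalues[1:], atol=1e-8)

    def test_matches_normal_equation_oracle(self, rng):
        """Effects with latent factors match an explicit linear-algebra oracle."""
        n, p, m, K = 15, 2, 25, 2
        X = rng.normal(0, 1, (n, p))
        Y = rng.uniform(0, 1, (n, m))
        ridge = 1e-6
        res = LFMM(Y, X, K_latent=K, ridge=ridge).fit()
        # oracle: same estimator assembled independently with explicit inverses
        Yc = Y - Y.mean(0)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        B1 = np.linalg.inv(Z.T @ Z + ridge * np.eye(p)) @ Z.T @ Yc
        U, s, _ = np.linalg.svd(Yc - Z @ B1, full_matrices=False)
        F = U[:, :K] * s[:K]
        D = np.column_stack([np.ones(n), Z, F])
        coef = np.linalg.inv(D.T @ D) @ D.T @ Yc
        np.testing.assert_allclose(res.effects, coef[1:1 + p], atol=1e-8)
        np.testing.assert_allclose(res.factors, F, atol=1e-8)

    def test_null_candidate_fraction_controlled(self):
        fracs = []
        for seed in range(20):
            ds = yo.simulate_landscape(yo.LandscapeConfig(
                n_pops=25, n_ind_per_pop=12, n_snps=500, frac_adaptive=0.0,
                missing_rate=0.0, seed=600 + seed))
            freqs = yo.population_allele_freqs(ds.genotypes)
            res = LFMM(freqs.freqs, ds.reference_climate.values, K_latent=2).fit()
            fracs.append(len(res.candidates(0.10)) / 500)
        assert np.mean(fracs) <= 0.12

    def test_k_latent_validation(self, rng):
        Y = rng.uniform(0, 1, (10, 20))
        X = rng.normal(0, 1, (10, 2))
        with pytest.raises(ValueError):
            LFMM(Y, X, K_latent=10)
        with pytest.raises(ValueError):
            LFMM(Y, X, K_latent=-1)


class TestGradientForest:
    def test_deterministic_snp_ranks_first(self, rng):
        n = 30
        X = rng.normal(0, 1, (n, 3))
        Y = rng.uniform(0, 1, (n, 15))
        Y[:, 0] = 1 / (1 + np.exp(-2 * X[:, 0]))  # monotone in one variable
        res = GradientForest(Y, X, n_trees=50, seed=0).fit()
        assert res.importance.idxmax() == "0"
        tf = res.turnover_functions()
        assert tf["0"].total > tf["1"].total

    def test_noise_snp_importance_near_zero(self, rng):
        n = 30
        X = rng.normal(0, 1, (n, 3))
        imps = []
        for seed in range(10):
            Y = np.random.default_rng(seed).uniform(0, 1, (n, 5))
            res = GradientForest(Y, X, n_trees=40, seed=seed).fit()
            imps.extend(res.importance_)
        assert np.mean(imps) < 0.05

    def test_constant_snp_zero_importance(self, rng):
        X = rng.normal(0, 1, (20, 3))
        Y = np.column_stack([np.full(20, 0.5), rng.uniform(0, 1, 20)])
        res = GradientForest(Y, X, n_trees=30, seed=1).fit()
        assert res.importance_[0] == 0.0
        assert "0" not in res.top_candidates(0.5)

    def test_single_run_candidates_are_top_fraction(self, rng):
        n = 25
        X = rng.normal(0, 1, (n, 3))
        Y = rng.uniform(0, 1, (n, 40))
        Y[:, :3] = 1 / (1 + np.exp(-3 * X[:, [0]] + rng.normal(0, 0.2, (n, 3))))
        imp, cands, res = gf_importance(Y, X, n_trees=40, n_runs=1,
                                        top_frac=0.10, seed=5)
        expected = res.top_candidates(0.10)
        assert cands == [s for s in res.model.snp_ids if s in set(expected)]
        assert len(cands) == max(1, round(0.10 * 40))

    def test_turnover_monotone_and_clamped(self):
        f = TurnoverFunction(np.array([0.0, 1.0, 2.0]), np.array([0.1, 0.3, 0.6]))
        x = np.array([-5.0, 0.5, 1.5, 99.0])
        np.testing.assert_allclose(f(x), [0.0, 0.1, 0.3, 0.6])
        assert f.total == pytest.approx(0.6)


class TestConsensusAndRandomSets:
    def test_consensus_examples(self):
        sets = {"m1": ["A", "B"], "m2": ["B", "C"], "m3": ["D"]}
        assert consensus_candidates(sets, 2) == ["B"]
        assert set(consensus_candidates(sets, 1)) == {"A", "B", "C", "D"}

    def test_consensus_matches_brute_force(self, rng):
        ids = [f"x{i}" for i in range(1000)]
        sets = {f"m{k}": list(rng.choice(ids, 200, replace=False)) for k in range(5)}
        got = set(consensus_candidates(sets, 2))
        counts = {}
        for s in sets.values():
            for sid in s:
                counts[sid] = counts.get(sid, 0) + 1
        assert got == {sid for sid, c in counts.items() if c >= 2}

    def test_matched_random_set_properties(self, landscape_freqs):
        _, freqs = landscape_freqs
        maf = snp_maf(freqs.freqs)
        rng = np.random.default_rng(0)
        target = list(rng.choice(freqs.snp_ids, 30, replace=False))
        exclude = target + list(rng.choice(freqs.snp_ids, 50, replace=False))
        rand = matched_random_set(freqs.snp_ids, maf, exclude, target,
                                  n_bins=8, seed=1)
        assert len(rand) == len(target)
        assert not set(rand) & set(exclude)
        edges = np.linspace(0, 0.5, 9)
        h_t, _ = np.histogram(maf.loc[target], bins=edges)
        h_r, _ = np.histogram(maf.loc[rand], bins=edges)
        # per-bin counts agree except where the pool ran short
        assert np.abs(h_t - h_r).sum() <= 2
        ks = stats.ks_2samp(maf.loc[target], maf.loc[rand]).statistic
        assert ks < 1.0 / 8 + 0.1

    def test_empty_target_gives_empty_set(self, landscape_freqs):
        _, freqs = landscape_freqs
        maf = snp_maf(freqs.freqs)
        assert matched_random_set(freqs.snp_ids, maf, [], [], seed=0) == []


class TestAdaptiveRecovery:
    def test_candidates_enrich_for_true_adaptive_loci(self):
        ds = yo.simulate_landscape(yo.LandscapeConfig(
            n_pops=30, n_ind_per_pop=14, n_snps=400, frac_adaptive=0.05,
            cline_slope=2.5, drift_fst=0.3, missing_rate=0.0, seed=43))
        freqs = yo.population_allele_freqs(ds.genotypes)
        res = RDA(freqs.freqs, ds.reference_climate.values).fit()
        truth_ids = {f"snp{j + 1}" for j in ds.truth.adaptive_loci}
        tab = rda_outliers(res, K=2, fdr=0.10)
        cands = set(tab.index[tab["candidate"]])
        assert cands
        precision = len(cands & truth_ids) / len(cands)
        assert precision > 0.8
        # true adaptive loci concentrate at the top of the D2 ranking
        ranks = tab["D2"].rank(ascending=False)[list(truth_ids)]
        assert ranks.median() <= 2 * len(truth_ids)

    def test_prda_downweights_structured_neutral_loci(self):
        """Partialling out structure PCs lowers the calibrated outlier
        statistic of high-differentiation neutral loci (directional check
        averaged over seeds)."""
        from yewoffset import popgen

        diffs = []
        for seed in (41, 42, 43, 44, 45):
            ds = yo.simulate_landscape(yo.LandscapeConfig(
                n_pops=30, n_ind_per_pop=14, n_snps=400, frac_adaptive=0.05,
                cline_slope=2.5, drift_fst=0.3, missing_rate=0.0, seed=seed))
            freqs = yo.population_allele_freqs(ds.genotypes)
            scores, _ = popgen.genotype_pca(ds.genotypes, 2)
            pcs = scores.groupby(
                ds.genotypes.ind_meta["population"].to_numpy(), sort=False).mean()
            pcs = pcs.loc[freqs.populations]
            X = ds.reference_climate.values
            rda_t = rda_outliers(RDA(freqs.freqs, X).fit(), 2, 0.10)
            prda_t = rda_outliers(RDA(freqs.freqs, X, condition=pcs).fit(), 2, 0.10)
            truth_ids = {f"snp{j + 1}" for j in ds.truth.adaptive_loci}
            # neutral loci with the largest between-pool frequency contrast
            dpool = (ds.truth.pool_freqs.loc["west"]
                     - ds.truth.pool_freqs.loc["east"]).abs()
            neutral_hi = list(dpool.drop(list(truth_ids)).sort_values().index[-80:])
            d2_rda = (rda_t.loc[neutral_hi, "D2"] / rda_t["gif"].iloc[0]).mean()
            d2_prda = (prda_t.loc[neutral_hi, "D2"] / prda_t["gif"].iloc[0]).mean()
            diffs.append(d2_rda - d2_prda)
        assert np.mean(diffs) > 0.0
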