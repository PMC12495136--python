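"""Tests of the synthetic-landscape generator and its ground truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import yewoffset as yo
from yewoffset.genio import MISSING
from yewoffset.landscape import garden_climate_distance


class TestAdaptiveClineFreq:
    @pytest.mark.parametrize(
        "env,intercept,slope,expected",
        [
            (0.0, 0.0, 3.0, 0.5),
            (5.0, 0.0, 0.0, 0.5),
            (-2.0, 0.0, 0.0, 0.5),
            (1.0, 0.0, 3.0, 1.0 / (1.0 + np.exp(-3.0))),
        ],
    )
    def test_logistic_values(self, env, intercept, slope, expected):
        assert yo.adaptive_cline_freq(env, intercept, slope) == pytest.approx(expected)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            yo.adaptive_cline_freq(np.nan, 0.0, 1.0)
        with pytest.raises(ValueError):
            yo.adaptive_cline_freq(0.0, np.inf, 1.0)

    @given(
        env=st.floats(-5, 5),
        intercept=st.floats(-3, 3),
        slope=st.floats(0.01, 3),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_open_interval_and_monotone(self, env, intercept, slope):
        f = yo.adaptive_cline_freq(env, intercept, slope)
        assert 0.0 < f < 1.0
        assert yo.adaptive_cline_freq(env + 1.0, intercept, slope) > f


class TestSimulateLandscape:
    def test_seeded_determinism(self):
        cfg = yo.LandscapeConfig(n_pops=6, n_ind_per_pop=5, n_snps=60, seed=5)
        a, b = yo.simulate_landscape(cfg), yo.simulate_landscape(cfg)
        np.testing.assert_array_equal(a.genotypes.calls, b.genotypes.calls)
        pd.testing.assert_frame_equal(a.coords, b.coords)
        for k in a.climates:
            pd.testing.assert_frame_equal(a.climates[k].values, b.climates[k].values)
        np.testing.assert_array_equal(a.truth.adaptive_loci, b.truth.adaptive_loci)

    def test_zero_missing_rate(self):
        ds = yo.simulate_landscape(
            yo.LandscapeConfig(n_pops=5, n_ind_per_pop=6, n_snps=40,
                               missing_rate=0.0, seed=2)
        )
        assert not (ds.genotypes.calls == MISSING).any()

    def test_zero_adaptive_warns(self):
        with pytest.warns(UserWarning):
            ds = yo.simulate_landscape(
                yo.LandscapeConfig(n_pops=4, n_ind_per_pop=4, n_snps=50,
                                   frac_adaptive=0.001, seed=1)
            )
        assert len(ds.truth.adaptive_loci) == 0

    def test_population_mean_genotype_matches_truth(self):
        """Mean genotype per locus tracks 2p within binomial error, averaged
        over replicate seeds."""
        cfg = dict(n_pops=4, n_ind_per_pop=20, n_snps=30, missing_rate=0.0,
                   frac_adaptive=0.0)
        n_rep = 60
        devs = []
        for seed in range(n_rep):
            ds = yo.simulate_landscape(yo.LandscapeConfig(**cfg, seed=seed))
            p = ds.truth.expected_freqs.to_numpy()
            for i, pop in enumerate(ds.truth.expected_freqs.index):
                sel = (ds.genotypes.ind_meta["population"] == pop).to_numpy()
                mean_geno = ds.genotypes.calls[sel].mean(axis=0)
                se = np.sqrt(2 * p[i] * (1 - p[i]) / (2 * cfg["n_ind_per_pop"]))
                devs.append((mean_geno - 2 * p[i]) / np.maximum(se * np.sqrt(2), 1e-9))
        z = np.concatenate(devs)
        # standardized deviations should be ~N(0,1): mean near 0, sd near 1
        assert abs(z.mean()) < 0.05
        assert 0.8 < z.std() < 1.2

    def test_within_contig_linkage_exceeds_between(self):
        ds = yo.simulate_landscape(
            yo.LandscapeConfig(n_pops=4, n_ind_per_pop=50, n_snps=100,
                               frac_adaptive=0.0, missing_rate=0.0,
                               contig_size=10, ld_rho=0.7, seed=9)
        )
        calls = ds.genotypes.calls.astype(float)
        resid = calls - np.vstack([
            calls[(ds.genotypes.ind_meta["population"] == p).to_numpy()].mean(0)
            for p in ds.genotypes.ind_meta["population"]
        ])
        within, between = [], []
        for j in range(0, 99):
            if resid[:, j].std() == 0 or resid[:, j + 1].std() == 0:
                continue  # monomorphic locus
            r = abs(np.corrcoef(resid[:, j], resid[:, j + 1])[0, 1])
            (within if (j % 10) != 9 else between).append(r)
        assert np.mean(within) > np.mean(between) + 0.1


class TestSimulatePhenotypes:
    def test_zero_noise_pops_at_garden_equal(self):
        ds = yo.simulate_landscape(
            yo.LandscapeConfig(n_pops=5, n_ind_per_pop=4, n_snps=40, seed=3)
        )
        ref = ds.reference_climate
        # place every population exactly at the garden: use a constant table
        flat = yo.ClimateTable(ref.values * 0.0, "reference", "")
        obs = yo.simulate_phenotypes(ds.truth, flat, np.zeros(6), noise_sd=0.0, seed=1)
        growth = obs[obs["trait"] == "growth"]["value"]
        assert growth.nunique() == 1

    def test_garden_optimum_population_scores_highest(self):
        ds = yo.simulate_landscape(
            yo.LandscapeConfig(n_pops=8, n_ind_per_pop=4, n_snps=40, seed=4)
        )
        ref = ds.reference_climate
        driver = int(np.unique(ds.truth.driver_vars)[0])
        garden = ref.values.iloc[0].to_numpy()  # garden equals pop 1's climate
        obs = yo.simulate_phenotypes(ds.truth, ref, garden, noise_sd=0.0, seed=1)
        means = obs[obs["trait"] == "growth"].groupby("population")["value"].mean()
        dist = garden_climate_distance(ds.truth, ref, garden)
        assert means.idxmax() == dist.idxmin()

    def test_variance_decomposition_recovers_noise_sd(self):
        """Within-genotype variance estimates noise_sd^2 within 15% at n~500."""
        ds = yo.simulate_landscape(
            yo.LandscapeConfig(n_pops=10, n_ind_per_pop=4, n_snps=40, seed=6)
        )
        noise_sd = 0.4
        obs = yo.simulate_phenotypes(
            ds.truth, ds.reference_climate, np.zeros(6), n_clones=6, n_ramets=9,
            noise_sd=noise_sd, traits=("growth",), seed=8,
        )
        # method of moments: residual variance = within-genotype variance
        within = obs.groupby("genotype_id")["value"].var(ddof=1).mean()
        assert within == pytest.approx(noise_sd**2, rel=0.15)

    def test_n_clones_validated(self):
        ds = yo.simulate_landscape(
            yo.LandscapeConfig(n_pops=4, n_ind_per_pop=4, n_snps=40, seed=3)
        )
        with pytest.raises(ValueError):
            yo.simulate_phenotypes(ds.truth, ds.reference_climate, np.zeros(6),
                                   n_clones=0)


class TestWriteFixtures:
    def test_round_trip_allele_freqs(self, tmp_path):
        ds = yo.simulate_landscape(
            yo.LandscapeConfig(n_pops=5, n_ind_per_pop=6, n_snps=30,
                               missing_rate=0.1, seed=11)
        )
        paths = yo.write_fixtures(ds, tmp_path)
        g = yo.read_inputs(paths["vcf"], paths["popmap"])
        np.testing.assert_array_equal(g.calls, ds.genotypes.calls)
        orig = yo.population_allele_freqs(ds.genotypes)
        back = yo.population_allele_freqs(g)
        pd.testing.assert_frame_equal(orig.freqs, back.freqs)
        tables = yo.landscape.read_climate_tables(paths["climate"])
        pd.testing.assert_frame_equal(
            tables[""].values, ds.reference_climate.values, check_names=False
        )

    def test_vcf_parses_with_independent_reader(self, tmp_path):
        import pysam

        ds = yo.simulate_landscape(
            yo.LandscapeConfig(n_pops=3, n_ind_per_pop=4, n_snps=12, seed=12)
        )
        paths = yo.write_fixtures(ds, tmp_path)
        vf = pysam.VariantFile(str(paths["vcf"]))
        records = list(vf)
        assert len(records) == 12
        rec = records[0]
        sample0 = ds.genotypes.ind_meta["id"].iloc[0]
        code = ds.genotypes.calls[0, 0]
        gt = rec.samples[sample0]["GT"]
        expected = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}[int(code)]
        assert gt == expected

    def test_empty_population_set_errors(self, tmp_path):
        ds = yo.simulate_landscape(
            yo.LandscapeConfig(n_pops=3, n_ind_per_pop=4, n_snps=12, seed=12)
        )
        ds.genotypes.ind_meta = ds.genotypes.ind_meta.iloc[0:0]
        ds.genotypes.calls = ds.genotypes.calls[0:0]
        with pytest.raises(ValueError):
            yo.write_fixtures(ds, tmp_path)
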