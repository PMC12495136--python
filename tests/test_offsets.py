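"""Tests of genomic offsets, class aggregation, robustness flags and GDI."""

import numpy as np
import pandas as pd
import pytest

import yewoffset as yo
from yewoffset.climsel import ClimateTable
from yewoffset.gea import TurnoverFunction
from yewoffset.offsets import (
    aggregate_offsets,
    garden_offset,
    gdi_rda,
    gf_offset,
    minmax_normalize,
    quantile_classes,
    rda_offset,
    robustness_flags,
)
from yewoffset.ordination import RDA


def clim_table(arr, names=None, pops=None):
    arr = np.atleast_2d(np.asarray(arr, float))
    names = names or [f"v{j}" for j in range(arr.shape[1])]
    pops = pops or [f"P{i}" for i in range(arr.shape[0])]
    return ClimateTable(pd.DataFrame(arr, index=pops, columns=names))


@pytest.fixture()
def toy_model(rng):
    n = 10
    X = rng.normal(0, 1, (n, 2))
    Y = X @ rng.normal(0, 1, (2, 20)) + 0.1 * rng.normal(0, 1, (n, 20))
    ref = clim_table(X)
    return RDA(Y, ref.values).fit(), ref


class TestRdaOffset:
    def test_zero_when_climate_unchanged(self, toy_model):
        res, ref = toy_model
        off = rda_offset(res, ref, ref, K=2)
        np.testing.assert_allclose(off, 0, atol=1e-10)

    def test_linear_in_displacement(self, toy_model, rng):
        res, ref = toy_model
        delta = rng.normal(0, 1, ref.values.shape)
        fut1 = ClimateTable(ref.values + delta)
        fut2 = ClimateTable(ref.values + 2 * delta)
        o1, o2 = rda_offset(res, ref, fut1, K=2), rda_offset(res, ref, fut2, K=2)
        np.testing.assert_allclose(o2, 2 * o1, rtol=1e-8)

    def test_matches_explicit_projection_oracle(self, toy_model):
        res, ref = toy_model
        fut = ClimateTable(ref.values + 1.0)
        off = rda_offset(res, ref, fut, K=2)
        # hand-computed: standardize climates, project through B and axes,
        # weight by eigenvalue share, Euclidean distance
        Zr = (ref.values.to_numpy() - res.x_mean) / res.x_sd
        Zf = (fut.values.to_numpy() - res.x_mean) / res.x_sd
        proj = res.coefficients @ res.snp_loadings[:, :2]
        lam = res.eigenvalues[:2]
        w = lam / lam.sum()
        d = np.sqrt(((((Zr - Zf) @ proj) * w) ** 2).sum(axis=1))
        np.testing.assert_allclose(off.to_numpy(), d, atol=1e-10)

    def test_variable_mismatch_errors(self, toy_model):
        res, ref = toy_model
        bad = ClimateTable(ref.values.rename(columns={"v0": "other"}))
        with pytest.raises(ValueError, match="other"):
            rda_offset(res, ref, bad, K=2)


class TestGfOffset:
    def setup_method(self):
        self.turnover = {
            "v0": TurnoverFunction(np.array([0.0, 1.0]), np.array([0.2, 0.5])),
            "v1": TurnoverFunction(np.array([]), np.array([])),  # flat
        }

    def test_zero_without_climate_change(self):
        ref = clim_table([[0.5, 0.0], [1.5, 1.0]])
        np.testing.assert_allclose(gf_offset(self.turnover, ref, ref), 0)

    def test_flat_turnover_contributes_nothing(self):
        ref = clim_table([[0.5, -3.0]])
        fut = clim_table([[0.5, 7.0]])
        assert gf_offset(self.turnover, ref, fut).iloc[0] == 0.0

    def test_step_function_hand_evaluation(self):
        ref = clim_table([[-1.0, 0.0]])   # below first threshold -> 0
        fut = clim_table([[1.5, 0.0]])    # past both thresholds -> 0.5
        off = gf_offset(self.turnover, ref, fut)
        assert off.iloc[0] == pytest.approx(0.5)

    def test_missing_variable_errors(self):
        ref = clim_table([[0.0, 0.0, 0.0]], names=["v0", "v1", "v2"])
        with pytest.raises(ValueError, match="v2"):
            gf_offset(self.turnover, ref, ref)


class TestAggregation:
    def test_single_gcm_mean_is_raw(self, rng):
        raw = pd.DataFrame({"g1": rng.uniform(0, 1, 8)},
                           index=[f"P{i}" for i in range(8)])
        res = aggregate_offsets(raw)
        pd.testing.assert_series_equal(res.mean_raw, raw["g1"], check_names=False)

    def test_normalized_extremes(self, rng):
        raw = pd.DataFrame(rng.uniform(0, 1, (10, 3)),
                           index=[f"P{i}" for i in range(10)])
        res = aggregate_offsets(raw)
        assert res.normalized.min() == 0.0 and res.normalized.max() == 1.0
        assert res.normalized.idxmax() == res.mean_raw.idxmax()

    def test_29_populations_class_sizes(self, rng):
        x = rng.uniform(0, 1, 29)
        classes = quantile_classes(x, 5)
        sizes = sorted(np.bincount(classes)[1:], reverse=True)
        assert sizes == [6, 6, 6, 6, 5]
        # lowest offsets get class 1
        assert classes[np.argmin(x)] == 1
        assert classes[np.argmax(x)] == 5

    def test_all_equal_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out = minmax_normalize(np.full(5, 0.3))
        np.testing.assert_array_equal(out, 0)


class TestRobustness:
    def make(self, classes):
        pops = [f"P{i}" for i in range(len(classes))]
        res = aggregate_offsets(
            pd.DataFrame({"g": np.arange(len(classes), dtype=float)}, index=pops))
        res.classes = pd.Series(classes, index=pops)
        return res

    def test_class_difference_rule(self):
        a = self.make([1, 1, 3])
        b = self.make([1, 2, 1])
        flags = robustness_flags(a, b)
        # identical -> ok; |1-2|=1 -> still congruent; |3-1|=2 -> non-robust
        assert list(flags) == [False, False, True]

    def test_population_mismatch_errors(self):
        a = self.make([1, 2])
        b = self.make([1, 2, 3])
        with pytest.raises(ValueError):
            robustness_flags(a, b)


class TestGardenOffset:
    def test_population_at_garden_climate_has_zero_offset(self, toy_model):
        res, ref = toy_model
        garden = ref.values.iloc[3].to_numpy()
        off = garden_offset(res, ref, garden, K=2)
        assert off.iloc[3] == pytest.approx(0.0, abs=1e-10)
        assert (off.drop(off.index[3]) > 0).all()

    def test_substitution_identity_with_rda_offset(self, toy_model):
        res, ref = toy_model
        garden = np.array([0.7, -0.2])
        fut = ClimateTable(pd.DataFrame(
            np.tile(garden, (len(ref.populations), 1)),
            index=ref.populations, columns=ref.variables))
        np.testing.assert_allclose(
            garden_offset(res, ref, garden, K=2).to_numpy(),
            rda_offset(res, ref, fut, K=2).to_numpy(), atol=1e-12)


class TestGDI:
    def test_exactly_linear_response_gives_zero_raw(self, rng):
        n = 12
        X = rng.normal(0, 1, (n, 2))
        Y = X @ rng.normal(0, 1, (2, 30))  # exactly linear in climate
        res = RDA(Y, X).fit()
        gdi = gdi_rda(res, K=2)
        np.testing.assert_allclose(gdi.raw.to_numpy(), 0, atol=1e-8)

    def test_normalized_range(self, rda_results):
        gdi = gdi_rda(rda_results, K=2)
        assert gdi.normalized.min() == 0.0
        assert gdi.normalized.max() == 1.0
        assert (gdi.raw >= 0).all()

    def test_matches_score_projection_oracle(self, toy_model):
        res, ref = toy_model
        gdi = gdi_rda(res, K=2)
        Yc = res.model.Y - res.y_mean
        obs = Yc @ res.snp_loadings[:, :2]
        Z = (ref.values.to_numpy() - res.x_mean) / res.x_sd
        pred = Z @ res.coefficients @ res.snp_loadings[:, :2]
        w = res.eigenvalues[:2] / res.eigenvalues[:2].sum()
        d = np.sqrt((((obs - pred) * w) ** 2).sum(axis=1))
        np.testing.assert_allclose(gdi.raw.to_numpy(), d, atol=1e-10)

    def test_off_cline_population_gets_top_gdi(self):
        """A population whose adaptive frequencies follow a shuffled climate
        stands out as the maximum GDI."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(900 + seed)
            ds = yo.simulate_landscape(yo.LandscapeConfig(
                n_pops=20, n_ind_per_pop=12, n_snps=300, frac_adaptive=0.3,
                cline_slope=2.5, missing_rate=0.0, seed=900 + seed))
            truth = ds.truth
            freqs = yo.population_allele_freqs(ds.genotypes).freqs.copy()
            ref = ds.reference_climate
            victim = freqs.index[rng.integers(len(freqs))]
            # rewrite the victim's adaptive loci as if it sat elsewhere on the cline
            fake_env = ref.values.loc[victim].to_numpy() * -1.0
            for a, j in enumerate(truth.adaptive_loci):
                f = yo.adaptive_cline_freq(
                    fake_env[truth.driver_vars[a]],
                    truth.cline_intercepts[a], truth.cline_slopes[a])
                freqs.loc[victim, f"snp{j + 1}"] = f
            res = RDA(freqs, ref.values).fit()
            gdi = gdi_rda(res, K=2)
            hits += gdi.normalized.idxmax() == victim
        assert hits >= 0.8 * n_seeds
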