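"""Cross-covariance PLS, spatial surrogates, gene ranking/enrichment and
receptor correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, spearmanr

import gliomap as gm
from gliomap import synth
from gliomap.frequency import parcellate
from gliomap.spatial import (_variogram, gene_set_enrichment,
                             pls_cross_covariance, prepare_xy, rank_genes,
                             receptor_correlation, spatial_null_maps,
                             spin_pvalue)


@pytest.fixture(scope="module")
def world32(space32):
    field = synth.make_occurrence_field(space32, n_foci=3, autocorr_length=10,
                                        seed=1)
    freq = parcellate(field.intensity, space32)
    expr, planted = synth.make_expression(space32, freq, n_genes=300,
                                          n_assoc=20, effect=0.9, seed=2)
    x, y = prepare_xy(expr, freq)
    return {"space": space32, "freq": freq, "x": x, "y": np.asarray(y),
            "planted": planted}


class TestPrepareXY:
    def test_constant_frequency_rejected(self, space32, rng):
        expr, _ = synth.make_expression(space32, rng.random(60), 10, 0, 0.0,
                                        seed=0)
        with pytest.raises(gm.ValidationError):
            prepare_xy(expr, np.full(60, 0.25))

    def test_sqrt_inverts_squared_ramp(self, space32, rng):
        ramp = np.linspace(1, 4, 60)
        expr, _ = synth.make_expression(space32, ramp, 10, 0, 0.0, seed=0)
        _, y = prepare_xy(expr, ramp**2)
        z = (ramp - ramp.mean()) / ramp.std(ddof=1)
        assert np.allclose(y, z, atol=1e-12)

    def test_outputs_standardized(self, world32):
        x, y = world32["x"].to_numpy(), world32["y"]
        assert np.allclose(x.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(x.std(axis=0, ddof=1), 1, atol=1e-9)
        assert abs(y.mean()) < 1e-9 and abs(y.std(ddof=1) - 1) < 1e-9

    def test_missing_regions_dropped_pairwise(self, space32, rng):
        freq = rng.random(60)
        expr, _ = synth.make_expression(space32, freq, 10, 0, 0.0, seed=0)
        expr.iloc[3, 2] = np.nan
        x, y = prepare_xy(expr, freq)
        assert len(x) == 59 and len(y) == 59


class TestCrossCovariancePLS:
    def test_planted_identical_gene_dominates(self, rng):
        r = 60
        y = rng.normal(size=r)
        y = (y - y.mean()) / y.std(ddof=1)
        x = rng.normal(size=(r, 30))
        x -= np.outer(y, y @ x) / (y @ y)  # noise orthogonal to the response
        x[:, 7] = y
        res = pls_cross_covariance(pd.DataFrame(x), y)
        assert abs(res.gene_loadings.iloc[7, 0]) > 0.9

    def test_orthogonal_response_gives_zero_singular_values(self):
        r = 20
        x = np.zeros((r, 5))
        for j in range(5):
            x[:, j] = np.sin(2 * np.pi * (j + 1) * np.arange(r) / r)
        y = np.cos(2 * np.pi * 6 * np.arange(r) / r)  # orthogonal mode
        y = y - y.mean()
        res = pls_cross_covariance(pd.DataFrame(x), y)
        assert np.all(res.singular_values < 1e-10)

    def test_component1_is_normalized_cross_covariance(self, rng):
        for _ in range(50):
            r, g = 25, 12
            x = rng.normal(size=(r, g))
            y = rng.normal(size=r)
            c = x.T @ y / (r - 1)
            res = pls_cross_covariance(pd.DataFrame(x), y)
            u = res.gene_loadings.iloc[:, 0].to_numpy()
            sign = np.sign(u @ c)
            assert np.allclose(u * sign, c / np.linalg.norm(c), atol=1e-10)
            assert res.singular_values[0] == pytest.approx(
                np.linalg.norm(c), abs=1e-10)

    def test_multi_response_matches_dense_svd(self, rng):
        r = 30
        x = rng.normal(size=(r, 15))
        y = rng.normal(size=(r, 4))
        c = x.T @ y / (r - 1)
        s_dense = np.linalg.svd(c, compute_uv=False)
        res = pls_cross_covariance(pd.DataFrame(x), y)
        assert np.allclose(res.singular_values, s_dense, atol=1e-10)
        assert np.all(np.diff(res.singular_values) <= 1e-12)

    def test_squared_singular_values_sum_to_frobenius(self, rng):
        x = rng.normal(size=(40, 25))
        y = rng.normal(size=(40, 3))
        c = x.T @ y / 39
        res = pls_cross_covariance(pd.DataFrame(x), y)
        assert (res.singular_values**2).sum() == pytest.approx(
            (c**2).sum(), abs=1e-9)
        assert res.covariance_explained.sum() == pytest.approx(1.0)

    def test_loadings_unit_norm(self, world32):
        res = pls_cross_covariance(world32["x"], world32["y"])
        norms = np.linalg.norm(res.gene_loadings.to_numpy(), axis=0)
        assert np.allclose(norms, 1.0, atol=1e-12)


@pytest.fixture(scope="module")
def surrogates(world32):
    return spatial_null_maps(world32["y"], world32["space"].region_centroids,
                             n_null=200, seed=3)


class TestSpatialNullMaps:
    def test_moments_preserved(self, world32, surrogates):
        y = world32["y"]
        assert np.allclose(surrogates.mean(axis=1), y.mean(), atol=1e-9)
        assert np.allclose(surrogates.std(axis=1), y.std(), rtol=0.10)

    def test_surrogates_decorrelated_from_original(self, world32, surrogates):
        rhos = [abs(spearmanr(world32["y"], m).statistic) for m in surrogates]
        assert np.median(rhos) < 0.3

    def test_variogram_matched_within_quarter(self, world32, surrogates):
        y = world32["y"]
        cent = world32["space"].region_centroids
        d = np.linalg.norm(cent[:, None] - cent[None, :], axis=-1)
        iu = np.triu_indices(len(y), 1)
        edges = np.quantile(d[iu], np.linspace(0, 1, 6))
        bins = np.clip(np.searchsorted(edges, d[iu], side="right") - 1, 0, 4)
        v0 = _variogram(y, bins, iu, 5)
        errs = np.array([np.abs(_variogram(m, bins, iu, 5) - v0) / v0
                         for m in surrogates])
        assert np.all(np.median(errs, axis=0) < 0.25)

    def test_deterministic_given_seed(self, world32):
        cent = world32["space"].region_centroids
        a = spatial_null_maps(world32["y"], cent, n_null=100, seed=5)
        b = spatial_null_maps(world32["y"], cent, n_null=100, seed=5)
        assert np.array_equal(a, b)

    def test_degenerate_inputs_rejected(self, world32):
        cent = world32["space"].region_centroids
        with pytest.raises(gm.ValidationError):
            spatial_null_maps(np.ones(60), cent, n_null=100, seed=0)
        with pytest.raises(gm.ValidationError):
            spatial_null_maps(world32["y"], cent, n_null=50, seed=0)


class TestSpinPvalue:
    def test_extreme_observation_hits_p_floor(self, world32):
        # unstructured nulls cannot reach the planted effect's covariance
        res = pls_cross_covariance(world32["x"], world32["y"])
        nulls = np.random.default_rng(0).normal(size=(100, 60))
        out = spin_pvalue(res, world32["x"], nulls)
        assert out.spin_p[0] == pytest.approx(1 / 101)

    def test_self_null_counts_as_tie(self, world32):
        res = pls_cross_covariance(world32["x"], world32["y"])
        nulls = np.vstack([np.random.default_rng(0).normal(size=(99, 60)),
                           world32["y"][None, :]])
        out = spin_pvalue(res, world32["x"], nulls)
        assert out.spin_p[0] > 1 / 101

    def test_planted_effect_is_significant(self, world32):
        res = pls_cross_covariance(world32["x"], world32["y"])
        nulls = spatial_null_maps(world32["y"],
                                 world32["space"].region_centroids,
                                 n_null=200, seed=7)
        out = spin_pvalue(res, world32["x"], nulls)
        assert out.spin_p[0] < 0.05


class TestRankGenes:
    def test_planted_genes_rank_top(self, world32):
        res = pls_cross_covariance(world32["x"], world32["y"])
        order = list(rank_genes(res).index)
        ranks = [order.index(g) + 1 for g in world32["planted"]]
        assert np.median(ranks) <= 0.05 * len(order)

    def test_negating_response_reverses_ranking(self, world32):
        res_pos = pls_cross_covariance(world32["x"], world32["y"])
        res_neg = pls_cross_covariance(world32["x"], -world32["y"])
        up = rank_genes(res_pos)
        down = rank_genes(res_neg)
        assert list(up.index) == list(down.index[::-1])

    def test_component_out_of_range(self, world32):
        res = pls_cross_covariance(world32["x"], world32["y"])
        with pytest.raises(gm.ValidationError):
            rank_genes(res, component=5)


class TestGeneSetEnrichment:
    def test_planted_set_reaches_significance(self, world32):
        res = pls_cross_covariance(world32["x"], world32["y"])
        loadings = rank_genes(res)
        rng = np.random.default_rng(4)
        sets = {"planted": world32["planted"]}
        sets.update({f"R{i}": list(rng.choice(loadings.index, 20, False))
                     for i in range(10)})
        out = gene_set_enrichment(loadings, sets, n_perm=1000, seed=5)
        tab = out.table.set_index("name")
        assert tab.loc["planted", "q"] < 0.05
        assert np.all(tab["q"] >= tab["p"] - 1e-12)

    def test_degenerate_sets_skipped(self, world32):
        res = pls_cross_covariance(world32["x"], world32["y"])
        loadings = rank_genes(res)
        out = gene_set_enrichment(
            loadings,
            {"tiny": list(loadings.index[:3]),
             "everything": list(loadings.index)},
            n_perm=100, seed=0)
        assert set(out.skipped) == {"tiny", "everything"}
        assert len(out.table) == 0


class TestReceptorCorrelation:
    def test_identical_and_reversed_vectors(self, world32):
        cent = world32["space"].region_centroids
        y = world32["y"]
        rho, _ = receptor_correlation(y, y.copy(), cent, n_null=100, seed=0)
        assert rho == pytest.approx(1.0)
        ranks = rankdata(y)
        rho2, _ = receptor_correlation(y, -ranks, cent, n_null=100, seed=0)
        assert rho2 == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self, rng):
        for _ in range(100):
            a, b = rng.normal(size=30), rng.normal(size=30)
            rho = spearmanr(a, b).statistic
            brute = np.corrcoef(rankdata(a), rankdata(b))[0, 1]
            assert rho == pytest.approx(brute, abs=1e-12)

    def test_invariant_under_monotone_transforms(self, world32):
        cent = world32["space"].region_centroids
        y = world32["y"]
        rec = synth.make_receptor_map(y, 0.6, seed=1)
        rho1, p1 = receptor_correlation(y, rec, cent, n_null=100, seed=2)
        # transforming the receptor leaves both rho and the surrogate p fixed
        rho2, p2 = receptor_correlation(y, 3 * np.tanh(rec) + 1, cent,
                                        n_null=100, seed=2)
        assert rho1 == pytest.approx(rho2, abs=1e-12)
        assert p1 == p2
        # transforming the tumor map leaves rho fixed (ranks unchanged)
        rho3, _ = receptor_correlation(np.exp(y), rec, cent, n_null=100,
                                       seed=2)
        assert rho3 == pytest.approx(rho1, abs=1e-12)

    def test_constant_inputs_rejected(self, world32):
        cent = world32["space"].region_centroids
        with pytest.raises(gm.ValidationError):
            receptor_correlation(np.ones(60), world32["y"], cent,
                                 n_null=100, seed=0)
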