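import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cchepnet import (NetworkConfig, PhenotypeTable, SimulationConfig,
                      adjacency, build_network, cluster_and_cut,
                      me_group_tests, merge_close_modules, module_eigengenes,
                      module_trait_correlation, pick_soft_threshold,
                      simulate_dataset, tom_similarity)
from cchepnet.network import export_edge_list, scale_free_fit
from cchepnet.simulate import simulate_scale_free_expression


def adjusted_rand_index(a, b):
    """Pair-counting ARI, written out independently of sklearn."""
    from collections import Counter
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    joint = Counter(zip(a, b))
    ca, cb = Counter(a), Counter(b)
    sum_comb = sum(v * (v - 1) / 2 for v in joint.values())
    sum_a = sum(v * (v - 1) / 2 for v in ca.values())
    sum_b = sum(v * (v - 1) / 2 for v in cb.values())
    expected = sum_a * sum_b / (n * (n - 1) / 2)
    max_index = (sum_a + sum_b) / 2
    return (sum_comb - expected) / (max_index - expected)


class TestAdjacency:
    def test_arithmetic(self):
        # |-0.5|^5 on a constructed 2-gene correlation of exactly -0.5
        rng = np.random.default_rng(0)
        z = rng.standard_normal((2, 2000))
        x = np.vstack([z[0], -0.5 * z[0] / np.std(z[0])
                       + np.sqrt(0.75) * z[1] / np.std(z[1])])
        a = adjacency(x, 5)
        r = np.corrcoef(x)[0, 1]
        assert a[0, 1] == pytest.approx(abs(r) ** 5, abs=1e-14)
        assert abs(abs(r) ** 5 - 0.03125) < 0.01  # near |-.5|^5

    def test_beta_one_equals_absolute_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((10, 40))
        a = adjacency(x, 1)
        np.testing.assert_allclose(a - np.eye(10),
                                   np.abs(np.corrcoef(x)) - np.eye(10),
                                   atol=1e-12)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((30, 50))
        a = adjacency(x, 6)
        for i in range(30):
            for j in range(30):
                r = np.corrcoef(x[i], x[j])[0, 1]
                expected = 1.0 if i == j else abs(r) ** 6
                assert a[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_gene_rejected(self):
        x = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="constant"):
            adjacency(x, 2)


class TestTom:
    @staticmethod
    def brute_tom(a):
        n = a.shape[0]
        a = a.copy()
        np.fill_diagonal(a, 0.0)
        out = np.eye(n)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                ki = sum(a[i, u] for u in range(n) if u != i)
                kj = sum(a[j, u] for u in range(n) if u != j)
                out[i, j] = (l + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
        return out

    def test_two_gene_closed_form(self):
        a = np.array([[1.0, 0.4], [0.4, 1.0]])
        tom = tom_similarity(a)
        assert tom[0, 1] == pytest.approx(0.4)

    def test_complete_graph_saturates(self):
        tom = tom_similarity(np.ones((4, 4)))
        np.testing.assert_allclose(tom, 1.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(3)
        r = rng.random((20, 20))
        a = (r + r.T) / 2
        np.fill_diagonal(a, 1.0)
        np.testing.assert_allclose(tom_similarity(a), self.brute_tom(a),
                                   atol=1e-12)

    def test_invariants_hold_on_real_adjacency(self, small_sim):
        ds, _, _ = small_sim
        a = adjacency(ds, 5)
        tom = tom_similarity(a)
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(tom), 1.0)
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12
        # numerator dominance: TOM_ij >= a_ij / (min(k_i,k_j) + 1 - a_ij)
        a0 = a.copy()
        np.fill_diagonal(a0, 0.0)
        k = a0.sum(axis=1)
        kmin = np.minimum(k[:, None], k[None, :])
        lower = a0 / (kmin + 1 - a0)
        off = ~np.eye(a.shape[0], dtype=bool)
        assert np.all(tom[off] >= lower[off] - 1e-12)

    def test_asymmetric_input_rejected(self):
        a = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(a)


class TestScaleFreeFit:
    def test_power_law_connectivity_fits_perfectly(self):
        rng = np.random.default_rng(4)
        # k ~ pure power-law: Pareto sample
        k = (1 - rng.random(5000)) ** (-1 / 2.0)
        r2, slope = scale_free_fit(k)
        assert r2 > 0.95
        assert slope < 0

    def test_increasing_density_gets_negative_signed_r2(self):
        rng = np.random.default_rng(5)
        k = rng.random(3000) ** 0.4  # density increasing in k
        r2, slope = scale_free_fit(k)
        assert slope > 0
        assert r2 < 0

    def test_tied_connectivities_rejected(self):
        with pytest.raises(ValueError, match="bin"):
            scale_free_fit(np.ones(100))


class TestSoftThreshold:
    def test_lowest_crossing_power_chosen(self):
        x = simulate_scale_free_expression(300, 120, seed=6)
        table, beta = pick_soft_threshold(x)
        crossing = table.index[table["signed_r2"] >= 0.9]
        assert len(crossing) > 0
        assert beta == crossing[0]
        # mean connectivity strictly decreases with power
        assert np.all(np.diff(table["mean_k"].to_numpy()) < 0)

    def test_iid_noise_falls_back_with_warning(self, caplog):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((60, 25))
        with caplog.at_level("WARNING"):
            table, beta = pick_soft_threshold(
                x, NetworkConfig(powers=tuple(range(1, 8))))
        if (table["signed_r2"] >= 0.9).any():
            pytest.skip("noise instance crossed the target by chance")
        assert "falling back" in caplog.text
        assert beta == table["signed_r2"].idxmax()

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="20"):
            pick_soft_threshold(np.random.default_rng(0).standard_normal((5, 30)))


class TestClusterAndCut:
    def test_planted_blocks_recovered_noise_grey(self):
        lam = np.sqrt(0.7 / 0.3)  # within-block correlation 0.7
        cfg = SimulationConfig(
            n_genes=320, sigma2_strain=0, sigma2_diet=0, sigma2_interaction=0,
            sigma2_batch=0, sigma2_resid=1.0, module_sizes=(40, 40, 40),
            module_loading=lam, module_factor_strain_h2=0.0, seed=70)
        ds, _, truth = simulate_dataset(cfg)
        labels = cluster_and_cut(tom_similarity(adjacency(ds, 5)))
        true = truth.genes["module"].to_numpy()
        planted = true > 0
        assert adjusted_rand_index(true[planted], labels[planted]) >= 0.9
        assert (labels[~planted] == 0).mean() >= 0.95

    def test_single_homogeneous_block_is_one_module(self):
        rng = np.random.default_rng(8)
        f = rng.standard_normal(100)
        x = 1.5 * f[None, :] + rng.standard_normal((60, 100))
        labels = cluster_and_cut(tom_similarity(adjacency(x, 5)))
        assert set(labels) == {1}

    def test_iid_noise_mostly_grey(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((400, 132))
        labels = cluster_and_cut(tom_similarity(adjacency(x, 5)))
        assert (labels == 0).mean() >= 0.95

    def test_fewer_genes_than_min_size_all_grey(self, caplog):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((10, 30))
        with caplog.at_level("WARNING"):
            labels = cluster_and_cut(tom_similarity(adjacency(x, 5)))
        assert set(labels) == {0}

    def test_gene_order_permutation_permutes_labels(self):
        rng = np.random.default_rng(11)
        f = rng.standard_normal((2, 80))
        x = np.vstack([1.5 * f[0] + rng.standard_normal((30, 80)),
                       1.5 * f[1] + rng.standard_normal((30, 80)),
                       rng.standard_normal((60, 80))])
        tom = tom_similarity(adjacency(x, 5))
        labels = cluster_and_cut(tom)
        perm = rng.permutation(120)
        labels_p = cluster_and_cut(tom[np.ix_(perm, perm)])
        # same partition up to label names
        assert adjusted_rand_index(labels[perm], labels_p) == pytest.approx(1.0)

    def test_deterministic_across_reruns(self, small_sim):
        ds, _, _ = small_sim
        tom = tom_similarity(adjacency(ds, 5))
        a = cluster_and_cut(tom)
        b = cluster_and_cut(tom)
        np.testing.assert_array_equal(a, b)


class TestEigengenes:
    def test_identical_genes_fully_explained(self, small_sim):
        ds, _, _ = small_sim
        x = np.tile(ds.values[0][None, :], (5, 1))
        sub = ds.subset_features(range(5))
        sub.values[:] = x
        labels = np.ones(5, dtype=int)
        ms = module_eigengenes(sub, labels)
        assert ms.variance_explained[1] == pytest.approx(1.0)
        z = (x[0] - x[0].mean()) / x[0].std()
        me = ms.eigengenes["ME1"].to_numpy()
        assert abs(np.corrcoef(me, z)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(me, z)[0, 1] > 0  # orientation rule

    def test_planted_factor_recovered(self, small_sim):
        ds, _, truth = small_sim
        labels = truth.genes["module"].to_numpy()[:ds.n_features]
        ms = module_eigengenes(ds, labels)
        f1 = truth.factors["M1"].to_numpy()
        me1 = ms.eigengenes["ME1"].to_numpy()
        assert abs(np.corrcoef(me1, f1)[0, 1]) >= 0.95

    def test_sign_flip_of_members_flips_eigengene(self, small_sim):
        ds, _, truth = small_sim
        labels = truth.genes["module"].to_numpy()[:ds.n_features]
        ms = module_eigengenes(ds, labels)
        flipped = ds.subset_features(range(ds.n_features))
        flipped.values[labels == 1] *= -1
        ms2 = module_eigengenes(flipped, labels)
        np.testing.assert_allclose(ms2.eigengenes["ME1"],
                                   -ms.eigengenes["ME1"], atol=1e-8)

    def test_singleton_module_is_gene_zscore(self, small_sim):
        ds, _, _ = small_sim
        labels = np.zeros(ds.n_features, dtype=int)
        labels[3] = 1
        ms = module_eigengenes(ds, labels)
        me = ms.eigengenes["ME1"].to_numpy()
        zz = (ds.values[3] - ds.values[3].mean()) / ds.values[3].std()
        np.testing.assert_allclose(me, zz / np.linalg.norm(zz), atol=1e-12)


class TestMergeModules:
    def _dataset_with_labels(self, cor_between=0.99, seed=12):
        rng = np.random.default_rng(seed)
        f1 = rng.standard_normal(100)
        f2 = cor_between * f1 + np.sqrt(1 - cor_between**2) * \
            rng.standard_normal(100)
        x = np.vstack([3 * f1 + 0.3 * rng.standard_normal((25, 100)),
                       3 * f2 + 0.3 * rng.standard_normal((25, 100))])
        meta = pd.DataFrame({"strain": ["A", "B"] * 50, "diet": ["HP", "HS"] * 50,
                             "week": ["wk1"] * 100},
                            index=pd.Index([f"s{i}" for i in range(100)],
                                           name="sample_id"))
        from cchepnet.datamodel import ExpressionDataset
        ds = ExpressionDataset(x, [f"T{i}" for i in range(50)],
                               [f"G{i}" for i in range(50)],
                               list(meta.index), meta)
        labels = np.repeat([1, 2], 25)
        return ds, labels

    def test_highly_correlated_modules_merged(self):
        ds, labels = self._dataset_with_labels(cor_between=0.99)
        merged = merge_close_modules(ds, labels, cut_height=0.15)
        assert len(set(merged) - {0}) == 1

    def test_orthogonal_modules_unchanged(self):
        ds, labels = self._dataset_with_labels(cor_between=0.0)
        merged = merge_close_modules(ds, labels, cut_height=0.15)
        assert len(set(merged) - {0}) == 2

    def test_chain_merge_matches_stepwise_trace(self):
        """Three modules with ME correlations ~(0.95, 0.95) along a chain and
        a weaker end-to-end correlation: average linkage joins the chain
        below the cut, so all three merge."""
        rng = np.random.default_rng(13)
        f1 = rng.standard_normal(120)
        f2 = 0.95 * f1 + np.sqrt(1 - 0.95**2) * rng.standard_normal(120)
        f3 = 0.95 * f2 + np.sqrt(1 - 0.95**2) * rng.standard_normal(120)
        blocks = [4 * f + 0.2 * rng.standard_normal((20, 120))
                  for f in (f1, f2, f3)]
        x = np.vstack(blocks)
        meta = pd.DataFrame({"strain": ["A", "B"] * 60, "diet": ["HP", "HS"] * 60,
                             "week": ["wk1"] * 120},
                            index=pd.Index([f"s{i}" for i in range(120)],
                                           name="sample_id"))
        from cchepnet.datamodel import ExpressionDataset
        ds = ExpressionDataset(x, [f"T{i}" for i in range(60)],
                               [f"G{i}" for i in range(60)],
                               list(meta.index), meta)
        labels = np.repeat([1, 2, 3], 20)
        ms = module_eigengenes(ds, labels)
        me = ms.eigengenes.to_numpy().T
        d12 = 1 - np.corrcoef(me[0], me[1])[0, 1]
        d23 = 1 - np.corrcoef(me[1], me[2])[0, 1]
        assert d12 < 0.15 and d23 < 0.15  # chain links below the cut
        merged = merge_close_modules(ds, labels, cut_height=0.15)
        assert len(set(merged) - {0}) == 1


class TestModuleTraitStats:
    def test_driving_module_has_largest_correlation(self, small_sim):
        ds, ph, truth = small_sim
        labels = truth.genes["module"].to_numpy()[:ds.n_features]
        ms = module_eigengenes(ds, labels)
        tab = module_trait_correlation(ms, ph)
        bf = tab[tab["trait"] == "body_fat_pct"].set_index("module")
        assert bf["rho"].abs().idxmax() == "ME1"
        assert bf.loc["ME1", "p"] < 1e-4

    def test_rank_invariance_under_monotone_transform(self, small_sim):
        ds, ph, truth = small_sim
        labels = truth.genes["module"].to_numpy()[:ds.n_features]
        ms = module_eigengenes(ds, labels)
        warped = ph.data.copy()
        warped["body_fat_pct"] = np.exp(warped["body_fat_pct"] / 10.0)
        tab1 = module_trait_correlation(ms, ph)
        tab2 = module_trait_correlation(ms, PhenotypeTable(warped))
        a = tab1[tab1["trait"] == "body_fat_pct"]["rho"].to_numpy()
        b = tab2[tab2["trait"] == "body_fat_pct"]["rho"].to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_permuted_phenotype_nominal_rate(self, small_sim):
        ds, ph, truth = small_sim
        labels = truth.genes["module"].to_numpy()[:ds.n_features]
        ms = module_eigengenes(ds, labels)
        rng = np.random.default_rng(14)
        ps = []
        for _ in range(100):
            perm = ph.data.copy()
            perm["body_fat_pct"] = rng.permutation(
                perm["body_fat_pct"].to_numpy())
            tab = module_trait_correlation(ms, PhenotypeTable(perm))
            ps.extend(tab[tab["trait"] == "body_fat_pct"]["p"])
        assert abs(np.mean(np.asarray(ps) < 0.05) - 0.05) < 0.04

    def test_diet_and_strain_group_tests(self, small_sim):
        ds, _, truth = small_sim
        labels = truth.genes["module"].to_numpy()[:ds.n_features]
        ms = module_eigengenes(ds, labels)
        tab = me_group_tests(ms, ds.metadata).set_index("module")
        # module 1 has a planted diet shift on its factor; module 2 does not
        assert tab.loc["ME1", "p_diet"] < 0.01
        assert tab.loc["ME2", "p_diet"] > 0.01
        # both factors carry strain structure
        assert tab.loc["ME1", "p_strain"] < 0.01
        assert tab.loc["ME2", "p_strain"] < 0.01


def test_build_network_end_to_end(small_sim):
    ds, _, truth = small_sim
    res = build_network(ds, NetworkConfig(powers=tuple(range(1, 13))),
                        keep_tom=True)
    labels = res.module_set.labels
    true = truth.genes["module"].to_numpy()[:ds.n_features]
    planted = true > 0
    assert adjusted_rand_index(true[planted], labels[planted]) >= 0.9
    edges = export_edge_list(res.tom, ds.feature_ids, threshold=0.1)
    assert len(edges) == ds.n_features * (ds.n_features - 1) // 2
    assert (edges["above_threshold"] == (edges["tom"] >= 0.1)).all()
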