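"""Signed-hybrid adjacency, TOM, module detection, eigengenes, regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stresshypo import (
    CoexpressionNetwork,
    adjacency_signed_hybrid,
    detect_modules,
    eigengenes,
    hub_genes,
    me_group_regression,
    module_membership,
    pick_power,
    scale_free_fit,
    tom_similarity,
)


def _expr_from_corr(c, n=40, seed=0):
    """Gaussian expression with target gene-gene correlation matrix."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(c + 1e-10 * np.eye(len(c)))
    return L @ rng.standard_normal((len(c), n))


class TestAdjacency:
    def test_signed_hybrid_rules(self):
        c = np.array([[1.0, -0.6, 0.8], [-0.6, 1.0, -0.3], [0.8, -0.3, 1.0]])
        expr = _expr_from_corr(c, n=20000, seed=1)
        a = adjacency_signed_hybrid(expr, 2)
        assert a[0, 1] == 0.0  # negative correlation zeroed
        assert a[0, 2] == pytest.approx(0.64, abs=0.02)  # 0.8^2
        assert np.allclose(np.diag(a), 1.0)
        assert np.allclose(a, a.T)
        assert a.min() >= 0 and a.max() <= 1

    def test_perfect_correlation_any_power(self):
        x = np.vstack([np.arange(10.0), np.arange(10.0) * 3 + 1])
        a = adjacency_signed_hybrid(x, 7)
        assert a[0, 1] == pytest.approx(1.0)

    def test_constant_gene_rejected(self):
        x = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="constant"):
            adjacency_signed_hybrid(x, 2)

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(2)
        expr = rng.normal(size=(15, 12))
        a = adjacency_signed_hybrid(expr, 3)
        for i in range(15):
            for j in range(15):
                c = np.corrcoef(expr[i], expr[j])[0, 1]
                expected = 1.0 if i == j else (c**3 if c > 0 else 0.0)
                assert a[i, j] == pytest.approx(expected, abs=1e-10)


class TestTOM:
    def test_hand_computed_triangle(self):
        # a12=0.8, a13=0.4, a23=0 -> TOM_12 = 0.8/(min(1.2,0.8)+1-0.8) = 0.8
        a = np.array([[1.0, 0.8, 0.4], [0.8, 1.0, 0.0], [0.4, 0.0, 1.0]])
        tom = tom_similarity(a)
        assert tom[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_identity_adjacency_gives_zero_overlap(self):
        tom = tom_similarity(np.eye(5))
        assert np.allclose(tom - np.eye(5), 0.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(3)
        expr = rng.normal(size=(15, 10))
        a = adjacency_signed_hybrid(expr, 2)
        tom = tom_similarity(a)
        n = len(a)
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                ki = sum(a[i, u] for u in range(n) if u != i)
                kj = sum(a[j, u] for u in range(n) if u != j)
                expected = (shared + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-10)

    def test_symmetric_unit_range(self):
        rng = np.random.default_rng(4)
        a = adjacency_signed_hybrid(rng.normal(size=(20, 15)), 4)
        tom = tom_similarity(a)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1


class TestPowerScan:
    def test_mean_connectivity_decreases_in_power(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(1, 30))
        expr = 0.8 * base + 0.6 * rng.normal(size=(60, 30))
        ks = [scale_free_fit(expr, b)[1] for b in (2, 3, 4, 5)]
        assert all(np.diff(ks) < 0)

    def test_equal_connectivity_fit_undefined(self):
        # two perfectly correlated genes: one occupied bin
        x = np.vstack([np.arange(12.0), 2 * np.arange(12.0)])
        r2, _ = scale_free_fit(x, 2)
        assert np.isnan(r2)

    def test_paper_rule_picks_minimal_connectivity(self, monkeypatch):
        import stresshypo.network as net

        fits = {4: (0.62, 50.0), 6: (0.85, 20.0), 8: (0.88, 9.0)}
        monkeypatch.setattr(
            net, "scale_free_fit", lambda expr, b, n_bins=10: fits[b]
        )
        scan = net.pick_power(None, powers=(4, 6, 8), rule="paper")
        assert scan.selected == 8 and not scan.flagged
        scan = net.pick_power(None, powers=(4, 6, 8), rule="smallest")
        assert scan.selected == 6

    def test_fallback_flags_when_none_qualifies(self, monkeypatch):
        import stresshypo.network as net

        fits = {2: (0.5, 9.0), 4: (0.7, 5.0)}
        monkeypatch.setattr(net, "scale_free_fit", lambda e, b, n_bins=10: fits[b])
        scan = net.pick_power(None, powers=(2, 4))
        assert scan.selected == 4 and scan.flagged

    def test_modular_data_reaches_good_fit_somewhere(self, small_experiment):
        from stresshypo import filter_prevalence, normalize_median_of_ratios

        _, counts, _, _ = small_experiment
        expr = normalize_median_of_ratios(filter_prevalence(counts)).to_numpy()
        r2s = [scale_free_fit(expr, b)[0] for b in (4, 6, 8, 10, 12)]
        assert np.nanmax(r2s) > 0.8


class TestModules:
    def test_two_perfect_blocks_recovered(self):
        rng = np.random.default_rng(6)
        b1 = np.tile(rng.normal(size=(1, 30)), (40, 1)) + 1e-6 * rng.normal(size=(40, 30))
        b2 = np.tile(rng.normal(size=(1, 30)), (40, 1)) + 1e-6 * rng.normal(size=(40, 30))
        expr = np.vstack([b1, b2])
        tom = tom_similarity(adjacency_signed_hybrid(expr, 6))
        labels = detect_modules(tom, min_module_size=30)
        assert len(set(labels)) == 2
        assert len(set(labels[:40])) == 1 and len(set(labels[40:])) == 1
        assert labels[0] != labels[40]

    def test_oversized_min_module_size_all_background(self):
        rng = np.random.default_rng(7)
        tom = tom_similarity(adjacency_signed_hybrid(rng.normal(size=(20, 10)), 2))
        assert (detect_modules(tom, min_module_size=10**6) == 0).all()

    def test_labels_invariant_to_gene_order(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(2, 25))
        expr = np.vstack(
            [base[0] + 0.3 * rng.normal(size=(35, 25)),
             base[1] + 0.3 * rng.normal(size=(35, 25))]
        )
        tom = tom_similarity(adjacency_signed_hybrid(expr, 6))
        labels = detect_modules(tom, min_module_size=20)
        perm = rng.permutation(70)
        tom_p = tom[np.ix_(perm, perm)]
        labels_p = detect_modules(tom_p, min_module_size=20)
        # agreement up to label renaming
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels[perm], labels_p) == pytest.approx(1.0)

    def test_dynamic_tree_variant_recovers_blocks(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(3, 30))
        expr = np.vstack(
            [base[k] + 0.4 * rng.normal(size=(30, 30)) for k in range(3)]
        )
        tom = tom_similarity(adjacency_signed_hybrid(expr, 6))
        labels = detect_modules(tom, min_module_size=20, method="dynamic_tree")
        from sklearn.metrics import adjusted_rand_score

        truth = np.repeat([1, 2, 3], 30)
        assert adjusted_rand_score(truth, labels) > 0.9


class TestEigengenes:
    def test_single_gene_module_is_standardized_gene(self):
        rng = np.random.default_rng(10)
        expr = rng.normal(size=(3, 20))
        labels = np.array([1, 0, 0])
        mes, varexp = eigengenes(expr, labels)
        z = (expr[0] - expr[0].mean()) / expr[0].std(ddof=1)
        np.testing.assert_allclose(mes["ME1"].to_numpy(), z, rtol=1e-9)
        assert varexp[1] == pytest.approx(1.0)

    def test_identical_genes_full_variance_explained(self):
        rng = np.random.default_rng(11)
        g = rng.normal(size=20)
        expr = np.tile(g, (5, 1))
        _, varexp = eigengenes(expr, np.ones(5, dtype=int))
        assert varexp[1] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(12)
        expr = rng.normal(size=(20, 15))
        labels = np.ones(20, dtype=int)
        mes, varexp = eigengenes(expr, labels)
        z = (expr - expr.mean(1, keepdims=True)) / expr.std(1, ddof=1, keepdims=True)
        evals, evecs = np.linalg.eigh(z.T @ z)
        pc1 = evecs[:, -1]
        pc1 /= pc1.std(ddof=1)
        me = mes["ME1"].to_numpy()
        assert abs(np.corrcoef(me, pc1)[0, 1]) == pytest.approx(1.0, abs=1e-9)
        assert me.std(ddof=1) == pytest.approx(1.0)
        assert varexp[1] == pytest.approx(evals[-1] / evals.sum(), rel=1e-9)

    def test_sign_oriented_toward_members(self):
        rng = np.random.default_rng(13)
        base = rng.normal(size=30)
        expr = np.vstack([base + 0.1 * rng.normal(size=30) for _ in range(10)])
        mes, _ = eigengenes(expr, np.ones(10, dtype=int))
        cors = [np.corrcoef(expr[i], mes["ME1"])[0, 1] for i in range(10)]
        assert np.mean(cors) > 0.9


class TestMembership:
    def test_own_module_single_gene_kme_one(self):
        rng = np.random.default_rng(14)
        expr = rng.normal(size=(2, 20))
        labels = np.array([1, 0])
        mes, _ = eigengenes(expr, labels)
        kme = module_membership(expr, mes)
        assert kme.iloc[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_anticorrelated_gene_kme_minus_one(self):
        rng = np.random.default_rng(15)
        g = rng.normal(size=20)
        expr = np.vstack([g, -g])
        mes, _ = eigengenes(expr, np.array([1, 0]))
        kme = module_membership(expr, mes)
        assert kme.iloc[1, 0] == pytest.approx(-1.0, abs=1e-9)

    def test_matches_direct_correlation_oracle(self):
        rng = np.random.default_rng(16)
        expr = rng.normal(size=(12, 18))
        labels = np.r_[np.ones(6, int), np.full(6, 2)]
        mes, _ = eigengenes(expr, labels)
        kme = module_membership(expr, mes)
        for i in range(12):
            for m in (1, 2):
                expected = np.corrcoef(expr[i], mes[f"ME{m}"])[0, 1]
                assert kme.iloc[i][f"ME{m}"] == pytest.approx(expected, abs=1e-10)


class TestGroupRegression:
    GROUP = np.r_[np.zeros(10), np.ones(10)]

    def test_identical_groups_zero_coefficient(self):
        me = pd.DataFrame({"ME1": np.tile(np.arange(10.0), 2)})
        res = me_group_regression(me, self.GROUP)
        assert res.loc["ME1", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_b_is_mean_difference_and_t_is_pooled_t(self):
        rng = np.random.default_rng(17)
        y = rng.normal(size=20)
        res = me_group_regression(pd.DataFrame({"ME1": y}), self.GROUP)
        assert res.loc["ME1", "b"] == pytest.approx(y[10:].mean() - y[:10].mean())
        from scipy import stats

        t_ref = stats.ttest_ind(y[10:], y[:10]).statistic
        assert res.loc["ME1", "b"] / res.loc["ME1", "SE"] == pytest.approx(t_ref, rel=1e-9)

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(18)
        y = rng.normal(size=20)
        res = me_group_regression(pd.DataFrame({"ME1": y}), self.GROUP)
        ref = sm.OLS(y, sm.add_constant(self.GROUP)).fit()
        assert res.loc["ME1", "b"] == pytest.approx(ref.params[1], rel=1e-10)
        assert res.loc["ME1", "SE"] == pytest.approx(ref.bse[1], rel=1e-10)
        assert res.loc["ME1", "p"] == pytest.approx(ref.pvalues[1], rel=1e-9)


class TestHubs:
    def test_small_module_returns_all_members_in_order(self):
        kme = pd.DataFrame({"ME1": [0.9, -0.95, 0.5]}, index=["a", "b", "c"])
        hubs = hub_genes(kme, np.ones(3, dtype=int), top_n=5)
        assert hubs[1] == ["b", "a", "c"]

    def test_gene_equal_to_me_ranks_first(self):
        rng = np.random.default_rng(19)
        base = rng.normal(size=25)
        expr = np.vstack([base] + [base + rng.normal(size=25) for _ in range(9)])
        labels = np.ones(10, dtype=int)
        mes, _ = eigengenes(expr, labels)
        kme = module_membership(
            pd.DataFrame(expr, index=[f"g{i}" for i in range(10)]), mes
        )
        hubs = hub_genes(kme, labels, top_n=3)
        assert hubs[1][0] == "g0"

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(8)]
        kme = pd.DataFrame({"ME1": rng.uniform(-1, 1, 8)}, index=genes)
        hubs = hub_genes(kme, np.ones(8, dtype=int), top_n=4)
        oracle = sorted(genes, key=lambda g: (-abs(kme.loc[g, "ME1"]), g))[:4]
        assert hubs[1] == oracle


class TestModelSurface:
    def test_fit_produces_consistent_results(self, small_experiment):
        from stresshypo import filter_prevalence, normalize_median_of_ratios

        _, counts, sheet, _ = small_experiment
        expr = normalize_median_of_ratios(filter_prevalence(counts))
        group = (sheet.loc[counts.sample_ids, "group"] == "Stressed").astype(int)
        res = CoexpressionNetwork(expr, group=group.to_numpy()).fit(min_module_size=20)
        assert res.n_modules >= 2
        # each assigned gene has defined kME with its own module
        for m in sorted(set(res.labels) - {0}):
            members = res.labels.index[res.labels == m]
            assert res.kme.loc[members, f"ME{m}"].notna().all()
        # MEs are unit variance
        np.testing.assert_allclose(
            res.eigengenes.std(ddof=1).to_numpy(), 1.0, rtol=1e-9
        )
        assert set(res.group_regression.index) == set(res.eigengenes.columns)
        assert "Signed-hybrid" in res.summary()
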