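"""Network construction: oracle equivalence, limits, and planted-structure recovery."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from radnet import network, synthetic


def frame(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )


def brute_force_tom(a):
    n = a.shape[0]
    w = np.empty_like(a)
    k = a.sum(axis=0)
    for i in range(n):
        for j in range(n):
            if i == j:
                w[i, j] = 1.0
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n))
            w[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return w


def random_adjacency(n, rng):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


class TestAdjacency:
    def test_identical_genes_at_beta_one(self):
        m = frame([[1, 2, 3, 4], [1, 2, 3, 4]])
        a = network.adjacency(m, 1)
        assert a.iloc[0, 1] == pytest.approx(1.0)

    def test_matches_elementwise_oracle(self, rng):
        m = frame(rng.standard_normal((10, 15)))
        a = network.adjacency(m, 6).to_numpy()
        oracle = np.abs(np.corrcoef(m.to_numpy())) ** 6
        np.fill_diagonal(oracle, 0.0)
        assert np.allclose(a, oracle, atol=1e-12)

    def test_signed_variant(self, rng):
        m = frame(rng.standard_normal((6, 12)))
        a = network.adjacency(m, 2, signed=True).to_numpy()
        oracle = ((1 + np.corrcoef(m.to_numpy())) / 2) ** 2
        np.fill_diagonal(oracle, 0.0)
        assert np.allclose(a, oracle, atol=1e-12)

    def test_independent_genes_near_zero_with_many_samples(self, rng):
        m = frame(rng.standard_normal((5, 1000)))
        a = network.adjacency(m, 6).to_numpy()
        assert a.max() < 1e-3

    def test_zero_variance_gene_named_in_error(self):
        m = frame([[1, 1, 1], [1, 2, 3]])
        with pytest.raises(ValueError, match="g0"):
            network.adjacency(m, 6)


class TestTom:
    def test_complete_graph_has_unit_overlap(self):
        a = np.ones((5, 5)) - np.eye(5)
        w = network.tom(pd.DataFrame(a)).to_numpy()
        assert np.allclose(w, 1.0)

    def test_empty_graph_has_zero_overlap(self):
        w = network.tom(pd.DataFrame(np.zeros((4, 4)))).to_numpy()
        assert np.allclose(w - np.eye(4), 0.0)

    def test_matches_brute_force_oracle(self, rng):
        a = random_adjacency(10, rng)
        w = network.tom(pd.DataFrame(a)).to_numpy()
        assert np.allclose(w, brute_force_tom(a), atol=1e-12)

    def test_output_symmetric_unit_diagonal_in_unit_interval(self, rng):
        for _ in range(5):
            a = random_adjacency(12, rng)
            w = network.tom(pd.DataFrame(a)).to_numpy()
            assert np.allclose(w, w.T)
            assert np.allclose(np.diag(w), 1.0)
            assert w.min() >= 0.0 and w.max() <= 1.0 + 1e-12

    def test_asymmetric_input_rejected(self, rng):
        a = rng.uniform(size=(4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            network.tom(pd.DataFrame(a))


class TestSoftThreshold:
    def test_mean_connectivity_decreasing_in_beta(self, cohort40):
        with pytest.warns(UserWarning, match="argmax"):  # restricted grid: falls back
            res = network.soft_threshold_select(cohort40.expression, powers=[2, 4, 6, 8])
        ks = [res.mean_connectivity[b] for b in (2, 4, 6, 8)]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_planted_power_law_connectivity_fits_well(self, rng):
        # k drawn from an exact discrete power law p(k) ~ k^-2.5
        support = np.arange(1, 16, dtype=float)
        p = support**-2.5
        k = rng.choice(support, size=20000, p=p / p.sum())
        k = k + rng.uniform(0, 1e-6, size=k.size)  # distinct values for binning
        assert network.scale_free_fit(k) >= 0.95

    def test_uniform_connectivity_fits_poorly(self, rng):
        k = rng.uniform(1, 2, size=2000)
        assert network.scale_free_fit(k) < 0.8

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            network.scale_free_fit(np.array([1.0, 2.0, 3.0] * 10))

    def test_recommended_power_table(self):
        assert network.recommended_power(10) == 9
        assert network.recommended_power(25) == 8
        assert network.recommended_power(40) == 7
        assert network.recommended_power(100) == 6
        assert network.recommended_power(40, signed=True) == 14


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self):
        expr, truth = synthetic.generate_expression(
            n_genes=50, n_samples=100, module_sizes=(25, 25), intra_cor=0.9, seed=4
        )
        w = network.tom(network.adjacency(expr, 6))
        part = network.detect_modules(1 - w, min_module_size=5, expression=expr)
        assert adjusted_rand_score(truth.module_labels, part) == pytest.approx(1.0)

    def test_pure_noise_with_huge_min_size_all_unassigned(self, rng):
        expr = frame(rng.standard_normal((30, 20)))
        w = network.tom(network.adjacency(expr, 6))
        part = network.detect_modules(1 - w, min_module_size=30)
        assert (part == 0).all()

    def test_gene_order_permutation_consistent(self, rng):
        expr, _ = synthetic.generate_expression(
            n_genes=40, n_samples=40, module_sizes=(15, 15), intra_cor=0.8, seed=6
        )
        w = network.tom(network.adjacency(expr, 6))
        part = network.detect_modules(1 - w, min_module_size=5, expression=expr)
        perm = rng.permutation(len(expr))
        expr_p = expr.iloc[perm]
        w_p = network.tom(network.adjacency(expr_p, 6))
        part_p = network.detect_modules(1 - w_p, min_module_size=5, expression=expr_p)
        assert adjusted_rand_score(part.loc[expr_p.index], part_p) == pytest.approx(1.0)

    def test_min_module_size_validated(self, rng):
        with pytest.raises(ValueError, match="min_module_size"):
            network.detect_modules(pd.DataFrame(np.zeros((3, 3))), min_module_size=1)

    def test_labels_contiguous_sorted_by_size(self, cohort40):
        w = network.tom(network.adjacency(cohort40.expression, 7))
        part = network.detect_modules(1 - w, expression=cohort40.expression)
        labels = sorted(set(part) - {0})
        assert labels == list(range(1, len(labels) + 1))
        sizes = [int((part == m).sum()) for m in labels]
        assert sizes == sorted(sizes, reverse=True)


class TestEigengene:
    def test_identical_profiles_recovered(self):
        profile = np.array([1.0, -2.0, 0.5, 3.0, -1.0, 0.2])
        expr = frame(np.tile(profile, (4, 1)))
        part = pd.Series([1] * 4, index=expr.index)
        eig = network.module_eigengene(expr, part)
        zed = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.allclose(eig.loc[1].to_numpy(), zed, atol=1e-10)

    def test_module_duplication_leaves_eigengene_unchanged(self, rng):
        expr, _ = synthetic.generate_expression(
            n_genes=10, n_samples=20, module_sizes=(10,), intra_cor=0.7, seed=8
        )
        part = pd.Series([1] * 10, index=expr.index)
        eig = network.module_eigengene(expr, part)
        dup = pd.concat([expr, expr.rename(index=lambda g: f"{g}_dup")])
        eig_dup = network.module_eigengene(dup, pd.Series([1] * 20, index=dup.index))
        assert np.allclose(eig.loc[1], eig_dup.loc[1], atol=1e-8)

    def test_planted_factor_recovered(self):
        expr, truth = synthetic.generate_expression(
            n_genes=50, n_samples=40, module_sizes=(50,), intra_cor=0.64, seed=11
        )
        part = truth.module_labels
        eig = network.module_eigengene(expr, part)
        r = np.corrcoef(eig.loc[1], truth.factors.loc[1])[0, 1]
        assert r >= 0.9  # sign convention orients along the mean profile

    def test_sign_convention_positive_against_mean_profile(self, cohort40):
        part = cohort40.truth.module_labels
        eig = network.module_eigengene(cohort40.expression, part)
        for m in eig.index:
            sub = cohort40.expression.loc[part[part == m].index]
            zed = ((sub.T - sub.mean(axis=1)) / sub.std(axis=1, ddof=1)).T
            r = np.corrcoef(eig.loc[m], zed.mean(axis=0))[0, 1]
            assert r > 0


class TestKme:
    def test_gene_equal_to_eigengene_has_unit_kme(self, cohort40):
        part = cohort40.truth.module_labels
        eig = network.module_eigengene(cohort40.expression, part)
        expr = pd.concat(
            [cohort40.expression, pd.DataFrame([eig.loc[1], -eig.loc[1]], index=["pos", "neg"])]
        )
        k = network.kme(expr, eig)
        assert k.loc["pos", 1] == pytest.approx(1.0)
        assert k.loc["neg", 1] == pytest.approx(-1.0)

    def test_matches_direct_correlation_oracle(self, rng):
        expr = frame(rng.standard_normal((20, 15)))
        eig = frame(rng.standard_normal((3, 15)), prefix="m")
        eig.index = [1, 2, 3]
        k = network.kme(expr, eig)
        for g in expr.index:
            for m in eig.index:
                oracle = np.corrcoef(expr.loc[g], eig.loc[m])[0, 1]
                assert k.loc[g, m] == pytest.approx(oracle, abs=1e-12)

    def test_own_module_kme_dominates(self, cohort40):
        part = cohort40.truth.module_labels
        eig = network.module_eigengene(cohort40.expression, part)
        k = network.kme(cohort40.expression, eig).abs()
        assigned = part[part > 0]
        own_highest = sum(
            k.loc[g].idxmax() == m for g, m in assigned.items()
        )
        assert own_highest / len(assigned) >= 0.95


class TestModuleTrait:
    def test_trait_equal_to_eigengene(self, cohort40):
        part = cohort40.truth.module_labels
        eig = network.module_eigengene(cohort40.expression, part)
        traits = pd.DataFrame({"T": eig.loc[1]}, index=eig.columns)
        table = network.module_trait_correlation(eig, traits)
        row = table[(table.module == 1) & (table.trait == "T")].iloc[0]
        assert row.r == pytest.approx(1.0) and row.p == pytest.approx(0.0, abs=1e-30)

    def test_planted_link_attains_max_correlation(self, cohort40):
        part = cohort40.truth.module_labels
        eig = network.module_eigengene(cohort40.expression, part)
        table = network.module_trait_correlation(eig, cohort40.traits[["MD", "FA"]])
        md_module = cohort40.truth.trait_module_links["MD"][0]
        sub = table[table.trait == "MD"]
        assert int(sub.loc[sub.r.abs().idxmax(), "module"]) == md_module

    def test_too_few_samples_rejected(self, rng):
        eig = frame(rng.standard_normal((2, 3)), prefix="m")
        traits = pd.DataFrame({"T": [1.0, 2, 3]}, index=eig.columns)
        with pytest.raises(ValueError, match="4 shared samples"):
            network.module_trait_correlation(eig, traits)


class TestExportAndHubs:
    def test_threshold_one_empty_threshold_zero_complete(self, rng):
        a = random_adjacency(8, rng) * 0.5
        w = network.tom(pd.DataFrame(a))
        part = pd.Series([1] * 8)
        edges_hi, _ = network.export_network(w, part, 1.0)
        edges_lo, _ = network.export_network(w, part, 0.0)
        assert len(edges_hi) == 0
        assert len(edges_lo) == 8 * 7 // 2

    def test_edge_set_matches_filter_oracle(self, rng):
        a = random_adjacency(10, rng)
        w = network.tom(pd.DataFrame(a))
        part = pd.Series(rng.integers(1, 3, size=10))
        edges, nodes = network.export_network(w, part, 0.2)
        wv = w.to_numpy()
        oracle = {(i, j) for i in range(10) for j in range(i + 1, 10) if wv[i, j] >= 0.2}
        got = {(int(r.fromNode), int(r.toNode)) for r in edges.itertuples()}
        assert got == oracle
        # intramodular connectivity oracle
        for idx, row in nodes.iterrows():
            same = [j for j in range(10) if part[j] == row.module and j != idx]
            assert row.intramodularConnectivity == pytest.approx(sum(wv[idx, j] for j in same))

    def test_hub_ranking_with_lexicographic_ties(self):
        k = pd.DataFrame({1: [0.9, 0.5, 0.7]}, index=["a", "b", "c"])
        part = pd.Series([1, 1, 1], index=["a", "b", "c"])
        top = network.hub_genes(k, part, 1, 2)
        assert list(top.index) == ["a", "c"]
        assert list(network.hub_genes(k, part, 1, 0).index) == []

    def test_oversized_top_n_warns_and_returns_all(self):
        k = pd.DataFrame({1: [0.9, 0.5]}, index=["a", "b"])
        part = pd.Series([1, 1], index=["a", "b"])
        with pytest.warns(UserWarning, match="module size"):
            top = network.hub_genes(k, part, 1, 10)
        assert len(top) == 2
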