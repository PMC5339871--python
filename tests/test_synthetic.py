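"""Planted-structure generator: determinism and calibration of every planted effect."""

import numpy as np
import pandas as pd
import pytest

from radnet import gsea, survival, synthetic


def upper_triangle_correlations(matrix):
    c = np.corrcoef(matrix)
    return c[np.triu_indices(matrix.shape[0], k=1)]


class TestGenerateExpression:
    def test_deterministic_given_seed(self):
        a, _ = synthetic.generate_expression(n_genes=60, n_samples=10, module_sizes=(20,), seed=7)
        b, _ = synthetic.generate_expression(n_genes=60, n_samples=10, module_sizes=(20,), seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_intra_cor_one_gives_identical_members(self):
        expr, truth = synthetic.generate_expression(
            n_genes=30, n_samples=8, module_sizes=(10,), intra_cor=1.0, seed=0
        )
        members = expr.loc[truth.module_labels[truth.module_labels == 1].index]
        r = upper_triangle_correlations(members.to_numpy())
        assert np.allclose(np.abs(r), 1.0, atol=1e-12)

    def test_intra_cor_zero_gives_uncorrelated_members(self):
        rs = []
        for seed in range(5):
            expr, truth = synthetic.generate_expression(
                n_genes=60, n_samples=100, module_sizes=(50,), intra_cor=0.0, seed=seed
            )
            members = expr.loc[truth.module_labels[truth.module_labels == 1].index]
            rs.append(np.abs(upper_triangle_correlations(members.to_numpy())).mean())
        assert np.mean(rs) < 0.1

    def test_within_module_correlation_near_intra_cor(self):
        # expectation E[cor] = intra_cor; simulation band from the spec'd conditions
        expr, truth = synthetic.generate_expression(
            n_genes=500, n_samples=40, module_sizes=(50, 50), intra_cor=0.64, seed=1
        )
        members = expr.loc[truth.module_labels[truth.module_labels == 1].index]
        mean_r = upper_triangle_correlations(members.to_numpy()).mean()
        assert 0.54 <= mean_r <= 0.74

    def test_convergence_to_intra_cor_at_large_n(self):
        expr, truth = synthetic.generate_expression(
            n_genes=100, n_samples=200, module_sizes=(50,), intra_cor=0.5, seed=3
        )
        members = expr.loc[truth.module_labels[truth.module_labels == 1].index]
        assert upper_triangle_correlations(members.to_numpy()).mean() == pytest.approx(0.5, abs=0.05)

    def test_mixed_sign_loadings_preserve_absolute_correlation(self):
        expr, truth = synthetic.generate_expression(
            n_genes=100, n_samples=200, module_sizes=(40,), intra_cor=0.6, neg_fraction=0.5, seed=2
        )
        members = expr.loc[truth.module_labels[truth.module_labels == 1].index]
        r = upper_triangle_correlations(members.to_numpy())
        assert np.abs(r).mean() == pytest.approx(0.6, abs=0.06)
        assert (truth.loadings == -1).sum() == 20

    def test_oversized_modules_rejected(self):
        with pytest.raises(ValueError, match="module sizes"):
            synthetic.generate_expression(n_genes=10, n_samples=5, module_sizes=(6, 6))

    def test_invalid_intra_cor_rejected(self):
        with pytest.raises(ValueError, match="intra_cor"):
            synthetic.generate_expression(n_genes=10, n_samples=5, module_sizes=(5,), intra_cor=1.2)


class TestGenerateTraits:
    def test_default_link_is_exact(self):
        _, truth = synthetic.generate_expression(n_genes=40, n_samples=30, module_sizes=(10, 10), seed=5)
        traits = synthetic.generate_traits(truth, seed=9)
        f_md = truth.factors.loc[1]
        f_fa = truth.factors.loc[2]
        assert np.corrcoef(traits["MD"], f_md)[0, 1] == pytest.approx(0.8, abs=1e-10)
        assert np.corrcoef(traits["FA"], f_fa)[0, 1] == pytest.approx(0.8, abs=1e-10)

    def test_zero_noise_zero_jitter_gives_perfect_collinearity(self):
        _, truth = synthetic.generate_expression(n_genes=40, n_samples=20, module_sizes=(10, 10), seed=2)
        traits = synthetic.generate_traits(truth, noise_sd=0.0, jitter_sd=0.0, link_cor=1.0, seed=1)
        c = traits[["AD", "RD", "MD"]].corr().to_numpy()
        assert np.allclose(c, 1.0, atol=1e-12)
        assert np.corrcoef(traits["MD"], truth.factors.loc[1])[0, 1] == pytest.approx(1.0)

    def test_default_jitter_keeps_diffusivities_collinear(self, cohort40):
        c = cohort40.traits[["AD", "RD", "MD"]].corr().to_numpy()
        assert c[np.triu_indices(3, 1)].min() > 0.95

    def test_fa_independent_of_md_module(self, cohort40):
        r = np.corrcoef(cohort40.traits["FA"], cohort40.truth.factors.loc[1])[0, 1]
        assert abs(r) < 0.5

    def test_fa_within_unit_interval(self, cohort40):
        assert cohort40.traits["FA"].between(0, 1).all()

    def test_same_module_for_md_and_fa_rejected(self):
        _, truth = synthetic.generate_expression(n_genes=40, n_samples=20, module_sizes=(10, 10), seed=2)
        with pytest.raises(ValueError, match="distinct"):
            synthetic.generate_traits(truth, md_module=1, fa_module=1)


class TestGenerateSurvival:
    def test_no_censoring_all_events(self, rng):
        trait = pd.Series(rng.standard_normal(30))
        data = synthetic.generate_survival(trait, censor_rate=0.0, seed=4)
        assert (data["event"] == 1).all()
        assert (data["time"] > 0).all()

    def test_censor_rate_approximately_achieved(self, rng):
        trait = pd.Series(rng.standard_normal(2000))
        data = synthetic.generate_survival(trait, log_hr_per_sd=0.0, censor_rate=0.3, seed=8)
        assert (1 - data["event"].mean()) == pytest.approx(0.3, abs=0.05)

    def test_deterministic_given_seed(self, rng):
        trait = pd.Series(rng.standard_normal(25))
        a = synthetic.generate_survival(trait, censor_rate=0.2, seed=3)
        b = synthetic.generate_survival(trait, censor_rate=0.2, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_log_hazard_recovered_by_cox(self, rng):
        trait = pd.Series(rng.standard_normal(40))
        z = (trait - trait.mean()) / trait.std()
        hits = 0
        for seed in range(50):
            data = synthetic.generate_survival(trait, log_hr_per_sd=np.log(4), censor_rate=0.0, seed=seed)
            fit = survival.cox_fit(data, z)
            hits += abs(fit.log_hr - np.log(4)) <= 0.5
        assert hits >= 40

    def test_nonfinite_trait_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            synthetic.generate_survival(pd.Series([1.0, np.inf, 2.0]))


class TestGenerateGeneSets:
    def test_planted_sets_match_module_membership(self, cohort40):
        truth = cohort40.truth
        for m, genes in truth.module_genes.items():
            assert cohort40.gene_sets.sets[f"planted_module_{m}"] == genes
        assert truth.enriched_sets == [f"planted_module_{m}" for m in truth.module_genes]

    def test_no_decoys_gives_one_set_per_module(self):
        _, truth = synthetic.generate_expression(n_genes=40, n_samples=10, module_sizes=(10, 10), seed=1)
        sets = synthetic.generate_gene_sets(truth, n_decoy=0, decoy_size=5, seed=0)
        assert len(sets) == 2

    def test_gmt_serialisation_deterministic(self, tmp_path):
        _, truth = synthetic.generate_expression(n_genes=40, n_samples=10, module_sizes=(10,), seed=1)
        paths = []
        for run in range(2):
            sets = synthetic.generate_gene_sets(truth, n_decoy=3, decoy_size=8, seed=42)
            p = tmp_path / f"sets{run}.gmt"
            gsea.write_gmt(sets, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_oversized_decoys_rejected(self):
        _, truth = synthetic.generate_expression(n_genes=20, n_samples=10, module_sizes=(10,), seed=1)
        with pytest.raises(ValueError, match="decoy_size"):
            synthetic.generate_gene_sets(truth, n_decoy=1, decoy_size=50)


class TestCohort:
    def test_shared_ordered_sample_ids(self, cohort40):
        samples = list(cohort40.expression.columns)
        assert list(cohort40.traits.index) == samples
        assert list(cohort40.survival.index) == samples

    def test_cohort_bitwise_reproducible(self):
        a = synthetic.generate_cohort(n_genes=100, n_samples=12, module_sizes=(20, 20), seed=9)
        b = synthetic.generate_cohort(n_genes=100, n_samples=12, module_sizes=(20, 20), seed=9)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.traits, b.traits)
        pd.testing.assert_frame_equal(a.survival, b.survival)
        assert a.gene_sets.sets == b.gene_sets.sets

    def test_truth_records_seeds_and_links(self, cohort40):
        truth = cohort40.truth
        assert {"expression", "traits", "gene_sets", "master"} <= set(truth.seeds)
        assert truth.trait_module_links["MD"][0] != truth.trait_module_links["FA"][0]
        assert truth.survival_link[0] == "MD"
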