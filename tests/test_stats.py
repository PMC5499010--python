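import dataclasses
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from deconartifact import (FractionEstimate, FractionSampler,
                           UndefinedCorrelationError, artifact_report,
                           partial_spearman, pearson,
                           purity_correlation_ranking, simulate_mixtures,
                           simulate_tumor_cohort, spearman)


def residual_of_ranks_oracle(x, y, z):
    """Correlate residuals of ranked x and ranked y regressed on ranked z."""
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rz = scipy.stats.rankdata(z)
    design = np.column_stack([np.ones_like(rz), rz])
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    return float(np.corrcoef(res_x, res_y)[0, 1])


class TestPearsonSpearman:
    def test_identity_and_reversal(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, x[::-1]) == pytest.approx(-1.0)
        assert spearman(np.arange(4), np.array([10, 9, 8, 7])) == \
            pytest.approx(-1.0)

    def test_hand_computed_product_moment(self):
        # (1,2,3,4) vs (1,2,4,3): cov 4, sd^2 5 each -> 0.8
        assert pearson([1, 2, 3, 4], [1, 2, 4, 3]) == pytest.approx(0.8)

    def test_spearman_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 50)
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman(x, x ** 3 + 2) == pytest.approx(1.0)

    def test_midrank_tie_handling(self):
        # ranks of (1,1,2) are (1.5,1.5,3); Pearson with (1,2,3) = sqrt(3)/2
        assert spearman([1, 1, 2], [1, 2, 3]) == \
            pytest.approx(math.sqrt(3) / 2)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=0, max_value=5), min_size=4,
                    max_size=30),
           st.data())
    def test_spearman_is_pearson_of_ranks_with_ties(self, xs, data):
        ys = data.draw(st.lists(st.integers(min_value=0, max_value=5),
                                min_size=len(xs), max_size=len(xs)))
        x, y = np.array(xs, float), np.array(ys, float)
        if np.std(x) == 0 or np.std(y) == 0:
            return
        expect = pearson(scipy.stats.rankdata(x), scipy.stats.rankdata(y))
        assert spearman(x, y) == pytest.approx(expect, abs=1e-12)

    def test_undefined_on_constant_input(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(UndefinedCorrelationError):
            spearman([1, 2, 3], [5, 5, 5])


class TestPartialSpearman:
    def test_matches_residual_oracle_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = rng.integers(6, 40)
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            z = 0.3 * x + rng.normal(size=n)
            assert partial_spearman(x, y, z) == pytest.approx(
                residual_of_ranks_oracle(x, y, z), abs=1e-10)

    def test_small_six_point_instance(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0, 9.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.5, 8.5]
        z = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        assert partial_spearman(x, y, z) == pytest.approx(
            residual_of_ranks_oracle(x, y, z), abs=1e-10)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        z = rng.normal(size=30)
        assert partial_spearman(x, x, z) == pytest.approx(1.0)

    def test_reduces_to_spearman_for_independent_conditioner(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=10000)
        y = 0.6 * x + rng.normal(size=10000)
        z = rng.normal(size=10000)  # independent of x and y
        assert abs(partial_spearman(x, y, z) - spearman(x, y)) <= 0.03

    def test_removes_a_purity_style_confounder(self):
        # x and y share z as their only common driver
        rng = np.random.default_rng(3)
        z = rng.uniform(0, 1, 2000)
        x = z + 0.3 * rng.normal(size=2000)
        y = z + 0.3 * rng.normal(size=2000)
        assert spearman(x, y) > 0.5
        assert abs(partial_spearman(x, y, z)) < 0.1

    def test_rank_degenerate_conditioner_errors(self):
        x = np.arange(10.0)
        with pytest.raises(UndefinedCorrelationError):
            partial_spearman(x, np.arange(10.0) ** 2, x)


def perfect_estimates(mix):
    """Estimates equal to the simplex closure of the true pair."""
    ests = []
    c1, c2 = mix.component_indices
    for i in range(mix.n_samples):
        f1, f2 = mix.true_fractions[i, c1], mix.true_fractions[i, c2]
        vec = np.zeros(len(mix.cell_types))
        vec[c1], vec[c2] = f1 / (f1 + f2), f2 / (f1 + f2)
        ests.append(FractionEstimate(mix.cell_types, vec, vec, "cls"))
    return ests


class TestArtifactReport:
    def test_closure_of_independent_pair_is_exactly_minus_one(self, sig22):
        """The pure normalization artifact: closing independent fractions to
        the 2-simplex forces g1 + g2 = 1, hence r(g1, g2) = -1 exactly."""
        mix = simulate_mixtures(sig22, (0, 1), FractionSampler(), 500, seed=10)
        report = artifact_report(mix, perfect_estimates(mix))
        assert report.r_est == pytest.approx(-1.0, abs=1e-12)
        assert report.rho_est == pytest.approx(-1.0, abs=1e-12)

    def test_independent_truth_is_uncorrelated(self, sig22):
        mix = simulate_mixtures(sig22, (0, 1), FractionSampler(), 500, seed=11)
        report = artifact_report(mix, perfect_estimates(mix))
        assert abs(report.r_truth) <= 0.1

    def test_perfect_estimates_track_truth(self, sig22):
        sampler = FractionSampler(mode="fixed", fixed_values=(0.3, 0.2))
        mix = simulate_mixtures(sig22, (0, 1), FractionSampler(), 100, seed=12)
        # closure of the pair correlates with each component's truth
        report = artifact_report(mix, perfect_estimates(mix))
        assert report.r_est_vs_truth[0] > 0.5
        assert report.n_used == 100 and report.n_excluded == 0
        del sampler

    def test_constant_truth_reported_undefined_not_zero(self, sig22):
        sampler = FractionSampler(mode="fixed", fixed_values=(0.25, 0.25))
        mix = simulate_mixtures(sig22, (0, 1), sampler, 50, seed=13)
        ests = perfect_estimates(mix)
        # perturb estimates so they are non-constant
        rng = np.random.default_rng(0)
        for e in ests:
            bump = rng.uniform(0, 0.1)
            e.normalized[0] += bump
            e.normalized[1] -= bump
        report = artifact_report(mix, ests)
        assert report.r_truth is None
        assert report.r_est is not None

    def test_degenerate_estimates_excluded_and_counted(self, sig22):
        mix = simulate_mixtures(sig22, (0, 1), FractionSampler(), 20, seed=14)
        ests = perfect_estimates(mix)
        for i in (3, 8):
            ests[i] = FractionEstimate(mix.cell_types,
                                       np.zeros(len(mix.cell_types)), None,
                                       "svr")
        report = artifact_report(mix, ests)
        assert report.n_used == 18 and report.n_excluded == 2
        assert report.r_est == pytest.approx(-1.0, abs=1e-12)

    def test_too_few_usable_samples_errors(self, sig22):
        mix = simulate_mixtures(sig22, (0, 1), FractionSampler(), 4, seed=15)
        ests = [FractionEstimate(mix.cell_types,
                                 np.zeros(len(mix.cell_types)), None, "svr")
                for _ in range(4)]
        with pytest.raises(ValueError, match="usable"):
            artifact_report(mix, ests)


class TestPurityRanking:
    def test_pure_malignant_noiseless_all_genes_perfect(self, small_sig):
        zero = FractionSampler(mode="fixed",
                               fixed_values=(0.0,) * small_sig.n_cell_types)
        coh = simulate_tumor_cohort(small_sig, 30, planted_fraction=1.0,
                                    noise_sd=0.0, immune_sampler=zero, seed=4)
        ranking = purity_correlation_ranking(coh)
        assert np.allclose(ranking.r, 1.0)
        assert ranking.n_positive == small_sig.n_genes

    def test_no_planted_signal_mostly_negative(self, small_sig):
        coh = simulate_tumor_cohort(small_sig, 200, planted_fraction=0.0,
                                    seed=5)
        ranking = purity_correlation_ranking(coh)
        assert ranking.n_positive <= 0.5 * small_sig.n_genes
        assert ranking.planted_recovery is None

    def test_planted_genes_rank_to_the_top(self, sig22):
        coh = simulate_tumor_cohort(sig22, 200, planted_fraction=0.25,
                                    malignant_magnitude=2.0, seed=6)
        ranking = purity_correlation_ranking(coh)
        assert ranking.planted_recovery >= 0.8
        assert sorted(ranking.gene_ids) == sorted(sig22.gene_ids)

    def test_constant_gene_ranked_last_with_missing_r(self, small_sig):
        coh = simulate_tumor_cohort(small_sig, 30, seed=7)
        expr = coh.expression.copy()
        expr[:, 2] = 42.0
        coh = dataclasses.replace(coh, expression=expr)
        ranking = purity_correlation_ranking(coh)
        assert ranking.gene_ids[-1] == small_sig.gene_ids[2]
        assert np.isnan(ranking.r[-1])

    def test_spearman_method_supported(self, small_sig):
        coh = simulate_tumor_cohort(small_sig, 50, seed=8)
        ranking = purity_correlation_ranking(coh, method="spearman")
        assert np.all(np.abs(ranking.r[~np.isnan(ranking.r)]) <= 1.0)
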