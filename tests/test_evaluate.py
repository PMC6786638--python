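import numpy as np
import pandas as pd
import pytest

from snakedragons.evaluate import (
    EvaluateError,
    benjamini_hochberg,
    characterize_clusters,
    confusion_and_misclassification,
    elementwise_matrix_tests,
    shannon_index,
    subnetwork_block_differences,
)
from snakedragons.matrix_io import MatrixCollection
from snakedragons.simulate import generate_prototype_pair, simulate_noisy_correlation

from conftest import random_correlation


class TestMisclassification:
    def test_perfect_prediction(self):
        truth = np.array([1, 1, 2, 2, 3])
        _, err = confusion_and_misclassification(truth, truth)
        assert err == 0.0

    def test_invariant_to_relabeling(self):
        truth = np.array([1, 1, 2, 2])
        swapped = np.array([2, 2, 1, 1])
        _, err = confusion_and_misclassification(truth, swapped)
        assert err == 0.0

    def test_three_of_thirtyseven_misassigned(self):
        # 20 'old' + 17 'young'; three old objects land in the young cluster
        truth = np.array([1] * 20 + [2] * 17)
        pred = truth.copy()
        pred[[9, 11, 15]] = 2
        cm, err = confusion_and_misclassification(truth, pred)
        assert err == pytest.approx(3 / 37)
        assert round(100 * err, 2) == 8.11
        assert cm.counts.sum() == 37

    def test_differing_cluster_counts_handled_by_padding(self):
        truth = np.array([1, 1, 2, 2, 3, 3])
        pred = np.array([1, 1, 1, 1, 2, 2])
        _, err = confusion_and_misclassification(truth, pred)
        assert err == pytest.approx(2 / 6)

    def test_error_bounded_by_worst_case(self, rng):
        truth = rng.integers(1, 4, 30)
        pred = rng.integers(1, 4, 30)
        _, err = confusion_and_misclassification(truth, pred)
        assert 0 <= err <= 1 - 1 / 3


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        adj, rej = benjamini_hochberg([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_hand_step_up_example(self):
        adj, _ = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_reject_nothing(self):
        adj, rej = benjamini_hochberg([1.0, 1.0, 1.0])
        assert not rej.any()
        np.testing.assert_allclose(adj, 1.0)

    def test_matches_hand_coded_step_up_on_random_p(self, rng):
        p = rng.uniform(size=25)
        adj, rej = benjamini_hochberg(p, q=0.1)
        # independent step-up oracle
        order = np.argsort(p)
        m = len(p)
        raw = p[order] * m / np.arange(1, m + 1)
        run_min = np.minimum.accumulate(raw[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(run_min, 1.0)
        np.testing.assert_allclose(adj, expected, atol=1e-12)
        np.testing.assert_array_equal(rej, adj <= 0.1)

    def test_superset_of_bonferroni(self, rng):
        p = rng.uniform(size=40) ** 2
        q = 0.05
        _, rej = benjamini_hochberg(p, q)
        bonferroni = p <= q / len(p)
        assert np.all(rej[bonferroni])

    def test_invalid_p_rejected(self):
        with pytest.raises(EvaluateError):
            benjamini_hochberg([0.5, np.nan])


class TestCharacterizeClusters:
    def test_flat_variable_not_significant(self, rng):
        cov = pd.DataFrame({"x": np.full(30, 5.0) + rng.normal(0, 1e-6, 30)})
        labels = np.r_[np.ones(15), 2 * np.ones(15)]
        out = characterize_clusters(cov, labels)
        assert not out.significant.any()

    def test_strongly_separated_means_detected(self, rng):
        cov = pd.DataFrame(
            {
                "signal": np.r_[rng.normal(0, 1, 20), rng.normal(5, 1, 20)],
                "noise": rng.normal(0, 1, 40),
            }
        )
        labels = np.r_[np.ones(20), 2 * np.ones(20)]
        out = characterize_clusters(cov, labels).set_index("variable")
        assert out.loc["signal", "significant"]
        assert out.loc["signal", "p_adjusted"] < 0.05

    def test_categorical_routes_to_chi_square(self, rng):
        cov = pd.DataFrame({"sex": ["F"] * 18 + ["M"] * 18})
        labels = np.r_[np.ones(18), 2 * np.ones(18)]
        out = characterize_clusters(cov, labels)
        assert out.test.iloc[0] == "chi-square"
        assert out.significant.iloc[0]

    def test_skewed_data_routes_to_kruskal_wallis(self, rng):
        x = rng.lognormal(0, 1.5, 60) ** 2
        cov = pd.DataFrame({"skewed": x})
        labels = np.r_[np.ones(30), 2 * np.ones(30)]
        out = characterize_clusters(cov, labels)
        assert out.test.iloc[0] == "kruskal-wallis"

    def test_constant_variable_skipped(self):
        cov = pd.DataFrame({"c": np.ones(10)})
        labels = np.r_[np.ones(5), 2 * np.ones(5)]
        out = characterize_clusters(cov, labels)
        assert out.test.iloc[0] == "skipped"

    def test_null_variables_controlled_at_fdr(self, rng):
        """10 pure-noise variables: BH at q=0.05 should rarely reject."""
        false_discoveries = 0
        reps = 60
        for _ in range(reps):
            cov = pd.DataFrame(rng.normal(size=(30, 10)), columns=[f"v{i}" for i in range(10)])
            labels = np.r_[np.ones(15), 2 * np.ones(15)]
            out = characterize_clusters(cov, labels)
            false_discoveries += int(out.significant.sum())
        assert false_discoveries / reps <= 0.5  # expected FDR bound with headroom


class TestElementwise:
    def test_null_clusters_significant_fraction_at_most_nominal(self, rng):
        proto = random_correlation(10, rng)
        mats = [simulate_noisy_correlation(proto, 30, rng, name=f"m{i}") for i in range(20)]
        coll = MatrixCollection([m.name for m in mats], mats)
        labels = np.r_[np.ones(10), 2 * np.ones(10)]
        res = elementwise_matrix_tests(coll, labels, q_fdr=0.05)
        assert res.n_significant / res.n_tested <= 0.05 + 0.05

    def test_planted_block_difference_is_enriched(self):
        A, B, _ = generate_prototype_pair(
            q=12, blocks_a=2, blocks_b=2, offset_b=3, rng_seed=3
        )
        rng = np.random.default_rng(10)
        mats = [simulate_noisy_correlation(A, 200, rng, name=f"a{i}") for i in range(15)]
        mats += [simulate_noisy_correlation(B, 200, rng, name=f"b{i}") for i in range(15)]
        coll = MatrixCollection([m.name for m in mats], mats)
        labels = np.r_[np.ones(15), 2 * np.ones(15)]
        res = elementwise_matrix_tests(coll, labels, q_fdr=0.05)
        truly_different = np.abs(A.values - B.values) > 0.1
        iu = np.triu_indices(12, 1)
        sig = res.significant_mask[iu]
        diff = truly_different[iu]
        rate_in_diff = sig[diff].mean()
        rate_elsewhere = sig[~diff].mean() if (~diff).any() else 0.0
        assert rate_in_diff > max(2 * rate_elsewhere, 0.5)

    def test_duplicated_identical_matrices_yield_empty_mask(self, rng):
        m = random_correlation(5, rng)
        mats = [m.copy() for _ in range(6)]
        for i, mm in enumerate(mats):
            mm.name = f"m{i}"
        coll = MatrixCollection([mm.name for mm in mats], mats)
        res = elementwise_matrix_tests(coll, np.r_[np.ones(3), 2 * np.ones(3)])
        assert res.n_significant == 0 and res.n_tested == 0

    def test_small_cluster_rejected(self, rng):
        mats = [random_correlation(4, rng) for _ in range(3)]
        for i, m in enumerate(mats):
            m.name = f"m{i}"
        coll = MatrixCollection([m.name for m in mats], mats)
        with pytest.raises(EvaluateError):
            elementwise_matrix_tests(coll, np.array([1, 1, 2]))


class TestBlockDifferences:
    def test_arithmetic_of_relative_difference(self):
        V1 = np.full((4, 4), 0.1)
        np.fill_diagonal(V1, 1.0)
        V2 = np.full((4, 4), 0.2)
        np.fill_diagonal(V2, 1.0)
        out = subnetwork_block_differences(V1, V2, {"all": [0, 1, 2, 3]})
        (bd,) = out
        assert bd.mean_difference == pytest.approx(0.1)
        assert bd.relative_difference == pytest.approx(1.0)  # +100%

    def test_identical_matrices_zero_everywhere(self, rng):
        m = random_correlation(6, rng)
        out = subnetwork_block_differences(
            m, m, {"x": [0, 1, 2], "y": [3, 4, 5]}
        )
        assert all(bd.mean_difference == 0 for bd in out)

    def test_four_node_toy_matches_hand_averages(self):
        V1 = np.eye(4)
        V1[0, 1] = V1[1, 0] = 0.2
        V1[2, 3] = V1[3, 2] = 0.4
        V1[0, 2] = V1[2, 0] = 0.6
        V1[0, 3] = V1[3, 0] = 0.8
        V1[1, 2] = V1[2, 1] = 1.0
        V1[1, 3] = V1[3, 1] = 0.0
        V2 = np.zeros_like(V1)
        np.fill_diagonal(V2, 1.0)
        out = {bd.block_pair: bd for bd in subnetwork_block_differences(
            V1, V2, {"p": [0, 1], "q": [2, 3]}
        )}
        assert out[("p", "p")].c1 == pytest.approx(0.2)
        assert out[("q", "q")].c1 == pytest.approx(0.4)
        assert out[("p", "q")].c1 == pytest.approx((0.6 + 0.8 + 1.0 + 0.0) / 4)

    def test_weighted_recombination_reproduces_global_mean(self, rng):
        m1, m2 = random_correlation(9, rng), random_correlation(9, rng)
        partition = {"a": [0, 1, 2], "b": [3, 4, 5, 6], "c": [7, 8]}
        out = subnetwork_block_differences(m1, m2, partition)
        total_w = sum(bd.n_elements for bd in out)
        recombined = sum(bd.mean_difference * bd.n_elements for bd in out) / total_w
        iu = np.triu_indices(9, 1)
        global_diff = (m2.values - m1.values)[iu].mean()
        assert recombined == pytest.approx(global_diff, abs=1e-12)

    def test_singleton_within_block_skipped(self, rng):
        m = random_correlation(3, rng)
        out = subnetwork_block_differences(m, m, {"solo": [0], "rest": [1, 2]})
        pairs = {bd.block_pair for bd in out}
        assert ("solo", "solo") not in pairs
        assert ("solo", "rest") in pairs

    def test_partition_must_cover_all_nodes(self, rng):
        m = random_correlation(4, rng)
        with pytest.raises(EvaluateError):
            subnetwork_block_differences(m, m, {"a": [0, 1]})


class TestShannonIndex:
    def test_single_taxon_is_zero(self):
        si, norm = shannon_index([1.0])
        assert si == 0.0 and norm is None

    @pytest.mark.parametrize("R", [2, 5, 17])
    def test_equal_abundances_hit_log_R_and_normalized_one(self, R):
        si, norm = shannon_index(np.full(R, 1.0 / R))
        assert si == pytest.approx(np.log(R))
        assert norm == pytest.approx(1.0)

    def test_two_taxa_closed_form(self):
        si, norm = shannon_index([0.5, 0.5])
        assert si == pytest.approx(np.log(2))
        assert norm == pytest.approx(1.0)

    def test_zero_abundances_contribute_nothing(self):
        si, _ = shannon_index([0.5, 0.5, 0.0])
        assert si == pytest.approx(np.log(2))

    def test_uniform_profile_maximizes_index(self, rng):
        for R in (2, 4, 6):
            uniform_si, _ = shannon_index(np.full(R, 1.0 / R))
            for _ in range(200):
                r = rng.dirichlet(np.ones(R))
                si, _ = shannon_index(r / r.sum())
                assert si <= uniform_si + 1e-9

    def test_negative_abundance_rejected(self):
        with pytest.raises(EvaluateError):
            shannon_index([1.2, -0.2])
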