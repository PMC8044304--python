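import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import linear_sum_assignment

import csfprofile as cp
from csfprofile.clustering import (
    LabelingConflictError, _em_single, _initial_parameters, n_free_parameters,
)


def best_permutation_distance(fitted_means, true_means):
    """Max per-component Euclidean distance under the optimal matching."""
    cost = np.linalg.norm(fitted_means[:, None, :] - true_means[None], axis=2)
    r, c = linear_sum_assignment(cost)
    return cost[r, c].max()


class TestGmmEm:
    def test_k1_is_the_closed_form_gaussian(self, rng):
        X = rng.normal(2, 3, (200, 3))
        reg = 1e-6
        fit = cp.fit_gmm_em(X, 1, seed=0, n_init=1, reg=reg)
        np.testing.assert_allclose(fit.means[0], X.mean(axis=0), atol=1e-8)
        ml_cov = np.cov(X, rowvar=False, ddof=0) + reg * np.eye(3)
        np.testing.assert_allclose(fit.covariances[0], ml_cov, atol=1e-6)
        expected_ll = stats.multivariate_normal(X.mean(axis=0), ml_cov).logpdf(X).sum()
        assert fit.log_likelihood == pytest.approx(expected_ll, abs=1e-6)

    def test_two_separated_blobs_recovered(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (100, 3)), rng.normal(10, 0.5, (100, 3))])
        truth = np.array([[0.0] * 3, [10.0] * 3])
        fit = cp.fit_gmm_em(X, 2, seed=1, n_init=5)
        assert best_permutation_distance(fit.means, truth) < 0.2

    def test_loglikelihood_is_monotone(self, z_matrix):
        fit = cp.fit_gmm_em(z_matrix, 4, seed=2, n_init=1)
        diffs = np.diff(fit.log_likelihood_path)
        assert (diffs >= -1e-8 * np.abs(fit.log_likelihood_path[:-1])).all()

    def test_responsibilities_rows_sum_to_one(self, gmm_fit):
        np.testing.assert_allclose(gmm_fit.responsibilities.sum(axis=1), 1.0,
                                   atol=1e-9)
        np.testing.assert_allclose(
            gmm_fit.hard_labels, np.argmax(gmm_fit.responsibilities, axis=1) + 1)
        assert gmm_fit.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_k_at_least_n_rejected(self):
        with pytest.raises(ValueError):
            cp.fit_gmm_em(np.zeros((5, 3)), 5)

    def test_matches_reference_em_from_same_initialization(self, rng):
        """Final log-likelihood within 1e-4 of scikit-learn's EM started from
        the identical initial parameters, over random small instances."""
        from sklearn.mixture import GaussianMixture
        n_checked = 0
        for trial in range(50):
            n = int(rng.integers(20, 61))
            K = int(rng.integers(1, 4))
            d = 2
            centers = rng.normal(0, 4, (K, d))
            X = np.vstack([rng.normal(centers[k], 1.0, (n // K + 1, d))
                           for k in range(K)])[:n]
            seed = int(rng.integers(2 ** 31))
            reg = 1e-6
            w0, m0, c0 = _initial_parameters(X, K, np.random.default_rng(seed), reg)
            mine = cp.fit_gmm_em(X, K, tol=1e-12, reg=reg, max_iter=3000,
                                 init=(w0, m0, c0))
            ref = GaussianMixture(
                n_components=K, covariance_type="full", tol=1e-12,
                reg_covar=reg, max_iter=3000, n_init=1,
                weights_init=w0, means_init=m0,
                precisions_init=np.linalg.inv(c0),
            ).fit(X)
            ref_ll = ref.score(X) * n
            assert mine.log_likelihood == pytest.approx(ref_ll, abs=1e-4)
            n_checked += 1
        assert n_checked == 50


class TestBic:
    def test_parameter_count_for_k6_d3(self):
        assert n_free_parameters(6, 3) == 5 + 18 + 36 == 59

    def test_k1_d1_closed_form(self, rng):
        n = 100
        x = rng.normal(0, 2, (n, 1))
        fit = cp.fit_gmm_em(x, 1, seed=0, n_init=1, reg=0.0)
        sigma2 = x.var(ddof=0)
        expected = n * (np.log(2 * np.pi * sigma2) + 1) + 2 * np.log(n)
        assert cp.bic_score(fit, n) == pytest.approx(expected, rel=1e-9)

    def test_doubling_n_adds_p_ln2(self, gmm_fit):
        n = 616
        assert cp.bic_score(gmm_fit, 2 * n) - cp.bic_score(gmm_fit, n) == \
            pytest.approx(gmm_fit.n_params * np.log(2), rel=1e-12)


class TestModelSelection:
    def test_single_gaussian_data_selects_k1(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            X = rng.normal(0, 1, (500, 3))
            k, _ = cp.select_num_clusters(X, range(1, 5), seed=seed)
            hits += k == 1
        assert hits >= 18

    def test_degenerate_range(self, z_matrix):
        k, curve = cp.select_num_clusters(z_matrix, [3], seed=0, n_init=2)
        assert k == 3
        assert len(curve) == 1

    def test_default_cohort_selects_six_in_most_seeds(self, default_spec):
        """Model-selection consistency at study scale: the six-component
        structure is recovered by BIC in at least 18 of 20 seeds."""
        hits = 0
        for seed in range(20):
            t = cp.generate_cohort(default_spec, n=616, seed=seed)
            Z = cp.fit_standardization(t).apply(t)
            k, _ = cp.select_num_clusters(Z, range(1, 11), seed=seed)
            hits += k == 6
        assert hits >= 18

    def test_component_mean_recovery(self, default_spec):
        """Fitting with the true K recovers each component's realized mean
        within 0.3 z-units (optimal matching) in >= 95% of 20 seeds."""
        passes = 0
        for seed in range(20):
            t = cp.generate_cohort(default_spec, n=616, seed=seed)
            tr = cp.fit_standardization(t)
            Z = tr.apply(t)
            fit = cp.fit_gmm_em(Z, 6, seed=seed, n_init=10)
            truth = np.vstack([Z[t["_component"] == k].mean(axis=0)
                               for k in range(1, 7)])
            if best_permutation_distance(fit.means, truth) < 0.3:
                passes += 1
        assert passes >= 19


class TestClusterProfiles:
    def test_percentile_convention(self):
        t = pd.DataFrame({"ratio": np.arange(1.0, 101.0),
                          "ptau": np.arange(1.0, 101.0),
                          "ttau": np.arange(1.0, 101.0)})
        prof = cp.cluster_profiles(t, np.ones(100, dtype=int))
        row = prof[prof.biomarker == "ratio"].iloc[0]
        assert row["median"] == pytest.approx(50.5)
        assert row["lo"] == pytest.approx(3.475)
        assert row["hi"] == pytest.approx(97.525)

    def test_degenerate_clusters(self):
        t = pd.DataFrame({"ratio": [5.0, 7.0, 7.0], "ptau": [1.0, 2.0, 2.0],
                          "ttau": [1.0, 2.0, 2.0]})
        prof = cp.cluster_profiles(t, [1, 2, 2])
        single = prof[(prof.cluster == 1) & (prof.biomarker == "ratio")].iloc[0]
        assert single["median"] == single["lo"] == single["hi"] == 5.0
        equal = prof[(prof.cluster == 2) & (prof.biomarker == "ratio")].iloc[0]
        assert equal["hi"] - equal["lo"] == 0.0


class TestPrevalenceMatrix:
    def test_arithmetic_and_exclusion(self):
        diag = ["AD"] * 10 + ["OND"] * 4
        labels = [1] * 7 + [2] * 3 + [1] * 4
        prev = cp.prevalence_matrix(diag, labels, min_n=5)
        assert list(prev.index) == ["AD"]  # OND has n=4 < 5: excluded
        np.testing.assert_allclose(prev.loc["AD"], [70.0, 30.0])

    def test_rows_sum_to_100(self, cohort, gmm_fit):
        prev = cp.prevalence_matrix(cohort["diagnosis"], gmm_fit.hard_labels)
        np.testing.assert_allclose(prev.sum(axis=1), 100.0, atol=1e-9)


class TestHierarchicalOrder:
    def test_upgma_by_hand(self):
        order, heights = cp.hierarchical_order(np.array([0.0, 1.0, 10.0]))
        assert heights[0] == pytest.approx(1.0)
        assert heights[1] == pytest.approx(9.5)  # average linkage: (10+9)/2

    def test_identical_rows_merge_first_at_zero(self):
        _, heights = cp.hierarchical_order(np.array([[1.0, 2.0], [5.0, 6.0],
                                                     [1.0, 2.0]]))
        assert heights[0] == 0.0

    def test_leaf_order_is_permutation(self, cohort, gmm_fit):
        prev = cp.prevalence_matrix(cohort["diagnosis"], gmm_fit.hard_labels)
        order, _ = cp.hierarchical_order(prev.to_numpy())
        assert sorted(order) == list(range(len(prev)))


class TestLabelClusters:
    def _make(self, ad_per_cluster, ond_per_cluster):
        diag, labels = [], []
        for c, (a, o) in enumerate(zip(ad_per_cluster, ond_per_cluster), start=1):
            diag += ["AD"] * a + ["OND"] * o
            labels += [c] * (a + o)
        return np.array(diag), np.array(labels)

    def test_constructed_shares(self):
        # AD shares (1,4,30,25,25,15)%, OND dominated by cluster 1
        diag, labels = self._make([1, 4, 30, 25, 25, 15], [77, 8, 5, 4, 3, 3])
        out = cp.label_clusters(diag, labels)
        assert out[1] == "control"
        assert out[2] == "intermediate"
        assert all(out[c] == "AD-like" for c in (3, 4, 5, 6))

    def test_tie_breaks_toward_higher_median_ratio(self):
        diag, labels = self._make([0, 0, 10], [5, 5, 1])
        ratio = np.where(labels == 2, 0.11, 0.05)
        out = cp.label_clusters(diag, labels, ratio=ratio)
        assert out[2] == "control"

    def test_conflict_raises(self):
        # a single cluster holding both most OND and most AD
        diag, labels = self._make([50, 1], [30, 5])
        with pytest.raises(LabelingConflictError):
            cp.label_clusters(diag, labels)

    def test_default_cohort_labeling(self, cohort, gmm_fit, cluster_labels_map):
        values = list(cluster_labels_map.values())
        assert values.count("control") == 1
        assert values.count("AD-like") == 4
        assert values.count("intermediate") == 1


def misdiagnosis_oracle(ad_counts, ond_counts, ratio_medians, threshold=0.10):
    """Exhaustive check over every distribution of m relabelings across
    clusters, for increasing m."""
    from csfprofile.clustering import _label_from_counts
    base = _label_from_counts(np.array(ad_counts), np.array(ond_counts),
                              ratio_medians, threshold)
    n_ond = sum(ond_counts)
    K = len(ad_counts)
    for m in range(1, n_ond + 1):
        for combo in itertools.product(*(range(min(m, o) + 1) for o in ond_counts)):
            if sum(combo) != m:
                continue
            ad = np.array(ad_counts) + np.array(combo)
            ond = np.array(ond_counts) - np.array(combo)
            try:
                if _label_from_counts(ad, ond, ratio_medians, threshold) != base:
                    return m
            except (ValueError, LabelingConflictError):
                return m
    return n_ond


class TestMisdiagnosisTolerance:
    def _cohort(self, ad_counts, ond_counts, ratios):
        diag, labels, ratio = [], [], []
        for c, (a, o, r) in enumerate(zip(ad_counts, ond_counts, ratios), start=1):
            diag += ["AD"] * a + ["OND"] * o
            labels += [c] * (a + o)
            ratio += [r] * (a + o)
        return np.array(diag), np.array(labels), np.array(ratio)

    def test_counting_example(self):
        # OND counts (10, 9, 0): two relabelings flip the OND-count argmax
        diag, labels, ratio = self._cohort([1, 2, 30], [10, 9, 0],
                                           [0.10, 0.08, 0.05])
        tol = cp.misdiagnosis_tolerance(diag, labels, ratio=ratio)
        assert tol.m == 2
        oracle = misdiagnosis_oracle([1, 2, 30], [10, 9, 0],
                                     np.array([0.10, 0.08, 0.05]))
        assert tol.m == oracle

    def test_matches_oracle_on_random_instances(self, rng):
        from csfprofile.clustering import _label_from_counts
        n_checked = 0
        for _ in range(40):
            K = int(rng.integers(2, 5))
            ad = rng.integers(0, 12, K).tolist()
            ond = rng.integers(0, 8, K).tolist()
            med = np.sort(rng.random(K))[::-1]
            if sum(ad) == 0 or sum(np.array(ond) > 0) < 2:
                continue
            try:
                _label_from_counts(np.array(ad), np.array(ond), med, 0.10)
            except (ValueError, LabelingConflictError):
                continue
            diag, labels, ratio = self._cohort(ad, ond, med)
            tol = cp.misdiagnosis_tolerance(diag, labels, ratio=ratio)
            assert tol.m == misdiagnosis_oracle(ad, ond, med)
            n_checked += 1
        assert n_checked >= 20

    def test_single_ond_cluster_is_an_error(self):
        diag, labels, ratio = self._cohort([1, 20], [10, 0], [0.1, 0.05])
        with pytest.raises(ValueError):
            cp.misdiagnosis_tolerance(diag, labels, ratio=ratio)

    def test_bounded_by_control_ond_count(self, cohort, gmm_fit):
        tol = cp.misdiagnosis_tolerance(cohort["diagnosis"], gmm_fit.hard_labels,
                                        ratio=cohort["ratio"])
        ond_per_cluster = pd.crosstab(gmm_fit.hard_labels,
                                      cohort["diagnosis"])["OND"]
        assert tol.m <= ond_per_cluster.max()
        assert 0 < tol.fraction <= 1


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = stats.hypergeom.pmf(x, n, col1, row1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return total


class TestFisherExact:
    @pytest.mark.parametrize("table,expected", [
        ((3, 1, 1, 3), 0.485714285714),
        ((5, 0, 0, 5), 2 / 252),
    ])
    def test_enumeration_examples(self, table, expected):
        assert cp.fisher_exact_2x2(*table) == pytest.approx(expected, rel=1e-7)
        assert fisher_oracle(*table) == pytest.approx(expected, rel=1e-7)

    def test_zero_margin_gives_one(self):
        assert cp.fisher_exact_2x2(0, 0, 3, 5) == 1.0

    def test_matches_oracle_on_random_tables(self, rng):
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(0, 12, 4))
            if a + b + c + d == 0:
                continue
            assert cp.fisher_exact_2x2(a, b, c, d) == \
                pytest.approx(fisher_oracle(a, b, c, d), rel=1e-7)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            cp.fisher_exact_2x2(-1, 2, 3, 4)

    def test_mci_vs_dementia_prevalence_across_ad_clusters(
            self, cohort, gmm_fit, cluster_labels_map):
        """Within AD patients, MCI-phase and dementia-phase subjects spread
        over the AD-like clusters similarly (no significant difference)."""
        ad = cohort[cohort["diagnosis"] == "AD"]
        labels = gmm_fit.hard_labels[(cohort["diagnosis"] == "AD").to_numpy()]
        ad_clusters = [c for c, l in cluster_labels_map.items() if l == "AD-like"]
        for c in ad_clusters:
            a = int(((labels == c) & (ad["stage"] == "MCI")).sum())
            b = int(((labels != c) & (ad["stage"] == "MCI")).sum())
            cc = int(((labels == c) & (ad["stage"] == "dementia")).sum())
            dd = int(((labels != c) & (ad["stage"] == "dementia")).sum())
            assert cp.fisher_exact_2x2(a, b, cc, dd) > 0.01
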