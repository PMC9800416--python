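"""stats_core: contingency tests, rank tests, BH, PCA, clustering, ROC."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from seedsoil import AnalysisError, DataValidationError
from seedsoil.stats import (
    bh_adjust,
    chi_square_test,
    combine_markers,
    hierarchical_cluster,
    pca,
    roc_auc,
    spearman,
    wilcoxon_rank_sum,
)


class TestChiSquare:
    def test_gender_table(self):
        # 2x2 clinical contingency table: p = 0.829 without continuity correction
        _, df, p = chi_square_test([[14, 6], [11, 4]])
        assert df == 1
        assert p == pytest.approx(0.829, abs=5e-4)

    def test_three_level_table(self):
        _, df, p = chi_square_test([[12, 7, 1], [5, 6, 4]])
        assert df == 2
        assert p == pytest.approx(0.127, abs=5e-4)

    def test_perfect_independence(self):
        stat, _, p = chi_square_test([[5, 5], [5, 5]])
        assert stat == 0.0
        assert p == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(AnalysisError, match="margin"):
            chi_square_test([[0, 0], [3, 4]])

    def test_matches_chi2_survival_function(self, rng):
        """Pearson statistic + chi2 upper tail recomputed by hand on
        random tables agrees with the implementation to 1e-10."""
        for _ in range(50):
            t = rng.integers(1, 40, size=(2, 3)).astype(float)
            stat, df, p = chi_square_test(t)
            expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
            stat_ref = ((t - expected) ** 2 / expected).sum()
            p_ref = sps.chi2.sf(stat_ref, df)
            assert stat == pytest.approx(stat_ref, rel=1e-12)
            assert p == pytest.approx(p_ref, rel=1e-10)


class TestWilcoxon:
    def test_exact_extreme_split(self):
        # all C(6,3)=20 rank splits; the observed one is the most extreme
        # in each direction: two-sided p = 2/20
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets(self):
        _, p = wilcoxon_rank_sum([1, 2, 2, 3], [2, 1, 3, 2])
        assert p == 1.0

    def test_empty_rejected(self):
        with pytest.raises(DataValidationError):
            wilcoxon_rank_sum([], [1.0])

    def test_approximation_close_to_exact_null(self, rng):
        """Normal-approximation p within 0.01 of the exact rank-split
        distribution at n = 30 vs 30 (tie-free draws)."""
        for _ in range(10):
            x = rng.normal(0, 1, 30)
            y = rng.normal(0.8, 1, 30)
            _, p_approx = wilcoxon_rank_sum(x, y)
            p_exact = sps.mannwhitneyu(x, y, alternative="two-sided",
                                       method="exact").pvalue
            assert abs(p_approx - p_exact) < 0.01


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_computed_step_up(self):
        # p_(i) * m / i = (0.04, 0.04, 0.04, 0.04) after the step-up min
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(200)
        ours = bh_adjust(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(ours, ref, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataValidationError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        shuffled = [p[i] for i in perm]
        out = bh_adjust(p)
        out_shuffled = bh_adjust(shuffled)
        np.testing.assert_allclose([out[i] for i in perm], out_shuffled)


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 4.0, 2.0, 8.0, 5.0]
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_ties_match_rank_pearson(self):
        x = [1, 2, 2, 3, 4, 5, 5, 5, 6, 7]
        y = [2, 1, 3, 3, 5, 4, 6, 6, 7, 9]
        rho, _ = spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        brute = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(brute, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(AnalysisError):
            spearman([1, 1, 1], [1, 2, 3])


class TestPca:
    def test_collinear_data_single_component(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([x, 3 * x])
        res = pca(X, n_components=1, scale=False)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(20, 6))
        res = pca(X, n_components=4)
        np.testing.assert_allclose(res.loadings.T @ res.loadings, np.eye(4),
                                   atol=1e-9)

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(15, 5))
        res = pca(X, n_components=5, scale=False)
        reconstructed = res.scores @ res.loadings.T + res.mean
        np.testing.assert_allclose(reconstructed, X, atol=1e-9)

    def test_rank_limit(self, rng):
        x = rng.normal(size=10)
        X = np.column_stack([x, 2 * x, -x])
        with pytest.raises(AnalysisError, match="rank"):
            pca(X, n_components=2, scale=False)


class TestHierarchicalCluster:
    def test_two_separated_pairs(self):
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels, _ = hierarchical_cluster(pts, k=2, linkage="complete")
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_k_equals_n(self):
        pts = np.arange(5, dtype=float)[:, None]
        labels, _ = hierarchical_cluster(pts, k=5)
        assert len(set(labels)) == 5

    def test_bad_k_rejected(self):
        with pytest.raises(DataValidationError):
            hierarchical_cluster(np.zeros((3, 2)), k=4)

    def test_merge_heights_match_naive_agglomeration(self, rng):
        """Six random points: complete-linkage merges recomputed by a
        literal agglomeration over the distance matrix."""
        pts = rng.normal(size=(6, 2))

        def naive_complete(points):
            clusters = [[i] for i in range(len(points))]
            heights = []
            while len(clusters) > 1:
                best = None
                for i in range(len(clusters)):
                    for j in range(i + 1, len(clusters)):
                        d = max(np.linalg.norm(points[a] - points[b])
                                for a in clusters[i] for b in clusters[j])
                        if best is None or d < best[0]:
                            best = (d, i, j)
                d, i, j = best
                heights.append(d)
                clusters[i] = clusters[i] + clusters[j]
                del clusters[j]
            return np.array(heights)

        _, heights = hierarchical_cluster(pts, k=1, linkage="complete")
        np.testing.assert_allclose(np.sort(heights),
                                   np.sort(naive_complete(pts)), rtol=1e-10)


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_tie_credit(self):
        # pos-neg pairs: (2>1)=1, (2=2)=0.5, (3>1)=1, (3>2)=1 -> 3.5/4
        res = roc_auc([1, 2, 2, 3], [False, True, False, True])
        assert res.auc == pytest.approx(0.875, abs=1e-12)

    def test_brute_force_pair_counting(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 51))
            scores = np.round(rng.normal(size=n), 1)  # provoke ties
            labels = rng.integers(0, 2, size=n).astype(bool)
            if labels.all() or not labels.any():
                continue
            pos, neg = scores[labels], scores[~labels]
            brute = np.mean([
                1.0 if p > q else 0.5 if p == q else 0.0
                for p in pos for q in neg
            ])
            assert roc_auc(scores, labels).auc == pytest.approx(brute, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40).astype(bool)
        labels[0], labels[1] = True, False
        a1 = roc_auc(scores, labels).auc
        a2 = roc_auc(np.exp(scores), labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_auc_within_ci(self, rng):
        scores = rng.normal(size=50) + np.linspace(0, 1, 50)
        labels = np.arange(50) > 24
        res = roc_auc(scores, labels)
        assert res.ci95[0] <= res.auc <= res.ci95[1]

    def test_single_class_rejected(self):
        with pytest.raises(AnalysisError):
            roc_auc([1, 2, 3], [True, True, True])


class TestCombineMarkers:
    def test_constant_second_marker_keeps_auc(self, rng):
        m1 = rng.normal(size=40)
        labels = (m1 + rng.normal(0, 0.8, 40)) > 0
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        m2 = np.zeros(40)
        combined = combine_markers(m1, m2, labels)
        assert roc_auc(combined, labels).auc == pytest.approx(
            roc_auc(m1, labels).auc, abs=1e-9)

    def test_combination_not_much_worse_than_best_single(self, rng):
        for _ in range(5):
            n = 60
            z = rng.integers(0, 2, n).astype(bool)
            z[:2] = [True, False]
            m1 = z + rng.normal(0, 1.0, n)
            m2 = z + rng.normal(0, 1.5, n)
            best = max(roc_auc(m1, z).auc, roc_auc(m2, z).auc)
            comb = roc_auc(combine_markers(m1, m2, z), z).auc
            assert comb >= best - 0.05

    def test_null_markers_give_chance_auc(self, rng):
        aucs = []
        for _ in range(10):
            labels = np.r_[np.ones(17, bool), np.zeros(18, bool)]
            m1, m2 = rng.normal(size=35), rng.normal(size=35)
            aucs.append(roc_auc(combine_markers(m1, m2, labels), labels).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.2
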