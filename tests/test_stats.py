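"""Rank statistics, Holm correction, exact tests, classification."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from dyadkin import (
    CANONICAL_FEATURES,
    CIB_COMPOSITES,
    ValidationError,
    classify_dyads,
    correlate_features_with_cib,
    fisher_exact,
    holm_adjust,
    rank_sum_test,
    spearman_rho,
)


class TestSpearman:
    def test_monotone_pair_is_one(self):
        rho, _ = spearman_rho([1, 2, 3], [2, 4, 9])
        assert rho == pytest.approx(1.0)

    def test_antitone_pair_is_minus_one(self):
        x = np.arange(6.0)
        rho, _ = spearman_rho(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_midrank_tie_case(self):
        rho, _ = spearman_rho([1, 2, 2, 4], [1, 2, 3, 4])
        assert rho == pytest.approx(4.5 / math.sqrt(22.5), abs=1e-12)

    def test_exact_p_matches_scipy_enumeration(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        _, p = spearman_rho(x, y)

        def statistic(perm_y):
            return sps.spearmanr(x, perm_y).statistic

        ref = sps.permutation_test(
            (y,),
            statistic,
            permutation_type="pairings",
            n_resamples=np.inf,
            alternative="two-sided",
        )
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = spearman_rho(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.integers(0, 2**32 - 1))
    def test_invariant_under_monotone_transforms(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=12)
        y = r.normal(size=12)
        rho, _ = spearman_rho(x, y)
        rho2, _ = spearman_rho(np.exp(x), y**3)
        assert rho2 == pytest.approx(rho, abs=1e-12)


class TestHolm:
    def test_hand_stepdown(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.2]), [0.2])

    def test_equal_ps_hit_bonferroni(self):
        np.testing.assert_allclose(
            holm_adjust([0.2, 0.2, 0.2, 0.2]), [0.8, 0.8, 0.8, 0.8]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            holm_adjust([0.5, 1.2])

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
        st.integers(0, 10**6),
    )
    def test_bounds_and_agreement_with_statsmodels(self, p, _seed):
        from statsmodels.stats.multitest import multipletests

        p = np.asarray(p)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= np.minimum(len(p) * p, 1.0) + 1e-12)
        ref = multipletests(p, method="holm")[1]
        np.testing.assert_allclose(adj, ref, atol=1e-12)


class TestRankSum:
    def test_fully_separated_small_groups(self):
        W, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert W == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=5), rng.normal(1.0, 1.0, size=7)
        W1, p1 = rank_sum_test(x, y)
        W2, p2 = rank_sum_test(y, x)
        assert W1 + W2 == pytest.approx(len(x) * len(y))
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_test([], [1.0])


class TestFisher:
    def test_balanced_table_p_one(self):
        _, p = fisher_exact([[1, 1], [1, 1]])
        assert p == pytest.approx(1.0)

    def test_diagonal_two_table(self):
        _, p = fisher_exact([[2, 0], [0, 2]])
        assert p == pytest.approx(1.0 / 3.0)

    def test_diagonal_ten_table(self):
        _, p = fisher_exact([[10, 0], [0, 10]])
        assert p == pytest.approx(2.0 / math.comb(20, 10), rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError, match="margin"):
            fisher_exact([[0, 0], [3, 4]])

    def test_conditional_mle_odds_ratio(self):
        orr, _ = fisher_exact([[7, 2], [3, 8]])
        ref = sps.contingency.odds_ratio(
            [[7, 2], [3, 8]], kind="conditional"
        ).statistic
        assert orr == pytest.approx(ref)


class TestCorrelationReport:
    def _cohort(self, rng, n=20):
        feats = pd.DataFrame(
            rng.uniform(size=(n, 17)), columns=list(CANONICAL_FEATURES)
        )
        feats.insert(0, "session_id", [f"s{i}" for i in range(n)])
        cib = pd.DataFrame(
            rng.uniform(1, 5, size=(n, 8)), columns=list(CIB_COMPOSITES)
        )
        cib.insert(0, "session_id", [f"s{i}" for i in range(n)])
        return feats, cib

    def test_shape_and_family_size(self, rng):
        feats, cib = self._cohort(rng)
        report = correlate_features_with_cib(feats, cib)
        assert report.rho.shape == (17, 8)
        assert report.family_size == 17
        glob = correlate_features_with_cib(feats, cib, family="global")
        assert glob.family_size == 136

    def test_holm_dominates_raw_p(self, rng):
        feats, cib = self._cohort(rng)
        report = correlate_features_with_cib(feats, cib)
        assert (
            report.p_holm.to_numpy() >= report.p_raw.to_numpy() - 1e-15
        ).all()
        assert (np.abs(report.rho.to_numpy()) <= 1.0 + 1e-12).all()

    def test_planted_monotone_link_tops_its_family(self, rng):
        feats, cib = self._cohort(rng)
        cib["dyadic_reciprocity"] = 1.0 + 3.5 * feats["pause_ratio"] ** 2
        report = correlate_features_with_cib(feats, cib)
        assert report.rho.loc["pause_ratio", "dyadic_reciprocity"] == (
            pytest.approx(1.0)
        )
        col = report.p_holm["dyadic_reciprocity"]
        assert col.idxmin() == "pause_ratio"

    def test_null_features_rarely_significant(self, rng):
        hits, total = 0, 0
        for _ in range(10):
            feats, cib = self._cohort(rng)
            report = correlate_features_with_cib(
                feats, cib, family="global"
            )
            hits += int((report.p_holm.to_numpy() < 0.05).sum())
            total += 136
        assert hits / total <= 0.05

    def test_session_mismatch_listed(self, rng):
        feats, cib = self._cohort(rng, n=6)
        cib.loc[0, "session_id"] = "zzz"
        with pytest.raises(ValidationError, match="zzz"):
            correlate_features_with_cib(feats, cib)


class TestClassification:
    def _separable(self, rng, n=20, gap=6.0, d=2):
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        X = rng.normal(size=(n, d))
        X[y == 1, 0] += gap
        return X, y

    def test_separable_clusters_are_perfect(self, rng):
        X, y = self._separable(rng)
        res = classify_dyads(X, y, k=5, seed=3)
        assert res.training_accuracy == 1.0
        assert res.total_accuracy == 1.0
        assert res.confusion.sum() == 20

    def test_permuted_labels_near_chance(self, rng):
        accs = []
        for seed in range(5):
            X = rng.normal(size=(40, 17))
            y = np.array([0, 1] * 20)
            accs.append(
                classify_dyads(X, y, k=5, seed=seed).total_accuracy
            )
        assert 0.2 <= np.mean(accs) <= 0.8

    def test_leave_one_out_runs_n_folds(self, rng):
        X, y = self._separable(rng, n=12)
        res = classify_dyads(X, y, k=6, seed=0)
        assert len(res.fold_accuracies) == 6

    def test_bit_reproducible_given_seed(self, rng):
        X, y = self._separable(rng, gap=1.0)
        r1 = classify_dyads(X, y, k=5, seed=11)
        r2 = classify_dyads(X, y, k=5, seed=11)
        assert r1.fold_accuracies == r2.fold_accuracies
        assert r1.total_accuracy == r2.total_accuracy
        np.testing.assert_array_equal(r1.confusion, r2.confusion)

    def test_oversized_k_advises_smaller(self, rng):
        X, y = self._separable(rng, n=20)
        with pytest.raises(ValidationError, match="smaller k"):
            classify_dyads(X, y, k=15, seed=0)

    def test_nan_features_rejected(self, rng):
        X, y = self._separable(rng)
        X[0, 0] = np.nan
        with pytest.raises(ValidationError, match="NaN"):
            classify_dyads(X, y, k=5, seed=0)
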