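"""Clustering engine, consensus, and characterization statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gcsubtype.classify import (
    SubtypeAssignment,
    consensus_cluster,
    crosstab_test,
    encode_features,
    pairwise_mannwhitney,
    survival_compare,
    ward_cluster,
)


class TestEncodeFeatures:
    def table(self):
        return pd.DataFrame({
            "sig_cluster": [1, 2, 3, 2],
            "cnv_cluster": [1, 1, 2, 2],
            "nea_cluster": [1, 2, 1, 2],
            "clonality_group": ["multiclonal", "oligoclonal", "oligoclonal",
                                "multiclonal"],
            "TP53_mut": [1, 1, 0, 0],
            "LRP1B_mut": [0, 1, 0, 0],
            "ERBB2_amp": [1, 0, 0, 0],
        }, index=list("abcd"))

    def test_one_hot_block_scaled_by_sqrt_width(self):
        X, names = encode_features(self.table())
        j = names.index("sig_cluster=2")
        np.testing.assert_allclose(X[1, names.index("sig_cluster=1")], 0.0)
        np.testing.assert_allclose(X[1, j], 1 / np.sqrt(3))
        np.testing.assert_allclose(X[1, names.index("sig_cluster=3")], 0.0)

    def test_flag_groups_form_blocks(self):
        X, names = encode_features(self.table())
        # two SMG flags: each scaled by 1/sqrt(2); one CNV flag: weight 1
        assert X[0, names.index("TP53_mut")] == pytest.approx(1 / np.sqrt(2))
        assert X[0, names.index("ERBB2_amp")] == pytest.approx(1.0)

    def test_identical_rows_have_zero_distance(self):
        table = pd.concat([self.table().iloc[[0]]] * 3)
        X, _ = encode_features(table)
        assert np.allclose(X[0], X[1]) and np.allclose(X[1], X[2])

    def test_constant_column_leaves_distances_unchanged(self):
        from scipy.spatial.distance import pdist

        table = self.table().drop(columns=["ERBB2_amp"])
        X1, _ = encode_features(table)
        table2 = table.copy()
        table2["ERBB2_amp"] = 1  # constant flag, forms its own block
        X2, _ = encode_features(table2)
        np.testing.assert_allclose(pdist(X1), pdist(X2), atol=1e-9)

    def test_missing_value_rejected(self):
        table = self.table()
        table.loc["a", "TP53_mut"] = np.nan
        with pytest.raises(ValueError):
            encode_features(table)


def brute_force_ward(X, k):
    """Exhaustive minimum within-cluster sum of squares partition."""
    n = len(X)
    best = (np.inf, None)
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) != k:
            continue
        cost = 0.0
        for c in set(labels):
            members = X[np.array(labels) == c]
            cost += ((members - members.mean(axis=0)) ** 2).sum()
        if cost < best[0] - 1e-12:
            best = (cost, labels)
    return best


class TestWardCluster:
    def test_two_separated_clouds_match_exhaustive_optimum(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.2, size=(4, 2)),
                       rng.normal(5, 0.2, size=(4, 2))])
        labels = ward_cluster(X, 2)
        _, optimum = brute_force_ward(X, 2)
        same = (np.array(optimum)[:, None] == np.array(optimum)[None, :])
        ours = (labels[:, None] == labels[None, :])
        np.testing.assert_array_equal(same, ours)

    @pytest.mark.parametrize("n,k", [(6, 2), (8, 3)])
    def test_separated_groups_match_optimum_various_sizes(self, n, k):
        rng = np.random.default_rng(n * 10 + k)
        centers = np.arange(k)[:, None] * 8.0
        X = np.vstack([centers[i % k] + rng.normal(0, 0.3, size=(1, 1))
                       for i in range(n)])
        labels = ward_cluster(X, k)
        _, optimum = brute_force_ward(X, k)
        same = (np.array(optimum)[:, None] == np.array(optimum)[None, :])
        ours = (labels[:, None] == labels[None, :])
        np.testing.assert_array_equal(same, ours)

    def test_identical_points_one_cluster(self):
        labels = ward_cluster(np.ones((5, 3)), 1)
        assert set(labels) == {1}

    def test_duplicating_points_preserves_partition(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, size=(3, 2)),
                       rng.normal(4, 0.1, size=(3, 2))])
        labels = ward_cluster(X, 2)
        doubled = ward_cluster(np.vstack([X, X]), 2)
        np.testing.assert_array_equal(doubled[:6], doubled[6:])
        same = labels[:, None] == labels[None, :]
        np.testing.assert_array_equal(doubled[:6][:, None] == doubled[:6][None, :], same)

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(np.ones((3, 2)), 4)

    def test_canonical_numbering_by_mean_tmb(self):
        X = np.vstack([np.zeros((3, 2)), np.ones((3, 2)) * 5])
        tmb = np.array([10, 10, 10, 500, 500, 500])
        labels = ward_cluster(X, 2, tmb=tmb)
        assert list(labels) == [2, 2, 2, 1, 1, 1]  # high-TMB group is subtype 1

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(i * 6, 0.2, size=(4, 3)) for i in range(3)])
        labels = ward_cluster(X, 3)
        perm = rng.permutation(len(X))
        permuted = ward_cluster(X[perm], 3)
        same_orig = labels[perm][:, None] == labels[perm][None, :]
        same_perm = permuted[:, None] == permuted[None, :]
        np.testing.assert_array_equal(same_orig, same_perm)


class TestConsensus:
    def test_degenerate_settings_reduce_to_plain_ward(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.3, size=(6, 2)),
                       rng.normal(5, 0.3, size=(6, 2))])
        assignments, consensus = consensus_cluster(X, k=2, n_resamples=1,
                                                   subsample_frac=1.0, seed=0)
        labels = np.array([a.subtype for a in assignments])
        np.testing.assert_array_equal(labels, ward_cluster(X, 2))
        np.testing.assert_allclose(np.diag(consensus), 1.0)

    def test_consensus_matrix_properties(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 4))
        _, consensus = consensus_cluster(X, k=3, n_resamples=100,
                                         subsample_frac=0.8, seed=1)
        np.testing.assert_allclose(consensus, consensus.T)
        np.testing.assert_allclose(np.diag(consensus), 1.0)
        assert consensus.min() >= 0.0 and consensus.max() <= 1.0

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 3))
        a = consensus_cluster(X, k=2, n_resamples=50, seed=9)
        b = consensus_cluster(X, k=2, n_resamples=50, seed=9)
        np.testing.assert_array_equal([x.subtype for x in a[0]],
                                      [x.subtype for x in b[0]])
        np.testing.assert_array_equal(a[1], b[1])

    def test_subsample_too_small_rejected(self):
        with pytest.raises(ValueError):
            consensus_cluster(np.ones((10, 2)), k=5, subsample_frac=0.3)

    def test_monte_carlo_error_shrinks_with_resamples(self):
        """Off-diagonal consensus entries stabilize as resamples grow."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(18, 3))

        def spread(n_resamples):
            mats = np.stack([consensus_cluster(X, k=3, n_resamples=n_resamples,
                                               seed=s)[1] for s in range(8)])
            off = ~np.eye(len(X), dtype=bool)
            return mats.std(axis=0)[off].mean()

        assert spread(400) < spread(25)


def brute_force_fisher(table):
    """Sum hypergeometric point probabilities <= the observed table's."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    observed_p = stats.hypergeom.pmf(a, n, row1, col1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = stats.hypergeom.pmf(x, n, row1, col1)
        if p <= observed_p * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestStatistics:
    def test_fisher_used_for_sparse_2x2_and_matches_enumeration(self):
        labels = pd.Series([1] * 4 + [2] * 4, index=range(8))
        category = pd.Series(["x", "x", "x", "y", "x", "y", "y", "y"],
                             index=range(8))
        result = crosstab_test(labels, category)
        assert result["test"] == "fisher"
        assert result["p"] == pytest.approx(brute_force_fisher([[3, 1], [1, 3]]),
                                            abs=1e-12)

    def test_identical_distributions_mannwhitney_p_one(self):
        values = pd.Series([1.0] * 10, index=range(10))
        labels = pd.Series([1] * 5 + [2] * 5, index=range(10))
        out = pairwise_mannwhitney(values, labels)
        assert out.loc[0, "p"] == 1.0


class TestSurvival:
    def assignments(self, groups):
        return [SubtypeAssignment(f"S{i}", g, 1.0) for i, g in enumerate(groups)]

    def clinical(self, times, events, **extra):
        df = pd.DataFrame({"os_months": times, "os_event": events,
                           **extra},
                          index=[f"S{i}" for i in range(len(times))])
        return df

    def test_identical_groups_logrank_zero(self):
        times = [5, 10, 15, 5, 10, 15]
        events = [1, 1, 0, 1, 1, 0]
        out = survival_compare(self.assignments([1, 1, 1, 2, 2, 2]),
                               self.clinical(times, events))
        assert out["logrank_statistic"] == pytest.approx(0.0, abs=1e-10)
        assert out["logrank_p"] == pytest.approx(1.0)

    def test_six_subject_hand_oracle(self):
        """Log-rank statistic equals the hand-computed at-risk-table value."""
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 1, 1, 1, 1]
        groups = [1, 2, 1, 2, 1, 2]
        # at each death time: observed deaths in group 1 minus expected
        # n1/n at-risk fraction; variance from the hypergeometric term
        at_risk = [(3, 6), (2, 5), (2, 4), (1, 3), (1, 2), (0, 1)]
        O_minus_E = 0.0
        V = 0.0
        for died_in_1, (n1, n) in zip([1, 0, 1, 0, 1, 0], at_risk):
            O_minus_E += died_in_1 - n1 / n
            if n > 1:
                V += (n1 / n) * (1 - n1 / n) * (n - 1) / (n - 1)
        expected = O_minus_E ** 2 / V
        out = survival_compare(self.assignments(groups),
                               self.clinical(times, events))
        assert out["logrank_statistic"] == pytest.approx(expected, rel=1e-6)

    def test_hazard_ratio_of_identical_groups_near_one(self):
        rng = np.random.default_rng(7)
        times = list(rng.exponential(20, 40))
        events = [1] * 40
        out = survival_compare(self.assignments([1] * 20 + [2] * 20),
                               self.clinical(times * 1, events))
        hr = out["cox"]["subtype_1"]["hr"]
        assert out["cox_baseline_subtype"] == 2
        assert 0.5 < hr < 2.0

    def test_fully_censored_group_still_computes(self):
        times = [5, 6, 7, 8, 9, 10]
        events = [1, 1, 1, 0, 0, 0]
        out = survival_compare(self.assignments([1, 1, 1, 2, 2, 2]),
                               self.clinical(times, events))
        assert np.isfinite(out["logrank_statistic"])
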