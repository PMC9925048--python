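import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from ornmotif import motif_analysis, population
from ornmotif.motif_analysis import (
    AdaptationProfile,
    adaptation_anova,
    adaptation_profile,
    cluster_motifs,
    cluster_test1,
    cluster_test2,
    conditional_motif_matrix,
    response_matrix,
    responsive_mask,
    select_cluster_count,
    switching_rate,
    validate_clustering,
)
from ornmotif.population import BinnedResponse, RateTrace


def _poisson_binned(rates, trials, seed, dt=0.05):
    """rates: (n_units, n_bins) expected spikes/s -> BinnedResponse."""
    rng = np.random.default_rng(seed)
    lam = np.repeat(rates[:, None, :], trials, axis=1) * dt
    return BinnedResponse(rng.poisson(lam), dt)


def _two_blobs(n=40, d=6.0, seed=0):
    """Two template-like response groups with opposite activation patterns."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n, 20))
    a[:, 10:] += d
    b = rng.normal(0.0, 1.0, (n, 20))
    b[:, :10] += d
    return np.vstack([a, b]), np.r_[np.zeros(n), np.ones(n)]


class TestResponsiveMask:
    def test_strong_increase_detected(self):
        rates = np.full((1, 60), 5.0)
        rates[0, 20:40] = 25.0
        b = _poisson_binned(rates, trials=5, seed=1)
        assert responsive_mask(b, pre_window=1.0)[0]

    def test_suppression_detected(self):
        rates = np.full((1, 60), 20.0)
        rates[0, 20:40] = 0.5
        b = _poisson_binned(rates, trials=5, seed=2)
        assert responsive_mask(b, pre_window=1.0)[0]

    def test_null_false_positive_rate_matches_monte_carlo_oracle(self):
        # flat Poisson units: responsive fraction equals the 2-SD rule's
        # multiple-comparison false-positive rate, estimated by an
        # independent Monte-Carlo reimplementation of the rule
        rates = np.full((400, 60), 10.0)
        b = _poisson_binned(rates, trials=5, seed=3)
        frac = responsive_mask(b, pre_window=1.0).mean()

        rng = np.random.default_rng(99)
        hits = 0
        n_mc = 800
        for _ in range(n_mc):
            avg = rng.poisson(10.0 * 0.05, size=(5, 60)).mean(axis=0)
            mu, sd = avg[:20].mean(), avg[:20].std()
            hits += bool(np.any(np.abs(avg[20:] - mu) > 2 * sd))
        oracle = hits / n_mc
        assert frac == pytest.approx(oracle, abs=0.06)

    def test_zero_variance_warns(self):
        b = BinnedResponse(np.zeros((1, 1, 40), dtype=int), 0.05)
        with pytest.warns(UserWarning):
            mask = responsive_mask(b, pre_window=1.0)
        assert not mask[0]


class TestClustering:
    def test_two_separated_groups_recovered(self):
        X, truth = _two_blobs()
        labels = cluster_motifs(X, 2)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_duplicates_co_cluster(self):
        X, _ = _two_blobs(n=10)
        X2 = np.vstack([X, X[:3]])
        labels = cluster_motifs(X2, 2)
        assert np.array_equal(labels[:3], labels[-3:])

    def test_ordering_invariance(self):
        X, _ = _two_blobs()
        perm = np.random.default_rng(0).permutation(len(X))
        l1 = cluster_motifs(X, 3)
        l2 = cluster_motifs(X[perm], 3)
        assert adjusted_rand_score(l1[perm], l2) == 1.0

    def test_affine_rescaling_invariance(self):
        # z-normalization absorbs per-response offset and scale
        X, _ = _two_blobs()
        Y = 3.0 * X + 7.0
        assert np.array_equal(cluster_motifs(X, 2), cluster_motifs(Y, 2))

    def test_k_bounds(self):
        X, _ = _two_blobs(n=3)
        with pytest.raises(ValueError):
            cluster_motifs(X, 1)
        with pytest.raises(ValueError):
            cluster_motifs(X, 100)

    def test_surrogate_four_templates_recovered(self, surrogate_table,
                                                surrogate_binned):
        mask = responsive_mask(surrogate_binned, pre_window=1.0)
        X = response_matrix(surrogate_binned)[mask]
        labels = cluster_motifs(X, 4)
        truth = np.asarray(surrogate_table.meta["true_motif"])[mask]
        agreement = adjusted_rand_score(truth, labels)
        assert agreement > 0.8


class TestValidityTests:
    def test_tight_cluster_passes_test1(self):
        X, truth = _two_blobs(n=30)
        passed, overlap = cluster_test1(X, truth + 1, n_boot=2000, seed=1)
        assert all(passed.values())
        assert all(v < 0.05 for v in overlap.values())

    def test_random_pseudocluster_false_pass_rate_near_5pct(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (60, 15))
        hits = 0
        reps = 250
        for r in range(reps):
            labels = np.ones(60, dtype=int)
            labels[rng.choice(60, 20, replace=False)] = 2
            passed, _ = cluster_test1(X, labels, n_boot=1000, seed=r)
            hits += passed[2]
        rate = hits / reps
        assert 0.02 <= rate <= 0.09

    def test_identical_responses_degenerate_pass(self):
        X = np.tile(np.linspace(0, 1, 12), (20, 1))
        labels = np.r_[np.ones(10), 2 * np.ones(10)].astype(int)
        passed, _ = cluster_test1(X, labels, n_boot=1000, seed=0, normalize=False)
        assert all(passed.values())

    def test_singleton_cluster_fails_with_warning(self):
        X, _ = _two_blobs(n=10)
        labels = np.ones(20, dtype=int)
        labels[0] = 2
        with pytest.warns(UserWarning):
            passed, _ = cluster_test1(X, labels, n_boot=1000, seed=0)
        assert not passed[2]

    def test_distant_blobs_significant_in_test2(self):
        X, truth = _two_blobs(n=30, d=8.0)
        P = cluster_test2(X, truth + 1)
        off = ~np.eye(2, dtype=bool)
        assert np.all(P[off] < 0.05)

    def test_arbitrary_split_not_significant(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (60, 15))
        labels = np.r_[np.ones(30), 2 * np.ones(30)].astype(int)
        P = cluster_test2(X, labels)
        assert np.nanmin(P) > 0.05

    def test_test2_is_nonsymmetric(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 0.5, (25, 10))        # tight
        b = rng.normal(2.0, 2.0, (25, 10))      # loose
        X = np.vstack([a, b])
        labels = np.r_[np.ones(25), 2 * np.ones(25)].astype(int)
        P = cluster_test2(X, labels, normalize=False)
        assert P[0, 1] != P[1, 0]


class TestClusterCountSelection:
    def test_two_templates_give_two(self):
        X, truth = _two_blobs(n=40, d=8.0)
        assert select_cluster_count(X, k_max=5, n_boot=1500, seed=2) == 2

    def test_no_valid_partition_returns_one(self):
        # one tight group plus mutually distant outliers: every cut produces
        # a loose or singleton cluster, so no k passes both tests
        rng = np.random.default_rng(3)
        X = np.vstack([
            np.tile(np.linspace(0, 1, 15), (10, 1)) + 0.01 * rng.normal(size=(10, 15)),
            40.0 * rng.normal(size=(3, 15)),
        ])
        with pytest.warns(UserWarning):
            k = select_cluster_count(X, k_max=4, n_boot=1200, seed=2)
        assert k == 1

    def test_validate_clustering_report(self):
        X, _ = _two_blobs(n=25, d=8.0)
        res = validate_clustering(X, 2, n_boot=1500, seed=0)
        assert res.k == 2 and res.all_pass
        assert res.test2_p.shape == (2, 2)


class TestSwitchingQuantification:
    def test_identical_labels_zero(self):
        labels = ["excitatory", "delayed", "offset"]
        assert switching_rate(labels, labels) == 0.0

    def test_all_different_one(self):
        a = ["excitatory"] * 5
        b = ["delayed"] * 5
        assert switching_rate(a, b) == 1.0

    def test_counting_with_missing_responses(self):
        a = ["excitatory"] * 13 + [None] * 4
        b = ["delayed"] * 5 + ["excitatory"] * 8 + ["offset"] * 4
        assert switching_rate(a, b) == pytest.approx(5 / 13)

    def test_no_opportunities_rejected(self):
        with pytest.raises(ValueError):
            switching_rate([None, None], ["excitatory", "delayed"])

    def test_conditional_matrix_identity_without_switching(self):
        labels = np.array(["excitatory", "delayed", "offset", "inhibitory"] * 10)
        M = conditional_motif_matrix(labels, labels)
        assert np.allclose(M.to_numpy(), np.eye(4))

    def test_conditional_matrix_uniform_at_full_switching(self):
        from ornmotif.odorspace import apply_switching
        rng_labels = np.array(["excitatory"] * 30000, dtype=object)
        switched = apply_switching(rng_labels, 1.0, seed=5)
        M = conditional_motif_matrix(rng_labels, switched)
        row = M.loc["excitatory"].to_numpy()
        assert row[0] == 0.0
        assert np.allclose(row[1:], 1 / 3, atol=0.02)

    def test_rows_sum_to_one(self):
        a = np.array(["excitatory", "delayed"] * 20)
        b = np.array(["delayed", "offset"] * 20)
        M = conditional_motif_matrix(a, b).to_numpy()
        sums = np.nansum(M, axis=1)
        assert np.allclose(sums[~np.isnan(M).all(axis=1)], 1.0)


class TestAdaptation:
    def _windows(self, n_pulses=5, ipi=0.5, onset=2.0, width=0.2):
        onsets = onset + np.arange(n_pulses) * (width + ipi)
        return [(o, o + width + 0.2) for o in onsets]

    def test_constant_rate_gives_equal_values(self):
        rate = np.full((1, 3, 800), 10.0)
        prof = adaptation_profile(RateTrace(rate, dt=0.01), self._windows(),
                                  baseline_window=2.0, ipi=0.5)
        assert np.allclose(prof.values, prof.values[:, :1])

    def test_decreasing_pulse_response_detected(self):
        t = np.arange(800) * 0.01
        rate = np.zeros((1, 4, 800))
        for k, (lo, hi) in enumerate(self._windows()):
            rate[:, :, (t >= lo) & (t < hi)] = 30.0 * (1 - 0.12 * k)
        prof = adaptation_profile(RateTrace(rate, dt=0.01), self._windows(),
                                  baseline_window=2.0, ipi=0.5)
        assert prof.mean[-1] < prof.mean[0]
        assert np.all(np.abs(prof.values) <= 1.0)

    def test_anova_flat_is_null(self):
        vals = np.full((8, 5), 0.4) + 1e-9 * np.arange(5)
        F, p = adaptation_anova(AdaptationProfile(vals, ipi=0.5))
        assert p > 0.9

    def test_anova_detects_monotone_trend(self):
        rng = np.random.default_rng(0)
        vals = 0.5 - 0.05 * np.arange(8) + 0.02 * rng.standard_normal((12, 8))
        F, p = adaptation_anova(AdaptationProfile(vals, ipi=0.5))
        assert p < 0.01

    def test_permuting_pulses_destroys_trend(self):
        rng = np.random.default_rng(1)
        base = 0.5 - 0.05 * np.arange(8)
        vals = base + 0.02 * rng.standard_normal((12, 8))
        perm_vals = np.array([row[rng.permutation(8)] for row in vals])
        _, p_perm = adaptation_anova(AdaptationProfile(perm_vals, ipi=0.5))
        _, p_true = adaptation_anova(AdaptationProfile(vals, ipi=0.5))
        assert p_true < 0.01 < p_perm
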