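"""Binary k-means etiology clustering and its scoring metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibrocv import classify


def exhaustive_1d_split(values):
    """Oracle: best two-cluster split of 1D data by within-cluster SS."""
    x = np.sort(np.asarray(values, dtype=float))
    best = None
    for k in range(1, len(x)):
        lo, hi = x[:k], x[k:]
        ss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if best is None or ss < best[0]:
            best = (ss, lo.mean(), hi.mean())
    return best


class TestKmeansBinary:
    def test_recovers_exhaustive_1d_partition(self):
        values = np.array([5.0, 6.0, 7.0, 30.0, 31.0, 32.0])
        res = classify.kmeans_binary(values, seed=0)
        ss, lo_c, hi_c = exhaustive_1d_split(values)
        assert res.inertia == pytest.approx(ss)
        assert res.centroids.ravel() == pytest.approx([lo_c, hi_c])
        assert res.threshold == pytest.approx(18.5)
        assert list(res.labels) == ["NIC"] * 3 + ["IC"] * 3

    def test_random_1d_data_matches_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = rng.normal(size=rng.integers(4, 30))
            res = classify.kmeans_binary(x, seed=1)
            assert res.inertia == pytest.approx(exhaustive_1d_split(x)[0], rel=1e-9)

    def test_threshold_is_centroid_midpoint(self):
        res = classify.kmeans_binary(np.array([10.0, 10.0, 30.0, 30.0]), seed=0)
        assert res.threshold == pytest.approx(20.0)

    def test_duplicated_dataset_keeps_centroids(self):
        x = np.array([1.0, 2.0, 8.0, 9.5])
        a = classify.kmeans_binary(x, seed=0)
        b = classify.kmeans_binary(np.repeat(x, 2), seed=0)
        assert a.centroids == pytest.approx(b.centroids)

    def test_labels_invariant_under_increasing_affine_map(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=16)
        a = classify.kmeans_binary(x, seed=3)
        b = classify.kmeans_binary(3.0 * x + 11.0, seed=3)
        assert list(a.labels) == list(b.labels)

    def test_identical_points_degenerate(self):
        res = classify.kmeans_binary(np.full(6, 4.2), seed=0)
        assert res.degenerate
        assert res.inertia == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(12, 2))
        a = classify.kmeans_binary(x, seed=9)
        b = classify.kmeans_binary(x, seed=9)
        assert list(a.labels) == list(b.labels)
        assert a.inertia == b.inertia

    def test_agrees_with_sklearn_reference(self):
        """Independent cross-check of the restarted Lloyd implementation."""
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(21)
        x = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(5, 1, (10, 2))])
        ours = classify.kmeans_binary(x, restarts=50, seed=0)
        ref = KMeans(n_clusters=2, n_init=20, random_state=0).fit(x)
        assert ours.inertia == pytest.approx(ref.inertia_, rel=1e-6)
        ours_part = ours.labels == "IC"
        ref_part = ref.labels_ == ref.labels_[ours_part.argmax()]
        assert np.array_equal(ours_part, ref_part)


class TestScoreClassification:
    def test_printed_confusion_counts(self):
        """7/8 IC and 6/8 NIC correct: the headline clustering metrics."""
        truth = ["IC"] * 8 + ["NIC"] * 8
        pred = ["IC"] * 7 + ["NIC"] + ["NIC"] * 6 + ["IC"] * 2
        m = classify.score_classification(pred, truth)
        assert (m.tp, m.fn, m.tn, m.fp) == (7, 1, 6, 2)
        assert m.accuracy == pytest.approx(81.25)
        assert m.sensitivity == pytest.approx(87.5)
        assert m.specificity == pytest.approx(75.0)
        assert round(m.ppv, 2) == 0.78
        assert round(m.npv, 2) == 0.86

    def test_perfect_labels(self):
        truth = ["IC", "NIC", "IC", "NIC"]
        m = classify.score_classification(truth, truth)
        assert m.accuracy == 100.0 and m.sensitivity == 100.0
        assert m.ppv == 1.0 and m.npv == 1.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            classify.score_classification([], [])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_metric_identities_for_random_confusions(self, counts):
        tp, fn, tn, fp = counts
        if tp + fn + tn + fp == 0:
            return
        truth = ["IC"] * (tp + fn) + ["NIC"] * (tn + fp)
        pred = (
            ["IC"] * tp + ["NIC"] * fn + ["NIC"] * tn + ["IC"] * fp
        )
        m = classify.score_classification(pred, truth)
        total = tp + fn + tn + fp
        assert m.accuracy == pytest.approx(100.0 * (tp + tn) / total)
        if tp + fn:
            assert m.sensitivity == pytest.approx(100.0 * tp / (tp + fn))
        if tn + fp:
            assert m.specificity == pytest.approx(100.0 * tn / (tn + fp))
        if tp + fp:
            assert m.ppv == pytest.approx(tp / (tp + fp))
        if tn + fn:
            assert m.npv == pytest.approx(tn / (tn + fn))


class TestRecovery:
    def test_recovery_from_group_sigma_distributions(self):
        """Clustering sigma_intra drawn from the IC (27.1 +/- 6.03) and NIC
        (15.69 +/- 5.76) distributions recovers etiology with mean accuracy
        in [70%, 95%] over 200 seeded cohorts."""
        truth = np.array(["IC"] * 8 + ["NIC"] * 8)
        accs = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            sig = np.concatenate([r.normal(27.1, 6.03, 8), r.normal(15.69, 5.76, 8)])
            labels = classify.kmeans_binary(sig, seed=seed).labels
            accs.append(classify.score_classification(labels, truth).accuracy)
        assert 70.0 <= np.mean(accs) <= 95.0

    def test_sigma_outperforms_vnm_as_feature(self):
        """The heterogeneity feature separates etiologies at least as well
        as the mean fraction in >= 80% of simulated cohorts (the IC V_nm
        distribution is wide, which hurts the V_nm-based clustering)."""
        truth = np.array(["IC"] * 8 + ["NIC"] * 8)
        wins = 0
        n_seeds = 200
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            sig = np.concatenate([r.normal(27.1, 6.03, 8), r.normal(15.69, 5.76, 8)])
            vnm = np.concatenate([r.normal(47.2, 16.18, 8), r.normal(32.16, 6.55, 8)])
            a_s = classify.score_classification(
                classify.kmeans_binary(sig, seed=seed).labels, truth
            ).accuracy
            a_v = classify.score_classification(
                classify.kmeans_binary(vnm, seed=seed).labels, truth
            ).accuracy
            wins += a_s >= a_v
        assert wins / n_seeds >= 0.8

    def test_random_labels_score_at_chance(self):
        accs = []
        for seed in range(200):
            r = np.random.default_rng(1000 + seed)
            x = r.normal(20.0, 8.0, 16)
            truth = np.array(["IC", "NIC"])[r.permutation([0] * 8 + [1] * 8)]
            labels = classify.kmeans_binary(x, seed=seed).labels
            accs.append(classify.score_classification(labels, truth).accuracy)
        assert 45.0 <= np.mean(accs) <= 55.0

    def test_widely_separated_groups_classify_perfectly(self):
        x = np.array([0.0, 0.1, 100.0, 100.1])
        truth = ["NIC", "NIC", "IC", "IC"]
        labels = classify.kmeans_binary(x, seed=0).labels
        assert classify.score_classification(labels, truth).accuracy == 100.0


class TestFeatureComparison:
    def test_table_has_one_row_per_feature_set(self):
        import pandas as pd

        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "group": ["IC"] * 8 + ["NIC"] * 8,
                "sigma_intra": np.concatenate(
                    [rng.normal(27, 6, 8), rng.normal(15, 5, 8)]
                ),
                "v_nm": np.concatenate([rng.normal(47, 16, 8), rng.normal(32, 6, 8)]),
                "largest_patch_area_um2": rng.lognormal(10, 1, 16),
            }
        )
        out = classify.feature_comparison(df, seed=0)
        assert len(out) == len(classify.DEFAULT_FEATURE_SETS)
        sig_row = out[out["features"] == "sigma_intra"].iloc[0]
        assert 0 <= sig_row["accuracy_pct"] <= 100

    def test_constant_feature_is_flagged(self):
        import pandas as pd

        df = pd.DataFrame(
            {"group": ["IC", "NIC"] * 3, "sigma_intra": [1.0] * 6}
        )
        out = classify.feature_comparison(df, feature_sets=(("sigma_intra",),))
        assert out.iloc[0]["skipped"] == "constant feature"
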