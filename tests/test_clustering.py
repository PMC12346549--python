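"""phenotype_clustering: elbow, K-means, embedding, profiling."""

import numpy as np
import pytest
from sklearn.datasets import make_blobs

from ecgaudit.clustering import (
    ClusterModel,
    assign_clusters,
    embed_2d,
    fit_phenotype_clusters,
    profile_clusters,
    select_cluster_count,
    select_positive_features,
)
from ecgaudit.synthetic import SubjectMetadata


def _blobs(c, n_per=40, std=0.2, seed=0):
    x, y = make_blobs(n_samples=n_per * c, centers=c, cluster_std=std,
                      center_box=(-30, 30), random_state=seed + 10)
    return x, y


def _meta(i, lvsd, **kw):
    defaults = dict(age=60.0, sex="M", hypertension=False, diabetes=False,
                    cad=False, ckd=False)
    defaults.update(kw)
    return SubjectMetadata(
        record_id=f"m{i}", label="LVSD" if lvsd else "non-LVSD",
        lvef_percent=30.0 if lvsd else 60.0, **defaults,
    )


class TestSelectClusterCount:
    @pytest.mark.parametrize("c", [3, 5])
    def test_recovers_planted_blob_count(self, c):
        x, _ = _blobs(c)
        k, curve = select_cluster_count(x, range(2, 9), seed=0)
        assert k == c

    def test_inertia_curve_non_increasing(self):
        x, _ = _blobs(4)
        _, curve = select_cluster_count(x, range(2, 9), seed=0)
        inertias = [v for _, v in curve]
        assert all(b <= a + 1e-9 for a, b in zip(inertias, inertias[1:]))

    def test_degenerate_features_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            select_cluster_count(np.ones((20, 3)), range(2, 5))

    def test_k_range_bounds(self):
        x, _ = _blobs(2, n_per=5)
        with pytest.raises(ValueError, match="k_range"):
            select_cluster_count(x, range(2, 50))


class TestFitClusters:
    def test_two_far_blobs_recovered(self):
        x, y = _blobs(2)
        model, assign = fit_phenotype_clusters(x, 2, seed=0)
        # assignments equal blob membership up to label swap
        agreement = max(np.mean(assign == y), np.mean(assign == 1 - y))
        assert agreement == 1.0

    def test_assignment_minimality(self):
        x, _ = _blobs(3)
        model, assign = fit_phenotype_clusters(x, 3, seed=0)
        std = (x - model.feature_mean) / model.feature_scale
        d = np.linalg.norm(std[:, None, :] - model.centroids[None], axis=2)
        assert np.array_equal(assign, d.argmin(axis=1))

    def test_seeded_determinism(self):
        x, _ = _blobs(4)
        _, a = fit_phenotype_clusters(x, 4, seed=3)
        _, b = fit_phenotype_clusters(x, 4, seed=3)
        assert np.array_equal(a, b)

    def test_k_greater_than_n_rejected(self):
        with pytest.raises(ValueError):
            fit_phenotype_clusters(np.random.default_rng(0).normal(size=(5, 2)),
                                   6, seed=0)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            fit_phenotype_clusters(np.zeros((5, 2)), 1, seed=0)

    def test_fit_on_a_assign_on_b(self):
        x, y = _blobs(2, n_per=50)
        model, _ = fit_phenotype_clusters(x[:60], 2, seed=0)
        assign_b = assign_clusters(model, x[60:])
        ref, _ = fit_phenotype_clusters(x, 2, seed=0)
        # new points land with their own blob
        d = np.linalg.norm(
            ((x[60:] - model.feature_mean) / model.feature_scale)[:, None]
            - model.centroids[None], axis=2)
        assert np.array_equal(assign_b, d.argmin(axis=1))


class TestEmbed2D:
    def test_shape_and_determinism(self):
        x, _ = _blobs(2, n_per=40)
        a = embed_2d(x, seed=0, perplexity=10)
        b = embed_2d(x, seed=0, perplexity=10)
        assert a.shape == (80, 2)
        assert np.array_equal(a, b)
        assert np.all(np.isfinite(a))

    def test_blobs_stay_separated(self):
        x, y = _blobs(2, n_per=40)
        emb = embed_2d(x, seed=0, perplexity=10)
        model, assign = fit_phenotype_clusters(emb, 2, seed=0)
        purity = max(np.mean(assign == y), np.mean(assign == 1 - y))
        assert purity == 1.0
        inter = np.linalg.norm(
            emb[y == 0].mean(axis=0) - emb[y == 1].mean(axis=0))
        assert inter > 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="perplexity"):
            embed_2d(np.random.default_rng(0).normal(size=(10, 3)),
                     seed=0, perplexity=10)


class TestSelectPositiveFeatures:
    def test_kept_ids_score_at_least_threshold(self, trained_small, eval_records):
        from ecgaudit.surrogate import predict_scores

        model, _ = trained_small
        records, _ = eval_records
        features, ids, scores = select_positive_features(model, records, 9.7, 1)
        assert set(ids) <= {r.record_id for r in records}
        assert np.all(scores >= 9.7)
        assert features.shape == (len(ids), 8)
        all_scores = {o.record_id: o.score
                      for o in predict_scores(model, records)}
        expected = {rid for rid, s in all_scores.items() if s >= 9.7}
        assert set(ids) == expected

    def test_no_positives_is_error(self, trained_small, eval_records):
        model, _ = trained_small
        records, _ = eval_records
        with pytest.raises(ValueError, match="threshold"):
            select_positive_features(model, records, 100.0, 1)


class TestProfiles:
    def test_single_cluster_equals_global_summary(self):
        metas = [_meta(i, lvsd=i % 2 == 0, age=50.0 + i) for i in range(10)]
        scores = np.linspace(10, 90, 10)
        profiles, df = profile_clusters(np.zeros(10, dtype=int), metas, scores)
        assert len(profiles) == 1
        p = profiles[0]
        assert p.n == 10
        assert p.true_positive_rate == 0.5
        assert p.mean_score == scores.mean()
        assert p.metadata_summary["mean_age"] == np.mean([m.age for m in metas])

    def test_sizes_sum_to_n(self):
        metas = [_meta(i, lvsd=True) for i in range(12)]
        assignments = np.array([0, 1, 2] * 4)
        profiles, _ = profile_clusters(assignments, metas, np.ones(12))
        assert sum(p.n for p in profiles) == 12

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError, match="align"):
            profile_clusters([0, 1], [_meta(0, True)], [1.0, 2.0])

    def test_cluster_model_invariants(self):
        with pytest.raises(ValueError, match="k must be >= 2"):
            ClusterModel(1, np.zeros((1, 2)), 1, 0, [(1, 1.0)],
                         np.zeros(2), np.ones(2))
        with pytest.raises(ValueError, match="distinct"):
            ClusterModel(2, np.zeros((2, 2)), 1, 0, [(2, 1.0)],
                         np.zeros(2), np.ones(2))

    def test_planted_phenotypes_differ_in_profiles(self, trained_small):
        # two planted morphologies among positives: wide-QRS vs AF-like
        from dataclasses import replace

        from ecgaudit.surrogate import extract_activations_all_blocks
        from ecgaudit.synthetic import MorphologyParams, simulate_record
        from ecgaudit.clustering import fit_phenotype_clusters

        model, _ = trained_small
        rng = np.random.default_rng(17)
        recs, widths = [], []
        archetypes = [
            MorphologyParams(qrs_width_ms=170.0, qrs_notch=0.8,
                             qrs_amplitude_scale=0.6),
            MorphologyParams(rhythm_irregularity=0.35, p_amplitude_scale=0.0,
                             heart_rate=110.0, qrs_amplitude_scale=1.8),
        ]
        for k, params in enumerate(archetypes):
            for i in range(20):
                p = replace(params, qrs_amplitude_scale=(
                    params.qrs_amplitude_scale * float(np.exp(rng.normal(0, 0.05)))))
                recs.append(simulate_record(p, 125, 5,
                                            seed=int(rng.integers(2**31)),
                                            record_id=f"p{k}-{i}"))
                widths.append(p.qrs_width_ms)
        feats = extract_activations_all_blocks(model, recs)[0]
        _, assign = fit_phenotype_clusters(feats, 2, seed=0)
        widths = np.array(widths)
        means = [widths[assign == c].mean() for c in (0, 1)]
        sds = [widths[assign == c].std() for c in (0, 1)]
        assert abs(means[0] - means[1]) > max(sds)
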