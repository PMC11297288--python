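import numpy as np
import pandas as pd
import pytest

from cpbatch.metrics import (
    average_precision,
    build_knn_graph,
    graph_connectivity,
    kbet_score,
    leiden_cluster_scores,
    lisi_score,
    mean_average_precision,
    silhouette_batch,
    silhouette_label,
)


def ap_bruteforce(query, positives, negatives):
    """Recall-increment formulation of AP, computed with explicit loops."""
    cands = [(p, True) for p in positives] + [(n, False) for n in negatives]
    sims = []
    for v, _ in cands:
        v = np.asarray(v, float)
        q = np.asarray(query, float)
        sims.append(float(q @ v / (np.linalg.norm(q) * np.linalg.norm(v))))
    order = sorted(range(len(cands)), key=lambda i: (-sims[i], i))
    n_pos = len(positives)
    ap, tp, prev_recall = 0.0, 0, 0.0
    for rank, i in enumerate(order, start=1):
        if cands[i][1]:
            tp += 1
        recall = tp / n_pos
        precision = tp / rank
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestKnnGraph:
    def test_collinear_points_k1(self):
        x = np.array([[0.0], [1.0], [2.0], [4.0]])
        g = build_knn_graph(x, k=1)
        assert g.indices[:, 0].tolist() == [1, 0, 1, 2]

    def test_matches_allpairs_bruteforce(self, rng):
        x = rng.normal(size=(50, 10))
        g = build_knn_graph(x, k=6)
        d = np.linalg.norm(x[:, None] - x[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        for i in range(50):
            expected = set(np.argsort(d[i])[:6])
            assert set(g.indices[i]) == expected

    def test_k_too_large_errors(self, rng):
        with pytest.raises(ValueError, match="smaller"):
            build_knn_graph(rng.normal(size=(5, 2)), k=5)

    def test_no_self_neighbors(self, rng):
        x = rng.normal(size=(30, 3))
        x[5] = x[9]  # exact duplicate
        g = build_knn_graph(x, k=4)
        for i in range(30):
            assert i not in g.indices[i]


class TestSilhouetteLabel:
    def test_separated_compound_clusters_score_high(self, rng):
        x = np.vstack([rng.normal(size=(30, 5)),
                       rng.normal(size=(30, 5)) + 40.0])
        labels = ["a"] * 30 + ["b"] * 30
        res = silhouette_label(x, labels)
        assert res.normalized_value > 0.95

    def test_random_labels_on_one_blob_score_half(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(300, 10))
        labels = rng.choice(list("abcde"), size=300)
        res = silhouette_label(x, labels)
        assert res.normalized_value == pytest.approx(0.5, abs=0.05)

    def test_identical_coordinates_score_half(self):
        x = np.ones((10, 3))
        labels = ["a"] * 5 + ["b"] * 5
        res = silhouette_label(x, labels)
        assert res.normalized_value == 0.5

    def test_singleton_labels_excluded_with_warning(self, rng):
        x = rng.normal(size=(9, 4))
        labels = ["a"] * 4 + ["b"] * 4 + ["solo"]
        with pytest.warns(UserWarning, match="single well"):
            silhouette_label(x, labels)

    def test_mirror_image_invariance(self, rng):
        x = rng.normal(size=(60, 6))
        labels = rng.choice(["a", "b", "c"], size=60)
        res = silhouette_label(x, labels)
        res_neg = silhouette_label(-x, labels)
        assert res.normalized_value == pytest.approx(res_neg.normalized_value,
                                                     abs=1e-12)


class TestSilhouetteBatch:
    def test_interleaved_batches_score_high(self, rng):
        x = np.vstack([rng.normal(size=(60, 5)),
                       rng.normal(size=(60, 5)) + 30.0])
        labels = ["a"] * 60 + ["b"] * 60
        batches = (["x", "y"] * 30) * 2
        res = silhouette_batch(x, batches, labels)
        assert res.normalized_value > 0.9

    def test_separated_batches_score_low(self, rng):
        base = rng.normal(size=(40, 5))
        x = np.vstack([base, base + 50.0])
        labels = (["a"] * 20 + ["b"] * 20) * 2
        batches = ["x"] * 40 + ["y"] * 40
        res = silhouette_batch(x, batches, labels)
        assert res.normalized_value < 0.1

    def test_single_batch_errors(self, rng):
        with pytest.raises(ValueError, match=">= 2 batches"):
            silhouette_batch(rng.normal(size=(10, 3)), ["b"] * 10,
                             ["a"] * 5 + ["c"] * 5)

    def test_label_in_single_batch_skipped(self, rng):
        x = rng.normal(size=(30, 4))
        labels = ["a"] * 10 + ["b"] * 20
        batches = ["x"] * 10 + ["x"] * 10 + ["y"] * 10  # label a only in x
        with pytest.warns(UserWarning, match="skipped"):
            res = silhouette_batch(x, batches, labels)
        assert list(res.details["per_label"]) == ["b"]


class TestGraphConnectivity:
    def test_fully_connected_labels_score_one(self, rng):
        x = rng.normal(size=(20, 3))
        g = build_knn_graph(x, k=19)
        res = graph_connectivity(g, ["a"] * 10 + ["b"] * 10)
        assert res.normalized_value == 1.0

    def test_split_label_scores_half(self, rng):
        # one label split into two far-apart blobs of equal size
        blob = rng.normal(size=(10, 3)) * 0.1
        x = np.vstack([blob, blob + 100.0])
        g = build_knn_graph(x, k=3)
        res = graph_connectivity(g, ["a"] * 20)
        assert res.details["per_label"]["a"] == 0.5

    def test_singleton_labels_contribute_one(self, rng):
        x = rng.normal(size=(8, 2))
        res = graph_connectivity(build_knn_graph(x, k=2),
                                 [f"l{i}" for i in range(8)])
        assert res.normalized_value == 1.0


class TestLisi:
    def test_well_mixed_equal_batches_high(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(600, 20))
        batches = np.array(["a", "b"] * 300)
        res = lisi_score(x, batches, "batch", perplexity=90)
        assert res.normalized_value >= 0.95

    def test_disjoint_batches_score_zero(self, rng):
        x = np.vstack([rng.normal(size=(150, 10)),
                       rng.normal(size=(150, 10)) + 100.0])
        batches = ["a"] * 150 + ["b"] * 150
        res = lisi_score(x, batches, "batch")
        assert res.normalized_value <= 0.02

    def test_pure_compound_clusters_give_clisi_one(self, rng):
        x = np.vstack([rng.normal(size=(60, 5)) * 0.1,
                       rng.normal(size=(60, 5)) * 0.1 + 50.0])
        labels = ["a"] * 60 + ["b"] * 60
        res = lisi_score(x, labels, "label")
        assert res.normalized_value >= 0.98

    def test_single_category_errors(self, rng):
        with pytest.raises(ValueError, match="single category"):
            lisi_score(rng.normal(size=(100, 3)), ["a"] * 100, "batch")

    def test_perplexity_bound(self, rng):
        with pytest.raises(ValueError, match="perplexity"):
            lisi_score(rng.normal(size=(60, 3)), ["a", "b"] * 30, "batch",
                       perplexity=30)

    def test_batch_label_renaming_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(200, 8))
        batches = rng.choice(["a", "b", "c"], size=200)
        renamed = np.array([{"a": "zz", "b": "q", "c": "mm"}[b] for b in batches])
        r1 = lisi_score(x, batches, "batch")
        r2 = lisi_score(x, renamed, "batch")
        assert r1.raw_value == pytest.approx(r2.raw_value, abs=1e-12)


class TestKbet:
    def test_well_mixed_null_close_to_alpha(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(400, 10))
        batches = rng.permutation(np.array(["a", "b"] * 200))
        res = kbet_score(x, batches)
        assert res.normalized_value >= 0.9

    def test_separated_batches_score_zero(self, rng):
        x = np.vstack([rng.normal(size=(100, 5)),
                       rng.normal(size=(100, 5)) + 60.0])
        batches = ["a"] * 100 + ["b"] * 100
        res = kbet_score(x, batches)
        assert res.normalized_value <= 0.05

    def test_neighborhood_smaller_than_batches_errors(self, rng):
        x = rng.normal(size=(60, 3))
        batches = ["a", "b", "c"] * 20
        with pytest.raises(ValueError, match="neighborhood_size"):
            kbet_score(x, batches, neighborhood_size=2)

    def test_batch_permutation_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(200, 6))
        batches = rng.choice(["a", "b"], size=200)
        renamed = np.where(batches == "a", "b", "a")
        r1 = kbet_score(x, batches)
        r2 = kbet_score(x, renamed)
        assert r1.raw_value == pytest.approx(r2.raw_value, abs=1e-12)


class TestLeiden:
    def test_separated_blobs_recovered_exactly(self, rng):
        x = np.vstack([rng.normal(size=(40, 5)),
                       rng.normal(size=(40, 5)) + 30.0,
                       rng.normal(size=(40, 5)) - 30.0])
        labels = ["a"] * 40 + ["b"] * 40 + ["c"] * 40
        ari, nmi = leiden_cluster_scores(x, labels, seed=0)
        assert ari.normalized_value == 1.0
        assert nmi.normalized_value == 1.0

    def test_shuffled_labels_give_zero_ari(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.normal(size=(60, 5)),
                       rng.normal(size=(60, 5)) + 30.0])
        labels = rng.permutation(["a"] * 60 + ["b"] * 60)
        ari, _ = leiden_cluster_scores(x, labels, seed=0)
        assert abs(ari.raw_value) <= 0.05

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(80, 6))
        labels = rng.choice(["a", "b", "c"], size=80)
        a1 = leiden_cluster_scores(x, labels, seed=9)
        a2 = leiden_cluster_scores(x, labels, seed=9)
        assert a1[0].raw_value == a2[0].raw_value
        assert a1[1].raw_value == a2[1].raw_value


class TestAveragePrecision:
    def test_perfect_retrieval(self):
        q = np.array([1.0, 0.0])
        pos = np.array([[1.0, 0.1], [1.0, -0.1]])
        neg = np.array([[-1.0, 0.0], [0.0, 1.0]])
        assert average_precision(q, pos, neg) == 1.0

    def test_positives_at_ranks_1_and_3(self):
        # similarities force ranking pos, neg, pos, neg -> AP = (1 + 2/3)/2
        q = np.array([1.0, 0.0])
        pos = np.array([[1.0, 0.0], [1.0, 1.0]])
        neg = np.array([[1.0, 0.5], [-1.0, 0.0]])
        assert average_precision(q, pos, neg) == pytest.approx(5 / 6)

    def test_positives_ranked_last(self):
        # ranking neg, neg, pos, pos -> AP = (1/3 + 2/4)/2 = 5/12
        q = np.array([1.0, 0.0])
        pos = np.array([[0.0, 1.0], [-0.1, 1.0]])
        neg = np.array([[1.0, 0.0], [1.0, 0.1]])
        assert average_precision(q, pos, neg) == pytest.approx(5 / 12)

    def test_zero_norm_vector_errors(self):
        with pytest.raises(ValueError, match="zero-norm"):
            average_precision(np.array([1.0, 0.0]),
                              np.array([[0.0, 0.0]]),
                              np.array([[1.0, 1.0]]))

    def test_matches_bruteforce_oracle_on_random_rankings(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            n_pos = int(rng.integers(1, 5))
            n_neg = int(rng.integers(1, 6))
            dim = int(rng.integers(2, 5))
            q = rng.normal(size=dim)
            pos = rng.normal(size=(n_pos, dim))
            neg = rng.normal(size=(n_neg, dim))
            got = average_precision(q, pos, neg)
            assert got == pytest.approx(ap_bruteforce(q, pos, neg), abs=1e-12)


def retrieval_meta(compounds, control_types, plates=None):
    n = len(compounds)
    plates = plates or ["p1"] * n
    return pd.DataFrame({
        "source_id": "s1", "batch_id": "b1", "plate_id": plates,
        "well_position": [f"A{i:02d}" for i in range(n)],
        "compound_id": compounds, "control_type": control_types,
    })


class TestMeanAveragePrecision:
    def test_identical_replicates_distinct_compounds_score_one(self):
        x = np.repeat(np.array([[1.0, 0.0], [0.0, 1.0]]), 3, axis=0)
        x = np.vstack([x, [[-1.0, -1.0]] * 2])
        meta = retrieval_meta(["a"] * 3 + ["b"] * 3 + ["DMSO"] * 2,
                              ["treatment"] * 6 + ["negative"] * 2)
        for mode in ("nonrep", "control"):
            res = mean_average_precision(x, meta, negatives_mode=mode)
            assert res.normalized_value == 1.0

    def test_toy_fixture_matches_hand_enumeration(self):
        # 2 compounds x 2 replicates + 2 DMSO; hand-enumerated similarities
        x = np.array([
            [1.0, 0.0],    # a1
            [0.9, 0.1],    # a2
            [0.0, 1.0],    # b1
            [0.1, 0.9],    # b2
            [0.6, 0.6],    # DMSO
            [-1.0, 0.0],   # DMSO
        ])
        meta = retrieval_meta(["a", "a", "b", "b", "DMSO", "DMSO"],
                              ["treatment"] * 4 + ["negative"] * 2)
        res = mean_average_precision(x, meta, negatives_mode="control")
        expected = {}
        for i, lab in [(0, "a"), (1, "a"), (2, "b"), (3, "b")]:
            pos = [j for j in range(4) if meta["compound_id"][j] == lab and j != i]
            expected.setdefault(lab, []).append(
                ap_bruteforce(x[i], x[pos], x[4:]))
        expected_map = np.mean([np.mean(v) for v in expected.values()])
        assert res.raw_value == pytest.approx(expected_map, abs=1e-12)

    def test_pure_noise_matches_random_ranking_expectation(self):
        # one heavily replicated compound (M=51) + 3 plate controls:
        # random AP expectation ~ (M-1)/(M-1+N) = 50/53
        rng = np.random.default_rng(0)
        x = rng.normal(size=(54, 40))
        meta = retrieval_meta(["pc"] * 51 + ["DMSO"] * 3,
                              ["treatment"] * 51 + ["negative"] * 3)
        res = mean_average_precision(x, meta, negatives_mode="control")
        aps = [average_precision(x[i], x[[j for j in range(51) if j != i]],
                                 x[51:]) for i in range(51)]
        se = np.std(aps, ddof=1) / np.sqrt(len(aps))
        assert res.raw_value == pytest.approx(50 / 53, abs=3 * se)

    def test_single_replicate_compounds_excluded_with_warning(self, rng):
        x = rng.normal(size=(5, 3))
        meta = retrieval_meta(["a", "a", "solo", "DMSO", "DMSO"],
                              ["treatment"] * 3 + ["negative"] * 2)
        with pytest.warns(UserWarning, match="single replicate"):
            res = mean_average_precision(x, meta, negatives_mode="control")
        assert set(res.details["per_compound"]) == {"a"}

    def test_nonrep_negatives_come_from_same_plate(self, rng):
        # query's negatives restricted to its own plate's treated wells
        x = rng.normal(size=(8, 4))
        meta = retrieval_meta(
            ["a", "a", "b", "c", "a", "d", "DMSO", "DMSO"],
            ["treatment"] * 6 + ["negative"] * 2,
            plates=["p1"] * 4 + ["p2"] * 2 + ["p1", "p2"],
        )
        with pytest.warns(UserWarning, match="single replicate"):
            res = mean_average_precision(x, meta, negatives_mode="nonrep")
        # oracle for the query at row 0 (plate p1): negs are rows 2, 3
        ap0 = ap_bruteforce(x[0], x[[1, 4]], x[[2, 3]])
        ap1 = ap_bruteforce(x[1], x[[0, 4]], x[[2, 3]])
        ap4 = ap_bruteforce(x[4], x[[0, 1]], x[[5]])
        assert res.details["per_compound"]["a"] == pytest.approx(
            np.mean([ap0, ap1, ap4]), abs=1e-12)


class TestNormalizationBounds:
    def test_all_metrics_in_unit_interval_on_random_input(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(120, 8))
        labels = rng.choice(["a", "b", "c", "d"], size=120)
        batches = rng.choice(["x", "y", "z"], size=120)
        results = [
            silhouette_label(x, labels),
            silhouette_batch(x, batches, labels),
            graph_connectivity(build_knn_graph(x, 10), labels),
            lisi_score(x, batches, "batch"),
            lisi_score(x, labels, "label"),
            kbet_score(x, batches, labels),
            *leiden_cluster_scores(x, labels, seed=0),
        ]
        for r in results:
            assert 0.0 <= r.normalized_value <= 1.0
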