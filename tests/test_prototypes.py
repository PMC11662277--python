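"""Multi-prototype construction and nearest-prototype classification:
k-means correctness against oracles, tie-breaking, persistence."""

import itertools
import json

import numpy as np
import pytest

from protoslide.prototypes import (
    EmptyClassError,
    PrototypeSet,
    PrototypeStoreFieldError,
    PrototypeStoreFormatError,
    PrototypeStoreVersionError,
    SupportSet,
    classify,
    classify_batch,
    compute_prototypes_kmeans,
    compute_prototypes_per_annotation,
    kmeans_fit,
    load_prototypes,
    save_prototypes,
)


def brute_force_two_cluster_means(x):
    """Best 2-partition of <=12 points by exhaustive assignment enumeration."""
    n = x.shape[0]
    best = None
    for bits in itertools.product([0, 1], repeat=n):
        bits = np.asarray(bits)
        if bits.sum() in (0, n):
            continue
        c0 = x[bits == 0].mean(axis=0)
        c1 = x[bits == 1].mean(axis=0)
        inertia = np.sum((x[bits == 0] - c0) ** 2) + np.sum((x[bits == 1] - c1) ** 2)
        if best is None or inertia < best[0]:
            best = (inertia, c0, c1)
    _, c0, c1 = best
    return sorted([c0, c1], key=tuple)


class TestKmeans:
    def test_k1_is_the_mean(self, rng):
        x = rng.normal(size=(40, 6))
        centers, labels, inertia = kmeans_fit(x, 1, seed=0)
        np.testing.assert_allclose(centers[0], x.mean(axis=0), atol=1e-12)
        assert set(labels) == {0}

    def test_recovers_planted_two_clusters_exactly(self, rng):
        for trial in range(5):
            x = np.concatenate(
                [rng.normal(0, 0.05, (6, 2)), rng.normal(5, 0.05, (6, 2))]
            )
            centers, _, _ = kmeans_fit(x, 2, seed=trial)
            expected = brute_force_two_cluster_means(x)
            got = sorted([centers[0], centers[1]], key=tuple)
            np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_matches_sklearn_inertia_on_random_data(self, rng):
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        x = rng.normal(size=(60, 5))
        _, _, inertia = kmeans_fit(x, 4, seed=1, n_restarts=10)
        sk = sklearn_cluster.KMeans(n_clusters=4, n_init=10, random_state=1).fit(x)
        assert inertia == pytest.approx(sk.inertia_, rel=0.02)

    def test_centers_are_means_of_their_members(self, rng):
        x = rng.normal(size=(30, 3))
        centers, labels, _ = kmeans_fit(x, 3, seed=0)
        for j in range(centers.shape[0]):
            np.testing.assert_allclose(centers[j], x[labels == j].mean(axis=0), atol=1e-9)

    def test_k_reduced_when_fewer_distinct_points(self):
        x = np.array([[1.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        centers, _, _ = kmeans_fit(x, 5, seed=0)
        assert centers.shape[0] == 2


class TestComputePrototypes:
    def test_k1_prototype_is_componentwise_mean(self, rng):
        supports = SupportSet({"a": rng.normal(size=(15, 4)), "b": rng.normal(size=(9, 4))})
        protos = compute_prototypes_kmeans(supports, 1, seed=0, embedder_id="e")
        np.testing.assert_allclose(
            protos.prototypes["a"][0], supports.vectors["a"].mean(axis=0), atol=1e-12
        )
        assert protos.k_used == {"a": 1, "b": 1}

    def test_requested_k_prototypes_returned(self, rng):
        supports = SupportSet({"a": rng.normal(size=(100, 8))})
        protos = compute_prototypes_kmeans(supports, 3, seed=0, embedder_id="e")
        assert protos.prototypes["a"].shape == (3, 8)
        assert protos.n_supports["a"] == 100

    def test_empty_class_raises_naming_the_class(self):
        with pytest.raises(EmptyClassError, match="necrosis"):
            SupportSet({"necrosis": np.zeros((0, 4))})

    def test_per_annotation_prototypes_one_per_annotation(self, rng):
        vecs = rng.normal(size=(30, 4))
        ids = [f"ann{i // 10}" for i in range(30)]
        supports = SupportSet({"a": vecs}, annotation_ids={"a": ids})
        protos = compute_prototypes_per_annotation(supports, embedder_id="e")
        assert protos.prototypes["a"].shape == (3, 4)
        np.testing.assert_allclose(protos.prototypes["a"][0], vecs[:10].mean(axis=0))

    def test_per_annotation_single_support_is_that_vector(self, rng):
        v = rng.normal(size=(1, 4))
        supports = SupportSet({"a": v}, annotation_ids={"a": ["only"]})
        protos = compute_prototypes_per_annotation(supports, embedder_id="e")
        np.testing.assert_allclose(protos.prototypes["a"][0], v[0])

    def test_one_annotation_per_class_equals_kmeans_k1(self, rng):
        vecs = rng.normal(size=(12, 5))
        supports = SupportSet({"a": vecs}, annotation_ids={"a": ["x"] * 12})
        by_ann = compute_prototypes_per_annotation(supports, embedder_id="e")
        by_kmeans = compute_prototypes_kmeans(supports, 1, seed=0, embedder_id="e")
        np.testing.assert_allclose(
            by_ann.prototypes["a"], by_kmeans.prototypes["a"], atol=1e-12
        )

    def test_missing_annotation_ids_error(self, rng):
        supports = SupportSet({"a": rng.normal(size=(5, 3))})
        with pytest.raises(ValueError, match="annotation"):
            compute_prototypes_per_annotation(supports, embedder_id="e")


def random_prototype_set(rng, d, n_classes=4, max_k=3):
    return PrototypeSet(
        embedder_id="test-embedder",
        prototypes={
            f"class_{i}": rng.normal(size=(rng.integers(1, max_k + 1), d))
            for i in range(n_classes)
        },
    )


class TestClassify:
    def test_query_on_a_prototype_has_zero_distance(self, rng):
        protos = random_prototype_set(rng, 6)
        q = protos.prototypes["class_2"][0]
        result = classify(q, protos)
        assert result.label == "class_2"
        assert result.distances["class_2"] == pytest.approx(0.0, abs=1e-12)

    def test_single_class_always_wins(self, rng):
        protos = PrototypeSet(embedder_id="e", prototypes={"only": rng.normal(size=(2, 3))})
        assert classify(rng.normal(size=3), protos).label == "only"

    def test_confidences_sum_to_one(self, rng):
        protos = random_prototype_set(rng, 5)
        result = classify(rng.normal(size=5), protos)
        assert sum(result.confidences.values()) == pytest.approx(1.0, abs=1e-6)
        assert result.label == max(result.confidences, key=result.confidences.get)

    def test_matches_exhaustive_scan(self, rng):
        protos = random_prototype_set(rng, 4)
        queries = rng.normal(size=(200, 4))
        labels, dists = classify_batch(queries, protos)
        for i, q in enumerate(queries):
            best_label, best_d = None, np.inf
            for label in sorted(protos.prototypes):
                for p in protos.prototypes[label]:
                    d = float(np.sum((q - p) ** 2))
                    if d < best_d - 1e-15:
                        best_label, best_d = label, d
            assert labels[i] == best_label
            assert dists[i].min() == pytest.approx(best_d, rel=1e-9)

    def test_exact_tie_breaks_lexicographically(self):
        protos = PrototypeSet(
            embedder_id="e",
            prototypes={"b": np.array([[1.0, 0.0]]), "a": np.array([[-1.0, 0.0]])},
        )
        assert classify(np.zeros(2), protos).label == "a"

    def test_dimension_mismatch_rejected(self, rng):
        protos = random_prototype_set(rng, 4)
        with pytest.raises(ValueError, match="dim"):
            classify(np.zeros(5), protos)

    def test_l2_normalized_distance_ignores_vector_magnitude(self):
        # prototype directions at 0 and 90 degrees; the query points almost
        # along class b but with a huge norm: raw distance prefers the
        # small-norm prototype, normalized distance prefers the direction
        protos = PrototypeSet(
            embedder_id="e",
            prototypes={"a": np.array([[1.0, 0.0]]), "b": np.array([[0.0, 1.0]])},
        )
        query = np.array([5.0, 100.0])
        raw = classify(query, protos)
        normed = classify(query, protos, l2_normalize=True)
        assert normed.label == "b"
        assert normed.distances["b"] < raw.distances["b"]
        # on the unit sphere distances are bounded by 4
        assert max(normed.distances.values()) <= 4.0

    def test_moving_toward_nearest_prototype_never_increases_distance(self, rng):
        protos = random_prototype_set(rng, 3)
        q = rng.normal(size=3)
        result = classify(q, protos)
        target = min(
            (p for p in protos.prototypes[result.label]),
            key=lambda p: np.sum((q - p) ** 2),
        )
        prev = result.distances[result.label]
        for t in np.linspace(0, 1, 7):
            moved = classify((1 - t) * q + t * target, protos)
            assert moved.distances[result.label] <= prev + 1e-12
            prev = moved.distances[result.label]


class TestPersistence:
    def test_round_trip_is_bit_exact(self, rng, tmp_path):
        protos = random_prototype_set(rng, 7)
        path = tmp_path / "protos.json"
        save_prototypes(protos, path)
        loaded = load_prototypes(path)
        assert loaded.embedder_id == protos.embedder_id
        for label in protos.classes:
            assert np.array_equal(loaded.prototypes[label], protos.prototypes[label])

    def test_missing_embedder_id_raises_dedicated_error(self, rng, tmp_path):
        protos = random_prototype_set(rng, 3)
        path = tmp_path / "protos.json"
        save_prototypes(protos, path)
        payload = json.loads(path.read_text())
        del payload["embedder_id"]
        path.write_text(json.dumps(payload))
        with pytest.raises(PrototypeStoreFieldError):
            load_prototypes(path)

    def test_version_mismatch_raises_dedicated_error(self, rng, tmp_path):
        protos = random_prototype_set(rng, 3)
        path = tmp_path / "protos.json"
        save_prototypes(protos, path)
        payload = json.loads(path.read_text())
        payload["version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(PrototypeStoreVersionError):
            load_prototypes(path)

    def test_malformed_json_raises_dedicated_error(self, tmp_path):
        path = tmp_path / "protos.json"
        path.write_text("{not json")
        with pytest.raises(PrototypeStoreFormatError):
            load_prototypes(path)

    def test_cross_process_replay_reproduces_predictions(self, rng, tmp_path):
        import subprocess
        import sys

        protos = random_prototype_set(rng, 5)
        store = tmp_path / "protos.json"
        save_prototypes(protos, store)
        queries = rng.normal(size=(50, 5))
        np.save(tmp_path / "queries.npy", queries)
        script = (
            "import numpy as np, sys, json\n"
            "from protoslide.prototypes import load_prototypes, classify_batch\n"
            f"protos = load_prototypes({str(store)!r})\n"
            f"q = np.load({str(tmp_path / 'queries.npy')!r})\n"
            "labels, dists = classify_batch(q, protos)\n"
            "print(json.dumps([list(labels), dists.tolist()]))\n"
        )
        out = subprocess.run(
            [sys.executable, "-c", script], capture_output=True, text=True, check=True
        )
        other_labels, other_dists = json.loads(out.stdout)
        labels, dists = classify_batch(queries, protos)
        assert list(labels) == other_labels
        np.testing.assert_array_equal(dists, np.asarray(other_dists))
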