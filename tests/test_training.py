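"""Episode sampling, the prototypical loss and its gradients, the training
loop's determinism, and checkpoint selection."""

import numpy as np
import pandas as pd
import pytest

from protoslide.embedding import build_reference_backbone
from protoslide.training import (
    EpisodeSpec,
    TrainingConfig,
    TrainingSet,
    episode_loss,
    sample_episode,
    select_best_checkpoint,
    train,
)
from protoslide.training import _prototypical_loss_from_embeddings


def make_training_set(rng, n_classes=5, per_class=30, size=16):
    patches = rng.integers(0, 256, (n_classes * per_class, size, size, 3), dtype=np.uint8)
    labels = np.repeat([f"class_{i}" for i in range(n_classes)], per_class)
    return TrainingSet(patches, labels)


class TestEpisodeSpec:
    def test_valid_paper_style_setting(self):
        spec = EpisodeSpec(nc=3, ns=20, nq=5, k_ep=3)
        assert (spec.nc, spec.ns, spec.nq, spec.k_ep) == (3, 20, 5, 3)

    @pytest.mark.parametrize("kwargs", [
        dict(nc=0, ns=5, nq=1),
        dict(nc=2, ns=2, nq=1, k_ep=3),
        dict(nc=2, ns=5, nq=0),
    ])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EpisodeSpec(**kwargs)


class TestSampleEpisode:
    def test_three_way_twenty_shot_counts(self, rng):
        ts = make_training_set(rng, n_classes=7, per_class=30)
        episode = sample_episode(ts, EpisodeSpec(nc=3, ns=20, nq=5, k_ep=3), rng)
        assert len(episode.classes) == 3
        assert episode.support_x.shape[0] == 60
        assert episode.query_x.shape[0] == 15

    def test_all_classes_appear_once_when_nc_equals_c(self, rng):
        ts = make_training_set(rng, n_classes=4)
        episode = sample_episode(ts, EpisodeSpec(nc=4, ns=3, nq=2), rng)
        assert sorted(episode.classes) == sorted(ts.classes)

    def test_supports_and_queries_disjoint_across_many_episodes(self, rng):
        ts = make_training_set(rng, n_classes=5, per_class=12)
        spec = EpisodeSpec(nc=3, ns=5, nq=4)
        for _ in range(300):
            ep = sample_episode(ts, spec, rng)
            assert not set(ep.support_indices) & set(ep.query_indices)
            assert len(set(ep.support_indices)) == len(ep.support_indices)

    def test_too_few_eligible_classes_raises(self, rng):
        ts = make_training_set(rng, n_classes=2, per_class=5)
        with pytest.raises(ValueError, match="eligible"):
            sample_episode(ts, EpisodeSpec(nc=3, ns=3, nq=2), rng)

    def test_deterministic_under_fixed_rng(self, rng):
        ts = make_training_set(rng, n_classes=5)
        spec = EpisodeSpec(nc=3, ns=4, nq=2)
        a = sample_episode(ts, spec, np.random.default_rng(77))
        b = sample_episode(ts, spec, np.random.default_rng(77))
        assert a.classes == b.classes
        assert np.array_equal(a.support_indices, b.support_indices)
        assert np.array_equal(a.query_indices, b.query_indices)


class TestLossAnalytics:
    """Closed-form values of the prototypical softmax cross-entropy."""

    def test_query_on_own_prototype_far_from_others_saturates(self):
        spec = EpisodeSpec(nc=2, ns=1, nq=1, k_ep=1)
        s_emb = np.array([[0.0], [20.0]])
        q_emb = np.array([[0.0], [20.0]])  # each query sits on its class prototype
        loss, _, _ = _prototypical_loss_from_embeddings(s_emb, q_emb, spec, 0)
        assert loss < 1e-8

    def test_equidistant_two_way_query_gives_ln2(self):
        spec = EpisodeSpec(nc=2, ns=1, nq=1, k_ep=1)
        s_emb = np.array([[-1.0], [1.0]])
        q_emb = np.array([[0.0], [0.0]])
        loss, _, _ = _prototypical_loss_from_embeddings(s_emb, q_emb, spec, 0)
        assert loss == pytest.approx(np.log(2.0), abs=1e-6)

    def test_hand_computed_distance_pair(self):
        # class-0 query at squared distances (1.0, 3.0), true class nearer:
        # its loss term is -log(e^-1 / (e^-1 + e^-3)) = log(1 + e^-2);
        # the class-1 query sits on its prototype with distances (3, 0),
        # contributing log(1 + e^-3); the episode loss is their mean
        spec = EpisodeSpec(nc=2, ns=1, nq=1, k_ep=1)
        s_emb = np.array([[0.0], [1.0 + np.sqrt(3.0)]])
        q_emb = np.array([[1.0], [1.0 + np.sqrt(3.0)]])
        loss, _, _ = _prototypical_loss_from_embeddings(s_emb, q_emb, spec, 0)
        d_other = (1.0 + np.sqrt(3.0)) ** 2  # class-1 query to class-0 prototype
        expected = (np.log(1.0 + np.exp(-2.0)) + np.log(1.0 + np.exp(-d_other))) / 2.0
        assert loss == pytest.approx(expected, abs=1e-6)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        embedder = build_reference_backbone(16, 6, init_seed=2, dtype=np.float64)
        ts = make_training_set(rng, n_classes=3, per_class=8, size=16)
        spec = EpisodeSpec(nc=3, ns=4, nq=2, k_ep=2)
        episode = sample_episode(ts, spec, rng)
        _, grads = episode_loss(episode, embedder, spec, kmeans_seed=5, want_grads=True)
        params = embedder.net.params()
        eps = 1e-6
        checked = 0
        for p, g in zip(params, grads):
            flat = p.reshape(-1)
            for k in rng.choice(flat.size, size=min(2, flat.size), replace=False):
                orig = flat[k]
                flat[k] = orig + eps
                up = episode_loss(episode, embedder, spec, kmeans_seed=5)
                flat[k] = orig - eps
                down = episode_loss(episode, embedder, spec, kmeans_seed=5)
                flat[k] = orig
                fd = (up - down) / (2 * eps)
                assert fd == pytest.approx(g.reshape(-1)[k], rel=1e-3, abs=1e-9)
                checked += 1
        assert checked >= 5

    def test_single_gradient_step_reduces_episode_loss(self, rng):
        from protoslide.nn import Adam

        embedder = build_reference_backbone(16, 8, init_seed=1)
        ts = make_training_set(rng, n_classes=3, per_class=10, size=16)
        spec = EpisodeSpec(nc=3, ns=5, nq=3, k_ep=2)
        episode = sample_episode(ts, spec, rng)
        before, grads = episode_loss(episode, embedder, spec, kmeans_seed=0, want_grads=True)
        Adam(embedder.net.params(), lr=1e-3).step(grads)
        after = episode_loss(episode, embedder, spec, kmeans_seed=0)
        assert after < before


class TestTrainingConfig:
    def test_corel_slot_is_reserved(self):
        with pytest.raises(NotImplementedError, match="corel"):
            TrainingConfig(loss="corel")

    def test_unknown_loss_rejected(self):
        with pytest.raises(ValueError, match="unknown loss"):
            TrainingConfig(loss="triplet")

    def test_clinical_scale_configuration_is_expressible(self):
        # the full-scale recipe: 20 epochs x 28,000 episodes, 3-way 20-shot,
        # lr 1e-5 with exponential decay — must validate without truncation
        cfg = TrainingConfig(epochs=20, episodes_per_epoch=28000, learning_rate=1e-5)
        spec = EpisodeSpec(nc=3, ns=20, nq=5, k_ep=3)
        assert cfg.epochs * cfg.episodes_per_epoch == 560_000
        assert spec.ns >= spec.k_ep


class TestSelectBestCheckpoint:
    def test_monotone_decreasing_selects_last(self):
        assert select_best_checkpoint([0.9, 0.5, 0.3, 0.1]) == 4

    def test_middle_minimum(self):
        assert select_best_checkpoint([0.9, 0.4, 0.7]) == 2

    def test_tie_selects_earliest(self):
        assert select_best_checkpoint([0.5, 0.5]) == 1

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            select_best_checkpoint([])

    def test_accepts_training_log_frame(self):
        log = pd.DataFrame({"epoch": [1, 2], "val_loss": [0.3, 0.2]})
        assert select_best_checkpoint(log) == 2


@pytest.fixture(scope="module")
def tiny_run():
    rng = np.random.default_rng(5)
    ts = make_training_set(rng, n_classes=3, per_class=12, size=16)
    val = make_training_set(np.random.default_rng(6), n_classes=3, per_class=8, size=16)
    cfg = TrainingConfig(
        epochs=2, episodes_per_epoch=4, learning_rate=1e-3, embed_dim=8,
        val_episodes=3,
    )
    spec = EpisodeSpec(nc=3, ns=4, nq=2, k_ep=2)
    return ts, val, cfg, spec


class TestTrainLoop:
    def test_log_shape_and_lr_decay(self, tiny_run):
        ts, val, cfg, spec = tiny_run
        result = train(ts, val, cfg, spec)
        assert list(result.log.columns) == ["epoch", "train_loss", "val_loss", "lr"]
        assert len(result.log) == cfg.epochs
        assert result.log["lr"].iloc[1] == pytest.approx(
            cfg.learning_rate * cfg.lr_decay
        )

    def test_identical_seeds_reproduce_the_loss_trajectory(self, tiny_run):
        ts, val, cfg, spec = tiny_run
        a = train(ts, val, cfg, spec)
        b = train(ts, val, cfg, spec)
        np.testing.assert_allclose(
            a.log[["train_loss", "val_loss"]], b.log[["train_loss", "val_loss"]], atol=1e-6
        )
        assert a.embedder.weight_hash() == b.embedder.weight_hash()

    def test_returned_embedder_carries_best_epoch_weights(self, tiny_run):
        ts, val, cfg, spec = tiny_run
        result = train(ts, val, cfg, spec)
        assert result.best_epoch == int(result.log["val_loss"].idxmin()) + 1
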