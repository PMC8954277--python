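"""Network components: sampling/grouping oracles, set abstraction, heads, loss."""

import numpy as np
import pytest

from bios2net.nn import (
    BioS2Net,
    ConfigError,
    ModelConfig,
    Tensor,
    combined_loss,
    farthest_point_sample,
    group_neighbors,
)
from bios2net.nn import autograd as ag
from bios2net.nn.layers import Inception1d
from bios2net.nn.model import SALayerConfig, SetAbstraction


def brute_force_fps(coords, m):
    """Independent greedy reference: full distance matrix + explicit scan."""
    n = len(coords)
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    chosen = [0]
    for _ in range(m - 1):
        best_i, best_v = None, -1.0
        for i in range(n):
            if i in chosen:
                continue
            v = min(d[i, j] for j in chosen)
            if v > best_v + 1e-12:
                best_i, best_v = i, v
        chosen.append(best_i)
    return np.array(chosen)


def brute_force_knn(coords, centroids, k):
    out = []
    for c in centroids:
        d = [(np.linalg.norm(coords[i] - coords[c]), i)
             for i in range(len(coords))]
        d.sort()
        out.append([i for _, i in d[:k]])
    return np.array(out)


class TestFarthestPointSampling:
    def test_collinear_points_pick_extremes(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        assert set(farthest_point_sample(coords, 2)) == {0, 3}

    def test_m_equals_n_returns_all(self, rng):
        coords = rng.normal(size=(7, 3))
        assert set(farthest_point_sample(coords, 7)) == set(range(7))

    def test_square_corners_before_center(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                           [0.5, 0.5, 0]])
        assert set(farthest_point_sample(coords, 4)) == {0, 1, 2, 3}

    def test_m_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            farthest_point_sample(rng.normal(size=(3, 3)), 4)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 51))
            m = int(rng.integers(1, n + 1))
            coords = rng.normal(size=(n, 3))
            np.testing.assert_array_equal(farthest_point_sample(coords, m),
                                          brute_force_fps(coords, m))


class TestGroupNeighbors:
    def test_k1_groups_self(self, rng):
        coords = rng.normal(size=(10, 3))
        centroids = np.array([2, 5, 7])
        groups = group_neighbors(coords, centroids, 1)
        np.testing.assert_array_equal(groups[:, 0], centroids)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 51))
            k = int(rng.integers(1, n + 1))
            coords = rng.normal(size=(n, 3))
            centroids = rng.choice(n, size=min(4, n), replace=False)
            np.testing.assert_array_equal(
                group_neighbors(coords, centroids, k),
                brute_force_knn(coords, centroids, k))

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            group_neighbors(rng.normal(size=(4, 3)), np.array([0]), 5)


class TestSetAbstraction:
    def _level(self, rng_seed=0):
        cfg = SALayerConfig(4, 5, (8, 16))
        return SetAbstraction(6, cfg, np.random.default_rng(rng_seed))

    def test_output_shape_is_s_by_f(self, rng):
        level = self._level()
        coords = rng.normal(size=(2, 20, 3))
        feats = Tensor(rng.normal(size=(2, 20, 6)).astype(np.float32))
        out = level(coords, feats)
        assert out.centroid_features.shape == (2, 4, 16)
        assert out.centroid_coords.shape == (2, 4, 3)
        assert out.centroid_source_indices.shape == (2, 4)

    def test_within_region_permutation_invariance_bitwise(self, rng):
        level = self._level()
        level.set_training(False)
        coords = rng.normal(size=(1, 20, 3))
        feats_data = rng.normal(size=(1, 20, 6)).astype(np.float32)
        out1 = level(coords, Tensor(feats_data))

        # permute points *within* one grouping region: swap two member points
        # of the cloud that fall in the same region, keeping geometry fixed
        groups = group_neighbors(coords[0], out1.centroid_source_indices[0], 5)
        a, b = groups[0][1], groups[0][2]
        perm = np.arange(20)
        perm[[a, b]] = perm[[b, a]]
        out2 = level(coords[:, perm], Tensor(feats_data[:, perm]))
        # same geometry, renamed points: pooled region features identical
        assert (out1.centroid_features.data == out2.centroid_features.data).all()

    def test_identical_members_pool_to_single_point_output(self, rng):
        level = self._level()
        level.set_training(False)
        coords = np.tile(rng.normal(size=(1, 1, 3)), (1, 8, 1))
        feats_data = np.tile(rng.normal(size=(1, 1, 6)), (1, 8, 1)).astype(np.float32)
        cfg = level.config
        out = level(coords, Tensor(feats_data))
        # all members identical -> max pool equals the per-point MLP output
        region = ag.concat([Tensor(np.zeros((1, 4, 1, 3), np.float32)),
                            Tensor(feats_data[:, :4][:, :, None, :])], axis=-1)
        single = level.mlp(region)
        np.testing.assert_allclose(out.centroid_features.data,
                                   single.data[:, :, 0, :], atol=1e-6)


class TestSequenceExtractor:
    def test_output_width_is_input_plus_branches(self, rng):
        cfg = ModelConfig.reduced(3)
        model = BioS2Net(cfg, seed=0)
        x = Tensor(rng.normal(size=(1, 256, 53)).astype(np.float32))
        feats_width = 53 + 4 * cfg.seq_filters_per_branch
        assert model.feat_dim == feats_width
        out = model.seq(x)
        assert out.shape == (1, 256, 4 * cfg.seq_filters_per_branch)

    def test_zeroed_weights_give_zero_features(self, rng):
        block = Inception1d(5, 4, np.random.default_rng(0))
        for p in block.parameters():
            p.data[...] = 0.0
        x = Tensor(rng.normal(size=(2, 10, 5)).astype(np.float32))
        assert not block(x).data.any()

    def test_row_permutation_changes_output(self, rng):
        cfg = ModelConfig.reduced(3)
        model = BioS2Net(cfg, seed=0)
        model.set_training(False)
        x = rng.normal(size=(1, 256, 53)).astype(np.float32)
        out1 = model.seq(Tensor(x)).data
        perm = np.random.default_rng(3).permutation(256)
        out2 = model.seq(Tensor(x[:, perm])).data
        assert not np.allclose(out1, out2[:, np.argsort(perm)], atol=1e-5)


@pytest.fixture(scope="module")
def model_and_out():
    cfg = ModelConfig.reduced(3)
    model = BioS2Net(cfg, seed=0)
    model.set_training(False)
    rng = np.random.default_rng(0)
    x = Tensor(rng.normal(size=(2, 256, 53)).astype(np.float32))
    return cfg, model, model(x)


class TestFullModel:
    def test_probabilities_sum_to_one(self, model_and_out):
        _, _, out = model_and_out
        np.testing.assert_allclose(out["probabilities"].sum(axis=1), 1.0,
                                   atol=1e-6)

    def test_global_vector_is_struct_plus_temporal(self, model_and_out):
        cfg, model, out = model_and_out
        assert out["struct_vector"].shape[1] == cfg.sa_layers[-1].mlp_widths[-1]
        assert out["global_vector"].shape[1] == (
            out["struct_vector"].shape[1] + out["temporal_vector"].shape[1])

    def test_temporal_centroids_sorted_by_source_index(self, model_and_out):
        _, _, out = model_and_out
        assert (np.diff(out["temporal_source_indices"], axis=1) >= 0).all()

    def test_pooling_arithmetic_before_gap(self, model_and_out):
        cfg, _, out = model_and_out
        expected = cfg.sa_layers[0].n_centroids // 2 ** cfg.temporal_n_modules
        assert out["temporal_rows_before_gap"] == expected

    def test_rotating_coordinates_changes_output(self, rng):
        cfg = ModelConfig.reduced(3)
        model = BioS2Net(cfg, seed=0)
        model.set_training(False)
        x = rng.normal(size=(1, 256, 53)).astype(np.float32)
        out1 = model(Tensor(x.copy()))["main_logits"].data
        from bios2net.sampling import rotation_matrix
        x2 = x.copy()
        x2[0, :, :3] = x2[0, :, :3] @ rotation_matrix(0.3, 0.7, 1.1).T.astype(np.float32)
        out2 = model(Tensor(x2))["main_logits"].data
        assert not np.allclose(out1, out2, atol=1e-5)

    def test_reversed_centroid_order_changes_temporal_vector(self, rng):
        cfg = ModelConfig.reduced(3)
        model = BioS2Net(cfg, seed=0)
        model.set_training(False)
        x = rng.normal(size=(1, 128, 149)).astype(np.float32)
        v1 = model.temporal(Tensor(x)).data
        v2 = model.temporal(Tensor(x[:, ::-1].copy())).data
        assert not np.allclose(v1, v2, atol=1e-5)

    @pytest.mark.parametrize("n_points", [256, 512, 1024])
    def test_forward_pass_finite_for_random_inputs(self, n_points):
        cfg = ModelConfig.reduced(
            3, n_points=n_points,
            sa_layers=(SALayerConfig(64, 8, (16, 32)),
                       SALayerConfig(16, 8, (32, 64)),
                       SALayerConfig(1, None, (64, 64), last_layer_global=True)),
            seq_filters_per_branch=4, temporal_filters_per_branch=4,
            head_widths=(32,))
        model = BioS2Net(cfg, seed=0)
        rng = np.random.default_rng(n_points)
        for _ in range(5):
            x = Tensor((rng.normal(size=(1, n_points, 53)) *
                        rng.uniform(0.1, 10)).astype(np.float32))
            out = model(x)
            assert np.isfinite(out["main_logits"].data).all()
            assert np.isfinite(out["struct_logits"].data).all()
            assert np.isfinite(out["temporal_logits"].data).all()


class TestAblation:
    def test_temporal_off_uses_structure_vector_alone(self, rng):
        cfg = ModelConfig.reduced(3, temporal_on=False)
        model = BioS2Net(cfg, seed=0)
        model.set_training(False)
        x = Tensor(rng.normal(size=(1, 256, 53)).astype(np.float32))
        out = model(x)
        assert out["temporal_logits"] is None
        assert out["global_vector"].shape[1] == out["struct_vector"].shape[1]

    def test_structure_off_temporal_gets_raw_and_seq_only(self, rng):
        cfg = ModelConfig.reduced(3, structure_on=False)
        model = BioS2Net(cfg, seed=0)
        model.set_training(False)
        out = model(Tensor(rng.normal(size=(1, 256, 53)).astype(np.float32)))
        assert out["struct_logits"] is None
        assert out["global_vector"].shape[1] == out["temporal_vector"].shape[1]

    def test_both_components_off_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig.reduced(3, structure_on=False, temporal_on=False)

    def test_sequence_off_shrinks_feature_width(self):
        cfg = ModelConfig.reduced(3, sequence_on=False)
        model = BioS2Net(cfg, seed=0)
        assert model.feat_dim == 53


class TestCombinedLoss:
    def _logits_with_ce(self, ce, n_classes=2):
        """Two-class logits whose cross-entropy for label 0 is exactly ce."""
        p = np.exp(-ce)
        return np.log(np.array([[p, 1 - p]]))

    def test_perfect_predictions_give_zero_loss(self):
        hot = Tensor(np.array([[50.0, 0.0, 0.0]]))
        labels = np.array([0])
        loss = combined_loss(hot, hot, hot, labels)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_predictions_give_log_c(self):
        for c in (2, 3, 10):
            uniform = Tensor(np.zeros((4, c)))
            labels = np.zeros(4, dtype=int)
            loss = combined_loss(uniform, uniform, uniform, labels)
            assert float(loss.data) == pytest.approx(np.log(c), rel=1e-9)

    def test_weighted_sum_of_head_cross_entropies(self):
        labels = np.array([0])
        l1 = Tensor(self._logits_with_ce(1.0))
        l2 = Tensor(self._logits_with_ce(2.0))
        l4 = Tensor(self._logits_with_ce(4.0))
        loss = combined_loss(l1, l2, l4, labels)
        assert float(loss.data) == pytest.approx(
            0.5 * 1.0 + 0.35 * 2.0 + 0.15 * 4.0, rel=1e-9)

    def test_disabled_heads_redistribute_weight(self):
        labels = np.array([0])
        l2 = Tensor(self._logits_with_ce(2.0))
        loss = combined_loss(l2, None, l2, labels)
        # weights 0.5 and 0.15 renormalized -> still CE = 2
        assert float(loss.data) == pytest.approx(2.0, rel=1e-9)

    def test_gradient_matches_numeric(self, rng):
        logits = rng.normal(size=(3, 4))
        labels = np.array([1, 0, 3])
        t = Tensor(logits.copy(), requires_grad=True)
        combined_loss(t, None, None, labels).backward()

        eps = 1e-6
        num = np.zeros_like(logits)
        for i in range(3):
            for j in range(4):
                for sign in (1, -1):
                    logits[i, j] += sign * eps
                    t2 = Tensor(logits.copy())
                    v = float(combined_loss(t2, None, None, labels).data)
                    num[i, j] += sign * v / (2 * eps)
                    logits[i, j] -= sign * eps
        np.testing.assert_allclose(t.grad, num, atol=1e-4)


class TestConfigValidation:
    def test_loss_weights_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            ModelConfig.reduced(3, loss_weights=(0.5, 0.4, 0.2))

    def test_exactly_three_sa_layers(self):
        with pytest.raises(ConfigError):
            ModelConfig.reduced(3, sa_layers=(
                SALayerConfig(64, 8, (16,)),
                SALayerConfig(1, None, (16,), last_layer_global=True)))

    def test_last_layer_single_centroid(self):
        with pytest.raises(ConfigError):
            ModelConfig.reduced(3, sa_layers=(
                SALayerConfig(64, 8, (16,)),
                SALayerConfig(16, 8, (16,)),
                SALayerConfig(4, None, (16,), last_layer_global=True)))

    def test_default_config_keeps_512_centroids_for_temporal(self):
        cfg = ModelConfig.default(5)
        assert cfg.sa_layers[0].n_centroids == 512

    def test_determinism_same_seed_same_initial_weights(self):
        m1 = BioS2Net(ModelConfig.reduced(3), seed=9)
        m2 = BioS2Net(ModelConfig.reduced(3), seed=9)
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            assert (p1.data == p2.data).all()
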