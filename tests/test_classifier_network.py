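"""Full classifier: probability law, fusion, parameter audit, checkpoints."""

import time

import numpy as np
import pytest

from msstgcn import preprocessing as pp
from msstgcn import skeleton_graph as sg
from msstgcn.classifier_network import (
    DEFAULT_CHANNEL_PLAN,
    FusionConfig,
    ModelConfig,
    bone_stream,
    build_model,
    count_parameters,
    fuse_scores,
    load_checkpoint,
    save_checkpoint,
)

TINY = ModelConfig(
    num_classes=3, num_layers=2, channel_plan=(4, 4), gamma=2, dropout=0.0
)


def closed_form_parameter_count(config: ModelConfig) -> int:
    """Layer-by-layer audit of the trainable scalar count, from first principles."""
    v = sg.build_layout(config.layout_name).num_joints
    total = 2 * config.in_channels * v * config.num_persons  # input BN gamma+beta
    c_prev = config.in_channels
    for i, c in enumerate(config.channel_plan):
        total += 3 * c_prev * c + 3 * v * v + c  # gcn transforms, masks, bias
        total += 2 * c  # block BN
        if config.multiscale:
            half = c // 2
            total += config.gamma * c * half + half  # short branch
            total += 2 * config.gamma * c * half + half  # long branch
        else:
            total += config.gamma * c * c + c
        total += 2 * c  # tcn BN
        if i > 0 and (c_prev != c or config.strides[i] != 1):
            total += c_prev * c + c  # 1x1 residual
        c_prev = c
    total += c_prev * config.num_classes + config.num_classes  # head
    return total


class TestModelConfig:
    def test_plan_length_must_match_layers(self):
        with pytest.raises(ValueError, match="entries"):
            ModelConfig(num_classes=4, num_layers=3, channel_plan=(8, 8))

    def test_odd_channels_rejected_in_multiscale(self):
        with pytest.raises(ValueError, match="even"):
            ModelConfig(num_classes=4, num_layers=2, channel_plan=(6, 7))

    def test_round_trips_through_dict(self):
        cfg = ModelConfig(num_classes=5, gamma=3)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


class TestForward:
    def test_rows_are_probability_vectors(self, rng):
        model = build_model(TINY, seed=0)
        probs = model(rng.standard_normal((4, 3, 8, 20, 2)).astype(np.float32))
        assert probs.shape == (4, 3)
        assert np.all(probs >= 0.0) and np.all(probs <= 1.0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_person_equals_single_person(self, rng):
        """Identical person slots give the same prediction as one copy."""
        from dataclasses import replace

        model = build_model(TINY, seed=0)
        model.eval()
        one = rng.standard_normal((3, 3, 8, 20, 1)).astype(np.float32)
        two = np.repeat(one, 2, axis=4)
        p2 = model(two)
        model1 = build_model(replace(TINY, num_persons=1), seed=0)
        model1.eval()
        p1 = model1(one)
        np.testing.assert_allclose(p2, p1, atol=1e-5)

    def test_default_model_runs_batch_quickly(self, rng):
        model = build_model(ModelConfig(num_classes=4), seed=0)
        model.eval()
        batch = rng.standard_normal((4, 3, 25, 20, 2)).astype(np.float32)
        model(batch)  # warm-up pass
        start = time.perf_counter()
        model(batch)
        assert time.perf_counter() - start < 1.0

    def test_translation_invariance_through_centering(self, rng, layout20):
        """Predictions ignore a constant offset removed by coordinate centering."""
        model = build_model(TINY, seed=0)
        model.eval()
        data = rng.standard_normal((3, 8, 20, 2)).astype(np.float32)
        seq = pp.SkeletonSequence(data, channels=("x", "y", "z"))
        shifted = pp.SkeletonSequence(data + 7.5, channels=("x", "y", "z"))
        a = pp.normalize_coordinates(seq, layout20).data[None]
        b = pp.normalize_coordinates(shifted, layout20).data[None]
        np.testing.assert_allclose(model(a), model(b), atol=1e-5)

    def test_wrong_joint_count_rejected(self, rng):
        model = build_model(TINY, seed=0)
        with pytest.raises(ValueError, match="joints"):
            model(rng.standard_normal((1, 3, 8, 19, 2)).astype(np.float32))

    def test_nonfinite_input_rejected(self):
        model = build_model(TINY, seed=0)
        bad = np.zeros((1, 3, 8, 20, 2), dtype=np.float32)
        bad[0, 0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            model(bad)


class TestFuseScores:
    def _probs(self, rng, n=5, k=4):
        u = rng.random((n, k))
        return u / u.sum(axis=1, keepdims=True)

    def test_alpha_one_returns_first_stream(self, rng):
        u, v = self._probs(rng), self._probs(rng)
        np.testing.assert_array_equal(fuse_scores(u, v, FusionConfig(1.0)), u)

    def test_alpha_zero_returns_second_stream(self, rng):
        u, v = self._probs(rng), self._probs(rng)
        np.testing.assert_array_equal(fuse_scores(u, v, FusionConfig(0.0)), v)

    def test_default_alpha_is_0p6(self, rng):
        u, v = self._probs(rng), self._probs(rng)
        np.testing.assert_allclose(fuse_scores(u, v), 0.6 * u + 0.4 * v)

    @pytest.mark.parametrize("alpha", [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
    def test_outputs_remain_probability_vectors(self, alpha, rng):
        fused = fuse_scores(self._probs(rng), self._probs(rng), FusionConfig(alpha))
        assert np.all(fused >= 0.0)
        np.testing.assert_allclose(fused.sum(axis=1), 1.0, atol=1e-12)

    def test_identical_streams_are_a_fixed_point(self, rng):
        u = self._probs(rng)
        for alpha in (0.0, 0.25, 0.6, 1.0):
            np.testing.assert_allclose(fuse_scores(u, u, FusionConfig(alpha)), u)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            FusionConfig(1.2)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            fuse_scores(self._probs(rng, 3), self._probs(rng, 4))

    def test_non_probability_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="sum to 1"):
            fuse_scores(np.ones((2, 3)), self._probs(rng, 2, 3))


class TestParameterCount:
    def test_matches_closed_form_audit(self):
        for cfg in (
            ModelConfig(num_classes=4),
            ModelConfig(num_classes=10, gamma=3),
            ModelConfig(num_classes=4, multiscale=False),
            ModelConfig(num_classes=4, num_persons=1),
            ModelConfig(num_classes=4, num_layers=3, channel_plan=(8, 8, 16),
                        strides=(1, 2, 1)),
        ):
            assert count_parameters(build_model(cfg, seed=0)) == \
                closed_form_parameter_count(cfg)

    def test_default_model_under_one_million(self):
        n = count_parameters(build_model(ModelConfig(num_classes=4), seed=0))
        assert n < 1_000_000
        # pinned by the closed-form audit: regression guard on the default plan
        assert n == 39_596

    def test_class_count_difference_is_final_layer_arithmetic(self):
        k1, k2 = 4, 9
        base = dict(num_layers=2, channel_plan=(4, 6), gamma=2)
        m1 = build_model(ModelConfig(num_classes=k1, **base), seed=0)
        m2 = build_model(ModelConfig(num_classes=k2, **base), seed=0)
        last_channels = 6
        assert count_parameters(m2) - count_parameters(m1) == (k2 - k1) * (
            last_channels + 1
        )

    def test_doubling_channels_scales_count_between_2x_and_4x(self):
        base = ModelConfig(num_classes=4, num_layers=3, channel_plan=(8, 8, 16))
        wide = ModelConfig(num_classes=4, num_layers=3, channel_plan=(16, 16, 32))
        ratio = closed_form_parameter_count(wide) / closed_form_parameter_count(base)
        assert 2.0 < ratio < 4.0

    def test_ten_blocks_in_default_model(self):
        model = build_model(ModelConfig(num_classes=4), seed=0)
        assert len(model.blocks) == 10
        assert model.config.channel_plan == DEFAULT_CHANNEL_PLAN


class TestBoneStream:
    def test_shapes_preserved_and_root_zero(self, rng, layout20):
        x = rng.standard_normal((2, 3, 5, 20, 2)).astype(np.float32)
        bones = bone_stream(x, layout20)
        assert bones.shape == x.shape
        assert np.all(bones[:, :, :, layout20.center_joint] == 0.0)

    def test_edge_differences(self, rng, layout20):
        x = rng.standard_normal((1, 3, 2, 20, 1)).astype(np.float32)
        bones = bone_stream(x, layout20)
        # joint 1 ("spine") hangs off joint 0 ("pelvis") in this layout
        np.testing.assert_allclose(
            bones[0, :, :, 1], x[0, :, :, 1] - x[0, :, :, 0], atol=1e-7
        )

    def test_translation_invariance(self, rng, layout20):
        x = rng.standard_normal((1, 3, 4, 20, 1)).astype(np.float32)
        np.testing.assert_allclose(
            bone_stream(x + 3.0, layout20), bone_stream(x, layout20), atol=1e-5
        )


class TestCheckpoints:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        model = build_model(TINY, seed=3)
        x = rng.standard_normal((2, 3, 8, 20, 2)).astype(np.float32)
        model.train()
        model.forward_logits(x)  # populate BN running stats
        model.eval()
        expected = model(x)
        path = tmp_path / "model.ckpt.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        np.testing.assert_allclose(restored(x), expected, atol=1e-6)

    def test_version_mismatch_rejected(self, tmp_path):
        import json

        model = build_model(TINY, seed=0)
        path = tmp_path / "model.ckpt.npz"
        save_checkpoint(model, path)
        with np.load(path) as archive:
            arrays = {k: archive[k] for k in archive.files}
        meta = json.loads(bytes(arrays["meta"]))
        meta["format_version"] = 99
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)
        with pytest.raises(ValueError, match="format_version 99"):
            load_checkpoint(path)
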