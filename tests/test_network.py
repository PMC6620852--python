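"""Architecture contracts: heads, depth, shapes, gradients, checkpoints."""

import numpy as np
import pytest

import myoseg.autodiff as ad
from myoseg import ModelConfig, build_model, forward, load_checkpoint, load_pretrained_encoder, save_checkpoint
from myoseg.autodiff import Tensor


@pytest.fixture(scope="module")
def micro_config():
    """Two-block, two-decoder miniature for gradient-level checks."""
    return ModelConfig(encoder_widths=((4, 4), (6,)), decoder_channels=4, n_decoders=2)


class TestBuildModel:
    def test_five_decoder_heads_and_five_channel_concat(self, tiny_model):
        assert len(tiny_model.decoders) == 5
        assert tiny_model.fuse.weight.data.shape[1] == 5  # 1x1 conv over the 5-channel concat
        assert tiny_model.fuse.weight.data.shape[2:] == (1, 1)

    def test_default_encoder_has_thirteen_conv_layers(self):
        model = build_model(ModelConfig())
        convs = model.encoder_convs()
        assert len(convs) == 13
        widths = [c.weight.data.shape[0] for c in convs]
        assert widths == [64, 64, 128, 128, 256, 256, 256, 512, 512, 512, 512, 512, 512]

    def test_decoder_i_has_i_minus_one_deconvolutions(self, tiny_model):
        for i, dec in enumerate(tiny_model.decoders, start=1):
            assert len(dec.deconvs) == i - 1

    def test_mismatched_decoder_count_raises(self):
        with pytest.raises(ValueError, match="n_decoders"):
            ModelConfig(n_decoders=4)

    def test_width_multiplier_scales_channels(self):
        model = build_model(ModelConfig(width_multiplier=0.125))
        assert model.encoder_convs()[0].weight.data.shape[0] == 8
        assert model.encoder_convs()[-1].weight.data.shape[0] == 64


class TestForward:
    @pytest.mark.parametrize("shape", [(300, 300), (97, 133), (64, 96)])
    def test_output_matches_input_size(self, tiny_model, shape):
        img = np.random.default_rng(0).integers(0, 255, (*shape, 3)).astype(np.uint8)
        bundle = forward(tiny_model, img)
        assert bundle.fused_map.shape == shape
        assert all(m.shape == shape for m in bundle.decoder_maps)
        assert len(bundle.decoder_maps) == 5

    def test_probabilities_in_open_unit_interval(self, tiny_model):
        img = np.random.default_rng(1).integers(0, 255, (64, 64, 3)).astype(np.uint8)
        bundle = forward(tiny_model, img)
        for m in bundle.decoder_maps + [bundle.fused_map]:
            assert (m > 0).all() and (m < 1).all()

    def test_eval_determinism(self, tiny_model):
        img = np.random.default_rng(2).integers(0, 255, (96, 96, 3)).astype(np.uint8)
        a = forward(tiny_model, img)
        b = forward(tiny_model, img)
        np.testing.assert_array_equal(a.fused_map, b.fused_map)

    def test_too_small_input_raises(self, tiny_model):
        with pytest.raises(ValueError, match="32"):
            forward(tiny_model, np.zeros((16, 40, 3), dtype=np.uint8))

    def test_decoder_upsampling_factor(self, micro_config):
        """Decoder i's pre-crop output restores its tap by exactly 2^(i-1):
        with a 2-block model on a 64x64 input, both decoder logits come out
        64x64 even though decoder 2 taps a 32x32 feature map."""
        model = build_model(micro_config, seed=3)
        x = Tensor(np.random.default_rng(0).normal(size=(1, 3, 64, 64)).astype(np.float32))
        with ad.no_grad():
            logits, fused = model.forward_tensor(x)
        assert logits[0].data.shape == logits[1].data.shape == (1, 1, 64, 64)
        assert fused.data.shape == (1, 1, 64, 64)


class TestGradientFlow:
    def test_shared_tap_accumulates_gradients_from_both_consumers(self, micro_config):
        """The last conv of block 1 feeds both decoder 1 and (through the
        pool) the rest of the network; its weight gradient under the joint
        loss must equal the sum of the gradients under each head's loss
        taken separately."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=(1, 3, 32, 32)).astype(np.float32)
        y = (rng.random((1, 1, 32, 32)) > 0.5).astype(np.float32)
        w = np.ones_like(y)

        def head_grads(selector):
            model = build_model(micro_config, seed=3)
            logits, fused = model.forward_tensor(Tensor(x))
            losses = [ad.weighted_bce_logits_sum(lg, y, w) for lg in logits]
            losses.append(ad.weighted_bce_logits_sum(fused, y, w))
            picked = [losses[i] for i in selector]
            ad.add_n(picked).backward() if len(picked) > 1 else picked[0].backward()
            return model.encoder_blocks[0][-1].weight.grad.copy()

        joint = head_grads([0, 1, 2])
        parts = sum(head_grads([i]) for i in range(3))
        np.testing.assert_allclose(joint, parts, rtol=1e-4, atol=1e-5)

    def test_conv_and_deconv_gradients_match_adjoint_identity(self):
        """<A x, u> == <x, A^T u> for the linear ops, exact to float32."""
        rng = np.random.default_rng(3)
        w = Tensor(rng.normal(size=(4, 3, 3, 3)).astype(np.float32))
        x = Tensor(rng.normal(size=(2, 3, 9, 9)).astype(np.float32), requires_grad=True)
        y = ad.conv2d(x, w, None, stride=1, padding=1)
        u = rng.normal(size=y.data.shape).astype(np.float32)
        y.backward(u)
        lhs = float((y.data.astype(np.float64) * u).sum())
        rhs = float((x.data.astype(np.float64) * x.grad).sum())
        assert lhs == pytest.approx(rhs, rel=1e-5)

        wt = Tensor(rng.normal(size=(3, 2, 4, 4)).astype(np.float32))
        xt = Tensor(rng.normal(size=(2, 3, 5, 6)).astype(np.float32), requires_grad=True)
        yt = ad.conv_transpose2d(xt, wt, None)
        assert yt.data.shape == (2, 2, 10, 12)  # exact x2 upsampling
        ut = rng.normal(size=yt.data.shape).astype(np.float32)
        yt.backward(ut)
        lhs = float((yt.data.astype(np.float64) * ut).sum())
        rhs = float((xt.data.astype(np.float64) * xt.grad).sum())
        assert lhs == pytest.approx(rhs, rel=1e-5)


class TestPretrainedEncoder:
    def test_matching_source_loads_26_tensors(self, tiny_config):
        source_model = build_model(tiny_config, seed=99)
        source = {p.name: p.data for c in source_model.encoder_convs() for p in c.parameters()}
        model = build_model(tiny_config, seed=0)
        n = load_pretrained_encoder(model, source)
        assert n == 26  # 13 conv layers x (weight + bias)
        np.testing.assert_array_equal(
            model.encoder_blocks[0][0].weight.data, source_model.encoder_blocks[0][0].weight.data
        )

    def test_decoders_untouched(self, tiny_config):
        source_model = build_model(tiny_config, seed=99)
        source = {p.name: p.data for c in source_model.encoder_convs() for p in c.parameters()}
        model = build_model(tiny_config, seed=0)
        before = model.decoders[0].head.weight.data.copy()
        load_pretrained_encoder(model, source)
        np.testing.assert_array_equal(model.decoders[0].head.weight.data, before)

    def test_shape_mismatch_names_layer(self, tiny_config):
        source_model = build_model(ModelConfig(width_multiplier=0.25), seed=0)
        source = {p.name: p.data for c in source_model.encoder_convs() for p in c.parameters()}
        model = build_model(tiny_config, seed=0)
        with pytest.raises(ValueError, match="conv1_1"):
            load_pretrained_encoder(model, source)

    def test_no_source_warns_and_leaves_model_unchanged(self, tiny_config):
        model = build_model(tiny_config, seed=0)
        before = model.encoder_blocks[0][0].weight.data.copy()
        with pytest.warns(UserWarning):
            assert load_pretrained_encoder(model, None) == 0
        np.testing.assert_array_equal(model.encoder_blocks[0][0].weight.data, before)


class TestCheckpoints:
    def test_roundtrip_preserves_parameters_and_config(self, tiny_config, tmp_path):
        model = build_model(tiny_config, seed=5)
        path = tmp_path / "model.npz"
        save_checkpoint(model, str(path))
        restored = load_checkpoint(str(path))
        assert restored.config == model.config
        for p, q in zip(model.parameters(), restored.parameters()):
            np.testing.assert_array_equal(p.data, q.data)
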