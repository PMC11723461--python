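"""Dual-branch generator: shapes, gating, fusion algebra, contracts."""

import numpy as np
import pytest

import eegdenoise as ed
from eegdenoise.autodiff import Tensor
from eegdenoise.generator import (
    BranchGenerator,
    DualBranchGenerator,
    LocalGlobalTransformerBlock,
    fuse,
)

from conftest import tiny_gen_cfg


@pytest.fixture(scope="module")
def tiny_gen():
    return DualBranchGenerator(tiny_gen_cfg()).eval()


def batch(rng, n, length):
    return rng.standard_normal((n, length)).astype(np.float32)


class TestPreprocess:
    def test_default_output_geometry(self, rng):
        # 1024 samples -> 32 channels x 512 tokens
        cfg = ed.GeneratorConfig(seed=0)
        branch = BranchGenerator(cfg, np.random.default_rng(0))
        out = branch.preprocess(Tensor(batch(rng, 4, 1024)))
        assert out.shape == (4, 32, 512)

    def test_zero_input_finite(self, tiny_gen):
        out = tiny_gen.branch1.preprocess(Tensor(np.zeros((2, 256), np.float32)))
        assert np.all(np.isfinite(out.data))

    def test_amplitude_sensitivity(self, rng, tiny_gen):
        x = batch(rng, 2, 256)
        a = tiny_gen.branch1.preprocess(Tensor(x)).data
        b = tiny_gen.branch1.preprocess(Tensor(2 * x)).data
        assert np.linalg.norm(a - b) > 0

    def test_wrong_length_rejected(self, tiny_gen, rng):
        with pytest.raises(ed.InvalidInputError):
            tiny_gen.branch1.preprocess(Tensor(batch(rng, 2, 128)))


class TestLocalGlobalAttention:
    def test_shape_preserved(self, rng):
        blk = LocalGlobalTransformerBlock(8, 8, 4, 2, 3, 0.2,
                                          np.random.default_rng(1))
        tokens = Tensor(rng.standard_normal((2, 16, 8)).astype(np.float32))
        assert blk.attention_stack(tokens).shape == (2, 16, 8)

    def test_single_partition_equals_full_sequence_attention(self, rng):
        blk = LocalGlobalTransformerBlock(8, 8, 1, 2, 3, 0.2,
                                          np.random.default_rng(2))
        tokens = Tensor(rng.standard_normal((2, 12, 8)).astype(np.float32))
        # with one partition the chunked local stage sees the whole sequence
        local_chunked = blk.local_attn(
            tokens.reshape(2 * 1, 12, 8)
        ).data.reshape(2, 12, 8)
        local_full = blk.local_attn(tokens).data
        np.testing.assert_array_equal(local_chunked, local_full)

    def test_indivisible_partition_rejected(self, rng):
        blk = LocalGlobalTransformerBlock(8, 8, 5, 2, 3, 0.2,
                                          np.random.default_rng(3))
        with pytest.raises(ed.ConfigurationError):
            blk.attention_stack(
                Tensor(rng.standard_normal((1, 12, 8)).astype(np.float32))
            )

    def test_residual_path_identity(self, rng):
        # zero attention output projections + zero feedforward second layers
        # make the whole attention stack the identity map
        blk = LocalGlobalTransformerBlock(8, 8, 4, 2, 3, 0.2,
                                          np.random.default_rng(4))
        for att in (blk.local_attn, blk.global_attn):
            att.out.weight.data[:] = 0
            att.out.bias.data[:] = 0
        for ffn in (blk.ffn1, blk.ffn2):
            ffn.fc2.weight.data[:] = 0
            ffn.fc2.bias.data[:] = 0
        tokens = Tensor(rng.standard_normal((2, 16, 8)).astype(np.float32))
        np.testing.assert_allclose(blk.attention_stack(tokens).data,
                                   tokens.data, atol=1e-6)


class TestEncode:
    def test_default_fused_channel_count(self, rng):
        # concat of the two streams (2048) fuses back to 1024 channels
        cfg = ed.GeneratorConfig(seed=0)
        branch = BranchGenerator(cfg, np.random.default_rng(0))
        branch.eval()
        z = branch.encode(branch.preprocess(Tensor(batch(rng, 2, 1024))))
        assert z.shape[1] == 1024
        assert branch.fusion_conv.weight.shape[1] == 2048

    def test_width_scaled_forward(self, rng):
        cfg = ed.GeneratorConfig(width_scale=8, seed=0)
        branch = BranchGenerator(cfg, np.random.default_rng(0))
        branch.eval()
        z = branch.encode(branch.preprocess(Tensor(batch(rng, 2, 1024))))
        assert z.shape == (2, 128, 16)

    def test_every_parameter_receives_gradient(self, rng):
        gen = DualBranchGenerator(tiny_gen_cfg(seed=1)).train()
        x = Tensor(batch(rng, 4, 256))
        out = gen(x)
        loss = (out.ypre ** 2.0).mean() + (out.y1 ** 2.0).mean() \
            + (out.y2 ** 2.0).mean()
        gen.zero_grad()
        loss.backward()
        dead = [p for p in gen.parameters()
                if p.grad is None or not np.any(p.grad)]
        assert not dead, f"{len(dead)} parameters with zero gradient"


class TestDecode:
    def test_restores_input_length(self, rng, tiny_gen):
        x = Tensor(batch(rng, 3, 256))
        y = tiny_gen.branch1(x)
        assert y.shape == (3, 256)
        assert np.all(np.isfinite(y.data))


class TestGate:
    def test_masks_strictly_inside_unit_interval(self, rng, tiny_gen):
        m = tiny_gen.gate1(Tensor(batch(rng, 4, 256))).data
        assert np.all(m > -1.0) and np.all(m < 1.0)

    def test_input_dependence(self, rng, tiny_gen):
        a = tiny_gen.gate1(Tensor(batch(rng, 1, 256))).data
        b = tiny_gen.gate1(Tensor(batch(rng, 1, 256))).data
        assert np.linalg.norm(a - b) > 0


class TestFuse:
    def test_mask_one_zero_selects_first_branch(self, rng):
        x, y1, y2 = (Tensor(batch(rng, 2, 32)) for _ in range(3))
        ones, zeros = Tensor(np.ones((2, 32), np.float32)), Tensor(np.zeros((2, 32), np.float32))
        np.testing.assert_array_equal(fuse(x, y1, y2, ones, zeros).data, y1.data)

    def test_pure_subtraction_route(self, rng):
        x = Tensor(batch(rng, 2, 32))
        y1 = Tensor(batch(rng, 2, 32))
        zeros = Tensor(np.zeros((2, 32), np.float32))
        ones = Tensor(np.ones((2, 32), np.float32))
        np.testing.assert_array_equal(
            fuse(x, y1, zeros, zeros, ones).data, x.data
        )

    def test_matches_scalar_loop_oracle(self, rng):
        ts = [Tensor(rng.standard_normal((2, 8))) for _ in range(5)]
        out = fuse(*ts).data
        x, y1, y2, m1, m2 = (t.data for t in ts)
        for i in range(2):
            for j in range(8):
                expected = m1[i, j] * y1[i, j] + m2[i, j] * (x[i, j] - y2[i, j])
                assert out[i, j] == pytest.approx(expected, abs=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        good = [Tensor(rng.standard_normal((2, 8))) for _ in range(4)]
        with pytest.raises(ed.InvalidInputError):
            fuse(*good, Tensor(rng.standard_normal((2, 9))))


class TestGeneratorForward:
    def test_output_shapes_and_consistency(self, rng, tiny_gen):
        x = batch(rng, 4, 256)
        out = tiny_gen(x)
        for t in (out.y1, out.y2, out.mask1, out.mask2, out.ypre):
            assert t.shape == (4, 256)
        recomputed = fuse(Tensor(x), out.y1, out.y2, out.mask1, out.mask2)
        np.testing.assert_allclose(out.ypre.data, recomputed.data, atol=1e-6)

    def test_eval_mode_bitwise_deterministic(self, rng, tiny_gen):
        x = batch(rng, 2, 256)
        np.testing.assert_array_equal(tiny_gen(x).ypre.data,
                                      tiny_gen(x).ypre.data)

    def test_param_count_is_function_of_config_not_seed(self):
        a = DualBranchGenerator(tiny_gen_cfg(seed=1))
        b = DualBranchGenerator(tiny_gen_cfg(seed=2))
        assert a.n_parameters() == b.n_parameters()
        assert any(
            not np.array_equal(p.data, q.data)
            for p, q in zip(a.parameters(), b.parameters())
        )

    def test_single_step_descent_on_one_batch(self, rng):
        from eegdenoise.autodiff import Adam

        gen = DualBranchGenerator(tiny_gen_cfg(seed=3)).train()
        x = batch(rng, 4, 256)
        target = batch(rng, 4, 256) * 0.1

        def loss_value():
            return ((gen(x).ypre - Tensor(target)) ** 2.0).mean()

        before = float(loss_value().data)
        opt = Adam(gen.parameters(), lr=1e-4)
        opt.zero_grad()
        loss_value().backward()
        opt.step()
        assert float(loss_value().data) < before


class TestAblations:
    @pytest.mark.parametrize("flag,branch_used", [
        ("clean_branch_only", "y1"),
        ("noise_branch_only", "y2"),
    ])
    def test_single_branch_modes(self, rng, flag, branch_used):
        gen = DualBranchGenerator(tiny_gen_cfg(**{flag: True})).eval()
        x = batch(rng, 2, 256)
        out = gen(x)
        assert out.ypre.shape == (2, 256)
        if branch_used == "y1":
            np.testing.assert_array_equal(out.ypre.data, out.y1.data)
        else:
            np.testing.assert_allclose(out.ypre.data, x - out.y2.data,
                                       atol=1e-6)

    @pytest.mark.parametrize("flag", ["no_transformer", "plain_self_attention"])
    def test_attention_ablations_forward(self, rng, flag):
        gen = DualBranchGenerator(tiny_gen_cfg(**{flag: True})).eval()
        out = gen(batch(rng, 2, 256))
        assert out.ypre.shape == (2, 256)

    def test_conflicting_flags_rejected(self):
        with pytest.raises(ed.ConfigurationError):
            tiny_gen_cfg(clean_branch_only=True, noise_branch_only=True)


class TestConfigValidation:
    def test_block_count_mismatch(self):
        with pytest.raises(ed.ConfigurationError):
            ed.GeneratorConfig(encoder_dims=(64, 128), n_blocks=5)

    def test_indivisible_partitions(self):
        with pytest.raises(ed.ConfigurationError):
            tiny_gen_cfg(local_partitions=3)

    def test_round_trip_dict(self):
        cfg = tiny_gen_cfg(width_scale=2.0)
        assert ed.GeneratorConfig.from_dict(cfg.to_dict()) == cfg
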