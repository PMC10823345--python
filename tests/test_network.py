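"""Architecture contracts, re-parameterization fusion, MHF supervision, loss."""

import dataclasses

import numpy as np
import pytest

from bmseg import autodiff as ad
from bmseg.network import (
    BN_EPS,
    BlockParams,
    NetworkConfig,
    NormStats,
    block_forward,
    build_network,
    composite_loss,
    fuse_reparameterize,
    mhf_targets,
    random_block_params,
)
from bmseg.harness import tiny_network_config


def small_config(**kw):
    base = dict(n_levels=2, base_channels=4, large_kernel_edge=7, parallel_kernel_edge=3)
    base.update(kw)
    return NetworkConfig(**base)


class TestConfigValidation:
    def test_rejects_even_kernel(self):
        with pytest.raises(ValueError):
            NetworkConfig(large_kernel_edge=12)

    def test_rejects_parallel_ge_large(self):
        with pytest.raises(ValueError):
            NetworkConfig(large_kernel_edge=5, parallel_kernel_edge=5)

    def test_kernel_must_fit_deepest_level_when_shape_declared(self):
        with pytest.raises(ValueError, match="level 3"):
            NetworkConfig(n_levels=4, large_kernel_edge=13, input_shape=(64, 64, 64))
        NetworkConfig(n_levels=4, large_kernel_edge=13, input_shape=(128, 128, 128))


class TestBuildAndForward:
    def test_level_structure(self):
        net = build_network(small_config(n_levels=3), seed=0)
        assert len(net.enc_blocks) == 3
        assert len(net.dec_blocks) == 2 and len(net.ups) == 2
        assert len(net.aux_heads) == 2

    def test_deterministic_initialization(self):
        a = build_network(small_config(), seed=5)
        b = build_network(small_config(), seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_forward_shape_and_softmax(self, easy_phantom):
        net = build_network(small_config(), seed=0)
        vol = easy_phantom.intensity[:32, :32, :32]
        out = net.forward(vol, training_mode=False)
        assert out.final_prob.data.shape == (1, 2, 32, 32, 32)
        sums = out.final_prob.data.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-6)
        assert out.aux_probs == []  # inference: full-resolution map only

    def test_training_mode_emits_one_aux_map_per_coarse_scale(self):
        net = build_network(small_config(n_levels=3), seed=0)
        out = net.forward(np.zeros((16, 16, 16), np.float32), training_mode=True)
        assert len(out.aux_probs) == 2
        assert out.aux_probs[0].data.shape == (1, 2, 8, 8, 8)
        assert out.aux_probs[1].data.shape == (1, 2, 4, 4, 4)

    def test_constant_zero_input_is_finite(self):
        net = build_network(small_config(), seed=1)
        out = net.forward(np.zeros((16, 16, 16), np.float32), training_mode=True)
        assert np.isfinite(out.final_prob.data).all()
        for aux in out.aux_probs:
            assert np.isfinite(aux.data).all()

    def test_indivisible_shape_rejected(self):
        net = build_network(small_config(n_levels=3), seed=0)
        with pytest.raises(ValueError, match="divisible by 4"):
            net.forward(np.zeros((18, 18, 18), np.float32))

    def test_gating_mode_runs(self):
        cfg = small_config(mhf_mode="gating")
        net = build_network(cfg, seed=0)
        out = net.forward(np.zeros((16, 16, 16), np.float32), training_mode=True)
        assert np.isfinite(out.final_prob.data).all()

    def test_receptive_field_bound_single_block(self):
        # one encoder block: a perturbation farther than (edge-1)/2 from a
        # voxel cannot change that voxel's output
        net = build_network(small_config(), seed=3)
        block = net.enc_blocks[0]
        x = np.random.default_rng(0).normal(size=(1, 4, 16, 16, 16)).astype(np.float32)
        with ad.no_grad():
            y0 = block(ad.Tensor(x), training=False).data
        x2 = x.copy()
        x2[:, :, 0, 0, 0] += 10.0  # distance 8 > 3 from voxel (8,8,8)
        with ad.no_grad():
            y1 = block(ad.Tensor(x2), training=False).data
        assert abs(y1[0, :, 8, 8, 8] - y0[0, :, 8, 8, 8]).max() < 1e-4
        assert abs(y1[0, :, 1, 1, 1] - y0[0, :, 1, 1, 1]).max() > 1e-3

    def test_checkpoint_roundtrip(self, tmp_path):
        net = build_network(small_config(), seed=2)
        vol = np.random.default_rng(1).random((16, 16, 16)).astype(np.float32)
        before = net.predict_foreground(vol)
        net.save(tmp_path / "ckpt.npz")
        from bmseg.network import Network

        loaded = Network.load(tmp_path / "ckpt.npz")
        assert np.array_equal(loaded.predict_foreground(vol), before)


def identity_norm(c):
    return NormStats(
        gamma=np.full(c, np.sqrt(1.0 + BN_EPS), np.float32),
        beta=np.zeros(c, np.float32),
        mean=np.zeros(c, np.float32),
        var=np.ones(c, np.float32),
    )


class TestFusion:
    def test_delta_small_branch_fuses_to_identity_kernel(self):
        c = 2
        small = np.zeros((c, 3, 3, 3), np.float32)
        small[:, 1, 1, 1] = 1.0  # centered delta
        params = BlockParams(
            pw_in_w=np.eye(c, dtype=np.float32),
            pw_in_b=np.zeros(c, np.float32),
            large_kernel=np.zeros((c, 7, 7, 7), np.float32),
            large_bias=np.zeros(c, np.float32),
            large_norm=identity_norm(c),
            small_kernel=small,
            small_bias=np.zeros(c, np.float32),
            small_norm=identity_norm(c),
            pw_out_w=np.eye(c, dtype=np.float32),
            pw_out_b=np.zeros(c, np.float32),
        )
        fused = fuse_reparameterize(params)
        expected = np.zeros((c, 7, 7, 7))
        expected[:, 3, 3, 3] = 1.0
        assert np.allclose(fused.large_kernel, expected, atol=1e-6)
        # the depthwise stage is then the identity map
        x = np.random.default_rng(0).normal(size=(1, c, 10, 10, 10)).astype(np.float32)
        y = ad.depthwise_conv3d(
            ad.Tensor(x), ad.Tensor(fused.large_kernel), ad.Tensor(fused.large_bias)
        ).data
        assert np.allclose(y, x, atol=1e-5)

    def test_small_kernel_offset_preserved_under_padding(self):
        c = 1
        small = np.zeros((c, 3, 3, 3), np.float32)
        small[:, 2, 1, 1] = 1.0  # offset (+1, 0, 0) from the small centre
        params = BlockParams(
            pw_in_w=np.eye(c, dtype=np.float32),
            pw_in_b=np.zeros(c, np.float32),
            large_kernel=np.zeros((c, 7, 7, 7), np.float32),
            large_bias=np.zeros(c, np.float32),
            large_norm=identity_norm(c),
            small_kernel=small,
            small_bias=np.zeros(c, np.float32),
            small_norm=identity_norm(c),
            pw_out_w=np.eye(c, dtype=np.float32),
            pw_out_b=np.zeros(c, np.float32),
        )
        fused = fuse_reparameterize(params)
        idx = np.unravel_index(np.argmax(fused.large_kernel[0]), (7, 7, 7))
        assert idx == (4, 3, 3)  # offset (+1, 0, 0) from the large centre

    @pytest.mark.parametrize("seed", range(5))
    def test_fused_equals_two_branch_float32(self, seed):
        rng = np.random.default_rng(seed)
        params = random_block_params(4, 13, 5, rng)
        x = rng.normal(size=(1, 4, 16, 16, 16)).astype(np.float32)
        y_multi = block_forward(params, x)
        y_fused = block_forward(fuse_reparameterize(params), x)
        assert np.abs(y_multi - y_fused).max() <= 1e-4

    def test_fused_equals_two_branch_float64(self):
        rng = np.random.default_rng(99)
        params = random_block_params(3, 7, 3, rng)
        for name in (
            "pw_in_w", "pw_in_b", "large_kernel", "large_bias",
            "small_kernel", "small_bias", "pw_out_w", "pw_out_b",
        ):
            setattr(params, name, getattr(params, name).astype(np.float64))
        for norm in (params.large_norm, params.small_norm):
            norm.gamma = norm.gamma.astype(np.float64)
            norm.beta = norm.beta.astype(np.float64)
            norm.mean = norm.mean.astype(np.float64)
            norm.var = norm.var.astype(np.float64)
        x = rng.normal(size=(1, 3, 12, 12, 12))
        y_multi = block_forward(params, x)
        y_fused = block_forward(fuse_reparameterize(params), x)
        assert np.abs(y_multi - y_fused).max() <= 1e-10

    def test_fusion_rejects_nonpositive_variance(self):
        rng = np.random.default_rng(0)
        params = random_block_params(2, 5, 3, rng)
        params.large_norm.var[0] = 0.0
        with pytest.raises(ValueError, match="variance"):
            fuse_reparameterize(params)


class TestMHFTargets:
    def test_single_voxel_survives_every_scale(self):
        gt = np.zeros((8, 8, 8), bool)
        gt[3, 5, 2] = True
        targets = mhf_targets(gt, 2)
        assert targets[0].sum() >= 1 and targets[1].sum() >= 1

    def test_empty_stays_empty(self):
        targets = mhf_targets(np.zeros((8, 8, 8), bool), 3)
        assert all(t.sum() == 0 for t in targets)

    def test_cube_matches_brute_force_maxpool(self):
        gt = np.zeros((16, 16, 16), bool)
        gt[4:8, 4:8, 4:8] = True
        (target,) = mhf_targets(gt, 1)
        brute = np.zeros((8, 8, 8), bool)
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    brute[i, j, k] = gt[2 * i : 2 * i + 2, 2 * j : 2 * j + 2,
                                        2 * k : 2 * k + 2].any()
        assert np.array_equal(target, brute)
        assert target.sum() == 8  # the 4^3 cube becomes a 2^3 block

    def test_indivisible_shape_rejected(self):
        with pytest.raises(ValueError):
            mhf_targets(np.zeros((6, 6, 6), bool), 2)


class TestCompositeLoss:
    def test_shape_mismatch_rejected(self):
        net = build_network(small_config(), seed=0)
        out = net.forward(np.zeros((16, 16, 16), np.float32), training_mode=True)
        with pytest.raises(ValueError, match="match"):
            composite_loss(out, np.zeros((8, 8, 8), bool))

    def test_aux_terms_decay_geometrically(self):
        gt = np.zeros((16, 16, 16), bool)
        gt[2:6, 2:6, 2:6] = True
        net = build_network(small_config(n_levels=3), seed=4)
        out = net.forward(np.zeros((16, 16, 16), np.float32), training_mode=True)
        targets = mhf_targets(gt, 2)
        base = float(composite_loss(out, gt, aux_targets=None).data)
        with_aux = float(
            composite_loss(out, gt, aux_targets=targets, aux_loss_decay=0.5).data
        )
        assert with_aux > base  # aux terms add non-negative weighted losses

    def test_loss_near_zero_for_confident_correct_logits(self):
        gt = np.zeros((8, 8, 8), bool)
        gt[1:3, 1:3, 1:3] = True
        logits = np.stack(
            [np.where(gt, -30.0, 30.0), np.where(gt, 30.0, -30.0)]
        )[None].astype(np.float32)
        from bmseg.network import MultiscaleOutputs

        prob = ad.softmax_channels(ad.Tensor(logits))
        out = MultiscaleOutputs(final_prob=prob, final_logits=ad.Tensor(logits))
        assert float(composite_loss(out, gt).data) < 1e-3


class TestTrainingSanity:
    def test_200_steps_halve_the_loss_on_one_easy_crop(self, easy_phantom):
        # one lesion-centred 16^3 crop, fixed seed: the composite loss must
        # drop by at least 50% after 200 Adam steps
        idx = np.argwhere(easy_phantom.gt_mask)
        center = idx[len(idx) // 2]
        sl = tuple(
            slice(int(np.clip(c - 8, 0, s - 16)), int(np.clip(c - 8, 0, s - 16)) + 16)
            for c, s in zip(center, easy_phantom.gt_mask.shape)
        )
        vol = easy_phantom.intensity[sl]
        gt = easy_phantom.gt_mask[sl]
        net = build_network(tiny_network_config(), seed=0)
        opt = ad.Adam(net.parameters(), lr=1e-3)
        losses = []
        for _ in range(200):
            out = net.forward(vol, training_mode=True)
            loss = composite_loss(out, gt, aux_targets=mhf_targets(gt, 1))
            losses.append(float(loss.data))
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert losses[-1] < 0.5 * losses[0]
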