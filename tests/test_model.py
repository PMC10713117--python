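import numpy as np
import pytest

from surfmae.config import ModelConfig
from surfmae.model import PointEncoder, SurfaceMAE, chamfer_loss, fuse_features
from surfmae.nn import Tensor
from surfmae.patches import apply_mask, make_patches


@pytest.fixture(scope="module")
def tiny_model(tiny_model_cfg):
    return SurfaceMAE(tiny_model_cfg, k_prime=16, seed=0)


@pytest.fixture(scope="module")
def patchset_masked(small_cloud):
    return make_patches(small_cloud.points, g=32, k_prime=16, m=0.6, seed=3)


@pytest.fixture(scope="module")
def patchset_unmasked(small_cloud):
    return make_patches(small_cloud.points, g=32, k_prime=16)


class TestPointEncoder:
    def test_output_width_six(self, tiny_model, small_cloud):
        out = tiny_model.point_encoder(small_cloud.chem_raw[:10])
        assert out.shape == (10, 6)

    def test_three_message_passing_blocks(self, tiny_model):
        pe = tiny_model.point_encoder
        assert PointEncoder.N_MESSAGE_BLOCKS == 3
        assert all(hasattr(pe, f"mp{i}") for i in range(3))

    def test_neighbor_permutation_invariance(self, tiny_model, small_cloud):
        x = small_cloud.chem_raw[:5]
        base = tiny_model.point_encoder(x).data
        rng = np.random.default_rng(0)
        perm = rng.permutation(16)
        permuted = tiny_model.point_encoder(x[:, perm, :]).data
        assert np.allclose(base, permuted, atol=1e-6)

    def test_rejects_wrong_trailing_dim(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.point_encoder(np.zeros((4, 16, 5)))


class TestFuseFeatures:
    def test_width_six_plus_ten(self):
        fused = fuse_features(np.ones((7, 6)), np.zeros((7, 10)))
        assert fused.shape == (7, 16)

    def test_order_chemical_then_curvature(self):
        chem = np.arange(12.0).reshape(2, 6)
        curv = np.zeros((2, 10))
        fused = fuse_features(chem, curv).data
        assert np.array_equal(fused[:, :6], chem)
        assert np.all(fused[:, 6:] == 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fuse_features(np.ones((3, 6)), np.ones((4, 10)))


class TestTokenizer:
    def test_token_count_is_visible_patches(self, tiny_model, small_cloud,
                                            patchset_masked):
        fused = tiny_model.fused_point_features(small_cloud)
        tokens = tiny_model.tokenize(patchset_masked, fused)
        assert tokens.shape == (patchset_masked.n_visible, 64)
        assert patchset_masked.n_visible == 32 - 19

    def test_member_permutation_invariance(self, tiny_model, small_cloud,
                                           patchset_unmasked):
        from dataclasses import replace

        fused = tiny_model.fused_point_features(small_cloud)
        base = tiny_model.tokenize(patchset_unmasked, fused).data
        rng = np.random.default_rng(1)
        members = patchset_unmasked.members.copy()
        for row in members:
            rng.shuffle(row)
        permuted = tiny_model.tokenize(replace(patchset_unmasked, members=members),
                                       fused).data
        assert np.allclose(base, permuted, atol=1e-6)

    def test_duplicated_members_leave_token_unchanged(self, tiny_model, small_cloud,
                                                      patchset_unmasked):
        from dataclasses import replace

        fused = tiny_model.fused_point_features(small_cloud)
        base = tiny_model.tokenize(patchset_unmasked, fused).data
        doubled = np.concatenate([patchset_unmasked.members] * 2, axis=1)
        out = tiny_model.tokenize(replace(patchset_unmasked, members=doubled),
                                  fused).data
        assert np.allclose(base, out, atol=1e-12)


class TestPositionalEncoding:
    def test_width_and_determinism(self, tiny_model):
        centers = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        out = tiny_model.enc_pos(centers).data
        assert out.shape == (2, 64)
        assert np.allclose(out[0], out[1])

    def test_encoder_and_decoder_sides_differ(self, tiny_model):
        c = np.array([[0.5, -1.0, 2.0]])
        assert not np.allclose(tiny_model.enc_pos(c).data, tiny_model.dec_pos(c).data)


class TestEncode:
    def test_output_counts(self, tiny_model):
        rng = np.random.default_rng(0)
        tokens = Tensor(rng.normal(size=(13, 64)))
        pos = Tensor(rng.normal(size=(13, 64)))
        assert tiny_model.encode(tokens, pos).shape == (13, 64)
        assert tiny_model.encode(tokens, pos, use_cls=True).shape == (14, 64)

    def test_permutation_equivariance(self, tiny_model):
        rng = np.random.default_rng(1)
        tokens = Tensor(rng.normal(size=(9, 64)))
        pos = Tensor(rng.normal(size=(9, 64)))
        base = tiny_model.encode(tokens, pos).data
        perm = rng.permutation(9)
        permuted = tiny_model.encode(Tensor(tokens.data[perm]),
                                     Tensor(pos.data[perm])).data
        assert np.allclose(base[perm], permuted, atol=1e-8)

    def test_default_depths(self):
        cfg = ModelConfig()
        model = SurfaceMAE(cfg, k_prime=32, seed=0)
        assert len(model.encoder.blocks) == 12
        assert len(model.decoder.blocks) == 4

    def test_width_mismatch(self, tiny_model):
        bad = Tensor(np.zeros((5, 32)))
        with pytest.raises(ValueError):
            tiny_model.encode(bad, bad)


class TestDecodeMasked:
    def test_output_shape(self, tiny_model, small_cloud, patchset_masked):
        loss_input = tiny_model.fused_point_features(small_cloud)
        tokens = tiny_model.tokenize(patchset_masked, loss_input)
        centers = patchset_masked.centers
        h = tiny_model.encode(tokens, tiny_model.enc_pos(centers[~patchset_masked.mask]))
        pred = tiny_model.decode_masked(h, centers[~patchset_masked.mask],
                                        centers[patchset_masked.mask])
        assert pred.shape == (19, 16, 3)

    def test_zero_head_predicts_patch_centers(self, tiny_model_cfg, small_cloud,
                                              patchset_masked):
        model = SurfaceMAE(tiny_model_cfg, k_prime=16, seed=1)
        model.coord_head.weight.data[:] = 0.0
        model.coord_head.bias.data[:] = 0.0
        fused = model.fused_point_features(small_cloud)
        tokens = model.tokenize(patchset_masked, fused)
        centers = patchset_masked.centers
        h = model.encode(tokens, model.enc_pos(centers[~patchset_masked.mask]))
        pred = model.decode_masked(h, centers[~patchset_masked.mask],
                                   centers[patchset_masked.mask])
        assert np.all(pred.data == 0.0)  # center-relative zeros

    def test_requires_masked_patches(self, tiny_model):
        h = Tensor(np.zeros((4, 64)))
        with pytest.raises(ValueError):
            tiny_model.decode_masked(h, np.zeros((4, 3)), np.zeros((0, 3)))


class TestChamferLoss:
    def test_identity_is_zero(self):
        rng = np.random.default_rng(0)
        p = rng.normal(size=(5, 8, 3))
        assert chamfer_loss(Tensor(p), p).item() == pytest.approx(0.0, abs=1e-12)

    def test_single_point_hand_case(self):
        pred = Tensor(np.array([[[0.0, 0, 0]]]))
        target = np.array([[[1.0, 0, 0]]])
        assert chamfer_loss(pred, target).item() == pytest.approx(2.0)

    def test_two_point_hand_case(self):
        pred = Tensor(np.array([[[0.0, 0, 0], [2.0, 0, 0]]]))
        target = np.array([[[1.0, 0, 0]]])
        # target->pred: min(1,1)=1; pred->target: (1+1)/2 = 1
        assert chamfer_loss(pred, target).item() == pytest.approx(2.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            np_pred = rng.normal(size=(int(rng.integers(1, 5)),
                                       int(rng.integers(1, 7)), 3))
            np_tgt = rng.normal(size=(np_pred.shape[0], int(rng.integers(1, 7)), 3))
            expected = 0.0
            for pp, tt in zip(np_pred, np_tgt):
                d2 = ((pp[:, None, :] - tt[None, :, :]) ** 2).sum(axis=2)
                expected += d2.min(axis=0).mean() + d2.min(axis=1).mean()
            got = chamfer_loss(Tensor(np_pred), np_tgt).item()
            assert got == pytest.approx(expected, abs=1e-9)

    def test_directional_symmetry_under_swap(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(3, 6, 3))
        b = rng.normal(size=(3, 6, 3))
        assert chamfer_loss(Tensor(a), b).item() == pytest.approx(
            chamfer_loss(Tensor(b), a).item())

    def test_empty_patch_rejected(self):
        with pytest.raises(ValueError):
            chamfer_loss(Tensor(np.zeros((1, 0, 3))), np.zeros((1, 2, 3)))


class TestHeads:
    def test_site_logits_per_point(self, tiny_model, small_cloud, patchset_unmasked):
        h, fused = tiny_model.encode_surface(small_cloud, patchset_unmasked)
        logits = tiny_model.head_site(h, patchset_unmasked, fused)
        assert logits.shape == (256,)

    def test_site_rejects_masked_patchset(self, tiny_model, small_cloud,
                                          patchset_masked):
        fused = tiny_model.fused_point_features(small_cloud)
        h = Tensor(np.zeros((32, 64)))
        with pytest.raises(ValueError):
            tiny_model.head_site(h, patchset_masked, fused)

    def test_pocket_logit_count_and_permutation_invariance(self, tiny_model):
        rng = np.random.default_rng(0)
        h = rng.normal(size=(10, 64))
        base = tiny_model.head_pocket(Tensor(h)).data
        assert base.shape == (7,)
        perm = np.concatenate([[0], 1 + rng.permutation(9)])  # CLS stays first
        assert np.allclose(base, tiny_model.head_pocket(Tensor(h[perm])).data)

    def test_pocket_requires_cls_plus_tokens(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.head_pocket(Tensor(np.zeros((1, 64))))

    def test_descriptors_unit_norm_and_width(self, tiny_model, small_cloud,
                                             patchset_unmasked):
        h, _ = tiny_model.encode_surface(small_cloud, patchset_unmasked)
        desc = tiny_model.head_descriptor(h, patchset_unmasked)
        assert desc.shape == (256, 64)
        assert np.allclose(np.linalg.norm(desc.data, axis=1), 1.0, atol=1e-6)

    def test_descriptors_deterministic(self, tiny_model, small_cloud,
                                       patchset_unmasked):
        h, _ = tiny_model.encode_surface(small_cloud, patchset_unmasked)
        a = tiny_model.head_descriptor(h, patchset_unmasked).data
        h2, _ = tiny_model.encode_surface(small_cloud, patchset_unmasked)
        b = tiny_model.head_descriptor(h2, patchset_unmasked).data
        assert np.array_equal(a, b)

    def test_interpolation_weights_sum_to_one(self, tiny_model, patchset_unmasked):
        # feed constant token field: any convex interpolation must return it
        h = Tensor(np.tile(np.arange(64.0), (32, 1)))
        out = tiny_model._interpolate_tokens(h, patchset_unmasked).data
        assert np.allclose(out, np.arange(64.0), atol=1e-9)


class TestEndToEnd:
    def test_pretrain_forward_finite_on_random_inputs(self, tiny_patch_cfg):
        from surfmae.surface import SurfaceCloud

        cfg = ModelConfig(d=32, encoder_depth=1, encoder_heads=2,
                          decoder_depth=1, decoder_heads=2)
        model = SurfaceMAE(cfg, k_prime=8, seed=0)
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = 64
            pts = rng.normal(scale=5.0, size=(n, 3))
            onehot = np.eye(6)[rng.integers(0, 6, size=(n, 16))]
            chem = np.concatenate(
                [onehot, rng.uniform(1, 8, size=(n, 16, 1))], axis=2)
            cloud = SurfaceCloud(points=pts, normals=np.tile([0, 0, 1.0], (n, 1)),
                                 curvatures=rng.normal(size=(n, 10)),
                                 chem_raw=chem,
                                 chem_neighbor_idx=np.zeros((n, 16), dtype=int))
            ps = make_patches(pts, g=8, k_prime=8, m=0.5, seed=trial)
            loss = model.pretrain_forward(cloud, ps)
            assert np.isfinite(loss.item())

    def test_forward_deterministic_given_weights(self, tiny_model, small_cloud,
                                                 patchset_masked):
        a = tiny_model.pretrain_forward(small_cloud, patchset_masked).item()
        b = tiny_model.pretrain_forward(small_cloud, patchset_masked).item()
        assert a == b

    def test_cls_never_reaches_decoder(self, tiny_model, small_cloud,
                                       patchset_masked):
        # loss with and without CLS participation must both be finite and the
        # decoder input count must equal visible + masked slots either way
        la = tiny_model.pretrain_forward(small_cloud, patchset_masked).item()
        lb = tiny_model.pretrain_forward(small_cloud, patchset_masked,
                                         use_cls=True).item()
        assert np.isfinite(la) and np.isfinite(lb)
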