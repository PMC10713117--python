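"""The masked-autoencoder network for protein surface point clouds.

Architecture overview (encoder/decoder are standard pre-norm transformers):

* point encoder — a shared MLP embeds each surface point's 16 neighbour-atom
  records (one-hot element + distance); three message-passing blocks refine a
  per-point local chemical feature (initialised to all-ones, residually
  updated from the mean over neighbour messages) down to 6 channels.
* feature fusion — the 6-D chemical feature is concatenated with the 10-D
  multi-scale curvature feature to a 16-D per-point feature.
* tokenizer — per patch, a shared MLP lifts member features to the token
  width d and a channel-wise max-pool collapses the k' members to one token.
* positional encoding — a learnable MLP of the patch center coordinate,
  added to tokens; encoder and decoder keep separate weight sets.
* encoder — depth x (multi-head self-attention + MLP) with an optional CLS
  token for whole-surface classification.
* decoder — projected visible tokens plus one shared learnable mask token
  per masked patch, four self-attention blocks, and a linear head predicting
  k' x 3 coordinates per masked patch, relative to the patch center.

Reconstruction is scored by a chamfer loss: per patch, the mean squared
distance from each target point to its nearest prediction plus the reverse
term, summed over patches.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import ModelConfig
from .nn import Tensor, concatenate
from .patches import PatchSet
from .surface import SurfaceCloud


def fuse_features(chem, curv):
    """Concatenate per-point chemical (6) and curvature (10) features -> 16."""
    chem_t = chem if isinstance(chem, Tensor) else Tensor(chem)
    curv_t = curv if isinstance(curv, Tensor) else Tensor(curv)
    if chem_t.shape[0] != curv_t.shape[0]:
        raise ValueError("chemical and curvature feature lengths differ")
    return concatenate([chem_t, curv_t], axis=1)


def chamfer_loss(pred: Tensor, target) -> Tensor:
    """Symmetric chamfer reconstruction loss over per-patch point sets.

    ``pred`` and ``target`` have shape (P, k, 3) in the same (center-relative)
    frame. Per patch: mean over target points of the squared distance to the
    nearest prediction, plus the mirror term; the total is the sum over
    patches.
    """
    target_t = target if isinstance(target, Tensor) else Tensor(target)
    if pred.shape[0] != target_t.shape[0]:
        raise ValueError("pred and target patch counts differ")
    if pred.shape[0] == 0 or pred.shape[1] == 0 or target_t.shape[1] == 0:
        raise ValueError("chamfer loss needs at least one point per side")
    diff = pred.reshape(pred.shape[0], pred.shape[1], 1, 3) - target_t.reshape(
        target_t.shape[0], 1, target_t.shape[1], 3
    )
    sq = (diff * diff).sum(axis=-1)  # (P, k_pred, k_tgt)
    t2p = sq.min(axis=1).mean(axis=1)  # per target point, nearest prediction
    p2t = sq.min(axis=2).mean(axis=1)  # per prediction, nearest target point
    return (t2p + p2t).sum()


class PointEncoder(nn.Module):
    """Raw chemical feature (N, 16, 7) -> local chemical feature (N, 6)."""

    N_MESSAGE_BLOCKS = 3

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        h = cfg.mp_hidden
        self.chem_dim = cfg.chem_dim
        self.embed = nn.MLP([7, h, h], rng, act="relu")
        for i in range(self.N_MESSAGE_BLOCKS):
            setattr(self, f"mp{i}", nn.MLP([cfg.chem_dim + h, h, cfg.chem_dim], rng,
                                           act="relu"))

    def forward(self, chem_raw) -> Tensor:
        x = chem_raw if isinstance(chem_raw, Tensor) else Tensor(chem_raw)
        if x.shape[-1] != 7:
            raise ValueError(f"expected trailing dim 7, got {x.shape[-1]}")
        n, k = x.shape[0], x.shape[1]
        emb = self.embed(x).relu()  # (N, k, h)
        local = Tensor(np.ones((n, self.chem_dim)))
        for i in range(self.N_MESSAGE_BLOCKS):
            expanded = local.reshape(n, 1, self.chem_dim).broadcast_to((n, k, self.chem_dim))
            msg = getattr(self, f"mp{i}")(concatenate([expanded, emb], axis=-1))
            local = local + msg.mean(axis=1)  # mean-aggregate, residual update
        return local


class PositionalMLP(nn.Module):
    """Learnable positional encoding: center coordinate (Å) -> d.

    The coordinate is lifted to random Fourier features sin/cos(B c) (B fixed
    at construction, bandwidth 1/length_scale) before a 2-layer MLP. A plain
    coordinate MLP carries a strong spectral bias toward smooth functions of
    position; the Fourier lift removes it, which matters at desk-scale step
    budgets where patch-level geometry must be regressed quickly.
    """

    def __init__(self, d: int, rng: np.random.Generator, hidden: int = 128,
                 n_freq: int = 32, length_scale: float = 1.5):
        super().__init__()
        self.register_buffer("B", rng.normal(scale=1.0 / length_scale, size=(3, n_freq)))
        self.mlp = nn.MLP([2 * n_freq, hidden, d], rng)

    def forward(self, centers) -> Tensor:
        c = np.asarray(centers.data if isinstance(centers, Tensor) else centers,
                       dtype=np.float64)
        proj = c @ self.B
        feat = np.concatenate([np.sin(proj), np.cos(proj)], axis=-1)
        return self.mlp(Tensor(feat))


class SurfaceMAE(nn.Module):
    """Encoder + masked decoder + downstream heads, built from a ModelConfig.

    ``k_prime`` (patch size) is fixed at construction because the decoder's
    linear head maps each masked slot to k' x 3 coordinates.
    """

    def __init__(self, cfg: ModelConfig, k_prime: int, seed: int = 0):
        super().__init__()
        cfg.validate_heads()
        self.cfg = cfg
        self.k_prime = k_prime
        rng = np.random.default_rng(seed)
        d = cfg.d

        self.point_encoder = PointEncoder(cfg, rng)
        self.token_mlp = nn.MLP([cfg.fused_dim, 128, d], rng, act="relu")
        self.enc_pos = PositionalMLP(d, rng, n_freq=cfg.pos_n_freq,
                                     length_scale=cfg.pos_length_scale)
        self.dec_pos = PositionalMLP(d, rng, n_freq=cfg.pos_n_freq,
                                     length_scale=cfg.pos_length_scale)
        self.cls_token = Tensor(rng.standard_normal((1, d)) * 0.02, requires_grad=True)
        self.cls_pos = Tensor(rng.standard_normal((1, d)) * 0.02, requires_grad=True)
        self.encoder = nn.TransformerStack(d, cfg.encoder_depth, cfg.encoder_heads,
                                           cfg.mlp_ratio, rng)
        self.dec_proj = nn.Linear(d, d, rng)
        self.mask_token = Tensor(rng.standard_normal((1, d)) * 0.02, requires_grad=True)
        self.decoder = nn.TransformerStack(d, cfg.decoder_depth, cfg.decoder_heads,
                                           cfg.mlp_ratio, rng)
        self.coord_head = nn.Linear(d, k_prime * 3, rng)

        # downstream heads
        self.site_head = nn.MLP([2 * d + cfg.fused_dim, 256, 64, 1], rng)
        self.pocket_head = nn.MLP([2 * d, 256, cfg.n_classes], rng)
        if cfg.descriptor_dim != d:
            self.desc_proj = nn.Linear(d, cfg.descriptor_dim, rng)
        else:
            self.desc_proj = None
        self.desc_scale = Tensor(np.array([5.0]), requires_grad=True)

    # ------------------------------------------------------------ tokenizing
    def fused_point_features(self, cloud: SurfaceCloud) -> Tensor:
        chem = self.point_encoder(cloud.chem_raw)
        return fuse_features(chem, Tensor(cloud.curvatures))

    def tokenize(self, patchset: PatchSet, fused: Tensor, visible_only: bool = True) -> Tensor:
        """Per-patch tokens: shared MLP on member features, max-pool over k'."""
        sel = ~patchset.mask if visible_only else np.ones(patchset.g, dtype=bool)
        members = patchset.members[sel]
        if members.size == 0:
            raise ValueError("no patches to tokenize")
        point_feats = self.token_mlp(fused)  # (N, d)
        gathered = point_feats[members]  # (q, k', d)
        return gathered.max(axis=1)

    # --------------------------------------------------------------- encoder
    def encode(self, tokens: Tensor, positions: Tensor, use_cls: bool = False) -> Tensor:
        """Transformer over tokens + positions; CLS (with its own learnable
        position) is prepended when requested and is row 0 of the output."""
        if tokens.shape != positions.shape:
            raise ValueError("tokens and positions must share a shape")
        if tokens.shape[-1] != self.cfg.d:
            raise ValueError(f"token width {tokens.shape[-1]} != d={self.cfg.d}")
        x = tokens + positions
        if use_cls:
            x = concatenate([self.cls_token + self.cls_pos, x], axis=0)
        return self.encoder(x)

    # --------------------------------------------------------------- decoder
    def decode_masked(self, h_visible: Tensor, visible_centers: np.ndarray,
                      masked_centers: np.ndarray) -> Tensor:
        """Predict the masked patches' coordinates, center-relative.

        Output shape (n_masked, k', 3); only masked slots are returned. The
        CLS row, if any, must be stripped by the caller before this point.
        """
        n_masked = masked_centers.shape[0]
        if n_masked == 0:
            raise ValueError("decode_masked requires at least one masked patch")
        x_vis = self.dec_proj(h_visible) + self.dec_pos(visible_centers)
        x_mask = self.mask_token.broadcast_to((n_masked, self.cfg.d)) + self.dec_pos(
            masked_centers
        )
        h = self.decoder(concatenate([x_vis, x_mask], axis=0))
        h_masked = h[np.arange(h.shape[0] - n_masked, h.shape[0])]
        return self.coord_head(h_masked).reshape(n_masked, self.k_prime, 3)

    # ------------------------------------------------------------ pretraining
    def pretrain_forward(self, cloud: SurfaceCloud, patchset: PatchSet,
                         use_cls: bool = False) -> Tensor:
        """Full masked-reconstruction forward pass; returns the chamfer loss."""
        fused = self.fused_point_features(cloud)
        tokens = self.tokenize(patchset, fused, visible_only=True)
        centers = patchset.centers
        vis_centers = centers[~patchset.mask]
        mask_centers = centers[patchset.mask]
        h = self.encode(tokens, self.enc_pos(vis_centers), use_cls=use_cls)
        if use_cls:
            h = h[np.arange(1, h.shape[0])]  # CLS never reaches the decoder
        pred = self.decode_masked(h, vis_centers, mask_centers)
        target = cloud.points[patchset.members[patchset.mask]] - mask_centers[:, None, :]
        return chamfer_loss(pred, target)

    # ------------------------------------------------------- downstream heads
    def _interpolate_tokens(self, h: Tensor, patchset: PatchSet,
                            n_nearest: int = 3) -> Tensor:
        """Patch tokens -> per-point features by inverse-distance interpolation
        over the 3 nearest patch centers (weights sum to 1 per point)."""
        if patchset.n_masked:
            raise ValueError("downstream heads require an unmasked patchset (m=0)")
        centers = patchset.centers
        d = np.linalg.norm(patchset.points[:, None, :] - centers[None, :, :], axis=2)
        order = np.argsort(d, axis=1, kind="stable")[:, :n_nearest]
        nd = np.take_along_axis(d, order, axis=1)
        w = 1.0 / (nd + 1e-8)
        w /= w.sum(axis=1, keepdims=True)
        gathered = h[order]  # (N, 3, d)
        return (gathered * Tensor(w[:, :, None])).sum(axis=1)

    def head_site(self, h: Tensor, patchset: PatchSet, fused: Tensor) -> Tensor:
        """Per-point binding-site logits, shape (N,)."""
        interp = self._interpolate_tokens(h, patchset)
        global_feat = h.max(axis=0, keepdims=True).broadcast_to(interp.shape)
        x = concatenate([interp, fused, global_feat], axis=1)
        return self.site_head(x).reshape(interp.shape[0])

    def head_pocket(self, h_with_cls: Tensor) -> Tensor:
        """Cofactor-class logits from CLS + max-pooled tokens, shape (n_classes,)."""
        if h_with_cls.shape[0] < 2:
            raise ValueError("pocket head needs a CLS row plus at least one token")
        cls = h_with_cls[np.arange(0, 1)]
        pooled = h_with_cls[np.arange(1, h_with_cls.shape[0])].max(axis=0, keepdims=True)
        return self.pocket_head(concatenate([cls, pooled], axis=1)).reshape(self.cfg.n_classes)

    def head_descriptor(self, h: Tensor, patchset: PatchSet) -> Tensor:
        """Per-point L2-normalised descriptors, shape (N, descriptor_dim)."""
        x = self._interpolate_tokens(h, patchset)
        if self.desc_proj is not None:
            x = self.desc_proj(x)
        norm = ((x * x).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
        return x / norm

    def pair_logits(self, desc_a: Tensor, desc_b: Tensor) -> Tensor:
        """Binding logit for aligned descriptor rows: scaled dot product."""
        return (desc_a * desc_b).sum(axis=1) * self.desc_scale.reshape(())

    # --------------------------------------------------------- shared encode
    def encode_surface(self, cloud: SurfaceCloud, patchset: PatchSet,
                       use_cls: bool = False) -> tuple[Tensor, Tensor]:
        """Tokenize-and-encode an unmasked surface; returns (h, fused)."""
        fused = self.fused_point_features(cloud)
        tokens = self.tokenize(patchset, fused, visible_only=True)
        h = self.encode(tokens, self.enc_pos(patchset.centers[~patchset.mask]),
                        use_cls=use_cls)
        return h, fused

    # ---------------------------------------------------------- transferable
    def encoder_state(self) -> dict[str, np.ndarray]:
        """Weights transferred from pretraining to fine-tuning (the encoder
        side: point encoder, tokenizer, positional MLP, transformer, CLS)."""
        keep = ("point_encoder.", "token_mlp.", "enc_pos.", "encoder.", "cls_token",
                "cls_pos")
        return {k: v for k, v in self.state_dict().items() if k.startswith(keep)}

    def load_encoder_state(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        buffers = self.named_buffers()
        for k, v in state.items():
            if k in params:
                params[k].data = np.asarray(v, dtype=np.float64).copy()
            elif k in buffers:
                *path, leaf = k.split(".")
                owner = self
                for part in path:
                    owner = getattr(owner, part)
                owner.register_buffer(leaf, v)
            else:
                raise KeyError(f"unknown encoder parameter {k}")
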