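"""Pretraining, fine-tuning and evaluation.

The entry points follow a model/results idiom: a trainer object is built
from data and configuration, its ``fit()`` runs the optimisation and returns
a results object carrying the loss curve, selected checkpoint and metrics,
with a ``summary()`` for quick inspection.

Pretraining follows the published protocol: per sample, patchify, mask a
ratio m of patches with a fresh seed each epoch, encode the visible patches,
decode the masked ones and minimise the chamfer reconstruction loss with
AdamW. The checkpoint with minimal reconstruction loss initialises the
fine-tuning encoder; fine-tuning never masks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .config import ModelConfig, PatchConfig, TrainConfig
from .model import SurfaceMAE
from .nn import AdamW, Tensor
from .patches import PatchSet, apply_mask, make_patches
from .surface import SurfaceCloud

# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve as the rank statistic: the probability that a
    random positive outscores a random negative, ties counting 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes")
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def classification_metrics(predictions, labels, threshold: float = 0.5) -> dict:
    """Accuracy, recall and F1 at a fixed threshold on scores in [0, 1]."""
    scores = np.asarray(predictions, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.size == 0:
        raise ValueError("empty input")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    accuracy = (tp + tn) / scores.size
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"accuracy": accuracy, "recall": recall, "f1": f1}


def balanced_accuracy(predictions, labels, n_classes: int) -> float:
    """Unweighted mean of per-class recalls."""
    pred = np.asarray(predictions).astype(int)
    labels = np.asarray(labels).astype(int)
    recalls = []
    for c in range(n_classes):
        in_class = labels == c
        if not in_class.any():
            raise ValueError(f"class {c} absent from labels")
        recalls.append(float(np.mean(pred[in_class] == c)))
    return float(np.mean(recalls))


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------


def _softplus(z: Tensor) -> Tensor:
    # relu(z) + log(1 + exp(-|z|)), stable for large |z|
    a = z.relu() + (-z).relu()
    return z.relu() + ((-a).exp() + 1.0).log()


def binary_cross_entropy_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean BCE over a 1-D logit tensor; targets are 0/1 floats."""
    t = np.asarray(targets, dtype=np.float64)
    return (_softplus(logits) - logits * Tensor(t)).mean()


def balanced_cross_entropy(logits: Tensor, labels, seed: int) -> Tensor:
    """dMaSIF-style class-balanced BCE: the majority class is subsampled
    (seeded, without replacement) to the minority count before the mean."""
    labels = np.asarray(labels).astype(int)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("balanced cross-entropy requires both classes")
    rng = np.random.default_rng(seed)
    if len(pos_idx) > len(neg_idx):
        pos_idx = rng.choice(pos_idx, size=len(neg_idx), replace=False)
    elif len(neg_idx) > len(pos_idx):
        neg_idx = rng.choice(neg_idx, size=len(pos_idx), replace=False)
    idx = np.concatenate([pos_idx, neg_idx])
    return binary_cross_entropy_with_logits(logits[idx], labels[idx])


def cross_entropy(logits: Tensor, label: int) -> Tensor:
    """Multi-class CE for a single (n_classes,) logit vector."""
    m = float(logits.data.max())
    lse = ((logits - m).exp().sum()).log() + m
    return lse - logits[np.arange(label, label + 1)].sum()


# --------------------------------------------------------------------------
# pretraining
# --------------------------------------------------------------------------


def select_best(losses: list[float]) -> int:
    """1-indexed epoch with minimal reconstruction loss; ties -> earliest."""
    if not losses:
        raise ValueError("empty loss log")
    return int(np.argmin(losses)) + 1


@dataclass
class TrainState:
    """Bookkeeping for a (pre)training run."""

    epoch: int = 0
    losses: list[float] = field(default_factory=list)
    seed: int = 0

    @property
    def best_epoch(self) -> int:
        return select_best(self.losses)


@dataclass
class PretrainResults:
    state: TrainState
    model: SurfaceMAE
    best_state_dict: dict
    final_state_dict: dict

    @property
    def loss_curve(self) -> list[float]:
        return self.state.losses

    @property
    def best_epoch(self) -> int:
        return self.state.best_epoch

    def summary(self) -> str:
        s = self.state
        lines = [
            "Masked-autoencoder pretraining",
            f"  epochs run        : {s.epoch}",
            f"  first-epoch loss  : {s.losses[0]:.4f}",
            f"  final-epoch loss  : {s.losses[-1]:.4f}",
            f"  best epoch (min L): {s.best_epoch} ({min(s.losses):.4f})",
            f"  parameters        : {self.model.n_parameters()}",
        ]
        return "\n".join(lines)


class Pretrainer:
    """Masked-reconstruction pretraining over a dataset of surface clouds."""

    def __init__(
        self,
        dataset: list[SurfaceCloud],
        model_cfg: ModelConfig,
        patch_cfg: PatchConfig,
        train_cfg: TrainConfig | None = None,
        seed: int = 0,
    ):
        if not dataset:
            raise ValueError("empty pretraining dataset")
        n_pts = {c.n_points for c in dataset}
        if len(n_pts) != 1:
            raise ValueError(f"all clouds must share a point count, got {sorted(n_pts)}")
        self.dataset = dataset
        self.model_cfg = model_cfg
        self.patch_cfg = patch_cfg
        self.train_cfg = train_cfg or TrainConfig()
        self.seed = seed
        self.model = SurfaceMAE(model_cfg, patch_cfg.k_prime, seed=seed)
        # FPS/KNN are deterministic per cloud; compute once
        self._patchsets = [
            make_patches(c.points, patch_cfg.g, patch_cfg.k_prime) for c in dataset
        ]

    def fit(self, epochs: int | None = None, log_path: str | Path | None = None,
            checkpoint_dir: str | Path | None = None,
            resample_masks: bool = True) -> PretrainResults:
        """Run the optimisation.

        ``resample_masks=False`` freezes each sample's mask at its epoch-1
        draw — the deterministic-target setting used by the single-sample
        overfit smoke test; normal pretraining redraws masks every epoch.
        """
        tc = self.train_cfg
        epochs = epochs or tc.epochs
        opt = AdamW(self.model.parameters(), lr=tc.lr, betas=(0.9, tc.adam_beta2),
                    weight_decay=tc.weight_decay)
        state = TrainState(seed=self.seed)
        best_loss, best_sd = np.inf, None
        log_f = open(log_path, "a") if log_path else None
        try:
            for epoch in range(1, epochs + 1):
                if tc.schedule == "cosine":
                    opt.lr = tc.lr * 0.5 * (1 + np.cos(np.pi * (epoch - 1) / epochs))
                epoch_losses = []
                pending = 0
                order = np.random.default_rng(
                    np.random.SeedSequence([self.seed, epoch, 0xA1])
                ).permutation(len(self.dataset))
                for j, i in enumerate(order):
                    cloud, ps = self.dataset[i], self._patchsets[i]
                    mask_epoch = epoch if resample_masks else 1
                    mask_seed = int(
                        np.random.SeedSequence(
                            [self.seed, mask_epoch, i]).generate_state(1)[0]
                        % (2**31)
                    )
                    masked = apply_mask(ps, self.patch_cfg.m, mask_seed)
                    loss = self.model.pretrain_forward(cloud, masked)
                    if not np.isfinite(loss.item()):
                        raise RuntimeError(
                            f"non-finite chamfer loss at epoch {epoch}, sample {i}"
                        )
                    loss.backward()
                    epoch_losses.append(loss.item())
                    pending += 1
                    if pending == tc.batch_size or j == len(self.dataset) - 1:
                        for p in self.model.parameters():
                            if p.grad is not None:
                                p.grad /= pending
                        opt.step()
                        opt.zero_grad()
                        pending = 0
                mean_loss = float(np.mean(epoch_losses))
                state.losses.append(mean_loss)
                state.epoch = epoch
                if log_f:
                    log_f.write(json.dumps({"epoch": epoch, "split": "pretrain",
                                            "loss": mean_loss}) + "\n")
                if checkpoint_dir:
                    from .io import save_checkpoint  # local import: io needs model types
                    save_checkpoint(Path(checkpoint_dir) / f"epoch_{epoch:04d}.npz",
                                    self.model, meta={"epoch": epoch, "loss": mean_loss,
                                                      "seed": self.seed})
                if mean_loss < best_loss:
                    best_loss, best_sd = mean_loss, self.model.state_dict()
        finally:
            if log_f:
                log_f.close()
        return PretrainResults(state, self.model, best_sd, self.model.state_dict())


# --------------------------------------------------------------------------
# fine-tuning
# --------------------------------------------------------------------------


@dataclass
class FinetuneResults:
    task: str
    model: SurfaceMAE
    train_losses: list[float]
    metrics: dict

    def summary(self) -> str:
        lines = [f"Fine-tuning results — task: {self.task}",
                 f"  epochs run       : {len(self.train_losses)}",
                 f"  final train loss : {self.train_losses[-1]:.4f}"]
        for k, v in self.metrics.items():
            lines.append(f"  {k:<17}: {v:.4f}" if isinstance(v, float) else f"  {k}: {v}")
        return "\n".join(lines)


class _FinetunerBase:
    def __init__(self, model_cfg: ModelConfig, patch_cfg: PatchConfig,
                 train_cfg: TrainConfig | None, seed: int,
                 init_state: dict | None):
        self.model_cfg = model_cfg
        self.patch_cfg = patch_cfg
        self.train_cfg = train_cfg or TrainConfig()
        self.seed = seed
        self.model = SurfaceMAE(model_cfg, patch_cfg.k_prime, seed=seed)
        if init_state is not None:
            # transfer only encoder-side weights (and fixed positional
            # projections) from the pretrained model
            known = (set(self.model.named_parameters())
                     | set(self.model.named_buffers()))
            enc = {k: v for k, v in init_state.items()
                   if k in known
                   and k.startswith(("point_encoder.", "token_mlp.", "enc_pos.",
                                     "encoder.", "cls_token", "cls_pos"))}
            self.model.load_encoder_state(enc)

    def _patchset(self, cloud: SurfaceCloud) -> PatchSet:
        return make_patches(cloud.points, self.patch_cfg.g, self.patch_cfg.k_prime)


class SiteFinetuner(_FinetunerBase):
    """Per-point binding-site segmentation with class-balanced BCE."""

    def __init__(self, dataset: list[tuple[SurfaceCloud, np.ndarray]],
                 model_cfg: ModelConfig, patch_cfg: PatchConfig,
                 train_cfg: TrainConfig | None = None, seed: int = 0,
                 init_state: dict | None = None):
        super().__init__(model_cfg, patch_cfg, train_cfg, seed, init_state)
        for cloud, labels in dataset:
            if len(labels) != cloud.n_points:
                raise ValueError("labels misaligned with surface points")
        self.dataset = dataset
        self._patchsets = [self._patchset(c) for c, _ in dataset]

    def fit(self, epochs: int | None = None,
            eval_dataset: list[tuple[SurfaceCloud, np.ndarray]] | None = None
            ) -> FinetuneResults:
        tc = self.train_cfg
        epochs = epochs or tc.finetune_epochs
        opt = AdamW(self.model.parameters(), lr=tc.finetune_lr,
                    betas=(0.9, tc.adam_beta2), weight_decay=tc.weight_decay)
        losses = []
        step = 0
        for epoch in range(epochs):
            epoch_losses = []
            order = np.random.default_rng(
                np.random.SeedSequence([self.seed, epoch, 0xB2])
            ).permutation(len(self.dataset))
            for i in order:
                (cloud, labels), ps = self.dataset[i], self._patchsets[i]
                h, fused = self.model.encode_surface(cloud, ps)
                logits = self.model.head_site(h, ps, fused)
                loss = balanced_cross_entropy(logits, labels,
                                              seed=self.seed + 7919 * step)
                loss.backward()
                opt.step()
                opt.zero_grad()
                epoch_losses.append(loss.item())
                step += 1
            losses.append(float(np.mean(epoch_losses)))
        metrics = self.evaluate(eval_dataset) if eval_dataset else {}
        return FinetuneResults("site", self.model, losses, metrics)

    def predict(self, cloud: SurfaceCloud) -> np.ndarray:
        """Per-point interface probability."""
        ps = self._patchset(cloud)
        h, fused = self.model.encode_surface(cloud, ps)
        logits = self.model.head_site(h, ps, fused)
        return 1.0 / (1.0 + np.exp(-logits.data))

    def evaluate(self, dataset: list[tuple[SurfaceCloud, np.ndarray]]) -> dict:
        scores = np.concatenate([self.predict(c) for c, _ in dataset])
        labels = np.concatenate([l for _, l in dataset])
        out = {"roc_auc": roc_auc(scores, labels)}
        out.update(classification_metrics(scores, labels))
        return out


class PocketFinetuner(_FinetunerBase):
    """Seven-way cofactor-preference classification via the CLS token."""

    def __init__(self, dataset: list[tuple[SurfaceCloud, int]],
                 model_cfg: ModelConfig, patch_cfg: PatchConfig,
                 train_cfg: TrainConfig | None = None, seed: int = 0,
                 init_state: dict | None = None):
        super().__init__(model_cfg, patch_cfg, train_cfg, seed, init_state)
        for _, y in dataset:
            if not 0 <= y < model_cfg.n_classes:
                raise ValueError(f"class {y} out of range [0, {model_cfg.n_classes})")
        self.dataset = dataset
        self._patchsets = [self._patchset(c) for c, _ in dataset]

    def fit(self, epochs: int | None = None,
            eval_dataset: list[tuple[SurfaceCloud, int]] | None = None
            ) -> FinetuneResults:
        tc = self.train_cfg
        epochs = epochs or tc.finetune_epochs
        opt = AdamW(self.model.parameters(), lr=tc.finetune_lr,
                    betas=(0.9, tc.adam_beta2), weight_decay=tc.weight_decay)
        losses = []
        for epoch in range(epochs):
            epoch_losses = []
            order = np.random.default_rng(
                np.random.SeedSequence([self.seed, epoch, 0xC3])
            ).permutation(len(self.dataset))
            for i in order:
                (cloud, y), ps = self.dataset[i], self._patchsets[i]
                h, _ = self.model.encode_surface(cloud, ps, use_cls=True)
                logits = self.model.head_pocket(h)
                loss = cross_entropy(logits, y)
                loss.backward()
                opt.step()
                opt.zero_grad()
                epoch_losses.append(loss.item())
            losses.append(float(np.mean(epoch_losses)))
        metrics = self.evaluate(eval_dataset) if eval_dataset else {}
        return FinetuneResults("pocket", self.model, losses, metrics)

    def predict(self, cloud: SurfaceCloud) -> int:
        ps = self._patchset(cloud)
        h, _ = self.model.encode_surface(cloud, ps, use_cls=True)
        return int(np.argmax(self.model.head_pocket(h).data))

    def evaluate(self, dataset: list[tuple[SurfaceCloud, int]]) -> dict:
        preds = np.array([self.predict(c) for c, _ in dataset])
        labels = np.array([y for _, y in dataset])
        return {"balanced_accuracy": balanced_accuracy(preds, labels,
                                                       self.model_cfg.n_classes)}


class PPIFinetuner(_FinetunerBase):
    """Descriptor matching for protein-protein interfaces.

    Each sample is (cloud_a, cloud_b, positive_pairs) where positive_pairs
    holds (i, j) index pairs of interacting points. Training scores a 1:1
    balanced, seeded sample of positive and random negative pairs by the
    scaled dot product of L2-normalised descriptors, under BCE.
    """

    def __init__(self, dataset: list[tuple[SurfaceCloud, SurfaceCloud, np.ndarray]],
                 model_cfg: ModelConfig, patch_cfg: PatchConfig,
                 train_cfg: TrainConfig | None = None, seed: int = 0,
                 init_state: dict | None = None, pairs_per_step: int = 64):
        super().__init__(model_cfg, patch_cfg, train_cfg, seed, init_state)
        for _, _, pairs in dataset:
            if len(pairs) == 0:
                raise ValueError("each PPI sample needs at least one positive pair")
        self.dataset = dataset
        self.pairs_per_step = pairs_per_step
        self._patchsets = [(self._patchset(a), self._patchset(b))
                           for a, b, _ in dataset]

    def _descriptors(self, cloud: SurfaceCloud, ps: PatchSet):
        h, _ = self.model.encode_surface(cloud, ps)
        return self.model.head_descriptor(h, ps)

    def fit(self, epochs: int | None = None,
            eval_dataset: list[tuple[SurfaceCloud, SurfaceCloud, np.ndarray]] | None = None
            ) -> FinetuneResults:
        tc = self.train_cfg
        epochs = epochs or tc.finetune_epochs
        opt = AdamW(self.model.parameters(), lr=tc.finetune_lr,
                    betas=(0.9, tc.adam_beta2), weight_decay=tc.weight_decay)
        losses = []
        step = 0
        for epoch in range(epochs):
            epoch_losses = []
            order = np.random.default_rng(
                np.random.SeedSequence([self.seed, epoch, 0xD4])
            ).permutation(len(self.dataset))
            for i in order:
                (a, b, pos), (ps_a, ps_b) = self.dataset[i], self._patchsets[i]
                rng = np.random.default_rng(self.seed + 104729 * step)
                n = min(self.pairs_per_step, len(pos))
                pos_sel = pos[rng.choice(len(pos), size=n, replace=False)]
                neg_sel = np.stack([rng.integers(0, a.n_points, size=n),
                                    rng.integers(0, b.n_points, size=n)], axis=1)
                da = self._descriptors(a, ps_a)
                db = self._descriptors(b, ps_b)
                idx = np.concatenate([pos_sel, neg_sel])
                logits = self.model.pair_logits(da[idx[:, 0]], db[idx[:, 1]])
                targets = np.concatenate([np.ones(n), np.zeros(n)])
                loss = binary_cross_entropy_with_logits(logits, targets)
                loss.backward()
                opt.step()
                opt.zero_grad()
                epoch_losses.append(loss.item())
                step += 1
            losses.append(float(np.mean(epoch_losses)))
        metrics = self.evaluate(eval_dataset) if eval_dataset else {}
        return FinetuneResults("ppi", self.model, losses, metrics)

    def evaluate(self, dataset, n_neg_per_pos: int = 1, seed: int | None = None) -> dict:
        """ROC-AUC over positive pairs vs an equal number of random pairs."""
        rng = np.random.default_rng(self.seed if seed is None else seed)
        scores, labels = [], []
        for a, b, pos in dataset:
            ps_a, ps_b = self._patchset(a), self._patchset(b)
            da = self._descriptors(a, ps_a).data
            db = self._descriptors(b, ps_b).data
            s = float(self.model.desc_scale.data[0])
            for i, j in pos:
                scores.append(s * float(da[i] @ db[j]))
                labels.append(1)
            neg = np.stack([rng.integers(0, a.n_points, size=len(pos) * n_neg_per_pos),
                            rng.integers(0, b.n_points, size=len(pos) * n_neg_per_pos)],
                           axis=1)
            for i, j in neg:
                scores.append(s * float(da[i] @ db[j]))
                labels.append(0)
        return {"roc_auc": roc_auc(np.array(scores), np.array(labels))}
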