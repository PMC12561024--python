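"""Training loop, cross-validation and the fold-ensemble ("weighted model").

One fold trains the network with the scheduled WBCE/soft-clDice compound
loss under AdamW; the learning rate is halved after a patience of
non-improving validation-loss epochs, while the checkpoint kept is the one
with the best validation *centerline Dice* — two different monitors, used
side by side on purpose.  Cross-validation partitions patients (groups)
into folds, trains one model per fold, and combines them at prediction
time by averaging sigmoid probabilities.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .data_io import AugmentConfig, BModeFrame, CenterlineMask, augment
from .losses import CombinedLoss, LossSchedule, SoftSkeletonParams, blend_weights
from .metrics import cl_dice
from .nn.autodiff import Tensor
from .nn.functional import _sigmoid_np
from .unext import UNeXt, UNeXtConfig, build_model


@dataclass
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 5e-4
    scheduler_factor: float = 0.5
    scheduler_patience: int = 3
    n_folds: int = 5
    total_epochs: int = 60
    batch_size: int = 8
    seed: int = 0
    schedule: LossSchedule | None = None
    skeleton: SoftSkeletonParams | None = None
    model: UNeXtConfig = field(default_factory=UNeXtConfig)
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    combine: str = "uniform"        # "uniform" | "val_cldice"
    threshold: float = 0.5

    def __post_init__(self):
        if self.lr <= 0 or self.weight_decay < 0:
            raise ValueError("lr must be positive, weight_decay non-negative")
        if self.scheduler_patience < 1:
            raise ValueError("scheduler_patience must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.schedule is None:
            self.schedule = LossSchedule(total_epochs=self.total_epochs)
        if self.schedule.total_epochs != self.total_epochs:
            raise ValueError("schedule.total_epochs must match total_epochs")
        if self.skeleton is None:
            self.skeleton = SoftSkeletonParams()


@dataclass
class Sample:
    """One training/evaluation item, fully in memory."""
    image: np.ndarray               # (H, W) float32 [0, 1]
    label: np.ndarray               # (H, W) uint8 {0, 1}
    group_id: str
    pixel_spacing_mm: tuple[float, float]
    age_group: str = ""
    anatomy: str = ""


def samples_from_phantom(rendered) -> list[Sample]:
    """Adapt ``phantom.render_arrays`` output."""
    out = []
    for s, gid in rendered:
        sp = (s.pixel_spacing_mm, s.pixel_spacing_mm)
        out.append(Sample(s.image.astype(np.float32), s.label, gid, sp,
                          age_group=s.age_group, anatomy=s.anatomy))
    return out


def _batches(n, batch_size, order=None):
    idx = np.arange(n) if order is None else order
    for i in range(0, n, batch_size):
        yield idx[i:i + batch_size]


def _stack(samples, idx):
    x = np.stack([samples[i].image for i in idx])[:, None].astype(np.float32)
    t = np.stack([samples[i].label for i in idx])[:, None].astype(np.float32)
    return x, t


def train_fold(train_set: list[Sample], val_set: list[Sample],
               cfg: TrainConfig, seed: int | None = None):
    """Train one model; returns ``(best_state, history)``.

    ``best_state`` is the weight snapshot with the highest validation
    clDice; ``history`` is a per-epoch DataFrame (losses, val clDice, LR,
    blend weights).
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    model = build_model(cfg.model, seed=int(rng.integers(2 ** 31)))
    opt = nn.AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    sched = nn.ReduceLROnPlateau(opt, factor=cfg.scheduler_factor,
                                 patience=cfg.scheduler_patience)
    loss_fn = CombinedLoss(cfg.schedule, cfg.skeleton)

    # augmentation replaces a seeded random quarter of the training set once
    if cfg.augment is not None and cfg.augment.augment_fraction > 0:
        train_set = [_augment_sample(s, cfg.augment, rng) for s in train_set]

    best_cldice = -1.0
    best_state = model.state_dict()
    best_epoch = 0
    history = []
    for epoch in range(1, cfg.total_epochs + 1):
        order = rng.permutation(len(train_set))
        model.train()
        train_losses = []
        for bidx in _batches(len(train_set), cfg.batch_size, order):
            x, t = _stack(train_set, bidx)
            logits = model(Tensor(x))
            loss = loss_fn(logits, t, epoch)
            lv = float(loss.data)
            if not np.isfinite(lv):
                raise RuntimeError(
                    f"non-finite training loss {lv} at epoch {epoch} "
                    f"(lr={opt.lr:.2e}); aborting")
            model.zero_grad()
            loss.backward()
            opt.step()
            train_losses.append(lv)

        val_loss, val_cld = _validate(model, val_set, loss_fn, cfg, epoch)
        sched.step(val_loss)
        w_wbce, w_cl = blend_weights(epoch, cfg.schedule)
        history.append({
            "epoch": epoch, "train_loss": float(np.mean(train_losses)),
            "val_loss": val_loss, "val_cldice": val_cld, "lr": opt.lr,
            "w_wbce": w_wbce, "w_cl": w_cl,
        })
        if val_cld > best_cldice:
            best_cldice = val_cld
            best_state = model.state_dict()
            best_epoch = epoch

    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best_epoch
    hist.attrs["best_val_cldice"] = best_cldice
    return best_state, hist


def _augment_sample(s: Sample, aug_cfg: AugmentConfig, rng) -> Sample:
    frame = BModeFrame(s.image, s.pixel_spacing_mm, source_id=s.group_id)
    mask = CenterlineMask(s.label, s.pixel_spacing_mm)
    f2, m2 = augment(frame, mask, aug_cfg, rng)
    return dataclasses.replace(s, image=f2.pixels, label=m2.pixels)


def _validate(model, val_set, loss_fn, cfg, epoch):
    model.eval()
    losses = []
    cldices = []
    with nn.no_grad():
        for bidx in _batches(len(val_set), cfg.batch_size):
            x, t = _stack(val_set, bidx)
            logits = model(Tensor(x))
            losses.append(float(loss_fn(logits, t, epoch).data))
            probs = _sigmoid_np(logits.data)
            preds = (probs >= cfg.threshold).astype(np.uint8)
            for k, i in enumerate(bidx):
                cldices.append(cl_dice(preds[k, 0], val_set[i].label).cl_dice)
    model.train()
    return float(np.mean(losses)), float(np.mean(cldices))


# ----------------------------------------------------------------------
# cross-validation ensemble
# ----------------------------------------------------------------------

@dataclass
class FoldEnsemble:
    model_cfg: UNeXtConfig
    fold_states: list[dict]
    fold_val_scores: list[float]
    combine: str = "uniform"
    threshold: float = 0.5

    def __post_init__(self):
        if not self.fold_states:
            raise ValueError("ensemble needs at least one fold model")

    def _weights(self):
        if self.combine == "uniform":
            w = np.ones(len(self.fold_states))
        elif self.combine == "val_cldice":
            w = np.asarray(self.fold_val_scores, dtype=float)
            if w.sum() <= 0:
                w = np.ones(len(self.fold_states))
        else:
            raise ValueError(f"unknown combine rule {self.combine!r}")
        return w / w.sum()

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Weighted mean of per-fold sigmoid outputs; images (N,1,H,W) or (H,W)."""
        single = images.ndim == 2
        if single:
            images = images[None, None]
        probs = np.zeros(images.shape, dtype=np.float64)
        model = build_model(self.model_cfg)
        for state, w in zip(self.fold_states, self._weights()):
            model.load_state_dict(state)
            probs += w * model.predict_proba(images.astype(np.float32))
        return probs[0, 0] if single else probs

    def predict(self, images: np.ndarray):
        probs = self.predict_proba(images)
        return probs, (probs >= self.threshold).astype(np.uint8)


def group_folds(samples: list[Sample], n_folds: int, seed: int):
    """Partition groups into ``n_folds`` validation chunks (group-disjoint)."""
    groups = sorted({s.group_id for s in samples})
    if len(groups) < n_folds:
        raise ValueError(f"need >= {n_folds} groups, got {len(groups)}")
    rng = np.random.default_rng(seed)
    rng.shuffle(groups)
    return [set(chunk) for chunk in np.array_split(groups, n_folds)]


def cross_validate(samples: list[Sample], cfg: TrainConfig):
    """Group-aware k-fold training; returns ``(ensemble, histories)``."""
    chunks = group_folds(samples, cfg.n_folds, cfg.seed)
    states, scores, histories = [], [], []
    for fold, val_groups in enumerate(chunks):
        train_set = [s for s in samples if s.group_id not in val_groups]
        val_set = [s for s in samples if s.group_id in val_groups]
        state, hist = train_fold(train_set, val_set, cfg,
                                 seed=cfg.seed + 1000 * (fold + 1))
        states.append(state)
        scores.append(float(hist.attrs["best_val_cldice"]))
        histories.append(hist)
    ensemble = FoldEnsemble(cfg.model, states, scores,
                            combine=cfg.combine, threshold=cfg.threshold)
    return ensemble, histories


def ensemble_predict(ensemble: FoldEnsemble, frame):
    """Probability map and thresholded centerline mask for one frame."""
    pixels = frame.pixels if hasattr(frame, "pixels") else np.asarray(frame)
    return ensemble.predict(pixels)


def save_ensemble(path, ensemble: FoldEnsemble):
    import json
    cfg = ensemble.model_cfg
    meta = json.dumps({
        "model": {
            "in_channels": cfg.in_channels,
            "conv_channels": list(cfg.conv_channels),
            "embed_dims": list(cfg.embed_dims),
            "conv_kernel": cfg.conv_kernel,
            "mlp_hidden_ratio": cfg.mlp_hidden_ratio,
            "out_channels": cfg.out_channels,
            "input_size": list(cfg.input_size),
        },
        "n_folds": len(ensemble.fold_states),
        "fold_val_scores": ensemble.fold_val_scores,
        "combine": ensemble.combine,
        "threshold": ensemble.threshold,
    })
    arrays = {"__meta__": np.array(meta)}
    for i, state in enumerate(ensemble.fold_states):
        for k, v in state.items():
            arrays[f"fold{i}/{k}"] = v
    np.savez(path, **arrays)


def load_ensemble(path) -> FoldEnsemble:
    import json
    with np.load(path) as data:
        meta = json.loads(str(data["__meta__"]))
        states = [dict() for _ in range(meta["n_folds"])]
        for key in data.files:
            if key == "__meta__":
                continue
            fold, name = key.split("/", 1)
            states[int(fold[4:])][name] = data[key]
    mc = meta["model"]
    cfg = UNeXtConfig(
        in_channels=mc["in_channels"], conv_channels=tuple(mc["conv_channels"]),
        embed_dims=tuple(mc["embed_dims"]), conv_kernel=mc["conv_kernel"],
        mlp_hidden_ratio=mc["mlp_hidden_ratio"], out_channels=mc["out_channels"],
        input_size=tuple(mc["input_size"]))
    return FoldEnsemble(cfg, states, meta["fold_val_scores"],
                        combine=meta["combine"], threshold=meta["threshold"])
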