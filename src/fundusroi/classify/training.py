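"""Branch training: Adam schedule, branch-specific losses, online
augmentation, and best-epoch selection by mean validation AUC.

The optic-disc branch is a two-class (background / disease) head trained with
softmax cross-entropy; the multi-target branches use element-wise sigmoid
binary cross-entropy. The checkpoint restored at the end is the epoch with
the highest mean validation AUC over the branch's targets (earliest epoch on
ties).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .. import evaluate
from .backbones import Adam, Params, TinyMLP, build_backbone
from .routing import BRANCH_REGION, BRANCH_TARGETS
from .transforms import augment, resize_to

DEFAULT_LR = {
    "od_gs": 1e-3,
    "mac_erm_amd": 1e-3,
    "full_dr_rb_rvo": 1e-4,
    "baseline_full6": 1e-4,
}


@dataclass(frozen=True)
class BranchConfig:
    branch_id: str
    backbone: str = "tiny-mlp"
    input_size: int = 32
    batch_size: int = 8
    epochs: int = 60
    lr_init: Optional[float] = None      # None -> branch default
    lr_decay: float = 0.5
    lr_decay_every: int = 10
    norm_mean: float = 0.5
    norm_sd: float = 0.5
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.branch_id not in BRANCH_TARGETS:
            raise ValueError(f"unknown branch {self.branch_id!r}")
        if self.lr_init is not None and self.lr_init <= 0:
            raise ValueError("lr_init must be positive")
        if not self.targets:
            raise ValueError("branch has no targets")

    @property
    def targets(self) -> Tuple[str, ...]:
        return BRANCH_TARGETS[self.branch_id]

    @property
    def region(self) -> str:
        return BRANCH_REGION[self.branch_id]

    @property
    def learning_rate(self) -> float:
        return self.lr_init if self.lr_init is not None else DEFAULT_LR[self.branch_id]

    @property
    def is_two_class(self) -> bool:
        """The single-disease optic-disc branch uses a softmax two-class head."""
        return self.branch_id == "od_gs"

    @property
    def n_outputs(self) -> int:
        return 2 if self.is_two_class else len(self.targets)


def softmax_ce_loss(logits: np.ndarray, classes: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its logit gradient."""
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    loss = float(-np.mean(np.log(probs[np.arange(n), classes] + 1e-12)))
    dlogits = probs.copy()
    dlogits[np.arange(n), classes] -= 1.0
    return loss, dlogits / n


def sigmoid_bce_loss(logits: np.ndarray, targets: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean element-wise binary cross-entropy with logits and its gradient."""
    z = np.asarray(logits, dtype=float)
    y = np.asarray(targets, dtype=float)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    sig = 1.0 / (1.0 + np.exp(-z))
    return loss, (sig - y) / z.size


def select_best_epoch(history: Sequence[Dict]) -> int:
    """Epoch whose entry maximizes mean validation AUC (first max wins)."""
    if not history:
        raise ValueError("empty history")
    best = max(range(len(history)),
               key=lambda i: (history[i]["mean_val_auc"], -i))
    return int(history[best]["epoch"])


@dataclass
class TrainedBranch:
    config: BranchConfig
    model: TinyMLP
    history: List[Dict] = field(default_factory=list)
    best_epoch: int = -1

    def _prepare(self, images: np.ndarray) -> np.ndarray:
        c = self.config
        x = np.stack([resize_to(img, c.input_size) for img in images])
        return (x - c.norm_mean) / c.norm_sd

    def predict_logits(self, images: np.ndarray) -> np.ndarray:
        """Raw logits for images given as float arrays in [0, 1]."""
        return self.model.forward(self._prepare(images))

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Per-target probabilities, shape (n, len(targets))."""
        logits = self.predict_logits(images)
        if self.config.is_two_class:
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            return (e / e.sum(axis=1, keepdims=True))[:, 1:2]
        return 1.0 / (1.0 + np.exp(-logits))

    def save(self, path: Path | str) -> None:
        path = Path(path)
        meta = json.dumps({
            "config": self.config.__dict__,
            "best_epoch": self.best_epoch,
            "history": self.history,
            "hidden": self.model.hidden,
            "input_dim": self.model.input_dim,
            "n_outputs": self.model.n_outputs,
        })
        np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.model.params)

    @classmethod
    def load(cls, path: Path | str) -> "TrainedBranch":
        data = np.load(path)
        meta = json.loads(bytes(data["_meta"]).decode())
        config = BranchConfig(**meta["config"])
        model = TinyMLP(meta["input_dim"], tuple(meta["hidden"]),
                        meta["n_outputs"], np.random.default_rng(0))
        model.set_params({k: data[k] for k in data.files if k != "_meta"})
        branch = cls(config=config, model=model, history=meta["history"],
                     best_epoch=meta["best_epoch"])
        return branch


def _check_val_targets(val_targets: np.ndarray, names: Sequence[str]) -> None:
    for j, name in enumerate(names):
        col = val_targets[:, j]
        if col.min() == col.max():
            raise ValueError(
                f"degenerate validation split: target {name!r} is single-class"
            )


def train_branch(
    train_set: Tuple[np.ndarray, np.ndarray],
    val_set: Tuple[np.ndarray, np.ndarray],
    config: BranchConfig,
) -> TrainedBranch:
    """Train one branch and restore the best-validation-AUC checkpoint.

    ``train_set`` / ``val_set`` are ``(images, targets)`` where images are
    float arrays in [0, 1] (any resolution; resized to ``config.input_size``)
    and targets an (n, len(targets)) binary matrix in the branch's target
    order. Fully deterministic given ``config.seed``.
    """
    x_train_raw, y_train = train_set
    x_val_raw, y_val = val_set
    y_train = np.atleast_2d(np.asarray(y_train))
    y_val = np.atleast_2d(np.asarray(y_val))
    if y_train.shape[0] == 1 and len(x_train_raw) > 1:
        y_train = y_train.T
    if y_val.shape[0] == 1 and len(x_val_raw) > 1:
        y_val = y_val.T
    if len(x_train_raw) == 0 or len(x_val_raw) == 0:
        raise ValueError("train and validation sets must be non-empty")
    _check_val_targets(y_val, config.targets)

    rng = np.random.default_rng(config.seed)
    size = config.input_size
    x_train = np.stack([resize_to(img, size) for img in x_train_raw])
    x_val = np.stack([resize_to(img, size) for img in x_val_raw])
    x_val_norm = (x_val - config.norm_mean) / config.norm_sd

    input_dim = int(np.prod(x_train.shape[1:]))
    model = build_backbone(config.backbone, input_dim, config.n_outputs, rng)
    optimizer = Adam(model.params)

    y_train_cls = y_train[:, 0].astype(int) if config.is_two_class else None
    n = x_train.shape[0]
    history: List[Dict] = []
    best_params: Params = model.get_params()
    best_auc, best_epoch = -np.inf, -1

    for epoch in range(config.epochs):
        lr = config.learning_rate * config.lr_decay ** (epoch // config.lr_decay_every)
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if config.augment:
                batch = np.stack([augment(x_train[i], rng) for i in idx])
            else:
                batch = x_train[idx]
            batch = (batch - config.norm_mean) / config.norm_sd
            logits, cache = model.forward(batch, return_cache=True)
            if config.is_two_class:
                loss, dlogits = softmax_ce_loss(logits, y_train_cls[idx])
            else:
                loss, dlogits = sigmoid_bce_loss(logits, y_train[idx])
            grads = model.backward(cache, dlogits)
            optimizer.step(model.params, grads, lr)
            epoch_loss += loss
            n_batches += 1

        val_logits = model.forward(x_val_norm)
        if config.is_two_class:
            z = val_logits - val_logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            val_probs = (e / e.sum(axis=1, keepdims=True))[:, 1:2]
        else:
            val_probs = 1.0 / (1.0 + np.exp(-val_logits))
        per_target = {
            name: evaluate.auc(val_probs[:, j], y_val[:, j])
            for j, name in enumerate(config.targets)
        }
        mean_auc = float(np.mean(list(per_target.values())))
        history.append({
            "epoch": epoch,
            "train_loss": epoch_loss / max(n_batches, 1),
            "val_auc": per_target,
            "mean_val_auc": mean_auc,
            "lr": lr,
        })
        if mean_auc > best_auc:
            best_auc, best_epoch = mean_auc, epoch
            best_params = model.get_params()

    model.set_params(best_params)
    assert best_epoch == select_best_epoch(history)
    return TrainedBranch(config=config, model=model, history=history,
                         best_epoch=best_epoch)


def smoke_config(branch_id: str, **overrides) -> BranchConfig:
    """Desk-scale profile: few epochs, small inputs, tiny backbone."""
    base = BranchConfig(branch_id=branch_id, epochs=5, input_size=24,
                        backbone="tiny-mlp")
    return replace(base, **overrides)
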