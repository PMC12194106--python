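"""Loss, initialization, optimization loop and cross-validation splitting.

The model is trained end-to-end with a balanced binary cross-entropy on the
pre-sigmoid scores (optionally foreground-weighted), Adam (lr 1e-3, weight
decay 1e-4, beta1 0.9), Kaiming weight initialization, mini-batches of 32
and 3000 iterations by default, with the learning rate cut by 10x when the
validation loss plateaus. Five-fold cross-validation splitting is provided
for experiment orchestration.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor
from .config import TrainConfig
from .nn import (BatchNorm2d, Conv2d, ConvTranspose2x2, Linear, Module,
                 kaiming_normal)

__all__ = [
    "balanced_bce_loss", "init_weights", "Adam", "ReduceLROnPlateau",
    "train_loop", "five_fold_split", "dice_coefficient",
    "save_checkpoint", "load_checkpoint",
]


def balanced_bce_loss(pred_logits, gt, pos_weight: "float | None" = None) -> Tensor:
    """Mean binary cross-entropy of sigmoid(pred_logits) against a binary mask.

    ``pos_weight`` (e.g. #background/#foreground) multiplies the foreground
    terms to counter class imbalance; ``None`` gives the unweighted loss.
    Computed in a numerically stable softplus form.
    """
    return ad.bce_with_logits(as_tensor(pred_logits), np.asarray(gt), pos_weight)


def dice_coefficient(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); returns 1.0 when both masks are empty."""
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(gt_mask).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def init_weights(model: Module, seed: int) -> Module:
    """Kaiming-initialize all convolutions/linear maps, reproducibly.

    Batch norms reset to identity (weight 1, bias 0, running stats fresh)
    and the attention gates to exactly zero, so a freshly initialized
    bottleneck is a pass-through.
    """
    rng = np.random.default_rng(seed)
    for name, mod in model.named_modules():
        if isinstance(mod, Conv2d):
            k = mod.kernel_size
            mod.weight.data[...] = kaiming_normal(
                mod.weight.shape, mod.in_channels * k * k, rng)
            if mod.bias is not None:
                mod.bias.data[...] = 0.0
        elif isinstance(mod, ConvTranspose2x2):
            mod.weight.data[...] = kaiming_normal(
                mod.weight.shape, mod.in_channels * 4, rng)
            if mod.bias is not None:
                mod.bias.data[...] = 0.0
        elif isinstance(mod, Linear):
            mod.weight.data[...] = kaiming_normal(
                mod.weight.shape, mod.weight.shape[1], rng)
            if mod.bias is not None:
                mod.bias.data[...] = 0.0
        elif isinstance(mod, BatchNorm2d):
            mod.weight.data[...] = 1.0
            mod.bias.data[...] = 0.0
            mod.running_mean[...] = 0.0
            mod.running_var[...] = 1.0
    for pname, p in model.named_parameters():
        if pname.endswith(("gamma", "gamma1", "gamma2")):
            p.data[...] = 0.0
    return model


class Adam:
    """Adam with classic L2 weight decay added to the gradients."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps, self.weight_decay = eps, float(weight_decay)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def state_dict(self):
        return {"t": self.t, "m": self.m, "v": self.v, "lr": self.lr}


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` after ``patience`` evaluations
    without improvement of the monitored loss."""

    def __init__(self, optimizer: Adam, factor: float = 0.1, patience: int = 4,
                 min_delta: float = 0.0):
        self.optimizer = optimizer
        self.factor, self.patience, self.min_delta = factor, patience, min_delta
        self.best = math.inf
        self.stale = 0

    @property
    def lr(self) -> float:
        return self.optimizer.lr

    def step(self, metric: float) -> bool:
        """Record one evaluation; returns True when the rate was reduced."""
        if metric < self.best - self.min_delta:
            self.best = metric
            self.stale = 0
            return False
        self.stale += 1
        if self.stale >= self.patience:
            self.optimizer.lr *= self.factor
            self.stale = 0
            return True
        return False


def five_fold_split(dataset, seed: int):
    """Five disjoint, seeded folds of indices covering the dataset.

    Fold sizes differ by at most one; the union is the full index set.
    """
    n = len(dataset)
    if n < 5:
        raise ValueError(f"five-fold split needs at least 5 samples, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(f) for f in np.array_split(perm, 5)]


def _stack(dataset):
    """Accepts (image, mask) pairs or objects with .image/.mask, channel-first."""
    xs, ys = [], []
    for item in dataset:
        if isinstance(item, (tuple, list)):
            img, mask = item
        else:
            img, mask = item.image, item.mask
        img = np.asarray(img, dtype=np.float32)
        if img.ndim == 3 and img.shape[-1] in (1, 3) and img.shape[0] not in (1, 3):
            img = img.transpose(2, 0, 1)        # h,w,c -> c,h,w at the I/O boundary
        if img.max() > 1.5:
            img = img / 255.0
        mask = np.asarray(mask)
        mask = (mask > 0).astype(np.float32)
        if mask.ndim == 2:
            mask = mask[None]
        xs.append(img)
        ys.append(mask)
    return np.stack(xs), np.stack(ys)


def train_loop(model, dataset, cfg: TrainConfig, checkpoint_dir=None,
               log_fn=None):
    """Optimize *model* on *dataset*; returns ``(model, history)``.

    History records the per-iteration training loss and, every
    ``cfg.val_interval`` iterations, the validation loss and current
    learning rate. Raises on an empty dataset and aborts with a diagnostic
    if the loss becomes non-finite.
    """
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    X, Y = _stack(dataset)
    n = X.shape[0]
    ss = np.random.SeedSequence(cfg.seed)
    shuffle_rng, split_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    n_val = int(round(n * cfg.val_fraction))
    if 0 < n_val < n:
        perm = split_rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
    else:
        train_idx = np.arange(n)
        val_idx = train_idx  # plateau monitored on the training data
    Xt, Yt = X[train_idx], Y[train_idx]
    Xv, Yv = X[val_idx], Y[val_idx]

    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               betas=(cfg.beta1, cfg.beta2), weight_decay=cfg.weight_decay)
    sched = ReduceLROnPlateau(opt, cfg.plateau_factor, cfg.plateau_patience)
    history = {"loss": [], "val": [], "lr": [], "config": cfg.__dict__.copy()}

    batch = min(cfg.batch_size, len(train_idx))
    order = shuffle_rng.permutation(len(train_idx))
    cursor = 0
    best_val = math.inf
    for it in range(cfg.total_iterations):
        if cursor + batch > len(order):
            order = shuffle_rng.permutation(len(train_idx))
            cursor = 0
        idx = order[cursor:cursor + batch]
        cursor += batch

        model.train()
        logits = model.forward_logits(Xt[idx])
        pw = cfg.pos_weight
        if pw == "auto":
            fg = Yt[idx].sum()
            pw = float((Yt[idx].size - fg) / max(fg, 1.0))
        loss = balanced_bce_loss(logits, Yt[idx], pw)
        loss_val = float(loss.data)
        if not math.isfinite(loss_val):
            raise RuntimeError(
                f"non-finite training loss at iteration {it}: {loss_val}")
        model.zero_grad()
        loss.backward()
        opt.step()
        history["loss"].append(loss_val)

        if (it + 1) % cfg.val_interval == 0 or it + 1 == cfg.total_iterations:
            vloss = _eval_loss(model, Xv, Yv, batch, cfg.pos_weight)
            sched.step(vloss)
            history["val"].append({"iteration": it + 1, "val_loss": vloss,
                                   "lr": opt.lr})
            history["lr"].append(opt.lr)
            if log_fn is not None:
                log_fn(f"iter {it + 1}: loss={loss_val:.4f} "
                       f"val={vloss:.4f} lr={opt.lr:g}")
            if checkpoint_dir is not None and vloss < best_val:
                best_val = vloss
                save_checkpoint(Path(checkpoint_dir) / "best.npz", model, cfg,
                                iteration=it + 1)
    if checkpoint_dir is not None:
        save_checkpoint(Path(checkpoint_dir) / "last.npz", model, cfg,
                        iteration=cfg.total_iterations)
        (Path(checkpoint_dir) / "history.json").write_text(
            json.dumps(history, indent=2))
    return model, history


def _eval_loss(model, X, Y, batch, pos_weight):
    model.eval()
    total, count = 0.0, 0
    with ad.no_grad():
        for i in range(0, X.shape[0], batch):
            xb, yb = X[i:i + batch], Y[i:i + batch]
            pw = pos_weight
            if pw == "auto":
                fg = yb.sum()
                pw = float((yb.size - fg) / max(fg, 1.0))
            loss = balanced_bce_loss(model.forward_logits(xb), yb, pw)
            total += float(loss.data) * xb.shape[0]
            count += xb.shape[0]
    return total / count


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, model, train_cfg: "TrainConfig | None" = None,
                    iteration: "int | None" = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    meta = {
        "model_config": model.cfg.__dict__ if hasattr(model, "cfg") else {},
        "train_config": train_cfg.__dict__ if train_cfg else {},
        "iteration": iteration,
    }
    np.savez(path, __meta__=json.dumps(meta, default=list),
             **{k: v for k, v in state.items()})


def load_checkpoint(path, model=None):
    """Load a checkpoint; builds the model from the stored config if needed."""
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    if model is None:
        from .config import ModelConfig
        from .model import build_model
        model = build_model(ModelConfig(**meta["model_config"]))
    model.load_state_dict(state)
    return model, meta
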