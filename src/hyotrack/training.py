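"""Training and inference for the segmentation network.

The recipe: RAdam, linearly scaled learning rate lr = 0.1 * batch_size / 256,
focal loss, up to ``max_epochs`` epochs with early stopping once the
validation loss has failed to improve for ``patience`` consecutive epochs;
the best-validation weights are restored at the end.  Everything is driven by
a single integer seed.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .losses import focal_loss_from_logits
from .model import BiFPNUNet, NetworkConfig
from .nn import RAdam, no_grad
from .nn.tensor import Tensor

Dataset = Tuple[np.ndarray, np.ndarray]  # frames (N,1,H,W) float32, labels (N,H,W) int


def _as_dataset(data: Dataset) -> Tuple[np.ndarray, np.ndarray]:
    x, y = data
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, None]
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError("frames and labels differ in length")
    if len(x) == 0:
        raise ValueError("empty dataset")
    return x, y


def _epoch_loss(model: BiFPNUNet, x: np.ndarray, y: np.ndarray, cfg: NetworkConfig) -> float:
    losses, weights = [], []
    with no_grad():
        for lo in range(0, len(x), cfg.batch_size):
            xb, yb = x[lo:lo + cfg.batch_size], y[lo:lo + cfg.batch_size]
            loss = focal_loss_from_logits(model(Tensor(xb)), yb,
                                          cfg.focal_alpha, cfg.focal_gamma)
            losses.append(float(loss.data))
            weights.append(len(xb))
    return float(np.average(losses, weights=weights))


def train(model: BiFPNUNet, train_set: Dataset, val_set: Dataset,
          config: Optional[NetworkConfig] = None, *,
          val_loss_fn: Optional[Callable[[BiFPNUNet, int], float]] = None,
          callback: Optional[Callable[[int, float, float], None]] = None,
          ) -> Tuple[BiFPNUNet, pd.DataFrame]:
    """Train ``model``; returns the model with best-validation weights and a
    per-epoch history frame (epoch, train_loss, val_loss, lr).

    ``val_loss_fn`` replaces the validation evaluation when given (used to
    test the early-stopping contract with a scripted loss sequence).
    """
    cfg = (config or model.config).validate()
    xtr, ytr = _as_dataset(train_set)
    xva, yva = _as_dataset(val_set)
    lr = cfg.base_lr
    opt = RAdam(model.parameters(), lr=lr)
    rng = np.random.default_rng(np.uint32(cfg.seed) ^ np.uint32(0x5EED))

    best_val = np.inf
    best_state = model.state_dict()
    since_best = 0
    history: List[Dict] = []

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(xtr))
        batch_losses, batch_sizes = [], []
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            model.zero_grad()
            loss = focal_loss_from_logits(model(Tensor(xtr[idx])), ytr[idx],
                                          cfg.focal_alpha, cfg.focal_gamma)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {float(loss.data)!r}; "
                    "check learning rate and input scaling")
            loss.backward()
            opt.step()
            batch_losses.append(float(loss.data))
            batch_sizes.append(len(idx))
        train_loss = float(np.average(batch_losses, weights=batch_sizes))
        if val_loss_fn is not None:
            val_loss = float(val_loss_fn(model, epoch))
        else:
            val_loss = _epoch_loss(model, xva, yva, cfg)
        history.append(dict(epoch=epoch, train_loss=train_loss, val_loss=val_loss, lr=lr))
        if callback is not None:
            callback(epoch, train_loss, val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    model.load_state_dict(best_state)
    return model, pd.DataFrame(history)


def predict(model: BiFPNUNet, frames: np.ndarray, batch_size: Optional[int] = None) -> np.ndarray:
    """Per-pixel class probabilities for a stack of frames.

    frames: (T, H, W) or (T, 1, H, W) float in [0, 1].
    Returns (T, H, W, K) float32 probabilities (rows on the simplex).
    """
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim == 3:
        frames = frames[:, None]
    if len(frames) == 0:
        raise ValueError("empty frame stack")
    if frames.shape[2:] != tuple(model.config.input_size):
        from skimage.transform import resize
        frames = np.stack([
            resize(f[0], model.config.input_size, order=1, preserve_range=True,
                   anti_aliasing=True).astype(np.float32)[None]
            for f in frames])
    bs = batch_size or model.config.batch_size
    out = []
    with no_grad():
        for lo in range(0, len(frames), bs):
            logits = model(Tensor(frames[lo:lo + bs])).data  # (n, K, H, W)
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            out.append((e / e.sum(axis=1, keepdims=True)).transpose(0, 2, 3, 1))
    return np.concatenate(out, axis=0)


# ------------------------------------------------------------- checkpointing
def save_checkpoint(model: BiFPNUNet, path) -> None:
    """npz checkpoint with the NetworkConfig embedded as YAML metadata."""
    meta = yaml.safe_dump(asdict(model.config))
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __config_yaml__=np.array(meta), **state)


def load_checkpoint(path) -> BiFPNUNet:
    with np.load(path, allow_pickle=False) as data:
        meta = yaml.safe_load(str(data["__config_yaml__"]))
        meta["input_size"] = tuple(meta["input_size"])
        meta["encoder_widths"] = tuple(meta["encoder_widths"])
        cfg = NetworkConfig(**meta)
        model = BiFPNUNet(cfg)
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    model.load_state_dict(state)
    return model


def save_history(history: pd.DataFrame, path) -> None:
    history.to_csv(path, index=False, columns=["epoch", "train_loss", "val_loss", "lr"])
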