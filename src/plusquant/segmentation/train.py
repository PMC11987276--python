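"""Training and inference for the patch-based vessel segmenter.

A small U-Net is trained on bifurcation-centered patches with the soft
Tversky loss (weighting false negatives more than false positives, which
suits thin, class-imbalanced vessels).  Whole-image inference runs a
sliding window with overlap averaging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._nn import UNet, Adam

_EPS = 1e-8


@dataclass
class SegmenterConfig:
    depth: int = 3
    base_channels: int = 16
    tversky_alpha: float = 0.7
    tversky_beta: float = 0.3
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 8
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self):
        if self.tversky_alpha < 0 or self.tversky_beta < 0:
            raise ValueError("Tversky weights must be non-negative")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class SegmenterModel:
    weights: list
    config: SegmenterConfig
    training_log: list = field(default_factory=list)  # per-epoch {train_loss, val_loss}

    def build_net(self) -> UNet:
        net = UNet(self.config.depth, self.config.base_channels, seed=self.config.seed)
        net.set_weights(self.weights)
        return net

    def save(self, path_prefix) -> None:
        """Persist as <prefix>.npz (weights) + <prefix>.json (config + log)."""
        prefix = Path(path_prefix)
        np.savez(str(prefix) + ".npz", *self.weights)
        meta = {"config": asdict(self.config), "training_log": self.training_log}
        Path(str(prefix) + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path_prefix) -> "SegmenterModel":
        prefix = str(path_prefix)
        with np.load(prefix + ".npz") as blob:
            weights = [blob[k] for k in blob.files]
        meta = json.loads(Path(prefix + ".json").read_text())
        return cls(weights, SegmenterConfig(**meta["config"]), meta["training_log"])


def _soft_tversky_batch(p: np.ndarray, t: np.ndarray, alpha: float, beta: float):
    """Batch soft Tversky loss and its gradient w.r.t. the probabilities."""
    tp = float((p * t).sum())
    fn = float(((1 - p) * t).sum())
    fp = float((p * (1 - t)).sum())
    denom = tp + alpha * fn + beta * fp + _EPS
    index = tp / denom
    # d(index)/dp = [t*denom - tp*(t - alpha*t + beta*(1-t))] / denom^2
    dindex = (t * denom - tp * ((1 - alpha) * t + beta * (1 - t))) / denom**2
    return 1.0 - index, -dindex.astype(np.float32)


def _stack(patches: list) -> tuple:
    x = np.stack([p.image_patch for p in patches]).astype(np.float32)[:, None]
    y = np.stack([p.mask_patch for p in patches]).astype(np.float32)[:, None]
    return x, y


def train_segmenter(
    train: list, val: list, config: SegmenterConfig | None = None
) -> SegmenterModel:
    """Train the U-Net on training patches, monitoring validation Tversky loss."""
    config = config or SegmenterConfig()
    if not train or not val:
        raise ValueError("train and validation sets must be non-empty")
    x_tr, y_tr = _stack(train)
    x_va, y_va = _stack(val)
    if y_tr.sum() == 0:
        raise ValueError("degenerate training labels: all masks empty")
    net = UNet(config.depth, config.base_channels, seed=config.seed)
    opt = Adam(net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    a, b = config.tversky_alpha, config.tversky_beta
    log_rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(train))
        losses = []
        for start in range(0, len(train), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            p = net.forward(xb)
            loss, dloss = _soft_tversky_batch(p, yb, a, b)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            net.zero_grad()
            net.backward(dloss)
            opt.step()
            losses.append(loss)
        val_loss = _validate(net, x_va, y_va, a, b, config.batch_size)
        log_rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": val_loss})
    return SegmenterModel(net.get_weights(), config, log_rows)


def _validate(net, x, y, alpha, beta, batch_size):
    losses, weights = [], []
    for start in range(0, len(x), batch_size):
        xb, yb = x[start : start + batch_size], y[start : start + batch_size]
        loss, _ = _soft_tversky_batch(net.forward(xb), yb, alpha, beta)
        losses.append(loss)
        weights.append(len(xb))
    return float(np.average(losses, weights=weights))


def predict_mask(
    model: SegmenterModel, img: np.ndarray, tile: int = 128, overlap: int = 32
) -> np.ndarray:
    """Segment a whole image by sliding-window inference with overlap averaging."""
    if tile < 128:
        raise ValueError("tile must be >= 128")
    if overlap < 0 or overlap >= tile:
        raise ValueError("overlap must be in [0, tile)")
    x = np.asarray(getattr(img, "pixels", img), dtype=np.float32)
    h, w = x.shape
    pad_h = max(0, tile - h)
    pad_w = max(0, tile - w)
    if pad_h or pad_w:
        x = np.pad(x, ((0, pad_h), (0, pad_w)), mode="reflect")
    hh, ww = x.shape
    net = model.build_net()
    prob = np.zeros((hh, ww), dtype=np.float64)
    weight = np.zeros((hh, ww), dtype=np.float64)
    step = tile - overlap
    rows = sorted({min(r, hh - tile) for r in range(0, hh - tile + step, step)})
    cols = sorted({min(c, ww - tile) for c in range(0, ww - tile + step, step)})
    for r in rows:
        for c in cols:
            patch = x[r : r + tile, c : c + tile]
            p = net.forward(patch[None, None])[0, 0]
            prob[r : r + tile, c : c + tile] += p
            weight[r : r + tile, c : c + tile] += 1.0
    prob /= weight
    return (prob[:h, :w] >= model.config.threshold)
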