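"""Training loop, augmentation, and transfer-learning protocol.

The network trains end to end with rmsprop: initial learning rate 1e-4,
dropped by a factor of 10 after 50,000 iterations, batch size 6, up to
500,000 iterations from scratch (120,000 when transfer learning), with
random horizontal flips (p = 0.5) and random rotations in [-30, 30]
degrees — and no random cropping.  The best-on-validation checkpoint is
returned, with class-average pixel accuracy as the validation metric.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.losses import class_balance_weights
from .nn.model import RootNet
from .targets import ClassMaps, HeatMaps

__all__ = [
    "TrainConfig",
    "Sample",
    "augment",
    "lr_schedule",
    "gray_to_rgb",
    "RMSProp",
    "train",
    "transfer_learn",
    "TrainingHistory",
    "class_average_accuracy",
]

TRANSFER_MAX_ITERATIONS = 120_000


@dataclass
class TrainConfig:
    optimizer: str = "rmsprop"
    lr0: float = 1e-4
    lr_drop_factor: float = 10.0
    lr_drop_at: int = 50_000
    batch_size: int = 6
    max_iterations: int = 500_000
    flip_prob: float = 0.5
    rotation_range: tuple[float, float] = (-30.0, 30.0)
    rng_seed: int = 0
    validation_interval: int = 250
    heat_alpha_balanced: bool = False  # use class weights on the heat head too
    prior_bias_init: bool = True  # start seg-head bias at class-prior log-odds

    def validate(self) -> None:
        if self.optimizer != "rmsprop":
            raise ValueError("only the rmsprop optimizer is supported")
        if not (0.0 <= self.flip_prob <= 1.0):
            raise ValueError("flip_prob must lie in [0, 1]")
        for name in ("lr0", "lr_drop_factor", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_iterations < 0 or self.lr_drop_at < 0:
            raise ValueError("iteration counts must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "rotation_range" in raw:
            raw["rotation_range"] = tuple(raw["rotation_range"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class Sample:
    """One training example: input image + aligned targets.

    ``image`` is (3, H, W) in [0, 1]; ``masks`` and ``heats`` live at the
    network's output resolution (H/2, W/2).
    """

    image: np.ndarray
    masks: ClassMaps
    heats: HeatMaps


def gray_to_rgb(image: np.ndarray) -> np.ndarray:
    """Duplicate a grayscale channel into 3 identical RGB channels.

    Accepts (H, W) or (1, H, W); a 3-channel input passes through
    unchanged.
    """
    img = np.asarray(image)
    if img.ndim == 3 and img.shape[0] == 3:
        return img
    if img.ndim == 3 and img.shape[0] == 1:
        img = img[0]
    if img.ndim != 2:
        raise ValueError(f"expected single-channel image, got shape {img.shape}")
    return np.repeat(img[None], 3, axis=0)


def _rotate_channels(arr: np.ndarray, angle: float, cval) -> np.ndarray:
    """Rotate a channel-first stack in one call; per-channel fill values.

    The fill is folded in by shifting each channel to zero mean-fill,
    rotating with a zero constant pad, and shifting back.
    """
    offsets = np.asarray(cval if np.ndim(cval) else [cval] * arr.shape[0],
                         dtype=arr.dtype)[:, None, None]
    rotated = ndimage.rotate(
        arr - offsets, angle, axes=(1, 2), reshape=False, order=1,
        mode="constant", cval=0.0,
    )
    return rotated + offsets


def augment(
    image: np.ndarray,
    masks: ClassMaps,
    heats: HeatMaps,
    rng: np.random.Generator,
    flip_prob: float = 0.5,
    rotation_range: tuple[float, float] = (-30.0, 30.0),
):
    """Apply one identical random flip + rotation to image, masks, and heats.

    The image's exposed corners are filled with its per-channel mean (a
    stand-in for the background texture); mask and heat channels are filled
    with 0 and the background mask channel is rebuilt as the complement of
    the root channels.  A zero rotation and no flip is the exact identity.
    """
    img = np.asarray(image, dtype=np.float32)
    m = masks.stack().astype(np.float32)
    h = heats.stack().astype(np.float32)

    if rng.random() < flip_prob:
        img = img[:, :, ::-1].copy()
        m = m[:, :, ::-1].copy()
        h = h[:, :, ::-1].copy()

    lo, hi = rotation_range
    angle = float(rng.uniform(lo, hi))
    if angle != 0.0:
        img = _rotate_channels(img, angle, img.mean(axis=(1, 2)))
        targets = _rotate_channels(np.concatenate([m, h]), angle, 0.0)
        m = (np.clip(targets[:3], 0.0, 1.0) >= 0.5).astype(np.float32)
        h = np.clip(targets[3:], 0.0, 1.0)
        m[0] = 1.0 - np.maximum(m[1], m[2])

    return (
        img,
        ClassMaps(background=m[0], order1=m[1], order2=m[2]),
        HeatMaps(seed=h[0], tip1=h[1], tip2=h[2]),
    )


def lr_schedule(iteration: int, config: TrainConfig | None = None) -> float:
    """Step schedule: lr0 before the drop iteration, lr0/drop_factor after."""
    cfg = config or TrainConfig()
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    if iteration < cfg.lr_drop_at:
        return cfg.lr0
    return cfg.lr0 / cfg.lr_drop_factor


class RMSProp:
    """rmsprop with smoothing constant 0.99 and epsilon 1e-8."""

    def __init__(self, params, alpha: float = 0.99, eps: float = 1e-8):
        self.params = list(params)
        self.alpha = alpha
        self.eps = eps
        self.state = [np.zeros_like(p.data) for _, p in self.params]

    def step(self, lr: float) -> None:
        for s, (_, p) in zip(self.state, self.params):
            if p.grad is None:
                continue
            g = p.grad
            s *= self.alpha
            s += (1.0 - self.alpha) * g * g
            p.data -= lr * g / (np.sqrt(s) + self.eps)


@dataclass
class TrainingHistory:
    rows: list[dict] = field(default_factory=list)

    def log(self, **kw) -> None:
        self.rows.append(kw)

    def column(self, name: str) -> list:
        return [r[name] for r in self.rows if name in r and r[name] is not None]

    def to_csv(self, path: str | Path | None = None) -> str:
        if not self.rows:
            return ""
        cols = ["iteration", "lr", "L1", "L2", "val_metric"]
        buf = io.StringIO()
        w = csv.DictWriter(buf, fieldnames=cols, lineterminator="\n")
        w.writeheader()
        for r in self.rows:
            w.writerow({c: r.get(c) for c in cols})
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text


def _label_map(masks: ClassMaps) -> np.ndarray:
    """Collapse class maps to one label per pixel (order 2 wins at crossings)."""
    stack = masks.stack()
    label = np.zeros(stack.shape[1:], dtype=np.int8)
    label[stack[1] >= 0.5] = 1
    label[stack[2] >= 0.5] = 2
    return label


def class_average_accuracy(model: RootNet, val_set: list[Sample]) -> float:
    """Mean per-class pixel accuracy (recall) over the validation set."""
    correct = np.zeros(3)
    total = np.zeros(3)
    for sample in val_set:
        seg, _ = model.predict(sample.image[None])
        pred = seg[0].argmax(axis=0)
        truth = _label_map(sample.masks)
        for c in range(3):
            sel = truth == c
            total[c] += sel.sum()
            correct[c] += (pred[sel] == c).sum()
    present = total > 0
    return float((correct[present] / total[present]).mean())


def _snapshot(model: RootNet) -> list[np.ndarray]:
    return [p.data.copy() for _, p in model.parameters()]


def _restore(model: RootNet, snap: list[np.ndarray]) -> None:
    for (_, p), arr in zip(model.parameters(), snap):
        p.data = arr.copy()


def train(
    model: RootNet,
    train_set: list[Sample],
    val_set: list[Sample],
    config: TrainConfig,
    val_metric=None,
) -> tuple[RootNet, TrainingHistory]:
    """Minimize L = L1 + L2 with rmsprop; return the best-on-validation model.

    Minibatches are drawn with per-epoch shuffling.  Validation runs every
    ``config.validation_interval`` iterations (and once at the end); the
    parameter snapshot with the highest metric is restored into the model
    before returning.  A non-finite loss aborts with a diagnostic.
    """
    config.validate()
    if not train_set or not val_set:
        raise ValueError("training and validation sets must be non-empty")
    history = TrainingHistory()
    if config.max_iterations == 0:
        return model, history
    metric = val_metric or class_average_accuracy

    table = class_balance_weights([s.masks for s in train_set])
    alpha = table.alpha_vector()
    n_cls = len(alpha)
    heat_w = alpha if config.heat_alpha_balanced else np.ones(n_cls)

    if config.prior_bias_init:
        # start the segmentation head at the class-prior log-odds so the
        # sigmoid outputs begin at each class's marginal rate; standard
        # practice for rare-class pixel classification, and it spends the
        # iteration budget on discriminative structure, not on marginals
        freqs = np.array([
            np.clip(table.freq[c], 1e-4, 1 - 1e-4)
            for c in ("background", "order1", "order2")
        ])
        model.seg_head.b.data = np.log(freqs / (1 - freqs)).astype(np.float32)

    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 0x7124]))
    opt = RMSProp(model.parameters())
    model.train()

    best_metric, best_snap = -np.inf, None
    order = rng.permutation(len(train_set))
    cursor = 0
    for iteration in range(1, config.max_iterations + 1):
        idx = []
        while len(idx) < config.batch_size:
            if cursor >= len(order):
                order = rng.permutation(len(train_set))
                cursor = 0
            idx.append(order[cursor])
            cursor += 1
        imgs, masks, heats = [], [], []
        for i in idx:
            s = train_set[i]
            img, m, h = augment(
                s.image, s.masks, s.heats, rng,
                flip_prob=config.flip_prob, rotation_range=config.rotation_range,
            )
            imgs.append(img)
            masks.append(m.stack())
            heats.append(h.stack())
        x = np.stack(imgs).astype(np.float32)
        g = np.stack(masks).astype(np.float32)
        p = np.stack(heats).astype(np.float32)

        model.zero_grad()
        seg_logits, heat = model(Tensor(x))
        # channel weights folded with the 1/N normalization of the printed losses
        l1 = ad.weighted_bce_with_logits(seg_logits, g, alpha / n_cls)
        l2 = ad.weighted_mse(heat, p, heat_w / n_cls)
        loss = ad.add_scalars(l1, l2)
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"training diverged at iteration {iteration}: "
                f"L1={float(l1.data)} L2={float(l2.data)}"
            )
        loss.backward()
        lr = lr_schedule(iteration - 1, config)
        opt.step(lr)

        row = dict(iteration=iteration, lr=lr,
                   L1=float(l1.data), L2=float(l2.data), val_metric=None)
        if iteration % config.validation_interval == 0 or iteration == config.max_iterations:
            m_val = float(metric(model, val_set))
            row["val_metric"] = m_val
            if m_val > best_metric:
                best_metric, best_snap = m_val, _snapshot(model)
            model.train()
        history.log(**row)

    if best_snap is not None:
        _restore(model, best_snap)
    model.eval()
    return model, history


def transfer_learn(
    base_model: RootNet,
    new_train_set: list[Sample],
    new_val_set: list[Sample],
    config: TrainConfig,
    val_metric=None,
) -> tuple[RootNet, TrainingHistory]:
    """Fine-tune a structurally identical copy of ``base_model`` on new data.

    Training is capped at 120,000 iterations.  Grayscale inputs must be
    expanded with :func:`gray_to_rgb` beforehand — the network keeps 3
    input channels in all cases so weights stay interchangeable.
    """
    target = RootNet(base_model.spec)
    base_params = dict(base_model.parameters())
    for name, p in target.parameters():
        src = base_params.get(name)
        if src is None or src.data.shape != p.data.shape:
            raise ValueError(
                f"transfer: layer {name} missing or shape mismatch "
                f"({None if src is None else src.data.shape} vs {p.data.shape})"
            )
        p.data = src.data.copy()
    for (_, buf), (_, src_buf) in zip(target.buffers(), base_model.buffers()):
        buf[...] = src_buf

    capped = replace(
        config, max_iterations=min(config.max_iterations, TRANSFER_MAX_ITERATIONS)
    )
    if capped.max_iterations == 0:
        return target, TrainingHistory()
    return train(target, new_train_set, new_val_set, capped, val_metric=val_metric)
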