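"""Loss functions and median-frequency class balancing.

The two heads are trained jointly: the segmentation head with a
class-balanced binary cross-entropy L1 and the heat-map head with a
(optionally weighted) summed squared error L2; the total loss is their
plain sum, L = L1 + L2, with no extra scaling.

Class weights follow median frequency balancing: freq(c) is the number of
pixels of class c divided by the total number of pixels of the images that
contain class c, and alpha_c = median_freq / freq(c) — down-weighting the
dominant background and up-weighting sparse root classes.

Conventions: the printed per-channel weight is applied inside the channel
sum (it depends on the channel); L1 is the *negated* log-likelihood sum so
the minimized loss is non-negative; N is the number of output channels per
head; sums run over pixels, and batched variants average over the batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClassFrequencyTable",
    "class_balance_weights",
    "LossBatch",
    "seg_loss",
    "heat_loss",
    "total_loss",
]

CLASS_NAMES = ("background", "order1", "order2")
_EPS = 1e-7


@dataclass
class ClassFrequencyTable:
    freq: dict[str, float]
    median_freq: float = field(init=False)
    alpha: dict[str, float] = field(init=False)

    def __post_init__(self):
        for c, f in self.freq.items():
            if f <= 0:
                raise ValueError(
                    f"class {c!r} has frequency 0: it occurs in no image, "
                    "so its balancing weight is undefined"
                )
        self.median_freq = float(np.median(list(self.freq.values())))
        self.alpha = {c: self.median_freq / f for c, f in self.freq.items()}

    def alpha_vector(self, order=CLASS_NAMES) -> np.ndarray:
        return np.array([self.alpha[c] for c in order], dtype=np.float64)


def class_balance_weights(dataset) -> ClassFrequencyTable:
    """Median-frequency balancing weights over a training set.

    ``dataset`` is an iterable of per-image binary class-map stacks of
    shape (3, H, W) (or objects with a ``stack()`` method).  For each
    class, only images *containing* that class enter its frequency's
    denominator.
    """
    pixels = np.zeros(3, dtype=np.float64)
    image_pixels = np.zeros(3, dtype=np.float64)
    for item in dataset:
        stack = item.stack() if hasattr(item, "stack") else np.asarray(item)
        npix = stack.shape[1] * stack.shape[2]
        counts = stack.reshape(3, -1).sum(axis=1)
        present = counts > 0
        pixels[present] += counts[present]
        image_pixels[present] += npix
    freq = {}
    for i, name in enumerate(CLASS_NAMES):
        freq[name] = float(pixels[i] / image_pixels[i]) if image_pixels[i] else 0.0
    return ClassFrequencyTable(freq=freq)


@dataclass
class LossBatch:
    """Aligned ground truth and predictions for one loss evaluation.

    ``g``/``g_hat`` are class maps, ``p``/``p_hat`` heat maps, all shaped
    (N, H, W) (or (B, N, H, W) for batches); ``alpha`` are the per-channel
    class weights for L1, and ``heat_alpha`` optionally weights L2's
    channels (identity by default).
    """

    g: np.ndarray
    g_hat: np.ndarray
    p: np.ndarray
    p_hat: np.ndarray
    alpha: np.ndarray | None = None
    heat_alpha: np.ndarray | None = None

    def _check(self, a, b, what):
        if np.shape(a) != np.shape(b):
            raise ValueError(f"{what}: shapes {np.shape(a)} vs {np.shape(b)} differ")


def _channel_weights(alpha, n) -> np.ndarray:
    w = np.ones(n, dtype=np.float64) if alpha is None else np.asarray(alpha, float)
    if w.shape != (n,):
        raise ValueError(f"expected {n} channel weights, got shape {w.shape}")
    return w


def _as_batched(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    return a[None] if a.ndim == 3 else a


def seg_loss(batch: LossBatch) -> float:
    """Class-balanced binary cross-entropy L1 (>= 0; 0 at perfect prediction).

    L1 = -(1/N) sum_n alpha_n sum_xy [g log g_hat + (1-g) log(1-g_hat)],
    averaged over the batch dimension if present.  Predictions are clamped
    away from {0, 1} before the logs.
    """
    batch._check(batch.g, batch.g_hat, "segmentation maps")
    g = _as_batched(batch.g)
    gh = np.clip(_as_batched(batch.g_hat), _EPS, 1.0 - _EPS)
    n = g.shape[1]
    w = _channel_weights(batch.alpha, n)
    ll = g * np.log(gh) + (1.0 - g) * np.log(1.0 - gh)
    per_channel = ll.sum(axis=(0, 2, 3)) / g.shape[0]
    return float(-(w * per_channel).sum() / n)


def heat_loss(batch: LossBatch) -> float:
    """Summed squared error L2 over heat-map channels (batch-averaged).

    L2 = (1/N) sum_n alpha_n sum_xy (p - p_hat)^2; the per-channel weight
    defaults to 1 for the heat head.
    """
    batch._check(batch.p, batch.p_hat, "heat maps")
    p = _as_batched(batch.p)
    ph = _as_batched(batch.p_hat)
    n = p.shape[1]
    w = _channel_weights(batch.heat_alpha, n)
    sq = (p - ph) ** 2
    per_channel = sq.sum(axis=(0, 2, 3)) / p.shape[0]
    return float((w * per_channel).sum() / n)


def total_loss(batch: LossBatch) -> float:
    """L = L1 + L2, with no additional scaling factors."""
    return seg_loss(batch) + heat_loss(batch)
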