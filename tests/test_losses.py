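import numpy as np
import pytest

from rhizotrace.nn import autodiff as ad
from rhizotrace.nn.autodiff import Tensor
from rhizotrace.nn.losses import (
    ClassFrequencyTable,
    LossBatch,
    class_balance_weights,
    heat_loss,
    seg_loss,
    total_loss,
)


def make_batch(g, g_hat, p=None, p_hat=None, **kw):
    zeros = np.zeros_like(np.asarray(g, dtype=float))
    return LossBatch(
        g=np.asarray(g, float),
        g_hat=np.asarray(g_hat, float),
        p=zeros if p is None else np.asarray(p, float),
        p_hat=zeros if p_hat is None else np.asarray(p_hat, float),
        **kw,
    )


class TestClassBalance:
    def test_uniform_frequencies_give_unit_weights(self):
        table = ClassFrequencyTable({"background": 0.5, "order1": 0.5, "order2": 0.5})
        assert table.alpha_vector() == pytest.approx([1.0, 1.0, 1.0])

    def test_skewed_frequencies(self):
        table = ClassFrequencyTable(
            {"background": 0.9, "order1": 0.08, "order2": 0.02}
        )
        assert table.median_freq == pytest.approx(0.08)
        assert table.alpha_vector() == pytest.approx([0.0889, 1.0, 4.0], abs=1e-4)

    def test_zero_frequency_raises(self):
        with pytest.raises(ValueError, match="no image"):
            ClassFrequencyTable({"background": 0.9, "order1": 0.1, "order2": 0.0})

    def test_frequency_denominator_counts_only_images_with_class(self):
        # image A: 3/4 background, 1/4 order1, no order2
        # image B: all background
        a = np.zeros((3, 2, 2))
        a[0] = [[1, 1], [1, 0]]
        a[1] = [[0, 0], [0, 1]]
        b = np.zeros((3, 2, 2))
        b[0] = 1.0
        with pytest.raises(ValueError):
            class_balance_weights([a, b])  # order2 absent everywhere
        a[2, 0, 0] = 1.0  # give order2 one (crossing) pixel in image A
        table = class_balance_weights([a, b])
        assert table.freq["background"] == pytest.approx(7 / 8)
        assert table.freq["order1"] == pytest.approx(1 / 4)
        assert table.freq["order2"] == pytest.approx(1 / 4)


class TestLosses:
    def test_perfect_prediction_is_zero(self):
        g = np.zeros((1, 2, 2))
        g[0, 0, 0] = 1.0
        batch = make_batch(g, g, p=g, p_hat=g)
        assert seg_loss(batch) == pytest.approx(0.0, abs=1e-5)
        assert heat_loss(batch) == 0.0

    def test_single_pixel_cross_entropy(self):
        batch = make_batch([[[1.0]]], [[[0.5]]])
        assert seg_loss(batch) == pytest.approx(0.6931, abs=1e-4)

    def test_doubling_alpha_doubles_channel_contribution(self):
        g = np.ones((2, 3, 3))
        gh = np.full((2, 3, 3), 0.6)
        base = seg_loss(make_batch(g, gh, alpha=np.array([1.0, 1.0])))
        double = seg_loss(make_batch(g, gh, alpha=np.array([2.0, 1.0])))
        # raising channel 0's weight from 1 to 2 adds exactly S_0 / N
        single = seg_loss(make_batch(g[:1], gh[:1], alpha=np.array([1.0]))) / 2
        assert double == pytest.approx(base + single)

    def test_single_pixel_squared_error(self):
        batch = make_batch([[[0.0]]], [[[0.0]]], p=[[[0.5]]], p_hat=[[[0.0]]])
        assert heat_loss(batch) == pytest.approx(0.25)

    def test_heat_loss_nonnegative(self):
        rng = np.random.default_rng(0)
        batch = make_batch(
            np.zeros((3, 4, 4)), np.zeros((3, 4, 4)),
            p=rng.random((3, 4, 4)), p_hat=rng.random((3, 4, 4)),
        )
        assert heat_loss(batch) >= 0.0

    def test_total_is_plain_sum(self):
        g = np.zeros((1, 2, 2)); g[0, 0, 0] = 1.0
        gh = np.full((1, 2, 2), 0.4)
        p = np.full((1, 2, 2), 0.3); ph = np.zeros((1, 2, 2))
        batch = make_batch(g, gh, p=p, p_hat=ph)
        assert total_loss(batch) == pytest.approx(seg_loss(batch) + heat_loss(batch))

    def test_shape_mismatch_raises(self):
        batch = make_batch(np.zeros((1, 2, 2)), np.zeros((1, 3, 3)))
        with pytest.raises(ValueError, match="shapes"):
            seg_loss(batch)

    def test_seg_loss_matches_independent_bce(self):
        # oracle: plain per-pixel binary cross-entropy written independently
        rng = np.random.default_rng(42)
        for _ in range(5):
            g = (rng.random((3, 5, 2)) > 0.5).astype(float)
            gh = np.clip(rng.random((3, 5, 2)), 1e-6, 1 - 1e-6)
            expected = -np.mean(
                [
                    (g[c] * np.log(gh[c]) + (1 - g[c]) * np.log(1 - gh[c])).sum()
                    for c in range(3)
                ]
            )
            got = seg_loss(make_batch(g, gh))
            assert got == pytest.approx(expected, rel=1e-9)


class TestTrainingLossGradients:
    def test_gradient_matches_finite_differences(self):
        # two-pixel toy batch through both fused heads
        rng = np.random.default_rng(1)
        z = rng.normal(size=(1, 2, 1, 2)).astype(np.float32)
        g = np.array([[[[1.0, 0.0]], [[0.0, 1.0]]]], dtype=np.float32)
        p = rng.random((1, 2, 1, 2)).astype(np.float32)
        w = np.array([1.0, 2.0], dtype=np.float32)

        def forward(zdata):
            t1, t2 = Tensor(zdata), Tensor(zdata)
            l1 = ad.weighted_bce_with_logits(t1, g, w)
            l2 = ad.weighted_mse(t2, p, w)
            return float(l1.data + l2.data)

        t1, t2 = Tensor(z), Tensor(z)
        t1.requires_grad = t2.requires_grad = True
        loss = ad.add_scalars(
            ad.weighted_bce_with_logits(t1, g, w), ad.weighted_mse(t2, p, w)
        )
        loss.backward()
        analytic = t1.grad + t2.grad
        eps = 1e-3
        for idx in np.ndindex(z.shape):
            zp = z.copy(); zp[idx] += eps
            zm = z.copy(); zm[idx] -= eps
            fd = (forward(zp) - forward(zm)) / (2 * eps)
            assert analytic[idx] == pytest.approx(fd, abs=2e-3)

    def test_training_loss_agrees_with_functional_form(self):
        # the autodiff heads, fed sigmoid inputs and per-channel weights
        # alpha/N, must reproduce the printed loss values
        rng = np.random.default_rng(3)
        z = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
        g = (rng.random((1, 3, 4, 4)) > 0.7).astype(np.float32)
        alpha = np.array([0.1, 1.0, 3.0])
        l1_train = float(
            ad.weighted_bce_with_logits(Tensor(z), g, alpha / 3).data
        )
        batch = LossBatch(
            g=g[0], g_hat=1 / (1 + np.exp(-z[0])), p=g[0], p_hat=g[0], alpha=alpha
        )
        assert l1_train == pytest.approx(seg_loss(batch), rel=1e-4)
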