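"""Autodiff core: op semantics and gradients against numeric differentiation."""

import numpy as np
import pytest

from icsms.nn import core
from icsms.nn.core import Tensor

from conftest import numeric_grad


class TestActivations:
    def test_hard_sigmoid_closed_form(self):
        x = Tensor(np.array([-4.0, -3.0, 0.0, 3.0, 4.0], dtype=np.float32))
        out = core.hard_sigmoid(x).data
        np.testing.assert_allclose(out, [0.0, 0.0, 0.5, 1.0, 1.0], atol=1e-7)

    def test_hard_swish_zero_and_saturation(self):
        x = np.array([0.0, 10.0, 100.0], dtype=np.float32)
        out = core.hard_swish(Tensor(x)).data
        assert out[0] == 0.0
        np.testing.assert_allclose(out[1:], x[1:], rtol=1e-6)

    def test_hard_swish_matches_piecewise_definition(self, rng):
        x = rng.normal(0, 3, 100).astype(np.float32)
        expected = x * np.clip(x + 3, 0, 6) / 6
        np.testing.assert_allclose(core.hard_swish(Tensor(x)).data, expected,
                                   rtol=1e-6)

    def test_sigmoid_range_strict(self, rng):
        # strictly inside (0, 1) over the numerically exact float32 range
        x = rng.normal(0, 4, 1000).astype(np.float32).clip(-15, 15)
        out = core.sigmoid(Tensor(x)).data
        assert np.all(out > 0) and np.all(out < 1)


class TestCrossEntropy:
    def test_uniform_prediction_gives_log_c(self):
        logits = Tensor(np.zeros((4, 11), dtype=np.float32))
        loss = core.cross_entropy_with_logits(logits, np.array([0, 3, 7, 10]))
        np.testing.assert_allclose(loss.data, np.log(11.0), rtol=1e-6)

    def test_confident_correct_prediction_is_zero(self):
        logits = np.full((2, 3), -100.0, dtype=np.float32)
        logits[0, 1] = logits[1, 2] = 100.0
        loss = core.cross_entropy_with_logits(Tensor(logits), np.array([1, 2]))
        assert loss.data == pytest.approx(0.0, abs=1e-6)

    def test_mean_reduction_over_batch(self, rng):
        z = rng.normal(size=(2, 5)).astype(np.float32)
        y = np.array([1, 4])
        la = core.cross_entropy_with_logits(Tensor(z[:1]), y[:1]).data
        lb = core.cross_entropy_with_logits(Tensor(z[1:]), y[1:]).data
        lab = core.cross_entropy_with_logits(Tensor(z), y).data
        assert lab == pytest.approx((la + lb) / 2, rel=1e-6)

    def test_label_out_of_range_raises(self):
        with pytest.raises(IndexError):
            core.cross_entropy_with_logits(
                Tensor(np.zeros((2, 3), dtype=np.float32)), np.array([0, 3]))


@pytest.mark.parametrize("case", [
    "conv_dense", "conv_depthwise", "conv_pointwise", "maxpool",
    "batchnorm", "cross_entropy", "sigmoid_matmul", "concat_narrow",
    "ca_style_pool",
])
def test_gradients_match_numeric_differentiation(case, rng):
    """Every fused op's backward agrees with central differences."""
    if case == "conv_dense":
        x = Tensor(rng.normal(size=(2, 3, 6, 6)).astype(np.float32), True)
        w = Tensor(rng.normal(size=(4, 3, 3, 3)).astype(np.float32), True)
        b = Tensor(rng.normal(size=4).astype(np.float32), True)
        fn = lambda: core.conv2d(x, w, b, stride=2, padding=1)
        leaves = [x, w, b]
    elif case == "conv_depthwise":
        x = Tensor(rng.normal(size=(2, 5, 5, 5)).astype(np.float32), True)
        w = Tensor(rng.normal(size=(5, 1, 3, 3)).astype(np.float32), True)
        fn = lambda: core.conv2d(x, w, None, padding=1, groups=5)
        leaves = [x, w]
    elif case == "conv_pointwise":
        x = Tensor(rng.normal(size=(2, 4, 3, 3)).astype(np.float32), True)
        w = Tensor(rng.normal(size=(6, 4, 1, 1)).astype(np.float32), True)
        fn = lambda: core.conv2d(x, w, None)
        leaves = [x, w]
    elif case == "maxpool":
        # well-separated values so central differences never cross a tie
        vals = rng.permutation(2 * 3 * 7 * 7).astype(np.float32) * 0.1
        x = Tensor(vals.reshape(2, 3, 7, 7), True)
        fn = lambda: core.max_pool2d(x, 3, 2, 1)
        leaves = [x]
    elif case == "batchnorm":
        x = Tensor(rng.normal(size=(3, 4, 5, 5)).astype(np.float32), True)
        g = Tensor(rng.uniform(0.5, 2, 4).astype(np.float32), True)
        b = Tensor(rng.normal(size=4).astype(np.float32), True)
        fn = lambda: core.batch_norm2d(x, g, b, np.zeros(4, np.float32),
                                       np.ones(4, np.float32), training=True)
        leaves = [x, g, b]
    elif case == "cross_entropy":
        x = Tensor(rng.normal(size=(3, 4)).astype(np.float32), True)
        y = np.array([0, 2, 1])
        fn = lambda: core.cross_entropy_with_logits(x, y)
        leaves = [x]
    elif case == "sigmoid_matmul":
        x = Tensor(rng.normal(size=(3, 4)).astype(np.float32), True)
        w = Tensor(rng.normal(size=(4, 5)).astype(np.float32), True)
        fn = lambda: core.sigmoid(core.matmul(x, w))
        leaves = [x, w]
    elif case == "concat_narrow":
        x = Tensor(rng.normal(size=(3, 3)).astype(np.float32), True)
        fn = lambda: core.transpose(
            core.narrow(core.concat([x, core.mul(x, 2.0)], 1), 1, 1, 3),
            (1, 0))
        leaves = [x]
    else:  # ca_style_pool: axis pooling + split + broadcast multiply
        x = Tensor(rng.normal(size=(2, 3, 4, 5)).astype(np.float32), True)

        def fn():
            ph = core.mean(x, axis=3, keepdims=True)
            pw = core.mean(x, axis=2, keepdims=True)
            return core.mul(core.mul(x, core.sigmoid(ph)), core.sigmoid(pw))
        leaves = [x]

    out = fn()
    g_out = rng.normal(size=out.shape).astype(np.float32)
    out.backward(g_out)
    tol = 5e-2 if case == "batchnorm" else 2e-2
    for leaf in leaves:
        num = numeric_grad(fn, leaf.data, g_out)
        scale = np.abs(num).max() + 1e-6
        assert np.abs(num - leaf.grad).max() / scale < tol


class TestConvSemantics:
    def test_pointwise_conv_macs_closed_form(self, rng):
        x = Tensor(rng.normal(size=(1, 16, 7, 7)).astype(np.float32))
        w = Tensor(rng.normal(size=(32, 16, 1, 1)).astype(np.float32))
        with core.count_macs_enabled() as counter:
            core.conv2d(x, w, None)
        assert counter[0] == 7 * 7 * 16 * 32  # 25,088

    def test_channel_mismatch_raises(self, rng):
        x = Tensor(np.zeros((1, 8, 4, 4), dtype=np.float32))
        w = Tensor(np.zeros((4, 16, 1, 1), dtype=np.float32))
        with pytest.raises(ValueError, match="channel mismatch"):
            core.conv2d(x, w, None)

    def test_depthwise_equals_dense_blockdiagonal(self, rng):
        """Depthwise conv = dense conv with a block-diagonal kernel."""
        x = rng.normal(size=(2, 3, 6, 6)).astype(np.float32)
        wd = rng.normal(size=(3, 1, 3, 3)).astype(np.float32)
        dense = np.zeros((3, 3, 3, 3), dtype=np.float32)
        for c in range(3):
            dense[c, c] = wd[c, 0]
        out_dw = core.conv2d(Tensor(x), Tensor(wd), None, padding=1,
                             groups=3).data
        out_dense = core.conv2d(Tensor(x), Tensor(dense), None,
                                padding=1).data
        np.testing.assert_allclose(out_dw, out_dense, rtol=1e-5, atol=1e-5)

    def test_strided_conv_halves_spatial_dims(self, rng):
        x = Tensor(rng.normal(size=(1, 4, 14, 14)).astype(np.float32))
        w = Tensor(rng.normal(size=(8, 4, 3, 3)).astype(np.float32))
        assert core.conv2d(x, w, None, stride=2, padding=1).shape == (1, 8, 7, 7)


def test_batchnorm_eval_uses_running_stats(rng):
    x = rng.normal(2.0, 3.0, size=(4, 2, 5, 5)).astype(np.float32)
    g = Tensor(np.ones(2, np.float32), True)
    b = Tensor(np.zeros(2, np.float32), True)
    rm, rv = np.zeros(2, np.float32), np.ones(2, np.float32)
    # train once with momentum 1 -> running stats = batch stats
    core.batch_norm2d(Tensor(x), g, b, rm, rv, training=True, momentum=1.0)
    out = core.batch_norm2d(Tensor(x), g, b, rm, rv, training=False).data
    # eval output should be standardized w.r.t. the (unbiased-var) stats
    assert abs(out.mean()) < 1e-3
    assert abs(out.std() - 1.0) < 2e-2
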