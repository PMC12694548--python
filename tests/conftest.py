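import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def numeric_grad(fn, x, g_out, eps=1e-3):
    """Central-difference gradient of sum(fn(x) * g_out) w.r.t. x."""
    num = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = fn().data
        x[i] = orig - eps
        fm = fn().data
        x[i] = orig
        num[i] = ((fp - fm) * g_out).sum() / (2 * eps)
    return num
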