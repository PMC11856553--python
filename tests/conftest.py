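import numpy as np
import pytest

from xaiseg import ClassifierHandle, make_test_backbone


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def handle16():
    """Untrained four-stage backbone wrapped for 16x16 inputs."""
    return ClassifierHandle(make_test_backbone(seed=3), input_size=(16, 16))


@pytest.fixture
def handle32():
    return ClassifierHandle(make_test_backbone(seed=5), input_size=(32, 32))


class LinearScorer:
    """Duck-typed handle whose class-1 score is sum(w * x): the analytic
    reference for gradient- and perturbation-method oracle tests."""

    def __init__(self, weights):
        self.w = np.asarray(weights, dtype=np.float64)
        self.input_size = self.w.shape[-2:]
        self.n_classes = 2

    def _check_target(self, target):
        if not 0 <= target < self.n_classes:
            raise ValueError("bad target")

    def forward(self, image):
        x = np.asarray(image, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        s = float((self.w * x).sum())
        return np.array([-s, s])

    def input_gradient(self, image, target, guided=False):
        self._check_target(target)
        w = self.w if self.w.ndim == 3 else self.w[None]
        return w if target == 1 else -w


@pytest.fixture
def linear_handle():
    rng = np.random.default_rng(7)
    return LinearScorer(rng.normal(size=(12, 12)))
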