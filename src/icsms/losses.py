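"""Joint supervision: cross-entropy + weighted center loss.

Cross-entropy (batch mean, natural log) drives class separability;
the center loss

    L_center = 1/2 * sum_i || f(x_i) - mu_{y_i} ||^2

(batch SUM, as conventional for this loss) pulls each projected feature
toward its class centroid, tightening intra-class scatter.  The joint
objective is ``L = L_CE + lambda * L_center``; because one term is a mean
and the other a sum, the weight lambda absorbs the scale difference — the
published sweep values {0, 0.01, 0.05, 0.1, 0.2} are used as-is, with 0.01
as the shipped default.

Class centers are not optimized by backprop through the loss: they follow
the canonical mini-batch update of discriminative feature learning,

    delta_mu_j = sum_{i: y_i = j} (mu_j - f_i) / (1 + n_j),
    mu_j <- mu_j - alpha * delta_mu_j,

applied by plain SGD with rate alpha (default 0.5), separate from the Adam
optimizer that trains the network weights.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import core
from .nn.core import Tensor

LAMBDA_SWEEP = (0.0, 0.01, 0.05, 0.1, 0.2)
DEFAULT_LAMBDA = 0.01      # best sweep value in the study setting
DEFAULT_CENTER_LR = 0.5


@dataclasses.dataclass
class LossConfig:
    lam: float = DEFAULT_LAMBDA          # center-loss weight (lambda)
    center_lr: float = DEFAULT_CENTER_LR  # alpha of the center update
    center_dim: int = 85                  # projected center-feature dim

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("center-loss weight lambda must be >= 0")
        if not 0 < self.center_lr <= 1:
            raise ValueError("center learning rate alpha must be in (0, 1]")
        if self.center_dim < 1:
            raise ValueError("center feature dimension must be >= 1")


class ClassCenters:
    """The C x d center matrix mu with its mini-batch update state."""

    def __init__(self, num_classes: int, dim: int,
                 storage: Tensor | None = None):
        self.num_classes = num_classes
        self.dim = dim
        if storage is not None:
            if storage.data.shape != (num_classes, dim):
                raise ValueError("center storage shape mismatch")
            self._storage = storage
        else:
            self._storage = Tensor(np.zeros((num_classes, dim),
                                            dtype=np.float32),
                                   requires_grad=True)
        self.update_counts = np.zeros(num_classes, dtype=np.int64)

    @property
    def matrix(self) -> np.ndarray:
        return self._storage.data

    def update(self, features: np.ndarray, labels: np.ndarray,
               alpha: float) -> None:
        """One SGD step of the canonical center update rule."""
        if not 0 < alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        features = np.asarray(features, dtype=np.float32)
        labels = np.asarray(labels)
        for j in np.unique(labels):
            sel = features[labels == j]
            n_j = sel.shape[0]
            delta = (n_j * self.matrix[j] - sel.sum(axis=0)) / (1.0 + n_j)
            self.matrix[j] -= alpha * delta
            self.update_counts[j] += 1


@dataclasses.dataclass
class LossBreakdown:
    ce: float
    center: float
    lam: float

    @property
    def total(self) -> float:
        return self.ce + self.lam * self.center


def cross_entropy(logits, labels) -> Tensor:
    """Mean over the batch of -log p(true class); natural log; >= 0."""
    return core.cross_entropy_with_logits(logits, labels)


def center_loss(features, labels, centers: ClassCenters) -> Tensor:
    """1/2 sum_i ||f_i - mu_{y_i}||^2 over the batch.

    Gradient w.r.t. features is (f_i - mu_{y_i}); the centers are treated as
    constants here (they move only through :meth:`ClassCenters.update`).
    """
    f = features if isinstance(features, Tensor) else Tensor(features)
    labels = np.asarray(labels)
    if f.data.shape[1] != centers.dim:
        raise ValueError(
            f"feature dim {f.data.shape[1]} != center dim {centers.dim}")
    mu = centers.matrix[labels]                       # (N, d), constant
    diff = core.add(f, Tensor(-mu))
    return core.mul(core.sum_(core.mul(diff, diff)), 0.5)


def joint_loss(ce, center, lam: float):
    """L = L_CE + lambda * L_center (componentwise non-negative)."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        return ce
    return core.add(ce, core.mul(center, lam))


def update_centers(features, labels, centers: ClassCenters,
                   alpha: float = DEFAULT_CENTER_LR) -> ClassCenters:
    if isinstance(features, Tensor):
        features = features.data
    centers.update(features, labels, alpha)
    return centers
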