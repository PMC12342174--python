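"""Small neural-network primitives shared by the GCN and GAT modules.

Everything here is plain NumPy. Networks in this package are tiny (two
graph layers plus a linear head, a few hundred nodes), so closed-form
backpropagation is implemented by hand in the model modules and the
helpers below only provide activations, losses and an Adam optimizer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "elu",
    "elu_grad",
    "leaky_relu",
    "leaky_relu_grad",
    "softmax",
    "cross_entropy",
    "dropout_mask",
    "Adam",
]


def elu(x: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Exponential linear unit: x for x > 0, alpha*(exp(x)-1) otherwise."""
    return np.where(x > 0, x, alpha * np.expm1(np.minimum(x, 0.0)))


def elu_grad(x: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Derivative of ELU with respect to its pre-activation input."""
    return np.where(x > 0, 1.0, alpha * np.exp(np.minimum(x, 0.0)))


def leaky_relu(x: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def leaky_relu_grad(x: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(x > 0, 1.0, slope)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable row-wise softmax."""
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray,
                  indices: np.ndarray) -> tuple[float, np.ndarray]:
    """Masked mean cross-entropy.

    Parameters
    ----------
    logits : (n, c) raw scores.
    targets : (n,) integer class labels.
    indices : rows that contribute to the loss.

    Returns
    -------
    loss : scalar mean cross-entropy over ``indices``.
    dlogits : (n, c) gradient of the loss w.r.t. ``logits`` (zero outside
        ``indices``).
    """
    indices = np.asarray(indices)
    probs = softmax(logits, axis=1)
    n_eval = len(indices)
    picked = probs[indices, targets[indices]]
    loss = float(-np.mean(np.log(np.maximum(picked, 1e-300))))
    dlogits = np.zeros_like(logits)
    dlogits[indices] = probs[indices]
    dlogits[indices, targets[indices]] -= 1.0
    dlogits[indices] /= n_eval
    return loss, dlogits


def dropout_mask(shape: tuple[int, ...], rate: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Inverted-dropout multiplier: 0 with probability ``rate``, else 1/(1-rate)."""
    if rate <= 0:
        return np.ones(shape)
    keep = 1.0 - rate
    return (rng.random(shape) < keep).astype(float) / keep


class Adam:
    """Adam with L2 weight decay folded into the gradient (the convention
    used by ``torch.optim.Adam``'s ``weight_decay`` argument)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 weight_decay: float = 0.0, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(v) for k, v in params.items()}
        self._v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, p in self.params.items():
            g = grads[key]
            if self.weight_decay:
                g = g + self.weight_decay * p
            self._m[key] = b1 * self._m[key] + (1 - b1) * g
            self._v[key] = b2 * self._v[key] + (1 - b2) * g * g
            m_hat = self._m[key] / (1 - b1 ** self.t)
            v_hat = self._v[key] / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed from a global seed.

    Stages can be re-run in isolation and still see the same randomness
    as inside the full pipeline.
    """
    import hashlib

    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")
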