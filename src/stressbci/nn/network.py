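"""Network wrapper, softmax cross-entropy, Adam, and the training loop."""

from __future__ import annotations

import numpy as np

from .layers import Layer, Param


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer labels ``y``; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.mean(np.log(np.clip(p[np.arange(n), y], 1e-300, None)))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


class Network:
    """A root layer producing class logits, plus prediction helpers."""

    def __init__(self, root: Layer, n_classes: int):
        self.root = root
        self.n_classes = n_classes

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.root.forward(x, train=train)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.logits(x, train=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=1)

    @property
    def params(self) -> list[Param]:
        return self.root.params

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class Adam:
    def __init__(self, params: list[Param], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def fit(
    net: Network,
    x: np.ndarray,
    y: np.ndarray,
    epochs: int,
    batch_size: int = 200,
    lr: float = 0.001,
    seed: int = 0,
) -> dict:
    """Mini-batch Adam training with a seeded shuffle per epoch.

    Returns a history dict with per-epoch mean loss and training accuracy.
    Raises :class:`TrainingDiverged` if the loss goes non-finite.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(net.params, lr=lr)
    n = len(x)
    history = {"loss": [], "accuracy": []}
    for epoch in range(epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, batch_size):
            idx = perm[start:start + batch_size]
            xb, yb = x[idx], y[idx]
            logits = net.logits(xb, train=True)
            loss, dlogits = softmax_xent(logits, yb)
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch offset {start}"
                )
            net.zero_grad()
            net.root.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((np.argmax(logits, axis=1) == yb).sum())
        history["loss"].append(float(np.sum(losses) / n))
        history["accuracy"].append(correct / n)
    return history


def numeric_gradient(f, value: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar ``f`` w.r.t. ``value`` in place."""
    grad = np.zeros_like(value)
    it = np.nditer(value, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = value[idx]
        value[idx] = orig + eps
        fp = f()
        value[idx] = orig - eps
        fm = f()
        value[idx] = orig
        grad[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return grad
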