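"""Minimal NumPy sequence-model engine for the character-level generator.

Implements exactly the stack the generator needs — LSTM -> dropout ->
LSTM -> time-distributed dense softmax — with masked categorical
cross-entropy, backpropagation through time, Adam, and per-layer freezing.

Conventions follow the common Keras layout so parameter counts match the
usual closed forms: each LSTM holds an input kernel ``W`` of shape
(I, 4U), a recurrent kernel ``R`` of shape (U, 4U) and a bias ``b`` of
shape (4U,), with gate order (input, forget, cell, output) and the forget
bias initialised to 1.  The dense layer holds (U, V) + (V,).  All
randomness flows through explicit ``numpy.random.Generator`` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(np.float64)


@dataclass
class LSTMLayer:
    """Single LSTM layer over a (B, L, I) batch; returns the full (B, L, U)
    hidden-state sequence."""

    W: np.ndarray  # (I, 4U)
    R: np.ndarray  # (U, 4U)
    b: np.ndarray  # (4U,)
    trainable: bool = True
    _cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def init(cls, rng: np.random.Generator, n_in: int, units: int) -> "LSTMLayer":
        b = np.zeros(4 * units)
        b[units : 2 * units] = 1.0  # forget-gate bias
        return cls(
            W=glorot_uniform(rng, (n_in, 4 * units)),
            R=glorot_uniform(rng, (units, 4 * units)),
            b=b,
        )

    @property
    def units(self) -> int:
        return self.R.shape[0]

    @property
    def param_count(self) -> int:
        return self.W.size + self.R.size + self.b.size

    def params(self) -> list[np.ndarray]:
        return [self.W, self.R, self.b]

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        h0: np.ndarray | None = None,
        c0: np.ndarray | None = None,
    ) -> np.ndarray:
        B, L, _ = X.shape
        U = self.units
        h = np.zeros((B, U)) if h0 is None else h0
        c = np.zeros((B, U)) if c0 is None else c0
        H = np.empty((B, L, U))
        gates = np.empty((B, L, 4 * U)) if train else None
        cells = np.empty((B, L, U)) if train else None
        prev_h = np.empty((B, L, U)) if train else None
        prev_c = np.empty((B, L, U)) if train else None
        XW = X @ self.W  # (B, L, 4U), hoisted out of the time loop
        for t in range(L):
            z = XW[:, t, :] + h @ self.R + self.b
            i = sigmoid(z[:, :U])
            f = sigmoid(z[:, U : 2 * U])
            g = np.tanh(z[:, 2 * U : 3 * U])
            o = sigmoid(z[:, 3 * U :])
            if train:
                prev_h[:, t] = h
                prev_c[:, t] = c
            c = f * c + i * g
            h = o * np.tanh(c)
            H[:, t] = h
            if train:
                gates[:, t] = np.concatenate([i, f, g, o], axis=1)
                cells[:, t] = c
        if train:
            self._cache = dict(X=X, gates=gates, cells=cells, prev_h=prev_h, prev_c=prev_c)
        self._last_state = (h, c)
        return H

    def step(self, x: np.ndarray, h: np.ndarray, c: np.ndarray):
        """One sampling step for a (B, I) input; returns (h, c)."""
        U = self.units
        z = x @ self.W + h @ self.R + self.b
        i = sigmoid(z[:, :U])
        f = sigmoid(z[:, U : 2 * U])
        g = np.tanh(z[:, 2 * U : 3 * U])
        o = sigmoid(z[:, 3 * U :])
        c = f * c + i * g
        h = o * np.tanh(c)
        return h, c

    def backward(self, dH: np.ndarray):
        """BPTT given gradient w.r.t. the hidden sequence; returns
        (dX, grads) with grads ordered like :meth:`params`."""
        cache = self._cache
        X, gates, cells = cache["X"], cache["gates"], cache["cells"]
        prev_h, prev_c = cache["prev_h"], cache["prev_c"]
        B, L, _ = X.shape
        U = self.units
        dW = np.zeros_like(self.W)
        dR = np.zeros_like(self.R)
        db = np.zeros_like(self.b)
        dX = np.empty_like(X)
        dh_next = np.zeros((B, U))
        dc_next = np.zeros((B, U))
        for t in range(L - 1, -1, -1):
            i = gates[:, t, :U]
            f = gates[:, t, U : 2 * U]
            g = gates[:, t, 2 * U : 3 * U]
            o = gates[:, t, 3 * U :]
            c = cells[:, t]
            tc = np.tanh(c)
            dh = dH[:, t] + dh_next
            dc = dc_next + dh * o * (1.0 - tc * tc)
            dz = np.concatenate(
                [
                    dc * g * i * (1.0 - i),
                    dc * prev_c[:, t] * f * (1.0 - f),
                    dc * i * (1.0 - g * g),
                    dh * tc * o * (1.0 - o),
                ],
                axis=1,
            )
            dW += X[:, t].T @ dz
            dR += prev_h[:, t].T @ dz
            db += dz.sum(axis=0)
            dX[:, t] = dz @ self.W.T
            dh_next = dz @ self.R.T
            dc_next = dc * f
        self._cache = {}
        return dX, [dW, dR, db]


@dataclass
class DenseSoftmax:
    """Time-distributed dense layer with softmax over the vocabulary."""

    W: np.ndarray  # (U, V)
    b: np.ndarray  # (V,)
    trainable: bool = True
    _cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def init(cls, rng: np.random.Generator, n_in: int, n_out: int) -> "DenseSoftmax":
        return cls(W=glorot_uniform(rng, (n_in, n_out)), b=np.zeros(n_out))

    @property
    def param_count(self) -> int:
        return self.W.size + self.b.size

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def forward(self, H: np.ndarray, train: bool = False) -> np.ndarray:
        P = softmax(H @ self.W + self.b)
        if train:
            self._cache = dict(H=H, P=P)
        return P

    def backward_from_ce(self, targets: np.ndarray, mask: np.ndarray):
        """Gradient of mean masked cross-entropy, fused with softmax.

        ``targets`` is (B, L) integer classes; ``mask`` is (B, L) in {0,1}.
        Returns (dH, grads).
        """
        H, P = self._cache["H"], self._cache["P"]
        B, L, V = P.shape
        n = max(mask.sum(), 1.0)
        dZ = P.copy()
        idx = np.indices(targets.shape)
        dZ[idx[0], idx[1], targets] -= 1.0
        dZ *= (mask / n)[..., None]
        dW = np.einsum("blu,blv->uv", H, dZ)
        db = dZ.sum(axis=(0, 1))
        dH = dZ @ self.W.T
        self._cache = {}
        return dH, [dW, db]


def masked_ce_and_acc(
    P: np.ndarray, targets: np.ndarray, mask: np.ndarray
) -> tuple[float, float]:
    """Mean categorical cross-entropy (nats) and top-1 accuracy over
    unmasked positions."""
    idx = np.indices(targets.shape)
    p_true = P[idx[0], idx[1], targets]
    n = max(mask.sum(), 1.0)
    ce = float(-(np.log(np.clip(p_true, 1e-12, None)) * mask).sum() / n)
    acc = float(((P.argmax(axis=-1) == targets) * mask).sum() / n)
    return ce, acc


class Adam:
    """Adam over an explicit parameter list; frozen layers simply never
    appear in the list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
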