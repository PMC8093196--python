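"""A small feed-forward / pseudo-Siamese neural network in NumPy.

The two-branch ("pseudo-Siamese") architecture is the core of the method:
each species' feature vector passes through its own branch (the branches
share structure but not weights), the branch outputs are concatenated, and
a final subnetwork maps them to a single probability of the pair being a
truly aligning pair.

Deliberate, recorded choices where the architecture leaves them open:
rectified-linear activations, He-uniform initialization, inverted dropout
after every hidden layer, Adam optimization, and a numerically stable
logit-space weighted binary cross-entropy.  All randomness flows from a
single seed, so training is reproducible on fixed hardware.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "MLP",
    "Adam",
    "PseudoSiameseNetwork",
    "FeedForwardNetwork",
    "sigmoid",
    "weighted_bce_from_logits",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


def weighted_bce_from_logits(
    z: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean weighted binary cross-entropy and its gradient w.r.t. the logits.

    Computed in logit space (softplus form), so no probability clamping is
    needed: ``loss_i = w_i * (softplus(z_i) - y_i * z_i)``.
    """
    n = len(z)
    loss = float(np.sum(w * (_softplus(z) - y * z)) / n)
    grad = w * (sigmoid(z) - y) / n
    return loss, grad


class Dense:
    """Fully connected layer with He-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / n_in)
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ grad_out
        self.db = grad_out.sum(axis=0)
        return grad_out @ self.W.T


class MLP:
    """Stack of dense layers; hidden layers use ReLU and inverted dropout.

    With ``linear_head=True`` the last layer has no activation or dropout
    (used for the output logit).
    """

    def __init__(
        self,
        n_in: int,
        widths: tuple[int, ...],
        rng: np.random.Generator,
        dropout: float = 0.0,
        linear_head: bool = False,
    ):
        if any(w < 1 for w in widths):
            raise ValueError("layer widths must be >= 1")
        if not (0.0 <= dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        self.dropout = dropout
        self.linear_head = linear_head
        self.layers: list[Dense] = []
        prev = n_in
        for w in widths:
            self.layers.append(Dense(prev, w, rng))
            prev = w
        self.n_out = prev
        self._caches: list[tuple[np.ndarray | None, np.ndarray | None]] = []

    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        self._caches = []
        h = x
        last = len(self.layers) - 1
        for i, layer in enumerate(self.layers):
            z = layer.forward(h)
            if self.linear_head and i == last:
                self._caches.append((None, None))
                h = z
                continue
            a = np.maximum(z, 0.0)
            mask = None
            if train and self.dropout > 0.0:
                keep = 1.0 - self.dropout
                mask = (rng.random(a.shape) < keep) / keep
                a = a * mask
            self._caches.append((z, mask))
            h = a
        return h

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = grad_out
        for i in range(len(self.layers) - 1, -1, -1):
            z, mask = self._caches[i]
            if z is not None:
                if mask is not None:
                    g = g * mask
                g = g * (z > 0.0)
            g = self.layers[i].backward(g)
        return g


class Adam:
    """Adam optimizer over a list of Dense layers."""

    def __init__(
        self,
        layers: list[Dense],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.layers = layers
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in layers]
        self.v = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, layer in enumerate(self.layers):
            for j, (param, grad) in enumerate(
                ((layer.W, layer.dW), (layer.b, layer.db))
            ):
                m_w, m_b = self.m[i]
                v_w, v_b = self.v[i]
                m = m_w if j == 0 else m_b
                v = v_w if j == 0 else v_b
                m *= b1
                m += (1 - b1) * grad
                v *= b2
                v += (1 - b2) * grad**2
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


_PREDICT_CHUNK = 512


def _chunked(fn, Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    """Apply ``fn`` over fixed-shape zero-padded chunks of the inputs."""
    n = len(Xa)
    out = np.empty(n)
    for start in range(0, n, _PREDICT_CHUNK):
        end = min(start + _PREDICT_CHUNK, n)
        m = end - start
        if m == _PREDICT_CHUNK:
            out[start:end] = fn(Xa[start:end], Xb[start:end])
        else:
            pa = np.zeros((_PREDICT_CHUNK, Xa.shape[1]))
            pb = np.zeros((_PREDICT_CHUNK, Xb.shape[1]))
            pa[:m] = Xa[start:end]
            pb[:m] = Xb[start:end]
            out[start:end] = fn(pa, pb)[:m]
    return out


class _NetworkBase:
    """Shared training-step and weight-snapshot machinery."""

    def all_layers(self) -> list[Dense]:  # pragma: no cover - overridden
        raise NotImplementedError

    def get_weights(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(l.W.copy(), l.b.copy()) for l in self.all_layers()]

    def set_weights(self, weights) -> None:
        for layer, (W, b) in zip(self.all_layers(), weights):
            layer.W = W.copy()
            layer.b = b.copy()

    def weight_signature(self) -> float:
        """A cheap scalar fingerprint of all weights (for change detection)."""
        return float(sum(np.abs(l.W).sum() + np.abs(l.b).sum() for l in self.all_layers()))


class PseudoSiameseNetwork(_NetworkBase):
    """Two distinct species branches feeding a final combining subnetwork."""

    def __init__(
        self,
        n_a: int,
        n_b: int,
        branch_widths: tuple[int, ...],
        final_widths: tuple[int, ...],
        dropout: float,
        seed: int,
    ):
        rng = np.random.default_rng(seed)
        self.branch_a = MLP(n_a, branch_widths, rng, dropout)
        self.branch_b = MLP(n_b, branch_widths, rng, dropout)
        n_merge = (branch_widths[-1] if branch_widths else n_a) + (
            branch_widths[-1] if branch_widths else n_b
        )
        self.final = MLP(
            n_merge, tuple(final_widths) + (1,), rng, dropout, linear_head=True
        )
        self._rng = rng
        self.n_a, self.n_b = n_a, n_b

    def all_layers(self) -> list[Dense]:
        return self.branch_a.layers + self.branch_b.layers + self.final.layers

    def forward_logits(
        self, Xa: np.ndarray, Xb: np.ndarray, train: bool = False
    ) -> np.ndarray:
        ha = self.branch_a.forward(Xa, train, self._rng)
        hb = self.branch_b.forward(Xb, train, self._rng)
        self._split = ha.shape[1]
        h = np.concatenate([ha, hb], axis=1)
        return self.final.forward(h, train, self._rng)[:, 0]

    def backward(self, grad_logits: np.ndarray) -> None:
        g = self.final.backward(grad_logits[:, None])
        self.branch_a.backward(g[:, : self._split])
        self.branch_b.backward(g[:, self._split :])

    def predict_proba(self, Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
        """Probability that each pair is a truly aligning pair.

        Evaluated in fixed-size zero-padded chunks so each row's result is
        bit-identical regardless of how predictions are batched (BLAS picks
        kernels by matrix shape, so variable batch sizes would otherwise
        drift in the last ulp).
        """
        return _chunked(lambda a, b: sigmoid(self.forward_logits(a, b)), Xa, Xb)

    def train_step(
        self,
        Xa: np.ndarray,
        Xb: np.ndarray,
        y: np.ndarray,
        w: np.ndarray,
        optimizer: Adam,
    ) -> float:
        z = self.forward_logits(Xa, Xb, train=True)
        loss, grad = weighted_bce_from_logits(z, y, w)
        self.backward(grad)
        optimizer.step()
        return loss


class FeedForwardNetwork(_NetworkBase):
    """Fully connected network on a single species' features.

    Used by the single-species baseline that predicts whether a region
    aligns to the other genome at all.
    """

    def __init__(
        self,
        n_in: int,
        widths: tuple[int, ...],
        dropout: float,
        seed: int,
    ):
        rng = np.random.default_rng(seed)
        self.net = MLP(n_in, tuple(widths) + (1,), rng, dropout, linear_head=True)
        self._rng = rng
        self.n_in = n_in

    def all_layers(self) -> list[Dense]:
        return self.net.layers

    def forward_logits(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(X, train, self._rng)[:, 0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _chunked(lambda a, b: sigmoid(self.forward_logits(a)), X, X)

    def train_step(
        self, X: np.ndarray, y: np.ndarray, w: np.ndarray, optimizer: Adam
    ) -> float:
        z = self.forward_logits(X, train=True)
        loss, grad = weighted_bce_from_logits(z, y, w)
        self.net.backward(grad[:, None])
        optimizer.step()
        return loss
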