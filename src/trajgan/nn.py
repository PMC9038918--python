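"""Minimal fully-connected networks with analytic backpropagation.

Both networks have a single hidden layer with LeakyReLU activation. The
generator maps latent vectors to [0, 1]-valued expression profiles through
a sigmoid output; the critic maps profiles to an unbounded scalar score.
Everything is float64 NumPy; gradients are exact (hand-derived), including
the gradient-penalty parameter gradients, which for piecewise-linear
activations coincide with what reverse-mode autodiff computes because the
second derivative of LeakyReLU is zero almost everywhere.

Rows are samples throughout: a batch is ``(B, dim)``.
"""

from __future__ import annotations

import numpy as np

LEAKY_SLOPE = 0.2


def leaky_relu(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, x, LEAKY_SLOPE * x)


def leaky_relu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, 1.0, LEAKY_SLOPE)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _init_weight(rng: np.random.Generator, shape: tuple[int, int], init_range) -> np.ndarray:
    lo, hi = init_range
    return rng.uniform(lo, hi, size=shape)


class MLPGenerator:
    """latent -> hidden (LeakyReLU) -> genes (sigmoid)."""

    def __init__(self, latent_dim: int, hidden: int, out_dim: int, init_range, rng):
        self.latent_dim = latent_dim
        self.hidden = hidden
        self.out_dim = out_dim
        self.params = {
            "W1": _init_weight(rng, (latent_dim, hidden), init_range),
            "b1": np.zeros(hidden),
            "W2": _init_weight(rng, (hidden, out_dim), init_range),
            "b2": np.zeros(out_dim),
        }

    def forward(self, z: np.ndarray):
        p = self.params
        h = z @ p["W1"] + p["b1"]
        a = leaky_relu(h)
        y = a @ p["W2"] + p["b2"]
        x = _sigmoid(y)
        cache = (z, h, a, x)
        return x, cache

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Generator output for latent rows ``z``; every entry in (0, 1)."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        return self.forward(z)[0]

    def backward(self, cache, dx: np.ndarray) -> dict[str, np.ndarray]:
        """Parameter gradients given dLoss/dOutput ``dx`` (same shape as x)."""
        z, h, a, x = cache
        p = self.params
        dy = dx * x * (1.0 - x)  # sigmoid'
        grads = {
            "W2": a.T @ dy,
            "b2": dy.sum(axis=0),
        }
        da = dy @ p["W2"].T
        dh = da * leaky_relu_grad(h)
        grads["W1"] = z.T @ dh
        grads["b1"] = dh.sum(axis=0)
        return grads


class MLPCritic:
    """genes -> hidden (LeakyReLU) -> scalar score (no output activation)."""

    def __init__(self, in_dim: int, hidden: int, init_range, rng):
        self.in_dim = in_dim
        self.hidden = hidden
        self.params = {
            "V1": _init_weight(rng, (in_dim, hidden), init_range),
            "c1": np.zeros(hidden),
            "v2": _init_weight(rng, (hidden, 1), init_range)[:, 0],
            "c2": np.zeros(1),
        }

    def forward(self, x: np.ndarray):
        p = self.params
        h = x @ p["V1"] + p["c1"]
        a = leaky_relu(h)
        s = a @ p["v2"] + p["c2"][0]
        cache = (x, h, a)
        return s, cache

    def score(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return self.forward(x)[0]

    def backward(self, cache, ds: np.ndarray) -> dict[str, np.ndarray]:
        """Parameter gradients given per-sample dLoss/dScore weights ``ds``."""
        x, h, a = cache
        p = self.params
        grads = {
            "v2": a.T @ ds,
            "c2": np.array([ds.sum()]),
        }
        dh = ds[:, None] * p["v2"][None, :] * leaky_relu_grad(h)
        grads["V1"] = x.T @ dh
        grads["c1"] = dh.sum(axis=0)
        return grads

    def input_grad(self, x: np.ndarray) -> np.ndarray:
        """d score / d input, one row per sample."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        p = self.params
        h = x @ p["V1"] + p["c1"]
        d = leaky_relu_grad(h) * p["v2"][None, :]  # (B, H)
        return d @ p["V1"].T

    def gp_value_and_grads(self, xhat: np.ndarray):
        """Gradient penalty ``mean((||grad_x s|| - 1)^2)`` and its parameter
        gradients at interpolated points ``xhat``.

        The activation pattern ``leaky_relu_grad(h)`` is piecewise constant,
        so differentiating through it contributes zero almost everywhere;
        the returned gradients treat it as constant, exactly as autodiff
        would.
        """
        p = self.params
        B = xhat.shape[0]
        h = xhat @ p["V1"] + p["c1"]
        d = leaky_relu_grad(h)  # (B, H)
        m = d * p["v2"][None, :]  # (B, H)
        g = m @ p["V1"].T  # (B, G) input gradients
        norms = np.sqrt((g**2).sum(axis=1))
        penalty = float(((norms - 1.0) ** 2).mean())
        safe = np.where(norms > 0, norms, 1.0)
        u = (2.0 / B) * ((norms - 1.0) / safe)[:, None] * g  # dP/dg, (B, G)
        grads = {
            "V1": u.T @ m,
            "v2": (d * (u @ p["V1"])).sum(axis=0),
            "c1": np.zeros_like(p["c1"]),
            "c2": np.zeros_like(p["c2"]),
        }
        return penalty, grads


class RMSProp:
    """RMSprop with the usual accumulator smoothing (alpha=0.99, eps=1e-8)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, alpha: float = 0.99, eps: float = 1e-8):
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.cache = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            c = self.cache[k]
            c *= self.alpha
            c += (1.0 - self.alpha) * g * g
            params[k] -= self.lr * g / (np.sqrt(c) + self.eps)
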