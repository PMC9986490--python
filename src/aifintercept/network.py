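"""Two-headed joint MLP and its optimizer, in plain numpy.

The joint model maps an observation o through a shared rectified-linear trunk

    z1 = relu(W1 o + b1),  z2 = relu(W2 z1 + b2)

to two linear heads: a negative-expected-free-energy (G-value) head with one
output per discrete action, and a transition head predicting the next
observation.  Parameters live in a single flat float32 vector with reshaped
views per weight matrix, so the gradient is one contiguous array and the
optimizer update is a handful of vectorized operations; reverse-mode
gradients are written out by hand (and checked against finite differences in
the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["JointModel", "Adam", "efe_loss"]


class JointModel:
    """Shared-trunk MLP with a G-value head (A outputs) and an observation
    head (D outputs).

    Weight initialization: He-normal (std sqrt(2/fan_in)) for every weight
    matrix, zero biases; deterministic under the supplied generator.  Biases
    can be disabled for the pure linear-algebra form.
    """

    def __init__(self, hidden_sizes: Sequence[int] = (128, 128),
                 obs_dim: int = 4, n_actions: int = 6,
                 bias: bool = True, dtype=np.float32,
                 rng: Optional[np.random.Generator] = None):
        if len(hidden_sizes) != 2 or any(int(j) <= 0 for j in hidden_sizes):
            raise ValueError("hidden_sizes must be two positive integers, "
                             f"got {hidden_sizes!r}")
        if obs_dim <= 0 or n_actions <= 0:
            raise ValueError("obs_dim and n_actions must be positive")
        self.obs_dim = int(obs_dim)
        self.n_actions = int(n_actions)
        self.j1, self.j2 = (int(j) for j in hidden_sizes)
        self.bias = bool(bias)
        self.dtype = np.dtype(dtype)
        rng = rng if rng is not None else np.random.default_rng()

        shapes = self._shapes()
        self.n_params = sum(int(np.prod(s)) for s in shapes.values())
        self.theta = np.zeros(self.n_params, dtype=self.dtype)
        self._views = {}
        off = 0
        for name, shape in shapes.items():
            size = int(np.prod(shape))
            self._views[name] = self.theta[off:off + size].reshape(shape)
            off += size
        for name in ("W1", "W2", "Wa", "Wo"):
            v = self._views[name]
            fan_in = v.shape[0]
            v[...] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                size=v.shape).astype(self.dtype)

    def _shapes(self) -> dict:
        d, a, j1, j2 = self.obs_dim, self.n_actions, self.j1, self.j2
        shapes = {"W1": (d, j1), "W2": (j1, j2), "Wa": (j2, a), "Wo": (j2, d)}
        if self.bias:
            shapes.update({"b1": (j1,), "b2": (j2,), "ba": (a,), "bo": (d,)})
        return shapes

    def __getattr__(self, name):
        views = self.__dict__.get("_views", {})
        if name in views:
            return views[name]
        raise AttributeError(name)

    # -- inference -----------------------------------------------------------

    def forward(self, X: np.ndarray, cache: bool = False):
        """G-values (B, A) and predicted next observations (B, D) for a batch.

        With ``cache=True`` also returns the intermediates needed by
        :meth:`backward`.
        """
        X = np.atleast_2d(np.asarray(X, dtype=self.dtype))
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite observation input")
        Z1 = X @ self.W1
        if self.bias:
            Z1 += self.b1
        np.maximum(Z1, 0.0, out=Z1)
        Z2 = Z1 @ self.W2
        if self.bias:
            Z2 += self.b2
        np.maximum(Z2, 0.0, out=Z2)
        G = Z2 @ self.Wa
        O = Z2 @ self.Wo
        if self.bias:
            G += self.ba
            O += self.bo
        if cache:
            return G, O, (X, Z1, Z2)
        return G, O

    def g_values(self, X: np.ndarray) -> np.ndarray:
        """Action-head output only."""
        return self.forward(X)[0]

    # -- reverse-mode gradient ----------------------------------------------

    def backward(self, cache, dG: np.ndarray, dO: np.ndarray) -> np.ndarray:
        """Gradient of a scalar loss wrt theta, given head output gradients.

        ``dG`` and ``dO`` are dLoss/dG and dLoss/dO for the cached batch.
        Returns a flat array aligned with :attr:`theta`.
        """
        X, Z1, Z2 = cache
        grad = np.zeros_like(self.theta)
        gv = {}
        off = 0
        for name, shape in self._shapes().items():
            size = int(np.prod(shape))
            gv[name] = grad[off:off + size].reshape(shape)
            off += size

        dG = dG.astype(self.dtype, copy=False)
        dO = dO.astype(self.dtype, copy=False)
        np.matmul(Z2.T, dG, out=gv["Wa"])
        np.matmul(Z2.T, dO, out=gv["Wo"])
        dZ2 = dG @ self.Wa.T
        dZ2 += dO @ self.Wo.T
        dZ2[Z2 <= 0.0] = 0.0
        np.matmul(Z1.T, dZ2, out=gv["W2"])
        dZ1 = dZ2 @ self.W2.T
        dZ1[Z1 <= 0.0] = 0.0
        np.matmul(X.T, dZ1, out=gv["W1"])
        if self.bias:
            np.sum(dG, axis=0, out=gv["ba"])
            np.sum(dO, axis=0, out=gv["bo"])
            np.sum(dZ2, axis=0, out=gv["b2"])
            np.sum(dZ1, axis=0, out=gv["b1"])
        return grad

    # -- parameter transport -------------------------------------------------

    def copy(self) -> "JointModel":
        """Independent deep copy (used for the frozen target network)."""
        clone = JointModel.__new__(JointModel)
        clone.obs_dim, clone.n_actions = self.obs_dim, self.n_actions
        clone.j1, clone.j2 = self.j1, self.j2
        clone.bias, clone.dtype = self.bias, self.dtype
        clone.n_params = self.n_params
        clone.theta = self.theta.copy()
        clone._views = {}
        off = 0
        for name, shape in self._shapes().items():
            size = int(np.prod(shape))
            clone._views[name] = clone.theta[off:off + size].reshape(shape)
            off += size
        return clone

    def load_theta(self, theta: np.ndarray) -> None:
        if theta.shape != self.theta.shape:
            raise ValueError("parameter vector shape mismatch")
        self.theta[...] = theta

    def state_dict(self) -> dict:
        return {name: v.copy() for name, v in self._views.items()}


class Adam:
    """Adam optimizer on a single flat parameter vector."""

    def __init__(self, n_params: int, lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, dtype=np.float32):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(n_params, dtype=dtype)
        self.v = np.zeros(n_params, dtype=dtype)
        self.t = 0

    def step(self, theta: np.ndarray, grad: np.ndarray) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        self.m *= b1
        self.m += (1.0 - b1) * grad
        self.v *= b2
        self.v += (1.0 - b2) * np.square(grad)
        mhat = self.m / (1.0 - b1 ** self.t)
        vhat = self.v / (1.0 - b2 ** self.t)
        theta -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {"m": self.m.copy(), "v": self.v.copy(), "t": self.t}

    def load_state_dict(self, state: dict) -> None:
        self.m[...] = state["m"]
        self.v[...] = state["v"]
        self.t = int(state["t"])


def efe_loss(g_pred: np.ndarray, g_target: np.ndarray,
             o_pred: np.ndarray, o_next: np.ndarray,
             sigma_a: float = 1.0, sigma_o: float = 1.0,
             obs_loss_weight: float = 1.0) -> float:
    """Multi-objective loss: L = La + Lo, averaged over the batch.

    La = ||t - g||^2 / (2 sigma_a^2) on the G head (the target vector equals
    the model's own output at non-taken actions, so only the taken action
    contributes); Lo = ||o_next - o_hat||^2 / (2 sigma_o^2) on the transition
    head, optionally down-weighted (0 disables the head, as in the DQN
    baseline).
    """
    if sigma_a <= 0 or sigma_o <= 0:
        raise ValueError("sigma_a and sigma_o must be positive")
    ra = g_pred - g_target
    ro = o_pred - o_next
    la = float(np.sum(ra * ra)) / (2.0 * sigma_a ** 2)
    lo = float(np.sum(ro * ro)) / (2.0 * sigma_o ** 2)
    n = g_pred.shape[0] if g_pred.ndim > 1 else 1
    return (la + obs_loss_weight * lo) / n
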