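"""The two-layer logistic feedforward network and its optimizers.

Architecture: input -> hidden -> output, logistic activation sigma(z) =
1/(1+exp(-z)) at both layers; default sizes 132-100-112.  Weights and
biases are initialised uniformly in [-0.5, +0.5].

Training minimises the halved summed squared error E = 1/2 sum_j (o_j -
t_j)^2 with binary 0/1 targets, giving the classic delta rule delta_j =
(o_j - t_j) o_j (1 - o_j); the stated learning rates assume this
convention.  Two optimizers are provided:

* **backprop**: per-pattern gradient descent with momentum,
  ``delta_w = -lr * dE/dw + momentum * delta_w_prev``.
* **quickprop**: epoch-wise batch updates.  Per weight, the secant step
  ``step = prev_step * g / (g_prev - g)`` jumps toward the vertex of the
  local parabola; its magnitude is capped at ``mu * |prev_step|`` and a
  plain gradient step ``-lr * g`` is used whenever the secant step is
  unavailable (no previous step, vanishing denominator) or points uphill.
  Quickprop gradients use the standard flat-spot elimination: a constant
  offset added to the logistic derivative so units pinned at the sigmoid's
  extremes keep a usable error signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np

PARAM_KEYS = ("W_ih", "b_h", "W_ho", "b_o")

#: magnitudes below this count as zero for gradients and Quickprop memories
ZERO_TOL = 1e-12


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class Hyperparams:
    """Training hyperparameters.

    The staged-curriculum simulations use learning rate 0.01 for the first
    three protocols and 0.05 elsewhere; momentum is 0.9 except in the
    momentum-control protocol where it is 0.
    """

    learning_rate: float = 0.05
    momentum: float = 0.9
    optimizer: str = "backprop"  # or "quickprop"
    quickprop_mu: float = 1.75
    quickprop_prime_offset: float = 0.1  # flat-spot elimination constant
    init_range: float = 0.5

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.optimizer not in ("backprop", "quickprop"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.quickprop_mu <= 0:
            raise ValueError("quickprop_mu must be positive")
        if self.quickprop_prime_offset < 0:
            raise ValueError("quickprop_prime_offset must be nonnegative")


@dataclass
class NetworkState:
    """Weights, biases and optimizer memory of the two-layer network."""

    W_ih: np.ndarray  # (hidden, input)
    b_h: np.ndarray  # (hidden,)
    W_ho: np.ndarray  # (output, hidden)
    b_o: np.ndarray  # (output,)
    prev_delta: Dict[str, np.ndarray] = field(default_factory=dict)  # momentum memory
    prev_grad: Dict[str, np.ndarray] = field(default_factory=dict)  # Quickprop memory
    rng_seed: int = 0

    @property
    def n_in(self) -> int:
        return self.W_ih.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W_ih.shape[0]

    @property
    def n_out(self) -> int:
        return self.W_ho.shape[0]

    def params(self) -> Dict[str, np.ndarray]:
        return {"W_ih": self.W_ih, "b_h": self.b_h, "W_ho": self.W_ho, "b_o": self.b_o}

    def copy(self) -> "NetworkState":
        return NetworkState(
            W_ih=self.W_ih.copy(),
            b_h=self.b_h.copy(),
            W_ho=self.W_ho.copy(),
            b_o=self.b_o.copy(),
            prev_delta={k: v.copy() for k, v in self.prev_delta.items()},
            prev_grad={k: v.copy() for k, v in self.prev_grad.items()},
            rng_seed=self.rng_seed,
        )

    # ------------------------------------------------------------------ I/O

    def save(self, path) -> None:
        """Self-describing JSON layout; float repr round-trips exactly."""
        doc = {
            "format": "aoanet-network",
            "version": 1,
            "sizes": {"n_in": self.n_in, "n_hidden": self.n_hidden, "n_out": self.n_out},
            "rng_seed": self.rng_seed,
            "params": {k: v.ravel().tolist() for k, v in self.params().items()},
            "prev_delta": {k: v.ravel().tolist() for k, v in self.prev_delta.items()},
            "prev_grad": {k: v.ravel().tolist() for k, v in self.prev_grad.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "NetworkState":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "aoanet-network":
            raise ValueError("not an aoanet network file")
        s = doc["sizes"]
        shapes = {
            "W_ih": (s["n_hidden"], s["n_in"]),
            "b_h": (s["n_hidden"],),
            "W_ho": (s["n_out"], s["n_hidden"]),
            "b_o": (s["n_out"],),
        }

        def arrs(group: Dict[str, list]) -> Dict[str, np.ndarray]:
            return {k: np.array(v, dtype=float).reshape(shapes[k]) for k, v in group.items()}

        p = arrs(doc["params"])
        return cls(
            W_ih=p["W_ih"],
            b_h=p["b_h"],
            W_ho=p["W_ho"],
            b_o=p["b_o"],
            prev_delta=arrs(doc.get("prev_delta", {})),
            prev_grad=arrs(doc.get("prev_grad", {})),
            rng_seed=int(doc.get("rng_seed", 0)),
        )


def init_network(
    n_in: int = 132,
    n_hidden: int = 100,
    n_out: int = 112,
    init_range: float = 0.5,
    seed: int = 0,
) -> NetworkState:
    """Fresh network with weights and biases uniform in [-init_range, +init_range]."""
    if min(n_in, n_hidden, n_out) < 1:
        raise ValueError("all layer sizes must be >= 1")
    rng = np.random.default_rng(seed)
    u = lambda *shape: rng.uniform(-init_range, init_range, size=shape)
    state = NetworkState(
        W_ih=u(n_hidden, n_in),
        b_h=u(n_hidden),
        W_ho=u(n_out, n_hidden),
        b_o=u(n_out),
        rng_seed=seed,
    )
    state.prev_delta = {k: np.zeros_like(v) for k, v in state.params().items()}
    state.prev_grad = {k: np.zeros_like(v) for k, v in state.params().items()}
    return state


# --------------------------------------------------------------------------
# forward / gradients


def forward(state: NetworkState, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Hidden and output activations for a single input vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (state.n_in,):
        raise ValueError(f"input shape {x.shape} does not match n_in={state.n_in}")
    h = sigmoid(state.W_ih @ x + state.b_h)
    o = sigmoid(state.W_ho @ h + state.b_o)
    return h, o


def forward_batch(state: NetworkState, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Row-wise forward pass: X is (n, n_in); returns (n, hidden), (n, out)."""
    X = np.asarray(X, dtype=float)
    H = sigmoid(X @ state.W_ih.T + state.b_h)
    O = sigmoid(H @ state.W_ho.T + state.b_o)
    return H, O


def sse(output: np.ndarray, target: np.ndarray) -> float:
    return float(np.sum((output - target) ** 2))


def gradients(
    state: NetworkState,
    x: np.ndarray,
    target: np.ndarray,
    prime_offset: float = 0.0,
) -> Dict[str, np.ndarray]:
    """Gradient of E = 1/2 sum (o - t)^2 by the delta rule with logistic derivative.

    ``prime_offset`` is added to the derivative term o(1-o) (flat-spot
    elimination); 0 gives the exact gradient.
    """
    h, o = forward(state, x)
    delta_o = (o - target) * (o * (1.0 - o) + prime_offset)
    delta_h = (state.W_ho.T @ delta_o) * (h * (1.0 - h) + prime_offset)
    return {
        "W_ih": np.outer(delta_h, x),
        "b_h": delta_h,
        "W_ho": np.outer(delta_o, h),
        "b_o": delta_o,
    }


def backprop_update(
    state: NetworkState, x: np.ndarray, target: np.ndarray, hp: Hyperparams
) -> NetworkState:
    """One per-pattern gradient-descent-with-momentum update, in place."""
    if hp.optimizer != "backprop":
        raise ValueError("backprop_update requires hp.optimizer == 'backprop'")
    g = gradients(state, x, target)
    params = state.params()
    for k in PARAM_KEYS:
        if not np.all(np.isfinite(g[k])):
            raise FloatingPointError(f"non-finite gradient in {k}")
        delta = -hp.learning_rate * g[k] + hp.momentum * state.prev_delta[k]
        params[k] += delta
        state.prev_delta[k] = delta
    return state


def quickprop_step(
    g: np.ndarray, g_prev: np.ndarray, prev_step: np.ndarray, lr: float, mu: float
) -> np.ndarray:
    """Element-wise Quickprop step.

    Secant step toward the vertex of the per-weight parabola, capped at
    ``mu * |prev_step|``; falls back to ``-lr * g`` when there is no usable
    previous step, the denominator vanishes, or the secant step points
    uphill (implied negative curvature).
    """
    g = np.asarray(g, dtype=float)
    g_prev = np.asarray(g_prev, dtype=float)
    prev_step = np.asarray(prev_step, dtype=float)
    fallback = -lr * g
    denom = g_prev - g
    with np.errstate(divide="ignore", invalid="ignore"):
        secant = prev_step * g / denom
    cap = mu * np.abs(prev_step)
    secant = np.clip(secant, -cap, cap)
    usable = (
        (np.abs(prev_step) >= ZERO_TOL)
        & (np.abs(denom) >= ZERO_TOL)
        & (secant * g <= 0)  # descent direction under positive estimated curvature
    )
    return np.where(usable, secant, fallback)


def quickprop_update(
    state: NetworkState,
    batch: Sequence[Tuple[np.ndarray, np.ndarray]],
    hp: Hyperparams,
) -> NetworkState:
    """One epoch-wise Quickprop update over the whole batch, in place.

    The batch gradient is the mean of per-pattern gradients so the fallback
    gradient step does not scale with the presentation-list length.
    """
    if hp.optimizer != "quickprop":
        raise ValueError("quickprop_update requires hp.optimizer == 'quickprop'")
    if len(batch) == 0:
        raise ValueError("batch must be nonempty")
    acc: Dict[str, np.ndarray] = {k: np.zeros_like(v) for k, v in state.params().items()}
    for x, t in batch:
        g = gradients(state, x, t, prime_offset=hp.quickprop_prime_offset)
        for k in PARAM_KEYS:
            acc[k] += g[k]
    params = state.params()
    n = float(len(batch))
    for k in PARAM_KEYS:
        g = acc[k] / n
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in {k}")
        step = quickprop_step(g, state.prev_grad[k], state.prev_delta[k], hp.learning_rate, hp.quickprop_mu)
        params[k] += step
        state.prev_delta[k] = step
        state.prev_grad[k] = g
    return state
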