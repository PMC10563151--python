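"""Feedforward scoring-network internals: forward, backprop, Adam.

The network maps one cell's marker vector to a scalar in (0, 1): ReLU hidden
layers, sigmoid output.  Implemented directly on NumPy arrays; parameters are
a list of (W, b) pairs.  Gradients are taken with respect to an arbitrary
per-cell upstream derivative dL/ds, which is how the sample-level losses
(functions of per-sample score means) reach the cell level.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

Params = List[Tuple[np.ndarray, np.ndarray]]


def init_params(layer_sizes: Sequence[int], rng: np.random.Generator) -> Params:
    """He-initialized weights for ReLU hidden layers, Xavier for the output."""
    params: Params = []
    for k in range(len(layer_sizes) - 1):
        fan_in, fan_out = layer_sizes[k], layer_sizes[k + 1]
        last = k == len(layer_sizes) - 2
        scale = np.sqrt(1.0 / fan_in) if last else np.sqrt(2.0 / fan_in)
        W = rng.normal(0.0, scale, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        params.append((W, b))
    return params


def clone_params(params: Params) -> Params:
    return [(W.copy(), b.copy()) for W, b in params]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward(params: Params, X: np.ndarray, want_cache: bool = False):
    """Score every row of X.  Returns (scores, cache); cache is None unless
    requested (activations needed for backprop)."""
    a = X
    acts = [X] if want_cache else None
    n_layers = len(params)
    for k, (W, b) in enumerate(params):
        z = a @ W + b
        if k < n_layers - 1:
            a = np.maximum(z, 0.0)
        else:
            a = _sigmoid(z)
        if want_cache:
            acts.append(a)
    scores = a[:, 0]
    return scores, acts


def backward(params: Params, acts: List[np.ndarray], dscore: np.ndarray) -> Params:
    """Gradients of sum_j dscore_j * s_j with respect to every W, b."""
    s = acts[-1][:, 0]
    delta = (dscore * s * (1.0 - s))[:, None]  # d/dz at the sigmoid output
    grads: Params = [None] * len(params)  # type: ignore[list-item]
    for k in range(len(params) - 1, -1, -1):
        a_prev = acts[k]
        gW = a_prev.T @ delta
        gb = delta.sum(axis=0)
        grads[k] = (gW, gb)
        if k > 0:
            delta = delta @ params[k][0].T
            delta = delta * (acts[k] > 0)  # ReLU mask
    return grads


class Adam:
    """Adam update rule over a flat list of arrays."""

    def __init__(self, shapes: List[Tuple[int, ...]], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, values: List[np.ndarray], grads: List[np.ndarray]) -> List[np.ndarray]:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        out = []
        for i, (x, g) in enumerate(zip(values, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            out.append(x - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def flatten(params: Params) -> List[np.ndarray]:
    flat: List[np.ndarray] = []
    for W, b in params:
        flat.extend([W, b])
    return flat


def unflatten(flat: List[np.ndarray]) -> Params:
    return [(flat[i], flat[i + 1]) for i in range(0, len(flat), 2)]
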