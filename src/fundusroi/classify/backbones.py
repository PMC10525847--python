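"""Small fully-connected backbones with a hand-rolled Adam optimizer.

The original pipeline plugs ImageNet-scale CNNs into each branch; here the
backbone is an interchangeable component behind a registry, and the bundled
implementations are deliberately tiny NumPy networks so the full training
loop runs deterministically on one CPU in seconds. Registering a heavier
backbone only requires the same forward/backward surface.
"""
from __future__ import annotations

from typing import Callable, Dict, List, Tuple

import numpy as np

Params = Dict[str, np.ndarray]


class TinyMLP:
    """Flatten -> (dense + ReLU)* -> dense logits.

    Weights use He-style initialization from a seeded generator. ``backward``
    returns gradients for the mean-reduced loss given d(loss)/d(logits).
    """

    def __init__(self, input_dim: int, hidden: Tuple[int, ...], n_outputs: int,
                 rng: np.random.Generator):
        self.input_dim = input_dim
        self.hidden = tuple(hidden)
        self.n_outputs = n_outputs
        dims = [input_dim, *hidden, n_outputs]
        self.params: Params = {}
        for i, (d_in, d_out) in enumerate(zip(dims[:-1], dims[1:])):
            scale = np.sqrt(2.0 / d_in)
            self.params[f"W{i}"] = rng.normal(0.0, scale, size=(d_in, d_out))
            self.params[f"b{i}"] = np.zeros(d_out)
        self.n_layers = len(dims) - 1

    def forward(self, x: np.ndarray, return_cache: bool = False):
        a = x.reshape(x.shape[0], -1).astype(np.float64)
        cache: List[np.ndarray] = [a]
        for i in range(self.n_layers):
            z = a @ self.params[f"W{i}"] + self.params[f"b{i}"]
            a = np.maximum(z, 0.0) if i < self.n_layers - 1 else z
            cache.append(a)
        return (a, cache) if return_cache else a

    def backward(self, cache: List[np.ndarray], dlogits: np.ndarray) -> Params:
        grads: Params = {}
        delta = dlogits
        for i in range(self.n_layers - 1, -1, -1):
            a_prev = cache[i]
            grads[f"W{i}"] = a_prev.T @ delta
            grads[f"b{i}"] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.params[f"W{i}"].T) * (cache[i] > 0)
        return grads

    def get_params(self) -> Params:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: Params) -> None:
        self.params = {k: v.copy() for k, v in params.items()}


class Adam:
    def __init__(self, params: Params, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Params, grads: Params, lr: float) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


BackboneFactory = Callable[[int, int, np.random.Generator], TinyMLP]

BACKBONE_REGISTRY: Dict[str, BackboneFactory] = {
    "tiny-mlp": lambda d, k, rng: TinyMLP(d, (32,), k, rng),
    "tiny-mlp-64": lambda d, k, rng: TinyMLP(d, (64,), k, rng),
    "linear": lambda d, k, rng: TinyMLP(d, (), k, rng),
}


def build_backbone(name: str, input_dim: int, n_outputs: int,
                   rng: np.random.Generator) -> TinyMLP:
    if name not in BACKBONE_REGISTRY:
        raise KeyError(
            f"unregistered backbone {name!r}; known: {sorted(BACKBONE_REGISTRY)}"
        )
    return BACKBONE_REGISTRY[name](input_dim, n_outputs, rng)
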