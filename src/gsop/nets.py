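"""Small fully connected networks used by the structured drift model and encoder.

Activations are pluggable but restricted to functions whose derivative is
itself expressible with the primitive ops of :mod:`gsop.autodiff`, so that
analytic input-gradients of a network remain differentiable with respect to
the network parameters (needed when the training loss contains ∇V).

ReQUr is a rectified-quadratic unit with asymptotically linear growth,

    ReQUr(x) = max(x, 0)^2 - max(x - 1/2, 0)^2,

quadratic near zero and linear for large x, which keeps the potential's
gradient Lipschitz.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


def _requr(x: Tensor) -> Tensor:
    return ad.square(ad.relu(x)) - ad.square(ad.relu(x - 0.5))


def _requr_prime(x: Tensor) -> Tensor:
    return 2.0 * ad.relu(x) - 2.0 * ad.relu(x - 0.5)


def _tanh_prime(x: Tensor) -> Tensor:
    return 1.0 - ad.square(ad.tanh(x))


def _relu_prime(x: Tensor) -> Tensor:
    # heaviside, expressed with primitives; value at 0 is irrelevant a.e.
    y = ad.relu(x)
    return ad.Tensor((y.data > 0).astype(float))


ACTIVATIONS = {
    "tanh": (ad.tanh, _tanh_prime),
    "requr": (_requr, _requr_prime),
    "relu": (ad.relu, _relu_prime),
}


class MLP:
    """Fully connected network with cached pre-activations.

    Parameters are ``Tensor`` leaves with ``requires_grad=True``.  The
    forward pass optionally returns the list of hidden pre-activations so
    that :meth:`vjp` can build the analytic input-gradient as a graph
    expression.
    """

    def __init__(self, sizes: list[int], activation: str = "tanh",
                 rng: np.random.Generator | None = None,
                 out_scale: float = 1.0, zero_init: bool = False):
        if activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.sizes = list(sizes)
        self.activation = activation
        self._act, self._act_prime = ACTIVATIONS[activation]
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for i, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            if zero_init:
                w = np.zeros((n_in, n_out))
            else:
                scale = np.sqrt(2.0 / (n_in + n_out))
                w = rng.normal(0.0, scale, size=(n_in, n_out))
                if i == len(sizes) - 2:
                    w *= out_scale
            self.weights.append(ad.parameter(w))
            self.biases.append(ad.parameter(np.zeros(n_out)))

    @property
    def parameters(self) -> list[Tensor]:
        return self.weights + self.biases

    def forward(self, x: Tensor, return_cache: bool = False):
        """Apply the network to a batch ``x`` of shape (B, n_in)."""
        x = ad.constant(x)
        cache = []
        h = x
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            pre = ad.matmul(h, w) + b
            if i < n_layers - 1:
                cache.append(pre)
                h = self._act(pre)
            else:
                h = pre
        return (h, cache) if return_cache else h

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def vjp(self, v: Tensor, cache: list[Tensor]) -> Tensor:
        """In-graph vector-Jacobian product ``v^T (d out / d x)``.

        ``v`` has shape (B, n_out); the result has shape (B, n_in).  The
        expression uses the activation derivative as a graph op, so it can
        itself be backpropagated through (with respect to the parameters).
        """
        g = ad.constant(v)
        for i in range(len(self.weights) - 1, -1, -1):
            g = ad.matmul(g, _t2(self.weights[i]))
            if i > 0:
                g = g * self._act_prime(cache[i - 1])
        return g

    def load_state(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            p.data = np.asarray(a, dtype=np.float64).copy()

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters]


def _t2(w: Tensor) -> Tensor:
    """Transpose of a 2-D parameter matrix (graph op)."""
    return ad.swap_last(w)
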