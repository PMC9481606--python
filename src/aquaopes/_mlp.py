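"""A small fully-connected network with manual backprop and Adam.

Sized for CV learning at desk scale (a few thousand parameters); training
is full-batch, single-threaded and seed-deterministic.
"""

from __future__ import annotations

import numpy as np

_ACTS = {
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "linear": (lambda z: z, lambda z: np.ones_like(z)),
}


class MLP:
    def __init__(self, layer_sizes, activation="tanh", seed=0,
                 linear_output=True):
        if activation not in _ACTS:
            raise ValueError(f"activation must be one of {sorted(_ACTS)}")
        self.layer_sizes = list(layer_sizes)
        self.activation = activation
        self.linear_output = linear_output
        rng = np.random.Generator(np.random.PCG64(seed))
        self.W, self.b = [], []
        for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            scale = np.sqrt(2.0 / (n_in + n_out))
            self.W.append(rng.normal(0.0, scale, size=(n_in, n_out)))
            self.b.append(np.zeros(n_out))
        self._adam_m = [np.zeros_like(p) for p in self.W + self.b]
        self._adam_v = [np.zeros_like(p) for p in self.W + self.b]
        self._adam_t = 0

    def forward(self, X, cache=False):
        act, _ = _ACTS[self.activation]
        a = X
        zs, activs = [], [a]
        n_layers = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            zs.append(z)
            last = i == n_layers - 1
            a = z if (last and self.linear_output) else act(z)
            activs.append(a)
        if cache:
            return a, (zs, activs)
        return a

    def backward(self, cache, dY):
        """Gradients of a scalar loss given dL/d(output); returns list
        matching self.W + self.b ordering."""
        _, dact = _ACTS[self.activation]
        zs, activs = cache
        n_layers = len(self.W)
        gW = [None] * n_layers
        gb = [None] * n_layers
        delta = dY
        for i in range(n_layers - 1, -1, -1):
            last = i == n_layers - 1
            if not (last and self.linear_output):
                delta = delta * dact(zs[i])
            gW[i] = activs[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
        return gW + gb

    def adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        params = self.W + self.b
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** self._adam_t)
            vhat = v / (1 - beta2 ** self._adam_t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def get_weights(self):
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def set_weights(self, W, b):
        self.W = [np.asarray(w, dtype=float).copy() for w in W]
        self.b = [np.asarray(x, dtype=float).copy() for x in b]
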