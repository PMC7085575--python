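"""Minimal convolutional network with Adam, in numpy.

Supports exactly the layer vocabulary the compact radiomic sequencer needs:
3x3 same-padded convolutions with ReLU, 2x2 max-pooling, a terminal global
average pool and a dense 2-way softmax head. Convolutions are evaluated as
nine shifted matrix products (no im2col copies); gradients are exact. All
randomness flows through a caller-supplied Generator, so training is
reproducible run-to-run for a fixed seed on one platform. Arithmetic is
float32 for speed; losses are accumulated in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ConvNet", "AdamState", "weighted_softmax_loss"]

DTYPE = np.float32


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class ConvNet:
    """Sequencer network: conv/maxpool stack -> GAP -> dense(2) -> softmax."""

    def __init__(self, layer_spec, rng: np.random.Generator, in_channels: int = 1):
        self.layer_spec = list(layer_spec)
        self.params: list[dict] = []
        c = in_channels
        for entry in self.layer_spec:
            if entry[0] == "conv":
                width = int(entry[1])
                self.params.append({
                    "W": _he_init(rng, (3, 3, c, width), 9 * c),
                    "b": np.zeros(width, dtype=DTYPE),
                })
                c = width
            elif entry[0] == "maxpool":
                self.params.append({})
            else:
                raise ValueError(f"unknown layer {entry!r}")
        self.head = {"W": _he_init(rng, (c, 2), c), "b": np.zeros(2, dtype=DTYPE)}
        self.out_channels = c

    # -- parameter plumbing -------------------------------------------------
    def parameters(self):
        out = []
        for p in self.params:
            out.extend(p.values())
        out.extend(self.head.values())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def get_state(self):
        return [p.copy() for p in self.parameters()]

    def set_state(self, state):
        for p, s in zip(self.parameters(), state):
            p[...] = s

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        """x: (N, H, W, C) -> logits (N, 2). Fills ``cache`` if given."""
        x = np.asarray(x, dtype=DTYPE)
        for spec, p in zip(self.layer_spec, self.params):
            if spec[0] == "conv":
                n, h, w, _ = x.shape
                xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
                z = np.broadcast_to(p["b"], (n, h, w, p["b"].size)).copy()
                for ki in range(3):
                    for kj in range(3):
                        z += xp[:, ki:ki + h, kj:kj + w, :] @ p["W"][ki, kj]
                relu_mask = z > 0
                if cache is not None:
                    cache.append(("conv", xp, relu_mask))
                x = z * relu_mask
            else:  # maxpool 2x2, stride 2 (inputs here have even H, W)
                n, h, w, c = x.shape
                xr = x.reshape(n, h // 2, 2, w // 2, 2, c) \
                      .transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
                idx = xr.argmax(axis=-1)
                out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
                if cache is not None:
                    cache.append(("maxpool", idx, x.shape))
                x = out
        feat = x.mean(axis=(1, 2))                     # global average pool
        logits = feat @ self.head["W"] + self.head["b"]
        if cache is not None:
            cache.append(("head", feat, x.shape))
        return logits

    def backward(self, dlogits: np.ndarray, cache: list) -> list[np.ndarray]:
        """Gradient of the loss w.r.t. every parameter (order of
        ``parameters()``)."""
        dlogits = np.asarray(dlogits, dtype=DTYPE)
        _, feat, feat_shape = cache[-1]
        grads_head_W = feat.T @ dlogits
        grads_head_b = dlogits.sum(axis=0)
        dfeat = dlogits @ self.head["W"].T
        n, h, w, c = feat_shape
        dx = np.broadcast_to(dfeat[:, None, None, :] / DTYPE(h * w),
                             feat_shape).astype(DTYPE)

        grads: list[np.ndarray] = []
        for spec, p, entry in zip(reversed(self.layer_spec),
                                  reversed(self.params), reversed(cache[:-1])):
            if spec[0] == "conv":
                _, xp, relu_mask = entry
                n, h, w, _ = relu_mask.shape
                dz = dx * relu_mask
                dW = np.empty_like(p["W"])
                dxp = np.zeros_like(xp)
                for ki in range(3):
                    for kj in range(3):
                        xs = xp[:, ki:ki + h, kj:kj + w, :]
                        dW[ki, kj] = np.tensordot(xs, dz, axes=([0, 1, 2],
                                                                [0, 1, 2]))
                        dxp[:, ki:ki + h, kj:kj + w, :] += dz @ p["W"][ki, kj].T
                grads.append(dz.sum(axis=(0, 1, 2)))     # db
                grads.append(dW)
                dx = dxp[:, 1:-1, 1:-1, :]
            else:
                _, idx, in_shape = entry
                n, h, w, c = in_shape
                dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=DTYPE)
                np.put_along_axis(dxr, idx[..., None], dx[..., None], axis=-1)
                dx = dxr.reshape(n, h // 2, w // 2, c, 2, 2) \
                        .transpose(0, 1, 4, 2, 5, 3).reshape(n, h, w, c)
        grads.reverse()   # now (W, b) per conv, input-to-output order
        grads.append(grads_head_W)
        grads.append(grads_head_b)
        return grads


def weighted_softmax_loss(logits: np.ndarray, labels: np.ndarray,
                          class_weights: tuple[float, float],
                          eps: float = 1e-12):
    """Class-weighted cross-entropy on a 2-way softmax head.

    Returns (loss, dlogits). Each sample's -log p(y) term is scaled by the
    weight of its class; the sum is divided by the batch size.
    """
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    w = np.where(labels == 1, class_weights[1], class_weights[0]).astype(float)
    py = np.clip(p[np.arange(n), labels], eps, 1.0)
    loss = float((w * -np.log(py)).sum() / n)
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits *= (w / n)[:, None]
    return loss, dlogits


class AdamState:
    """Adam optimizer state over a parameter list."""

    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            g = np.asarray(g, dtype=np.float64)
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
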