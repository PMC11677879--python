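"""Minimal NumPy convolutional-network engine.

Just enough machinery for the two small models this package trains: the
CFPNet-style HFUS layer segmenter and the desk-scale dermoscopy CNN
feature extractor.  Layers keep their forward caches and implement
explicit backward passes; parameters are updated with Adam.  Arrays are
``float32`` in ``(N, C, H, W)`` layout.  All randomness (init, batch
shuffling) flows from a single ``numpy`` Generator, so training is
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """A tensor with gradient and Adam state."""

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv2D(Layer):
    """Same-padded 2-D convolution (square kernel, optional dilation)."""

    def __init__(
        self,
        rng: np.random.Generator,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        dilation: int = 1,
    ):
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init
        self.w = Param(rng.normal(0.0, scale, size=(out_ch, in_ch, kernel, kernel)))
        self.b = Param(np.zeros(out_ch))
        self.kernel = kernel
        self.dilation = dilation
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _pad(self) -> int:
        return self.dilation * (self.kernel - 1) // 2

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, d, p = self.kernel, self.dilation, self._pad()
        if k == 1:
            patches = x.reshape(n, c, h * w)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
            shifts = [
                xp[:, :, ky * d : ky * d + h, kx * d : kx * d + w]
                for ky in range(k)
                for kx in range(k)
            ]
            # (N, C*k*k, H*W)
            patches = np.concatenate(shifts, axis=1).reshape(n, c * k * k, h * w)
        w2 = self.w.value.reshape(self.w.value.shape[0], -1)
        out = (w2[None] @ patches).reshape(n, -1, h, w)
        out += self.b.value[None, :, None, None]
        self._cache = (patches, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        patches, x_shape = self._cache
        n, c, h, w = x_shape
        k, d, p = self.kernel, self.dilation, self._pad()
        dflat = dout.reshape(n, -1, h * w)
        self.b.grad += dflat.sum(axis=(0, 2))
        w2 = self.w.value.reshape(self.w.value.shape[0], -1)
        self.w.grad += np.matmul(dflat, patches.transpose(0, 2, 1)).sum(
            axis=0
        ).reshape(self.w.value.shape)
        dpatches = np.matmul(w2.T[None], dflat)
        if k == 1:
            return dpatches.reshape(x_shape)
        dpatches = dpatches.reshape(n, k * k, c, h, w)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        idx = 0
        for ky in range(k):
            for kx in range(k):
                dxp[:, :, ky * d : ky * d + h, kx * d : kx * d + w] += dpatches[
                    :, idx
                ]
                idx += 1
        return dxp[:, :, p : p + h, p : p + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class AvgPool2(Layer):
    """2x2 average pooling (stride 2)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) * F32(0.25)


class Upsample2(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class CFPBlock(Layer):
    """Contextual feature pyramid block.

    Parallel same-size convolutions with different dilation rates see
    different perceptual fields; their outputs are concatenated and
    fused by a 1x1 convolution, mixing local and global context.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        in_ch: int,
        out_ch: int,
        dilations: tuple[int, ...] = (1, 2, 4),
    ):
        branch_ch = max(out_ch // 2, 4)
        self.branches = [
            Conv2D(rng, in_ch, branch_ch, kernel=3, dilation=d) for d in dilations
        ]
        self.branch_relus = [ReLU() for _ in dilations]
        self.fuse = Conv2D(rng, branch_ch * len(dilations), out_ch, kernel=1)
        self.fuse_relu = ReLU()
        self._branch_ch = branch_ch

    def params(self) -> list[Param]:
        out = []
        for br in self.branches:
            out.extend(br.params())
        out.extend(self.fuse.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        outs = [
            relu.forward(conv.forward(x))
            for conv, relu in zip(self.branches, self.branch_relus)
        ]
        return self.fuse_relu.forward(self.fuse.forward(np.concatenate(outs, axis=1)))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dcat = self.fuse.backward(self.fuse_relu.backward(dout))
        bc = self._branch_ch
        dx = None
        for i, (conv, relu) in enumerate(zip(self.branches, self.branch_relus)):
            d = conv.backward(relu.backward(dcat[:, i * bc : (i + 1) * bc]))
            dx = d if dx is None else dx + d
        return dx


class Dense(Layer):
    def __init__(self, rng: np.random.Generator, in_dim: int, out_dim: int):
        scale = np.sqrt(2.0 / in_dim)
        self.w = Param(rng.normal(0.0, scale, size=(in_dim, out_dim)))
        self.b = Param(np.zeros(out_dim))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad**2
            p.value -= self.lr * (p.m / corr1) / (np.sqrt(p.v / corr2) + self.eps)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def ce_dice_loss(
    logits: np.ndarray, target: np.ndarray, n_classes: int
) -> tuple[float, np.ndarray]:
    """Pixel-wise cross-entropy plus soft-Dice loss and its logit gradient.

    ``target`` holds integer class labels, shape (N, H, W).  The Dice
    term averages the per-class soft Dice over all classes, which keeps
    gradients alive for the thin foreground bands that pixel-frequency-
    weighted cross-entropy alone would neglect.
    """
    n, k, h, w = logits.shape
    p = softmax(logits, axis=1)
    onehot = np.eye(k, dtype=F32)[target].transpose(0, 3, 1, 2)
    npix = n * h * w

    p_true = np.clip((p * onehot).sum(axis=1), 1e-7, None)
    ce = float(-np.log(p_true).mean())
    dL_dp_ce = -onehot / np.clip(p, 1e-7, None) / npix

    eps = 1.0
    inter = (p * onehot).sum(axis=(0, 2, 3))
    denom = p.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3))
    dice_k = (2 * inter + eps) / (denom + eps)
    dice_loss = float(1 - dice_k.mean())
    # d(dice_k)/dp = (2*onehot*(denom+eps) - (2*inter+eps)) / (denom+eps)^2
    num = 2 * onehot * (denom + eps)[None, :, None, None] - (2 * inter + eps)[
        None, :, None, None
    ]
    dL_dp_dice = -num / ((denom + eps) ** 2)[None, :, None, None] / k

    dL_dp = dL_dp_ce + dL_dp_dice
    inner = (dL_dp * p).sum(axis=1, keepdims=True)
    dlogits = (p * (dL_dp - inner)).astype(F32)
    return ce + dice_loss, dlogits


def ce_loss_classifier(
    logits: np.ndarray, target: np.ndarray
) -> tuple[float, np.ndarray]:
    """Cross-entropy for an (N, K) classifier head."""
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    loss = float(-np.log(np.clip(p[np.arange(n), target], 1e-9, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), target] -= 1
    return loss, (dlogits / n).astype(F32)


def state_dict(layers: list[Layer]) -> list[np.ndarray]:
    return [p.value.copy() for layer in layers for p in layer.params()]


def load_state_dict(layers: list[Layer], state: list[np.ndarray]) -> None:
    params = [p for layer in layers for p in layer.params()]
    if len(params) != len(state):
        raise ValueError("checkpoint does not match model architecture")
    for p, v in zip(params, state):
        if p.value.shape != v.shape:
            raise ValueError(
                f"checkpoint shape {v.shape} != parameter shape {p.value.shape}"
            )
        p.value[...] = v.astype(F32)
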