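"""Compact CNN engine: a seeded 2D+time U-Net in pure numpy.

The segmentation network is deliberately small — a "vanilla" two-level
encoder/decoder with skip connections whose input stacks the time frames of
a space-time patch as channels and whose output is a per-pixel 3-class
softmax.  Forward and backward passes are written against BLAS-backed
im2col matrix products, with Adam as the optimiser and categorical
cross-entropy as the loss.  Everything is deterministic given the
construction seed, which is what makes pool training reproducible.

The engine is gradient-checked against central finite differences in the
test suite; it is not a general autodiff framework and only supports the
fixed topology below.
"""

from __future__ import annotations

import hashlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNet2DT", "build_unet"]


class _Conv:
    """Same-padded k x k convolution with bias (k in {1, 3})."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        self.k = k
        self.cin, self.cout = cin, cout
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in))
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        # Adam state
        self.mW = np.zeros_like(self.W); self.vW = np.zeros_like(self.W)
        self.mb = np.zeros_like(self.b); self.vb = np.zeros_like(self.b)
        self._cols = None
        self._shape = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if self.k == 1:
            return x.transpose(0, 2, 3, 1).reshape(n, h * w, c)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # n,c,h,w,3,3
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * 9)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        y = cols @ self.W.T + self.b
        if train:
            self._cols, self._shape = cols, (n, c, h, w)
        return y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(n, h * w, self.cout)
        flat = dyf.reshape(-1, self.cout)
        self.dW = flat.T @ self._cols.reshape(flat.shape[0], -1)
        self.db = flat.sum(axis=0)
        dcols = dyf @ self.W  # n, h*w, cin*k*k
        if self.k == 1:
            return dcols.reshape(n, h, w, c).transpose(0, 3, 1, 2)
        dcols = dcols.reshape(n, h, w, c, 3, 3)
        dxp = np.zeros((n, c, h + 2, w + 2))
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, 1 : 1 + h, 1 : 1 + w]

    def adam_step(self, lr: float, t: int, beta1=0.9, beta2=0.999, eps=1e-8):
        for p, g, m, v in (
            (self.W, self.dW, self.mW, self.vW),
            (self.b, self.db, self.mb, self.vb),
        ):
            m *= beta1; m += (1 - beta1) * g
            v *= beta2; v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


def _relu_fwd(x, cache, key, train):
    y = np.maximum(x, 0.0)
    if train:
        cache[key] = x > 0
    return y


def _pool_fwd(x, cache, key, train):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    if train:
        cache[key] = (idx, (n, c, h, w))
    return y


def _pool_bwd(dy, cache, key):
    idx, (n, c, h, w) = cache[key]
    dflat = np.zeros((n, c, h // 2, w // 2, 4))
    np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
    return (
        dflat.reshape(n, c, h // 2, w // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h, w)
    )


def _up_fwd(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _up_bwd(dy):
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet2DT:
    """Two-level U-Net over space-time patches (time frames as channels).

    Parameters
    ----------
    in_frames : int
        Number of time frames (input channels).
    n_classes : int
        Output classes (3: background / myocardium / bloodpool).
    width : int
        Base channel count; doubles per encoder level.
    seed : int
        Weight-initialisation seed; two nets built with the same seed have
        bit-identical initial parameters.
    """

    def __init__(self, in_frames: int, n_classes: int = 3, width: int = 8,
                 seed: int = 0):
        if in_frames < 1:
            raise ValueError("in_frames must be >= 1")
        if width < 1:
            raise ValueError("width must be >= 1")
        self.in_frames = in_frames
        self.n_classes = n_classes
        self.width = width
        self.seed = seed
        rng = np.random.default_rng(seed)
        w = width
        self.c1a = _Conv(in_frames, w, 3, rng)
        self.c1b = _Conv(w, w, 3, rng)
        self.c2a = _Conv(w, 2 * w, 3, rng)
        self.c2b = _Conv(2 * w, 2 * w, 3, rng)
        self.c3 = _Conv(2 * w, 4 * w, 3, rng)
        self.c4 = _Conv(6 * w, 2 * w, 3, rng)
        self.c5 = _Conv(3 * w, w, 3, rng)
        self.head = _Conv(w, n_classes, 1, rng)
        self._t = 0  # Adam step counter
        self._cache: dict = {}

    @property
    def layers(self) -> list[_Conv]:
        return [self.c1a, self.c1b, self.c2a, self.c2b, self.c3, self.c4,
                self.c5, self.head]

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    # -- forward ----------------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_frames:
            raise ValueError(f"expected {self.in_frames} channels, got {c}")
        if h % 4 or w % 4:
            raise ValueError(
                f"patch extent must be divisible by 4 (two pooling levels), "
                f"got {h}x{w}"
            )
        cc = self._cache
        e1 = _relu_fwd(self.c1b.forward(
            _relu_fwd(self.c1a.forward(x, train), cc, "r1a", train), train),
            cc, "r1b", train)
        p1 = _pool_fwd(e1, cc, "p1", train)
        e2 = _relu_fwd(self.c2b.forward(
            _relu_fwd(self.c2a.forward(p1, train), cc, "r2a", train), train),
            cc, "r2b", train)
        p2 = _pool_fwd(e2, cc, "p2", train)
        b = _relu_fwd(self.c3.forward(p2, train), cc, "r3", train)
        u1 = np.concatenate([_up_fwd(b), e2], axis=1)
        d1 = _relu_fwd(self.c4.forward(u1, train), cc, "r4", train)
        u2 = np.concatenate([_up_fwd(d1), e1], axis=1)
        d2 = _relu_fwd(self.c5.forward(u2, train), cc, "r5", train)
        return self.head.forward(d2, train)

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, shape (N, patch, patch, n_classes).

        ``x`` is (N, in_frames, patch, patch).
        """
        probs = self._softmax(self._forward(np.asarray(x, float), train=False))
        return probs.transpose(0, 2, 3, 1)

    # -- training ---------------------------------------------------------

    def loss_and_grads(self, x: np.ndarray, labels: np.ndarray) -> float:
        """Cross-entropy loss; fills each layer's dW/db.

        ``labels`` is (N, patch, patch) integer class codes.
        """
        x = np.asarray(x, float)
        logits = self._forward(x, train=True)
        probs = self._softmax(logits)
        n, k, h, w = logits.shape
        onehot = np.zeros_like(probs)
        ii, hh, ww = np.meshgrid(
            np.arange(n), np.arange(h), np.arange(w), indexing="ij"
        )
        onehot[ii, labels, hh, ww] = 1.0
        npix = n * h * w
        loss = float(-(onehot * np.log(probs + 1e-12)).sum() / npix)
        dlogits = (probs - onehot) / npix

        cc = self._cache
        d = self.head.backward(dlogits)
        d = self.c5.backward(d * cc["r5"])
        d_up2, d_e1 = d[:, : 2 * self.width], d[:, 2 * self.width :]
        d = self.c4.backward(_up_bwd(d_up2) * cc["r4"])
        d_up1, d_e2 = d[:, : 4 * self.width], d[:, 4 * self.width :]
        d = self.c3.backward(_up_bwd(d_up1) * cc["r3"])
        d = _pool_bwd(d, cc, "p2") + d_e2
        d = self.c2a.backward(self.c2b.backward(d * cc["r2b"]) * cc["r2a"])
        d = _pool_bwd(d, cc, "p1") + d_e1
        self.c1a.backward(self.c1b.backward(d * cc["r1b"]) * cc["r1a"])
        self._cache = {}
        return loss

    def train_step(self, x: np.ndarray, labels: np.ndarray,
                   lr: float = 1e-3) -> float:
        """One Adam update on a mini-batch; returns the batch loss."""
        loss = self.loss_and_grads(x, labels)
        self._t += 1
        for layer in self.layers:
            layer.adam_step(lr, self._t)
        return loss

    # -- weight plumbing ---------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for l in self.layers:
            out.extend([l.W.copy(), l.b.copy()])
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for l in self.layers:
            l.W[...] = next(it)
            l.b[...] = next(it)

    def snapshot(self) -> "UNet2DT":
        """Frozen copy sharing architecture but not parameters/optimiser."""
        clone = UNet2DT(self.in_frames, self.n_classes, self.width, self.seed)
        clone.set_weights(self.get_weights())
        return clone

    def weight_hash(self) -> str:
        h = hashlib.sha256()
        for arr in self.get_weights():
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:16]

    @property
    def architecture_fingerprint(self) -> str:
        return f"unet2dt-T{self.in_frames}-w{self.width}-c{self.n_classes}"


def build_unet(in_frames: int, n_classes: int = 3, width: int = 8,
               seed: int = 0) -> UNet2DT:
    """Seeded constructor for the 2D+time patch segmentation network."""
    return UNet2DT(in_frames, n_classes=n_classes, width=width, seed=seed)
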