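"""2D BiLSTM-CNN classifier, implemented in seeded pure numpy.

The reference layer plan (``ArchitectureSpec.paper()``) is a five-block
convolutional front end followed by a bidirectional LSTM and a dense head::

    input 224x224x3
    conv1 7x7x3  -> bilinear resample to 150x150x3
    conv2 7x7x512 -> 144x144x512 -> maxpool 4x4/2 -> 71x71x512 -> dropout
    conv3 7x7x256 -> 65x65x256   -> maxpool 4x4/2 -> 31x31x256 -> dropout
    conv4 7x7x128 -> 25x25x128   -> maxpool 4x4/2 -> 11x11x128
    conv5 5x5x64  -> 7x7x64      -> maxpool 4x4/2 -> 2x2x64
    reshape -> sequence 256x1 -> BiLSTM (64 per direction, concat -> 128)
    dropout -> dense 128 -> dense 2 (softmax over normal/abnormal)

The printed 224->150 spatial reduction of the first layer is not realisable
by a 7x7 stride-1 convolution alone, so conv1 is followed by a
deterministic bilinear resampling of its feature maps to 150x150; every
later size then follows from standard convolution arithmetic
(``conv_output_size``).  ``channel_scale`` shrinks the conv widths (the
3-channel stem excluded) while preserving all spatial sizes, which keeps
the architecture testable on a CPU.  An optional fused input concatenates
a z-normalised hand-crafted feature vector to the BiLSTM output before the
first dense layer.

Training uses Adam with categorical cross-entropy; every source of
randomness (weight init, batch shuffling, dropout) derives from one seed,
so identical (data, config, seed) gives bitwise-identical models.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numba
import numpy as np

from .io_formats import GrayImage, LabelledDataset, LABELS, NORMAL, ABNORMAL

__all__ = ["ArchitectureSpec", "TrainConfig", "ConvBlock", "BiLstmCnn",
           "conv_output_size", "images_to_array"]

F32 = np.float32


def conv_output_size(F: int, W: int, pad: int = 0, stride: int = 1) -> int:
    """Spatial output size of a convolution/pooling: floor((F-W+2p)/s)+1."""
    if F < W:
        raise ValueError(f"input size {F} smaller than kernel {W}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    out = (F - W + 2 * pad) // stride + 1
    if out <= 0:
        raise ValueError(f"non-positive output size for F={F}, W={W}, "
                         f"pad={pad}, stride={stride}")
    return out


@dataclass(frozen=True)
class ConvBlock:
    kernel: int
    out_channels: int
    stride: int = 1
    pool_kernel: int = 4
    pool_stride: int = 2
    dropout: float = 0.0


@dataclass(frozen=True)
class ArchitectureSpec:
    input_size: int = 224
    stem_kernel: int = 7
    stem_channels: int = 3            # tied to the RGB-replicated input
    stem_resample: int = 150
    conv_blocks: tuple[ConvBlock, ...] = (
        ConvBlock(7, 512, dropout=0.25),
        ConvBlock(7, 256, dropout=0.25),
        ConvBlock(7, 128),
        ConvBlock(5, 64),
    )
    bilstm_hidden_total: int = 128
    dense_units: int = 128
    n_classes: int = 2
    fusion_dim: int = 0
    channel_scale: float = 1.0
    head_dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.n_classes != 2:
            raise ValueError("this classifier is two-class")
        if self.bilstm_hidden_total % 2:
            raise ValueError("bilstm_hidden_total must be even")
        if any(max(1, round(b.out_channels * self.channel_scale)) < 1
               for b in self.conv_blocks):
            raise ValueError("channel_scale collapses a block below 1 channel")

    def scaled_channels(self, block: ConvBlock) -> int:
        return max(1, int(round(block.out_channels * self.channel_scale)))

    @classmethod
    def paper(cls, **overrides) -> "ArchitectureSpec":
        """The published layer plan at full width."""
        return cls(**overrides)

    @classmethod
    def test_scale(cls, **overrides) -> "ArchitectureSpec":
        """Same spatial plan at 1/8 of the conv widths (CPU-friendly)."""
        overrides.setdefault("channel_scale", 0.125)
        return cls(**overrides)

    def with_fusion(self, fusion_dim: int) -> "ArchitectureSpec":
        return replace(self, fusion_dim=fusion_dim)


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0
    loss: str = "categorical_cross_entropy"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


# ---------------------------------------------------------------------------
# layers (forward caches what backward needs; parameters exposed for Adam)
# ---------------------------------------------------------------------------

class _Layer:
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []


@numba.njit(cache=True, fastmath=True)
def _im2col_fill(x, k, cols):  # pragma: no cover - exercised via _Conv
    n, h, w, c = x.shape
    ho, wo = h - k + 1, w - k + 1
    for ni in range(n):
        for i in range(ho):
            for j in range(wo):
                for di in range(k):
                    for dj in range(k):
                        for ci in range(c):
                            cols[ni, i, j, di, dj, ci] = x[ni, i + di, j + dj, ci]


@numba.njit(cache=True, fastmath=True)
def _col2im_add(dcols, k, dx):  # pragma: no cover - exercised via _Conv
    n, ho, wo = dcols.shape[0], dcols.shape[1], dcols.shape[2]
    c = dcols.shape[5]
    for ni in range(n):
        for i in range(ho):
            for j in range(wo):
                for di in range(k):
                    for dj in range(k):
                        for ci in range(c):
                            dx[ni, i + di, j + dj, ci] += dcols[ni, i, j, di, dj, ci]


class _Conv(_Layer):
    """Valid (no-pad) convolution via im2col + one sgemm.

    ``needs_dx=False`` (first layer) skips the input-gradient pass.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 needs_dx: bool = True):
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = (rng.standard_normal((k, k, cin, cout)) * std).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.k = k
        self.needs_dx = needs_dx
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        # persistent scratch (im2col patches, their gradient, input gradient)
        # so the large buffers are not re-allocated every step
        self._cols = None
        self._dcols = None
        self._dx = None

    def _scratch(self, name: str, shape: tuple) -> np.ndarray:
        buf = getattr(self, name)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype=F32)
            setattr(self, name, buf)
        return buf

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        k = self.k
        n, h, w, cin = x.shape
        cout = self.b.shape[0]
        ho, wo = h - k + 1, w - k + 1
        cols = self._scratch("_cols", (n, ho, wo, k, k, cin))
        _im2col_fill(np.ascontiguousarray(x, dtype=F32), k, cols)
        cols2d = cols.reshape(n * ho * wo, k * k * cin)
        y = cols2d @ self.W.reshape(k * k * cin, cout) + self.b
        if train:
            self._x_shape = x.shape
        return y.reshape(n, ho, wo, cout)

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        k = self.k
        n, h, w, cin = self._x_shape
        ho, wo = dy.shape[1], dy.shape[2]
        cout = dy.shape[-1]
        dyf = np.ascontiguousarray(dy).reshape(-1, cout)
        cols2d = self._cols.reshape(n * ho * wo, k * k * cin)
        self.grads[1][...] = dyf.sum(axis=0)
        self.grads[0][...] = (cols2d.T @ dyf).reshape(self.W.shape)
        if not self.needs_dx:
            return None
        dcols = self._scratch("_dcols", (n, ho, wo, k, k, cin))
        np.matmul(dyf, self.W.reshape(k * k * cin, cout).T,
                  out=dcols.reshape(n * ho * wo, k * k * cin))
        dx = self._scratch("_dx", self._x_shape)
        dx[...] = 0
        _col2im_add(dcols, k, dx)
        return dx


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (half-pixel centres)."""
    A = np.zeros((n_out, n_in), dtype=F32)
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    A[np.arange(n_out), lo] += (1 - frac).astype(F32)
    A[np.arange(n_out), hi] += frac.astype(F32)
    return A


class _Resample(_Layer):
    """Deterministic bilinear resampling of feature maps (differentiable)."""

    def __init__(self, size_in: int, size_out: int):
        self.Ar = _bilinear_matrix(size_out, size_in)
        self.Ac = self.Ar if size_in == size_out else _bilinear_matrix(size_out, size_in)

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = np.tensordot(self.Ar, x, axes=([1], [1]))        # (Ho, N, W, C)
        y = np.tensordot(self.Ac, y, axes=([1], [2]))        # (Wo, Ho, N, C)
        return np.ascontiguousarray(np.transpose(y, (2, 1, 0, 3)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = np.tensordot(self.Ar.T, dy, axes=([1], [1]))     # (Hin, N, Wo, C)
        d = np.tensordot(self.Ac.T, d, axes=([1], [2]))      # (Win, Hin, N, C)
        return np.ascontiguousarray(np.transpose(d, (2, 1, 0, 3)))


class _ReLU(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _MaxPool(_Layer):
    """Overlapping max pooling.

    The 4x4/stride-2 pool of the reference plan decomposes exactly into a
    2x2/stride-2 max followed by a 2x2/stride-1 max, which avoids
    materialising the window tensor. The gradient routes ``dy`` through the
    stage-wise argmax comparisons; equal-valued winners within a window
    share the gradient, which coincides with the usual single-winner
    routing almost surely for continuous activations.
    """

    def __init__(self, k: int, stride: int):
        self.k, self.s = k, stride
        if (k, stride) != (4, 2):
            raise NotImplementedError("only the 4x4/2 pooling of the "
                                      "reference plan is supported")

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h, w = x.shape[1], x.shape[2]
        ho = conv_output_size(h, 4, 0, 2)
        wo = conv_output_size(w, 4, 0, 2)
        # stage 1: disjoint 2x2/2 max (one extra row/col for the overlap)
        xr0 = x[:, 0:2 * ho + 2:2]
        xr1 = x[:, 1:2 * ho + 2:2]
        pr = np.maximum(xr0, xr1)                  # (N, Ho+1, W, C)
        p = np.maximum(pr[:, :, 0:2 * wo + 2:2], pr[:, :, 1:2 * wo + 2:2])
        # stage 2: overlapping 2x2/1 max on the coarse grid
        q = np.maximum(
            np.maximum(p[:, :-1, :-1], p[:, 1:, :-1]),
            np.maximum(p[:, :-1, 1:], p[:, 1:, 1:]))
        if train:
            self._x_shape = x.shape
            self._x = x
            self._p = p
        return q

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, p = self._x, self._p
        ho, wo = dy.shape[1], dy.shape[2]
        y = np.maximum(
            np.maximum(p[:, :-1, :-1], p[:, 1:, :-1]),
            np.maximum(p[:, :-1, 1:], p[:, 1:, 1:]))
        dp = np.zeros_like(p)
        for di in (0, 1):
            for dj in (0, 1):
                ps = p[:, di:di + ho, dj:dj + wo]
                dp[:, di:di + ho, dj:dj + wo] += dy * (ps == y)
        dx = np.zeros(self._x_shape, dtype=dy.dtype)
        php, pwp = p.shape[1], p.shape[2]
        for di in (0, 1):
            for dj in (0, 1):
                xs = x[:, di:2 * php + di:2, dj:2 * pwp + dj:2]
                dx[:, di:2 * php + di:2, dj:2 * pwp + dj:2] += dp * (xs == p)
        self._x = self._p = None
        return dx


class _Dropout(_Layer):
    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x: np.ndarray, train: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class _Dense(_Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / nin)
        self.W = (rng.standard_normal((nin, nout)) * std).astype(F32)
        self.b = np.zeros(nout, dtype=F32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class _LSTM(_Layer):
    """Unidirectional LSTM returning the final hidden state."""

    def __init__(self, din: int, hidden: int, rng: np.random.Generator):
        lim = np.sqrt(6.0 / (din + hidden + 4 * hidden))
        self.Wx = rng.uniform(-lim, lim, (din, 4 * hidden)).astype(F32)
        self.Wh = rng.uniform(-lim, lim, (hidden, 4 * hidden)).astype(F32)
        self.b = np.zeros(4 * hidden, dtype=F32)
        self.b[hidden:2 * hidden] = 1.0      # forget-gate bias
        self.H = hidden
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, T, _ = x.shape
        H = self.H
        h = np.zeros((n, H), dtype=F32)
        c = np.zeros((n, H), dtype=F32)
        self._cache = []
        self._x = x
        for t in range(T):
            z = x[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            self._cache.append((h, c, i, f, g, o, tc))
            h = o * tc
            c = c_new
        return h

    def backward(self, dh_last: np.ndarray) -> np.ndarray:
        x = self._x
        n, T, _ = x.shape
        H = self.H
        for gr in self.grads:
            gr[...] = 0
        dx = np.zeros_like(x)
        dh = dh_last.astype(F32)
        dc = np.zeros_like(dh)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            do = dh * tc
            dct = dc + dh * o * (1 - tc * tc)
            di = dct * g
            df = dct * c_prev
            dg = dct * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g * g), do * o * (1 - o)], axis=1)
            self.grads[0] += x[:, t, :].T @ dz
            self.grads[1] += h_prev.T @ dz
            self.grads[2] += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dct * f
        self._cache = None
        self._x = None
        return dx


class _BiLSTM(_Layer):
    def __init__(self, din: int, hidden_total: int, rng: np.random.Generator):
        h = hidden_total // 2
        self.fwd = _LSTM(din, h, rng)
        self.bwd = _LSTM(din, h, rng)
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads

    def forward(self, x: np.ndarray) -> np.ndarray:
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1, :])
        return np.concatenate([hf, hb], axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h = dy.shape[1] // 2
        dxf = self.fwd.backward(dy[:, :h])
        dxb = self.bwd.backward(dy[:, h:])
        return dxf + dxb[:, ::-1, :]


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

def images_to_array(images: list[GrayImage], size: int) -> np.ndarray:
    """Stack grayscale images into an (N, size, size, 3) float array in
    [0, 1], replicating the gray channel to 3 channels."""
    from .preprocess import resize_image

    out = np.empty((len(images), size, size, 3), dtype=F32)
    for k, img in enumerate(images):
        if (img.height, img.width) != (size, size):
            img = resize_image(img, (size, size))
        g = (img.pixels / img.max_value).astype(F32)
        out[k] = g[:, :, None]
    return out


class BiLstmCnn:
    """The classifier: build with a spec, ``train`` to fit, ``predict`` to
    score. ``label_order`` is (normal, abnormal); ties at prediction break
    toward 'abnormal' as the clinically safer default."""

    label_order = LABELS

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        self.fitted = False
        self.feature_mean: np.ndarray | None = None
        self.feature_sd: np.ndarray | None = None
        self.history: list[float] = []
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        s = spec
        self._shape_plan: list[tuple[str, tuple]] = []
        size = conv_output_size(s.input_size, s.stem_kernel)
        self.stem = _Conv(3, s.stem_channels, s.stem_kernel, rng,
                          needs_dx=False)
        self.stem_relu = _ReLU()
        self.resample = _Resample(size, s.stem_resample)
        self._shape_plan.append(
            ("conv1+resample", (s.stem_resample, s.stem_resample, s.stem_channels)))
        size = s.stem_resample
        cin = s.stem_channels
        self.blocks = []
        for bi, blk in enumerate(s.conv_blocks, start=2):
            cout = s.scaled_channels(blk)
            conv = _Conv(cin, cout, blk.kernel, rng)
            size = conv_output_size(size, blk.kernel, 0, blk.stride)
            self._shape_plan.append((f"conv{bi}", (size, size, cout)))
            pool = _MaxPool(blk.pool_kernel, blk.pool_stride)
            size = conv_output_size(size, blk.pool_kernel, 0, blk.pool_stride)
            self._shape_plan.append((f"pool{bi - 1}", (size, size, cout)))
            drop = _Dropout(blk.dropout) if blk.dropout > 0 else None
            if drop is not None:
                self._shape_plan.append((f"dropout{bi - 1}", (size, size, cout)))
            self.blocks.append((conv, _ReLU(), pool, drop))
            cin = cout
        self.seq_len = size * size * cin
        self._shape_plan.append(("reshape", (self.seq_len, 1)))
        self.bilstm = _BiLSTM(1, s.bilstm_hidden_total, rng)
        self._shape_plan.append(("bilstm", (s.bilstm_hidden_total,)))
        self.head_drop = _Dropout(s.head_dropout)
        self._shape_plan.append(("dropout_head", (s.bilstm_hidden_total,)))
        dense_in = s.bilstm_hidden_total + s.fusion_dim
        if s.fusion_dim:
            self._shape_plan.append(("concat_features", (dense_in,)))
        self.dense1 = _Dense(dense_in, s.dense_units, rng)
        self.dense1_relu = _ReLU()
        self._shape_plan.append(("dense1", (s.dense_units,)))
        self.dense2 = _Dense(s.dense_units, s.n_classes, rng)
        self._shape_plan.append(("dense2_softmax", (s.n_classes,)))

        self._layers_with_params: list[_Layer] = [self.stem]
        for conv, *_ in self.blocks:
            self._layers_with_params.append(conv)
        self._layers_with_params += [self.bilstm, self.dense1, self.dense2]
        self._adam_state = None

    # -- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray, feats: np.ndarray | None,
                 train: bool = False,
                 rng: np.random.Generator | None = None) -> np.ndarray:
        if self.spec.fusion_dim and feats is None:
            raise ValueError("spec has fusion_dim > 0 but no features given")
        h = self.stem_relu.forward(self.stem.forward(x, train))
        h = self.resample.forward(h)
        for conv, relu, pool, drop in self.blocks:
            h = pool.forward(relu.forward(conv.forward(h, train)), train)
            if drop is not None:
                h = drop.forward(h, train, rng)
        n = h.shape[0]
        self._pre_seq_shape = h.shape
        h = h.reshape(n, self.seq_len, 1)
        h = self.bilstm.forward(h)
        h = self.head_drop.forward(h, train, rng)
        if self.spec.fusion_dim:
            h = np.concatenate([h, feats.astype(F32)], axis=1)
        h = self.dense1_relu.forward(self.dense1.forward(h))
        return self.dense2.forward(h)

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self.dense2.backward(dlogits)
        d = self.dense1.backward(self.dense1_relu.backward(d))
        if self.spec.fusion_dim:
            d = d[:, :self.spec.bilstm_hidden_total]
        d = self.head_drop.backward(d)
        d = self.bilstm.backward(d)
        d = d.reshape(self._pre_seq_shape)
        for conv, relu, pool, drop in reversed(self.blocks):
            if drop is not None:
                d = drop.backward(d)
            d = conv.backward(relu.backward(pool.backward(d)))
        d = self.resample.backward(d)
        self.stem.backward(self.stem_relu.backward(d))

    # -- introspection ------------------------------------------------------

    def introspect_shapes(self, dry_run: bool = True) -> list[tuple[str, tuple]]:
        """Layer plan as (name, output shape) pairs; with ``dry_run`` the
        shapes are confirmed by a forward pass on one zero input."""
        if dry_run:
            x = np.zeros((1, self.spec.input_size, self.spec.input_size, 3),
                         dtype=F32)
            feats = (np.zeros((1, self.spec.fusion_dim), dtype=F32)
                     if self.spec.fusion_dim else None)
            logits = self._forward(x, feats, train=False)
            assert logits.shape == (1, self.spec.n_classes)
        return list(self._shape_plan)

    # -- optimisation -------------------------------------------------------

    def _adam_step(self, lr: float) -> None:
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": [np.zeros_like(p) for layer in self._layers_with_params
                      for p in layer.params],
                "v": [np.zeros_like(p) for layer in self._layers_with_params
                      for p in layer.params],
            }
        st = self._adam_state
        st["t"] += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = st["t"]
        k = 0
        for layer in self._layers_with_params:
            for p, g in zip(layer.params, layer.grads):
                st["m"][k] = b1 * st["m"][k] + (1 - b1) * g
                st["v"][k] = b2 * st["v"][k] + (1 - b2) * g * g
                mhat = st["m"][k] / (1 - b1 ** t)
                vhat = st["v"][k] / (1 - b2 ** t)
                p -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(p.dtype)
                k += 1

    # -- public API ---------------------------------------------------------

    def _prepare_features(self, feats: np.ndarray | None,
                          fit: bool) -> np.ndarray | None:
        if feats is None:
            return None
        feats = np.asarray(feats, dtype=np.float64)
        if fit:
            self.feature_mean = feats.mean(axis=0)
            sd = feats.std(axis=0)
            self.feature_sd = np.where(sd > 0, sd, 1.0)
        if self.feature_mean is None:
            raise RuntimeError("feature normaliser not fitted")
        return ((feats - self.feature_mean) / self.feature_sd).astype(F32)

    def train(self, data: LabelledDataset | np.ndarray,
              features: np.ndarray | None = None,
              cfg: TrainConfig | None = None,
              labels: list[str] | None = None) -> "BiLstmCnn":
        """Fit with Adam / categorical cross-entropy; deterministic in
        ``cfg.seed``. ``data`` may be a LabelledDataset or a pre-stacked
        (N, H, W, 3) array with ``labels`` supplied separately."""
        cfg = cfg or TrainConfig()
        if isinstance(data, LabelledDataset):
            x = images_to_array(data.images, self.spec.input_size)
            labels = data.labels
        else:
            x = np.asarray(data, dtype=F32)
            if labels is None:
                raise ValueError("labels required with array input")
        y = np.array([self.label_order.index(l) for l in labels])
        if len(set(y.tolist())) < 2:
            raise ValueError("training set contains a single class")
        if features is not None and len(features) != len(x):
            raise ValueError("features not row-aligned with images")
        feats = self._prepare_features(features, fit=True)
        onehot = np.eye(self.spec.n_classes, dtype=F32)[y]

        ss = np.random.SeedSequence([cfg.seed, 1])
        shuffle_rng, drop_rng = (np.random.default_rng(c) for c in ss.spawn(2))
        n = len(x)
        self.history = []
        for _epoch in range(cfg.epochs):
            order = shuffle_rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb = x[idx]
                fb = feats[idx] if feats is not None else None
                yb = onehot[idx]
                logits = self._forward(xb, fb, train=True, rng=drop_rng)
                shifted = logits - logits.max(axis=1, keepdims=True)
                expz = np.exp(shifted)
                probs = expz / expz.sum(axis=1, keepdims=True)
                loss = float(-np.mean(
                    np.sum(yb * np.log(np.maximum(probs, 1e-12)), axis=1)))
                if not np.isfinite(loss):
                    raise FloatingPointError("non-finite training loss")
                epoch_loss += loss * len(idx)
                self._backward((probs - yb) / len(idx))
                self._adam_step(cfg.learning_rate)
            self.history.append(epoch_loss / n)
        self.fitted = True
        return self

    def predict_proba(self, data: LabelledDataset | list[GrayImage] | np.ndarray,
                      features: np.ndarray | None = None,
                      batch_size: int = 8) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("model is not trained")
        if isinstance(data, LabelledDataset):
            x = images_to_array(data.images, self.spec.input_size)
        elif isinstance(data, list):
            x = images_to_array(data, self.spec.input_size)
        else:
            x = np.asarray(data, dtype=F32)
        feats = self._prepare_features(features, fit=False) \
            if features is not None else None
        out = []
        for start in range(0, len(x), batch_size):
            xb = x[start:start + batch_size]
            fb = feats[start:start + batch_size] if feats is not None else None
            logits = self._forward(xb, fb, train=False)
            shifted = logits - logits.max(axis=1, keepdims=True)
            expz = np.exp(shifted)
            out.append(expz / expz.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0).astype(np.float64)

    def predict(self, data, features: np.ndarray | None = None
                ) -> tuple[np.ndarray, list[str]]:
        probs = self.predict_proba(data, features)
        # tie toward 'abnormal' (index 1)
        labels = [ABNORMAL if p[1] >= p[0] else NORMAL for p in probs]
        return probs, labels
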