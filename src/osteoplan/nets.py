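"""Convolutional models for leg separation, landmark localization and
2D-3D reconstruction, with their losses, built on a compact NumPy
reverse-mode engine.

Three networks cooperate:

* a **separation network** (one 2D encoder, two decoders) that turns the
  two-leg sagittal radiograph into per-leg sagittal images, trained with
  ``0.5 * (MSE + (1 - gradient_correlation))``;
* a **landmark network** (2D U-net) regressing per-landmark Gaussian
  heatmaps with binary cross-entropy;
* a **reconstruction network** that processes the frontal and sagittal crops
  in two separate 2D branches for two levels, replicates the resulting
  S/4 x S/4 feature maps S/4 times along the third dimension, averages the
  two volumes voxel-wise into one fused 3D feature map, and continues with a
  3D encoder/decoder (skip connections on the fused-3D levels only) to a
  two-class softmax volume, trained with Dice + cross-entropy.

Convolutions use kernel 3, 'same' zero padding, stride 1; pooling is 2x max
pooling; weights are He-normal; optimization is Adam.  All randomness flows
through explicit seeds so training is reproducible run-to-run.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import drr as _drr

EPS_CLIP = 1e-7

# ===========================================================================
# Losses (value + gradient w.r.t. the prediction, plain NumPy)
# ===========================================================================


def _cdiff(x: np.ndarray, axis: int) -> np.ndarray:
    """Central-difference image gradient (one-sided at the edges)."""
    return np.gradient(x, axis=axis)


def _cdiff_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint of ``_cdiff`` (needed to backpropagate through it)."""
    g = np.moveaxis(g, axis, 0)
    out = np.zeros_like(g)
    n = g.shape[0]
    if n == 1:
        return np.moveaxis(out, 0, axis)
    out[0] -= g[0]
    out[1] += g[0]
    out[n - 2] -= g[n - 1]
    out[n - 1] += g[n - 1]
    if n > 2:
        out[2:] += 0.5 * g[1:-1]
        out[:-2] -= 0.5 * g[1:-1]
    return np.moveaxis(out, 0, axis)


def _ncc_value_grad(a: np.ndarray, b: np.ndarray):
    """Normalized cross-correlation of two images and d(NCC)/d(b)."""
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.sqrt((ac * ac).sum())
    nb = np.sqrt((bc * bc).sum())
    if na == 0.0 or nb == 0.0:
        return None, None  # caller applies the zero-variance guard
    ncc = float((ac * bc).sum() / (na * nb))
    g = ac / (na * nb) - ncc * bc / (nb * nb)
    g -= g.mean()
    return ncc, g


def gradient_correlation(y: np.ndarray, y_hat: np.ndarray,
                         return_grad: bool = False):
    """Gradient correlation of two images, in [-1, 1].

    Mean of the NCCs of the horizontal and vertical central-difference
    gradient images.  Constant inputs have zero-variance gradients; the
    correlation is then defined as 0 (with a warning).  Symmetric in its
    arguments; optionally also returns d(GC)/d(y_hat).
    """
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.shape != y_hat.shape:
        raise ValueError("shape mismatch")
    total = 0.0
    grad = np.zeros_like(y_hat)
    degenerate = False
    for axis in (1, 0):  # horizontal (lambda) then vertical (kappa) gradients
        ax = y.ndim - 2 + axis if y.ndim > 2 else axis
        ncc, g = _ncc_value_grad(_cdiff(y, ax), _cdiff(y_hat, ax))
        if ncc is None:
            degenerate = True
            continue
        total += 0.5 * ncc
        if return_grad:
            grad += 0.5 * _cdiff_adjoint(g, ax)
    if degenerate:
        warnings.warn("zero-variance gradient image; gradient correlation "
                      "term defined as 0")
    if return_grad:
        return total, grad
    return total


def separation_loss(y: np.ndarray, y_hat: np.ndarray,
                    return_grad: bool = False):
    """``0.5 * (MSE + (1 - gradient_correlation))``; 0 iff prediction == target.

    The correlation enters as a dissimilarity ``1 - GC`` so that minimizing
    the loss sharpens (rather than destroys) the leg outlines.
    """
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    diff = y_hat - y
    mse = float((diff * diff).mean())
    if return_grad:
        gc, ggrad = gradient_correlation(y, y_hat, return_grad=True)
        val = 0.5 * (mse + (1.0 - gc))
        grad = 0.5 * (2.0 * diff / diff.size - ggrad)
        return val, grad
    gc = gradient_correlation(y, y_hat)
    return 0.5 * (mse + (1.0 - gc))


def bce_loss(y: np.ndarray, y_hat: np.ndarray, return_grad: bool = False):
    """Mean binary cross-entropy with probability clipping at 1e-7."""
    y = np.asarray(y, float)
    p = np.clip(np.asarray(y_hat, float), EPS_CLIP, 1.0 - EPS_CLIP)
    val = float(-(y * np.log(p) + (1.0 - y) * np.log1p(-p)).mean())
    if not return_grad:
        return val
    inside = (y_hat > EPS_CLIP) & (y_hat < 1.0 - EPS_CLIP)
    grad = np.where(inside, (p - y) / (p * (1.0 - p)), 0.0) / y.size
    return val, grad


def dice_ce_loss(y: np.ndarray, y_hat: np.ndarray, return_grad: bool = False):
    """Dice loss over foreground classes plus cross-entropy.

    ``y`` is one-hot ``(C, ...)`` (class 0 = background), ``y_hat`` a softmax
    field summing to 1 over the class axis.  The Dice term is
    ``sum_{c>=1} (1 - 2*sum(y*yh) / (sum(y) + sum(yh)))``; the cross-entropy
    term is the voxel-mean of ``-sum_c y log yh``.
    """
    y = np.asarray(y, float)
    p = np.asarray(y_hat, float)
    if y.shape != p.shape:
        raise ValueError("shape mismatch")
    sums = p.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-5):
        raise ValueError("y_hat must sum to 1 over the class axis")
    nvox = float(y[0].size)
    pc = np.clip(p, EPS_CLIP, 1.0 - EPS_CLIP)
    ce = float(-(y * np.log(pc)).sum() / nvox)
    val = ce
    grad = np.zeros_like(p) if return_grad else None
    if return_grad:
        inside = (p > EPS_CLIP) & (p < 1.0 - EPS_CLIP)
        grad += np.where(inside, -y / pc, 0.0) / nvox
    for c in range(1, y.shape[0]):
        inter = float((y[c] * p[c]).sum())
        denom = float(y[c].sum() + p[c].sum())
        if denom == 0.0:
            continue
        val += 1.0 - 2.0 * inter / denom
        if return_grad:
            grad[c] += -2.0 * (y[c] * denom - inter) / (denom * denom)
    if return_grad:
        return val, grad
    return val


# ===========================================================================
# Minimal reverse-mode engine
# ===========================================================================


class Var:
    """A node in the computation tape: array data + gradient accumulator."""

    __slots__ = ("data", "grad", "parents", "bw", "is_param", "name")

    def __init__(self, data, parents=(), bw=None, is_param=False, name=""):
        self.data = np.asarray(data, np.float32)
        self.grad = None
        self.parents = parents
        self.bw = bw
        self.is_param = is_param
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, np.float32).copy()
        else:
            self.grad += g

    def backward(self, seed):
        order, seen = [], set()

        def visit(v):
            if id(v) in seen:
                return
            seen.add(id(v))
            for p in v.parents:
                visit(p)
            order.append(v)

        visit(self)
        self.accumulate(seed)
        for v in reversed(order):
            if v.bw is not None and v.grad is not None:
                v.bw(v.grad)


def _he_normal(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def conv(x: Var, w: Var, b: Var) -> Var:
    """N-dimensional convolution, kernel 3, stride 1, 'same' zero padding."""
    k = w.data.shape[2:]
    nd = len(k)
    spatial = x.data.shape[2:]
    pads = [(0, 0), (0, 0)] + [(ki // 2, ki // 2) for ki in k]
    xp = np.pad(x.data, pads)
    win = sliding_window_view(xp, k, axis=tuple(range(2, 2 + nd)))
    # (N, C, *S, *k) -> (N, P, C*K)
    n = x.data.shape[0]
    perm = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
    mat = np.ascontiguousarray(np.transpose(win, perm)).reshape(
        n, int(np.prod(spatial)), -1)
    o = w.data.shape[0]
    w2 = w.data.reshape(o, -1)
    y = mat @ w2.T + b.data
    y = np.moveaxis(y.reshape((n,) + spatial + (o,)), -1, 1)

    def bw(dy):
        dmat = np.moveaxis(dy, 1, -1).reshape(n, -1, o)
        dw = np.einsum("npo,npk->ok", dmat, mat, optimize=True).reshape(w.data.shape)
        w.accumulate(dw)
        b.accumulate(dmat.sum(axis=(0, 1)))
        # dX = same conv of dY with channel-transposed, spatially flipped W
        wf = w.data
        for ax in range(2, 2 + nd):
            wf = np.flip(wf, axis=ax)
        wf = np.swapaxes(wf, 0, 1)  # (C, O, *k)
        dyp = np.pad(dy, pads)
        winb = sliding_window_view(dyp, k, axis=tuple(range(2, 2 + nd)))
        matb = np.ascontiguousarray(np.transpose(winb, perm)).reshape(
            n, int(np.prod(spatial)), -1)
        dx = matb @ wf.reshape(w.data.shape[1], -1).T
        x.accumulate(np.moveaxis(dx.reshape((n,) + spatial + (-1,)), -1, 1))

    return Var(y, (x, w, b), bw)


def relu(x: Var) -> Var:
    y = np.maximum(x.data, 0.0)

    def bw(dy):
        x.accumulate(dy * (x.data > 0))

    return Var(y, (x,), bw)


def sigmoid(x: Var) -> Var:
    z = x.data
    y = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                 np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))

    def bw(dy):
        x.accumulate(dy * y * (1.0 - y))

    return Var(y, (x,), bw)


def softmax_channels(x: Var) -> Var:
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=1, keepdims=True)

    def bw(dy):
        dot = (dy * y).sum(axis=1, keepdims=True)
        x.accumulate(y * (dy - dot))

    return Var(y, (x,), bw)


def maxpool(x: Var, nd: int) -> Var:
    """2x max pooling over the trailing ``nd`` spatial axes."""
    shp = x.data.shape
    spatial = shp[2:]
    if any(s % 2 for s in spatial):
        raise ValueError("spatial sizes must be divisible by the pool size 2")
    new = []
    for s in spatial:
        new += [s // 2, 2]
    r = x.data.reshape(shp[:2] + tuple(new))
    # move the block axes (odd positions among spatial) to the end
    block_axes = tuple(2 + 2 * i + 1 for i in range(nd))
    keep_axes = tuple(2 + 2 * i for i in range(nd))
    perm = (0, 1) + keep_axes + block_axes
    r = np.transpose(r, perm).reshape(
        shp[:2] + tuple(s // 2 for s in spatial) + (2 ** nd,))
    idx = r.argmax(axis=-1)
    y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def bw(dy):
        dr = np.zeros(shp[:2] + tuple(s // 2 for s in spatial) + (2 ** nd,),
                      np.float32)
        np.put_along_axis(dr, idx[..., None], dy[..., None], axis=-1)
        inv = np.argsort(perm)
        dr = dr.reshape(shp[:2] + tuple(s // 2 for s in spatial)
                        + (2,) * nd)
        dr = np.transpose(dr, inv)
        x.accumulate(dr.reshape(shp))

    return Var(y, (x,), bw)


def upsample(x: Var, nd: int) -> Var:
    """Nearest-neighbour 2x upsampling over the trailing ``nd`` axes."""
    y = x.data
    for ax in range(2, 2 + nd):
        y = np.repeat(y, 2, axis=ax)

    def bw(dy):
        g = dy
        for i, ax in enumerate(range(2, 2 + nd)):
            s = g.shape
            half = s[ax] // 2
            g = g.reshape(s[:ax] + (half, 2) + s[ax + 1:]).sum(axis=ax + 1)
        x.accumulate(g)

    return Var(y, (x,), bw)


def concat_channels(a: Var, b: Var) -> Var:
    ca = a.data.shape[1]
    y = np.concatenate([a.data, b.data], axis=1)

    def bw(dy):
        a.accumulate(dy[:, :ca])
        b.accumulate(dy[:, ca:])

    return Var(y, (a, b), bw)


def replicate_frontal(x: Var, n: int) -> Var:
    """(N, C, V, X) frontal map -> (N, C, Y, V, X) replicated along Y."""
    y = np.broadcast_to(x.data[:, :, None], x.data.shape[:2] + (n,)
                        + x.data.shape[2:]).copy()

    def bw(dy):
        x.accumulate(dy.sum(axis=2))

    return Var(y, (x,), bw)


def replicate_sagittal(x: Var, n: int) -> Var:
    """(N, C, V, Y) sagittal map -> (N, C, Y, V, X) replicated along X."""
    t = np.swapaxes(x.data, 2, 3)  # (N, C, Y, V)
    y = np.broadcast_to(t[..., None], t.shape + (n,)).copy()

    def bw(dy):
        x.accumulate(np.swapaxes(dy.sum(axis=4), 2, 3))

    return Var(y, (x,), bw)


def mean_pair(a: Var, b: Var) -> Var:
    y = 0.5 * (a.data + b.data)

    def bw(dy):
        a.accumulate(0.5 * dy)
        b.accumulate(0.5 * dy)

    return Var(y, (a, b), bw)


# ===========================================================================
# Configuration
# ===========================================================================


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of one network (reference defaults, desk-scalable).

    The reference configuration fixes kernel 3, pool 2, ReLU, 'same' padding,
    He-normal init, Adam, and per-network learning rate / epochs / batch size
    (0.001/0.0001/0.00005, 20/20/30, 16/1/1); channel widths and desk-scale
    epochs are this package's choices.
    """

    which: str                      # separation | landmarks | reconstruction
    input_size: int = 128
    n_channels_out: int = 1
    learning_rate: float = 0.001
    epochs: int = 20
    batch_size: int = 16
    n_levels: int = 3
    base_channels: int = 8
    kernel_size: int = 3
    pool_size: int = 2
    final_activation: str = "sigmoid"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.input_size % (self.pool_size ** (self.n_levels - 1)):
            raise ValueError("pool size must divide the spatial size at every level")


def separation_config(**kw) -> NetworkConfig:
    base = dict(which="separation", learning_rate=0.001, epochs=20,
                batch_size=16, n_channels_out=1, final_activation="sigmoid")
    base.update(kw)
    return NetworkConfig(**base)


def landmark_config(n_channels: int = 6, **kw) -> NetworkConfig:
    if n_channels not in (3, 6):
        raise ValueError("landmark nets use 3 (per-leg sagittal) or 6 (frontal) channels")
    base = dict(which="landmarks", learning_rate=0.0001, epochs=20,
                batch_size=1, n_channels_out=n_channels,
                final_activation="sigmoid")
    base.update(kw)
    return NetworkConfig(**base)


def reconstruction_config(**kw) -> NetworkConfig:
    base = dict(which="reconstruction", learning_rate=0.00005, epochs=30,
                batch_size=1, n_channels_out=2, final_activation="softmax",
                n_levels=2)
    base.update(kw)
    return NetworkConfig(**base)


# ===========================================================================
# Models
# ===========================================================================


class Model:
    """A parameterized forward function with named weights."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        self.params: dict[str, Var] = {}
        self._rng = None

    def add_conv(self, name, c_in, c_out, nd, rng):
        k = (self.cfg.kernel_size,) * nd
        w = Var(_he_normal(rng, (c_out, c_in) + k, c_in * int(np.prod(k))),
                is_param=True, name=name + ".w")
        b = Var(np.zeros(c_out, np.float32), is_param=True, name=name + ".b")
        self.params[name + ".w"] = w
        self.params[name + ".b"] = b
        return w, b

    def c(self, name, x, nd=2, act="relu"):
        w, b = self.params[name + ".w"], self.params[name + ".b"]
        y = conv(x, w, b)
        if act == "relu":
            return relu(y)
        if act == "sigmoid":
            self.last_logits = y  # enables numerically safe with-logits losses
            return sigmoid(y)
        if act == "softmax":
            self.last_logits = y
            return softmax_channels(y)
        return y

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def state_dict(self):
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, state):
        for k, v in state.items():
            self.params[k].data = np.asarray(v, np.float32).copy()

    def save(self, path):
        np.savez_compressed(path, **self.state_dict())
        desc = {"which": self.cfg.which, "config": self.cfg.__dict__}
        with open(str(path) + ".json", "w") as fh:
            json.dump(desc, fh, indent=2, default=str)

    def load(self, path):
        with np.load(path) as z:
            self.load_state({k: z[k] for k in z.files})


class SeparationModel(Model):
    """One 2D encoder, two decoders with skips -> right and left sagittals."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__(cfg)
        rng = np.random.default_rng(seed)
        ch = [cfg.base_channels * 2 ** i for i in range(cfg.n_levels)]
        self.ch = ch
        c_in = 1
        for i, c in enumerate(ch):
            self.add_conv(f"enc{i}", c_in, c, 2, rng)
            c_in = c
        for branch in ("right", "left"):
            for i in range(cfg.n_levels - 2, -1, -1):
                self.add_conv(f"dec_{branch}{i}", ch[i + 1] + ch[i], ch[i], 2, rng)
            self.add_conv(f"out_{branch}", ch[0], 1, 2, rng)

    def forward(self, x: np.ndarray):
        h = Var(x)
        feats = []
        for i in range(self.cfg.n_levels):
            if i > 0:
                h = maxpool(h, 2)
            h = self.c(f"enc{i}", h)
            feats.append(h)
        outs = {}
        for branch in ("right", "left"):
            d = feats[-1]
            for i in range(self.cfg.n_levels - 2, -1, -1):
                d = upsample(d, 2)
                d = concat_channels(d, feats[i])
                d = self.c(f"dec_{branch}{i}", d)
            outs[branch] = self.c(f"out_{branch}", d, act="sigmoid")
        return outs


class LandmarkModel(Model):
    """2D U-net emitting one sigmoid heatmap channel per landmark."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__(cfg)
        rng = np.random.default_rng(seed)
        ch = [cfg.base_channels * 2 ** i for i in range(cfg.n_levels)]
        self.ch = ch
        c_in = 1
        for i, c in enumerate(ch):
            self.add_conv(f"enc{i}", c_in, c, 2, rng)
            c_in = c
        for i in range(cfg.n_levels - 2, -1, -1):
            self.add_conv(f"dec{i}", ch[i + 1] + ch[i], ch[i], 2, rng)
        self.add_conv("out", ch[0], cfg.n_channels_out, 2, rng)

    def forward(self, x: np.ndarray):
        h = Var(x)
        feats = []
        for i in range(self.cfg.n_levels):
            if i > 0:
                h = maxpool(h, 2)
            h = self.c(f"enc{i}", h)
            feats.append(h)
        d = feats[-1]
        for i in range(self.cfg.n_levels - 2, -1, -1):
            d = upsample(d, 2)
            d = concat_channels(d, feats[i])
            d = self.c(f"dec{i}", d)
        return self.c("out", d, act="sigmoid")


class ReconstructionModel(Model):
    """Two 2D branches -> replicate -> fused 3D U-net -> 2-class softmax.

    Input images of size S x S give an S/4 cube (two pooled 2D levels), so a
    512-pixel study yields a 128-cube and the 128-pixel desk preset a 32-cube.
    Skip connections exist on the fused-3D levels only.
    """

    def __init__(self, cfg: NetworkConfig, seed: int = 0,
                 n3d_levels: int | None = None):
        super().__init__(cfg)
        if n3d_levels is None:
            n3d_levels = cfg.n_levels
        rng = np.random.default_rng(seed)
        c2 = [cfg.base_channels, cfg.base_channels * 2]
        self.c2 = c2
        for view in ("frontal", "sagittal"):
            self.add_conv(f"{view}0", 1, c2[0], 2, rng)
            self.add_conv(f"{view}1", c2[0], c2[1], 2, rng)
        c3 = [cfg.base_channels * 2 * 2 ** i for i in range(n3d_levels)]
        self.c3 = c3
        c_in = c2[1]
        for i, c in enumerate(c3):
            self.add_conv(f"enc3d{i}", c_in, c, 3, rng)
            c_in = c
        for i in range(n3d_levels - 2, -1, -1):
            self.add_conv(f"dec3d{i}", c3[i + 1] + c3[i], c3[i], 3, rng)
        self.add_conv("out", c3[0], cfg.n_channels_out, 3, rng)
        self.cube = cfg.input_size // 4

    def forward(self, frontal: np.ndarray, sagittal: np.ndarray):
        if frontal.shape != sagittal.shape:
            raise ValueError("frontal and sagittal inputs must share size")
        maps = {}
        for view, arr in (("frontal", frontal), ("sagittal", sagittal)):
            h = self.c(f"{view}0", Var(arr))
            h = maxpool(h, 2)
            h = self.c(f"{view}1", h)
            h = maxpool(h, 2)
            maps[view] = h
        n = self.cube
        fused = mean_pair(replicate_frontal(maps["frontal"], n),
                          replicate_sagittal(maps["sagittal"], n))
        feats = []
        h = fused
        for i in range(len(self.c3)):
            if i > 0:
                h = maxpool(h, 3)
            h = self.c(f"enc3d{i}", h)
            feats.append(h)
        d = feats[-1]
        for i in range(len(self.c3) - 2, -1, -1):
            d = upsample(d, 3)
            d = concat_channels(d, feats[i])
            d = self.c(f"dec3d{i}", d)
        return self.c("out", d, act="softmax")


def build_separation_model(cfg: NetworkConfig | None = None, seed: int = 0):
    return SeparationModel(cfg or separation_config(), seed=seed)


def build_landmark_model(cfg: NetworkConfig | None = None, n_channels: int = 6,
                         seed: int = 0):
    if cfg is None:
        cfg = landmark_config(n_channels)
    elif cfg.n_channels_out != n_channels:
        cfg = replace(cfg, n_channels_out=n_channels)
    return LandmarkModel(cfg, seed=seed)


def build_reconstruction_model(cfg: NetworkConfig | None = None, seed: int = 0):
    return ReconstructionModel(cfg or reconstruction_config(), seed=seed)


# ===========================================================================
# Optimization / training
# ===========================================================================


class Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _dice_logit_grad(y: np.ndarray, p: np.ndarray) -> np.ndarray:
    """d(dice_ce)/d(logits) for one softmax sample: saturation-safe.

    The cross-entropy part collapses analytically to ``(p - y)/n_vox``; the
    Dice part is pushed through the softmax Jacobian explicitly (its
    probability-space gradient is bounded, unlike the raw CE one).
    """
    nvox = float(y[0].size)
    grad = (p - y) / nvox
    g = np.zeros_like(p)
    for c in range(1, y.shape[0]):
        inter = float((y[c] * p[c]).sum())
        denom = float(y[c].sum() + p[c].sum())
        if denom == 0.0:
            continue
        g[c] = -2.0 * (y[c] * denom - inter) / (denom * denom)
    grad += p * (g - (g * p).sum(axis=0, keepdims=True))
    return grad


def _loss_and_backward(model, sample_inputs, target, which):
    """Forward one batch, compute its loss, backpropagate; returns the loss.

    The landmark and reconstruction nets backpropagate from the logits
    (cross-entropy gradient ``p - y``) so saturated sigmoid/softmax outputs
    keep a healthy training signal.
    """
    if which == "separation":
        outs = model.forward(*sample_inputs)
        total = 0.0
        for side in ("right", "left"):
            val, grad = separation_loss(target[side], outs[side].data,
                                        return_grad=True)
            total += 0.5 * val
            outs[side].backward(0.5 * grad)
        return total
    if which == "landmarks":
        out = model.forward(*sample_inputs)
        val = bce_loss(target, out.data)
        model.last_logits.backward((out.data - target) / target.size)
        return val
    if which == "reconstruction":
        out = model.forward(*sample_inputs)
        total = 0.0
        nb = out.data.shape[0]
        grads = np.empty_like(out.data)
        for b in range(nb):
            total += dice_ce_loss(target[b], out.data[b]) / nb
            grads[b] = _dice_logit_grad(target[b], out.data[b]) / nb
        model.last_logits.backward(grads)
        return total
    raise ValueError(which)


def _eval_loss(model, samples, which):
    tot = 0.0
    for inputs, target in samples:
        if which == "separation":
            outs = model.forward(*inputs)
            tot += 0.5 * sum(separation_loss(target[s], outs[s].data)
                             for s in ("right", "left"))
        elif which == "landmarks":
            tot += bce_loss(target, model.forward(*inputs).data)
        else:
            out = model.forward(*inputs).data
            tot += float(np.mean([dice_ce_loss(target[b], out[b])
                                  for b in range(out.shape[0])]))
    return tot / max(len(samples), 1)


@dataclass
class TrainHistory:
    train: list = field(default_factory=list)
    val: list = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"epoch": range(len(self.train)),
                             "train_loss": self.train,
                             "val_loss": self.val})


def _stack_batch(batch):
    inputs = tuple(np.concatenate([s[0][i] for s in batch], axis=0)
                   for i in range(len(batch[0][0])))
    t0 = batch[0][1]
    if isinstance(t0, dict):
        target = {k: np.concatenate([s[1][k] for s in batch], axis=0)
                  for k in t0}
    else:
        target = np.concatenate([s[1] for s in batch], axis=0)
    return inputs, target


def train(model: Model, dataset: dict, cfg: NetworkConfig | None = None,
          seed: int = 0):
    """Train on ``dataset["train"]`` monitoring ``dataset["val"]``.

    Samples are ``(inputs_tuple, target)`` with a leading batch axis of 1 on
    every array.  Keeps (and restores) the parameters of the best validation
    epoch.  Deterministic for a fixed seed.
    """
    cfg = cfg or model.cfg
    train_samples = list(dataset["train"])
    val_samples = list(dataset.get("val", []))
    if not train_samples:
        raise ValueError("empty training split")
    rng = np.random.default_rng(seed)
    opt = Adam(model.params, cfg.learning_rate)
    hist = TrainHistory()
    best = (np.inf, model.state_dict(), -1)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_samples))
        ep_loss, nb = 0.0, 0
        for i0 in range(0, len(order), cfg.batch_size):
            batch = [train_samples[j] for j in order[i0:i0 + cfg.batch_size]]
            inputs, target = _stack_batch(batch)
            model.zero_grad()
            ep_loss += _loss_and_backward(model, inputs, target, cfg.which)
            nb += 1
            opt.step()
        hist.train.append(ep_loss / nb)
        vloss = (_eval_loss(model, val_samples, cfg.which)
                 if val_samples else hist.train[-1])
        hist.val.append(vloss)
        if vloss < best[0]:
            best = (vloss, model.state_dict(), epoch)
    model.load_state(best[1])
    hist.best_epoch = best[2]
    return model, hist


# ===========================================================================
# Inference
# ===========================================================================

NOT_DETECTED = None


def extract_landmark(channel: np.ndarray, window: int = 7):
    """Decode a heatmap channel to a continuous (u, v) pixel position.

    Argmax (ties break to the smallest (v, u)) refined by the center of mass
    of a ``window`` x ``window`` patch.  An all-zero channel yields ``None``.
    """
    ch = np.asarray(channel, float)
    if ch.max() <= 0.0:
        return NOT_DETECTED
    v0, u0 = np.unravel_index(int(np.argmax(ch)), ch.shape)
    r = window // 2
    vs, ve = max(v0 - r, 0), min(v0 + r + 1, ch.shape[0])
    us, ue = max(u0 - r, 0), min(u0 + r + 1, ch.shape[1])
    patch = ch[vs:ve, us:ue]
    tot = patch.sum()
    vv, uu = np.mgrid[vs:ve, us:ue]
    return (float((patch * uu).sum() / tot), float((patch * vv).sum() / tot))


@dataclass
class LabelVolume:
    """Binary proximal-tibia label grid in the world frame (axes X, Y, Z)."""

    grid: np.ndarray   # uint8, [ix, iy, iz]
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.spacing = np.asarray(self.spacing, float)
        self.origin = np.asarray(self.origin, float)
        u = np.unique(self.grid)
        if not np.all(np.isin(u, [0, 1])):
            raise ValueError("label volume must be binary")


def net_output_to_label_volume(prob: np.ndarray, grid_spec: dict) -> LabelVolume:
    """Argmax a (2, Y, V, X) softmax field into a world-frame LabelVolume."""
    binary = (prob.argmax(axis=0) == 1).astype(np.uint8)  # (Y, V, X)
    # (Y, V, X) -> (X, Y, Z): transpose, then flip V (v runs along -Z)
    g = np.transpose(binary, (2, 0, 1))[:, :, ::-1].copy()
    s = float(grid_spec["spacing"])
    ny = binary.shape[0]
    origin = np.array([grid_spec["x0"], grid_spec["y0"],
                       grid_spec["z_top"] - s * (binary.shape[1] - 1)])
    return LabelVolume(g, np.full(3, s), origin)


def target_to_label_volume(target_onehot: np.ndarray, grid_spec: dict) -> LabelVolume:
    return net_output_to_label_volume(target_onehot, grid_spec)


@dataclass
class PredictionResult:
    separated: dict      # side -> Radiograph (predicted or passthrough)
    landmarks2d: dict    # view -> {name: (u, v) | None}
    volumes: dict        # side -> LabelVolume
    grids: dict          # side -> grid spec
    probabilities: dict  # side -> (2, Y, V, X) softmax output


def predict_study(models: dict, study, recon_spec=None,
                  separation_mode: str = "network",
                  crop_landmarks: str = "predicted") -> PredictionResult:
    """Run the full inference pipeline on one biplanar study.

    ``models`` maps ``separation``, ``landmarks_frontal``,
    ``landmarks_sagittal``, ``recon_left``, ``recon_right`` to trained
    models.  ``separation_mode``: "network" uses the separation model,
    "oracle" the study's ground-truth separated targets, "none" the raw
    two-leg sagittal.  ``crop_landmarks``: center the reconstruction crops on
    predicted or ground-truth knee positions.  Left and right
    reconstructions run independently of one another.
    """
    spec = recon_spec or _drr.ReconSpec()
    sag = study.I_sag

    if separation_mode == "network":
        if "separation" not in models:
            raise KeyError("separation model missing")
        outs = models["separation"].forward(sag.pixels[None, None])
        separated = {s: _drr.Radiograph(outs[s].data[0, 0], "sagittal",
                                        sag.geometry, {"predicted": True})
                     for s in ("right", "left")}
    elif separation_mode == "oracle":
        separated = {"right": study.I_sag_R, "left": study.I_sag_L}
    elif separation_mode == "none":
        separated = {"right": sag, "left": sag}
    else:
        raise ValueError(separation_mode)

    landmarks2d = {"frontal": {}, "sagittal_left": {}, "sagittal_right": {}}
    if "landmarks_frontal" in models:
        hm = models["landmarks_frontal"].forward(study.I_fron.pixels[None, None])
        names = [f"{side}/{n}" for side in ("left", "right")
                 for n in _drr.LANDMARK_NAMES]
        for i, name in enumerate(names):
            landmarks2d["frontal"][name] = extract_landmark(hm.data[0, i])
    if "landmarks_sagittal" in models:
        for side in ("left", "right"):
            img = separated[side]
            if img is None:
                continue
            hm = models["landmarks_sagittal"].forward(img.pixels[None, None])
            for i, name in enumerate(_drr.LANDMARK_NAMES):
                landmarks2d[f"sagittal_{side}"][name] = extract_landmark(
                    hm.data[0, i])

    volumes, grids, probs = {}, {}, {}
    for side in ("left", "right"):
        key = f"recon_{side}"
        if key not in models:
            continue
        if crop_landmarks == "predicted" and landmarks2d["frontal"].get(
                f"{side}/KC") is not None:
            uf, vf = landmarks2d["frontal"][f"{side}/KC"]
            us, _ = (landmarks2d[f"sagittal_{side}"].get("KC")
                     or study.landmarks2d[f"sagittal_{side}"]["KC"])
            # same window convention as the training crops: shared frontal
            # v, centred below the knee
            vc = vf + spec.v_offset_px
            centers = {"frontal": (uf, vc), "sagittal": (us, vc)}
        else:
            centers = _drr.knee_crop_centers(study, side, spec)
        fr_crop, _ = _drr.extract_crop(study.I_fron, centers["frontal"], spec)
        sg_crop, _ = _drr.extract_crop(separated[side], centers["sagittal"], spec)
        grid = _drr.recon_grid(study, side, centers, spec)
        fr = _drr.upsample_crop(fr_crop, spec.upsample)[None, None]
        sg = _drr.upsample_crop(sg_crop, spec.upsample)[None, None]
        out = models[key].forward(fr, sg).data[0]
        probs[side] = out
        grids[side] = grid
        volumes[side] = net_output_to_label_volume(out, grid)
    return PredictionResult(separated, landmarks2d, volumes, grids, probs)
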