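"""Learned segmentation stages: RoI cropping, 3D chambers/myocardium U-net,
and per-slice 2D blood-pool U-net with an explicit boundary class.

Two interchangeable backends drive every stage:

* :class:`OracleBackend` derives the stage output directly from an attached
  ground-truth label volume.  With oracle backends the downstream graph
  stages receive exactly the maps a perfectly trained network would
  produce, so they can be tested in isolation.
* :class:`TrainedBackend` wraps a small convolutional U-net implemented in
  numpy (encoder/decoder with skip connections, average-pool downsampling,
  nearest-neighbour upsampling, hand-written backprop, Adam).  It is meant
  for desk-scale overfit experiments, not full clinical training.

Normalised voxel-coordinate channels are appended to the network input by
default: the four chambers share one blood-pool intensity, so a small
receptive field cannot tell LV from RA without positional context.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import zoom as nd_zoom
from scipy.ndimage import binary_erosion

from .core import (AO, BACKGROUND, BLOODPOOL_BOUNDARY, BLOODPOOL_CODES,
                   BLOODPOOL_INTERIOR, PA, IntensityVolume, LabelVolume,
                   combined_loss, dice_loss_grad)

ROI_GRID = 64                 #: low-resolution grid used for RoI and 3D net
ROI_MARGIN = 8                #: bounding-box margin, in 64-grid voxels
PATCHES_PER_EPOCH = 4         #: random 32^3 patches per volume per 3D epoch
LEAKY_SLOPE = 0.1             #: leaky-ReLU negative slope
HEALTHY_WORST_DICE = 0.3      #: training attempt accepted above this;
                              #: flags clear class collapse, not weak classes
INTENSITY_SCALE = 300.0       #: blood-pool intensity used to normalise input

#: class layout of the 3D chambers net: index == taxonomy code
CHAMBER_CLASSES = 6           # background, LV, RV, LA, RA, Myo
#: class layout of the 2D blood-pool net
BLOODPOOL_CLASSES = 3         # background, interior, boundary


class NoHeartFoundError(RuntimeError):
    """The coarse segmentation found no foreground."""


class BackendStateError(RuntimeError):
    """A backend is asked for a task it is not equipped for."""


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""


# ---------------------------------------------------------------------------
# Resampling helpers
# ---------------------------------------------------------------------------

def majority_downsample(labels: np.ndarray, out_shape) -> np.ndarray:
    """Downsample an integer label grid by per-cell majority vote.

    Each input voxel votes into the output cell it maps to
    (proportional index mapping).  The majority label wins; on ties the
    background loses first, then the lowest code wins.
    """
    labels = np.asarray(labels)
    out_shape = tuple(int(s) for s in out_shape)
    n_codes = int(labels.max()) + 1
    idx = [np.minimum((np.arange(labels.shape[k]) * out_shape[k])
                      // labels.shape[k], out_shape[k] - 1)
           for k in range(3)]
    cell = (idx[0][:, None, None] * (out_shape[1] * out_shape[2])
            + idx[1][None, :, None] * out_shape[2]
            + idx[2][None, None, :])
    n_cells = int(np.prod(out_shape))
    counts = np.zeros((n_cells, n_codes), np.int64)
    np.add.at(counts, (cell.ravel(), labels.ravel()), 1)
    codes = np.arange(n_codes)
    # lexicographic priority: count, then foreground over background,
    # then lower code
    score = counts * 1000 + (codes != 0) * 100 + (99 - codes)
    score[counts == 0] = -1
    out = np.argmax(score, axis=1).astype(labels.dtype)
    out = out.reshape(out_shape)
    # cells with no votes (an output axis larger than the input axis):
    # fall back to nearest-neighbour gather
    empty = (counts.sum(axis=1) == 0).reshape(out_shape)
    if empty.any():
        gather = [np.minimum(((np.arange(out_shape[k]) * 2 + 1)
                              * labels.shape[k]) // (2 * out_shape[k]),
                             labels.shape[k] - 1) for k in range(3)]
        nn = labels[np.ix_(gather[0], gather[1], gather[2])]
        out[empty] = nn[empty]
    return out


def resample_intensity(data: np.ndarray, out_shape) -> np.ndarray:
    """Trilinear resampling of an intensity grid to ``out_shape``."""
    factors = [o / s for o, s in zip(out_shape, data.shape)]
    out = nd_zoom(data.astype(np.float32), factors, order=1,
                  grid_mode=True, mode="nearest")
    # zoom can be off by one voxel on exact shape; enforce it
    slc = tuple(slice(0, s) for s in out_shape)
    out = out[slc]
    pad = [(0, o - s) for o, s in zip(out_shape, out.shape)]
    if any(p[1] for p in pad):
        out = np.pad(out, pad, mode="edge")
    return out


def upsample_labels(labels: np.ndarray, out_shape) -> np.ndarray:
    """Nearest-neighbour upsampling of a label grid (label-preserving)."""
    idx = [np.minimum((np.arange(out_shape[k]) * labels.shape[k])
                      // out_shape[k], labels.shape[k] - 1)
           for k in range(3)]
    return labels[np.ix_(idx[0], idx[1], idx[2])]


# ---------------------------------------------------------------------------
# Numpy U-net
# ---------------------------------------------------------------------------

def _offsets(ndim):
    return list(itertools.product((0, 1, 2), repeat=ndim))


def _conv_forward(x, W, b):
    """Convolution with 3^ndim kernel (same padding) or 1-kernel.

    ``x``: (Cin, *S); ``W``: (K, Cin, Cout); returns (Cout, *S).
    """
    ndim = x.ndim - 1
    cout = W.shape[2]
    S = x.shape[1:]
    n = int(np.prod(S))
    if W.shape[0] == 1:
        y = (W[0].T @ x.reshape(x.shape[0], n)).reshape((cout,) + S)
    else:
        xp = np.pad(x, ((0, 0),) + ((1, 1),) * ndim)
        yf = np.zeros((cout, n), np.float32)
        for o, off in enumerate(_offsets(ndim)):
            sl = tuple(slice(off[k], off[k] + S[k]) for k in range(ndim))
            xs = xp[(slice(None),) + sl].reshape(x.shape[0], n)
            yf += W[o].T @ xs
        y = yf.reshape((cout,) + S)
    return y + b.reshape((-1,) + (1,) * ndim)


def _conv_backward(dy, x, W):
    ndim = x.ndim - 1
    S = x.shape[1:]
    n = int(np.prod(S))
    dyf = dy.reshape(dy.shape[0], n)
    dW = np.zeros_like(W)
    db = dyf.sum(axis=1)
    if W.shape[0] == 1:
        dW[0] = x.reshape(x.shape[0], n) @ dyf.T
        dx = (W[0] @ dyf).reshape(x.shape)
        return dx, dW, db
    xp = np.pad(x, ((0, 0),) + ((1, 1),) * ndim)
    dxp = np.zeros_like(xp)
    for o, off in enumerate(_offsets(ndim)):
        sl = tuple(slice(off[k], off[k] + S[k]) for k in range(ndim))
        xs = xp[(slice(None),) + sl].reshape(x.shape[0], n)
        dW[o] = xs @ dyf.T
        dxp[(slice(None),) + sl] += (W[o] @ dyf).reshape(xp[(slice(None),) + sl].shape)
    core = tuple(slice(1, 1 + S[k]) for k in range(ndim))
    return dxp[(slice(None),) + core], dW, db


def _avgpool(x):
    ndim = x.ndim - 1
    shape = [x.shape[0]]
    for s in x.shape[1:]:
        shape += [s // 2, 2]
    xr = x.reshape(shape)
    axes = tuple(2 + 2 * k for k in range(ndim))
    return xr.mean(axis=axes)


def _avgpool_backward(dy, in_shape):
    ndim = dy.ndim - 1
    out = dy / (2 ** ndim)
    for ax in range(1, ndim + 1):
        out = np.repeat(out, 2, axis=ax)
    return np.ascontiguousarray(out.reshape(in_shape))


def _upsample(x):
    for ax in range(1, x.ndim):
        x = np.repeat(x, 2, axis=ax)
    return x


def _upsample_backward(dy):
    ndim = dy.ndim - 1
    shape = [dy.shape[0]]
    for s in dy.shape[1:]:
        shape += [s // 2, 2]
    axes = tuple(2 + 2 * k for k in range(ndim))
    return dy.reshape(shape).sum(axis=axes)


def _instnorm_forward(z, gamma, beta, eps=1e-5):
    ax = tuple(range(1, z.ndim))
    mu = z.mean(axis=ax, keepdims=True)
    var = z.var(axis=ax, keepdims=True)
    std = np.sqrt(var + eps)
    xhat = (z - mu) / std
    shape = (-1,) + (1,) * (z.ndim - 1)
    return gamma.reshape(shape) * xhat + beta.reshape(shape), (xhat, std)


def _instnorm_backward(dy, gamma, xhat, std):
    ax = tuple(range(1, dy.ndim))
    n = int(np.prod(dy.shape[1:]))
    shape = (-1,) + (1,) * (dy.ndim - 1)
    dgamma = (dy * xhat).sum(axis=ax)
    dbeta = dy.sum(axis=ax)
    dxhat = dy * gamma.reshape(shape)
    dz = (dxhat - dxhat.mean(axis=ax, keepdims=True)
          - xhat * (dxhat * xhat).mean(axis=ax, keepdims=True)) / std
    return dz, dgamma, dbeta


class UNet:
    """Minimal encoder/decoder convolutional network (2D or 3D).

    ``levels`` resolution levels with two 3^ndim convolutions each,
    channel counts doubling per level from ``base_filters``; each
    convolution is followed by per-channel instance normalisation and a
    ReLU; a 1-kernel output head with channel softmax.
    """

    def __init__(self, ndim: int, in_channels: int, n_classes: int,
                 levels: int = 2, base_filters: int = 8, seed: int = 0,
                 instance_norm: bool = False):
        if ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")
        self.ndim = ndim
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.levels = levels
        self.base_filters = base_filters
        self.instance_norm = instance_norm
        rng = np.random.default_rng(seed)
        k = 3 ** ndim
        f = [base_filters * 2 ** l for l in range(levels)]
        self.params = {}

        def add_conv(name, kk, cin, cout, norm=instance_norm):
            std = np.sqrt(2.0 / (kk * cin))
            self.params[name + ".W"] = rng.normal(0, std, (kk, cin, cout)).astype(np.float32)
            self.params[name + ".b"] = np.zeros(cout, np.float32)
            if norm:
                self.params[name + ".g"] = np.ones(cout, np.float32)
                self.params[name + ".c"] = np.zeros(cout, np.float32)

        cin = in_channels
        for l in range(levels):
            add_conv(f"enc{l}a", k, cin, f[l])
            add_conv(f"enc{l}b", k, f[l], f[l])
            cin = f[l]
        for l in range(levels - 2, -1, -1):
            add_conv(f"dec{l}a", k, f[l] + f[l + 1], f[l])
            add_conv(f"dec{l}b", k, f[l], f[l])
        add_conv("head", 1, f[0], n_classes, norm=False)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Return class probabilities (C, *S); optionally an autodiff cache."""
        p = self.params
        cache = {"inputs": {}, "relu": {}, "norm": {}, "pool_in": {}}

        def conv_relu(name, h):
            cache["inputs"][name] = h
            z = _conv_forward(h, p[name + ".W"], p[name + ".b"])
            if self.instance_norm:
                z, norm_cache = _instnorm_forward(z, p[name + ".g"],
                                                  p[name + ".c"])
                cache["norm"][name] = norm_cache
            # leaky ReLU: a width-8 net with hard ReLUs can lose whole
            # feature channels early and never recover
            r = np.where(z > 0, z, LEAKY_SLOPE * z)
            cache["relu"][name] = np.where(z > 0, np.float32(1.0),
                                           np.float32(LEAKY_SLOPE))
            return r

        skips = {}
        h = x.astype(np.float32)
        for l in range(self.levels):
            h = conv_relu(f"enc{l}a", h)
            h = conv_relu(f"enc{l}b", h)
            skips[l] = h
            if l < self.levels - 1:
                cache["pool_in"][l] = h.shape
                h = _avgpool(h)
        for l in range(self.levels - 2, -1, -1):
            h = _upsample(h)
            h = np.concatenate([skips[l], h], axis=0)
            h = conv_relu(f"dec{l}a", h)
            h = conv_relu(f"dec{l}b", h)
        cache["inputs"]["head"] = h
        logits = _conv_forward(h, p["head.W"], p["head.b"])
        logits -= logits.max(axis=0, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=0, keepdims=True)
        if want_cache:
            return probs, cache
        return probs

    def backward(self, dlogits: np.ndarray, cache) -> dict:
        """Gradients of all parameters given d(loss)/d(logits)."""
        p = self.params
        grads = {}

        def conv_back(name, dy):
            dy = dy * cache["relu"][name]
            if self.instance_norm:
                xhat, std = cache["norm"][name]
                dy, dg, dc = _instnorm_backward(dy, p[name + ".g"], xhat, std)
                grads[name + ".g"] = dg
                grads[name + ".c"] = dc
            dx, dW, db = _conv_backward(dy, cache["inputs"][name], p[name + ".W"])
            grads[name + ".W"] = dW
            grads[name + ".b"] = db
            return dx

        dh, dW, db = _conv_backward(dlogits, cache["inputs"]["head"], p["head.W"])
        grads["head.W"] = dW
        grads["head.b"] = db
        f = [self.base_filters * 2 ** l for l in range(self.levels)]
        dskips = {}
        for l in range(0, self.levels - 1):
            dh = conv_back(f"dec{l}b", dh)
            dh = conv_back(f"dec{l}a", dh)
            dskips[l] = dh[:f[l]]
            dh = _upsample_backward(dh[f[l]:])
        for l in range(self.levels - 1, -1, -1):
            if l < self.levels - 1:
                dh = _avgpool_backward(dh, cache["pool_in"][l])
                dh = dh + dskips[l]
            dh = conv_back(f"enc{l}b", dh)
            dh = conv_back(f"enc{l}a", dh)
        return grads

    # -- persistence ---------------------------------------------------------
    def descriptor(self) -> dict:
        return {"ndim": self.ndim, "in_channels": self.in_channels,
                "n_classes": self.n_classes, "levels": self.levels,
                "base_filters": self.base_filters,
                "instance_norm": self.instance_norm}

    def save(self, path):
        np.savez(path, **self.params,
                 __descriptor__=np.frombuffer(
                     json.dumps(self.descriptor()).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "UNet":
        data = np.load(path)
        desc = json.loads(bytes(data["__descriptor__"]).decode())
        net = cls(**desc)
        for k in net.params:
            net.params[k] = data[k]
        return net


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

@dataclass
class OracleBackend:
    """Backend that reads every answer off an attached ground truth.

    ``chambers_truth`` optionally supplies a chamber-only reference for
    the 3D stage (vessels cleared); without it the merged-vein labelling
    convention would make the coarse chamber stage claim thin anomalous
    vessels as atrium, hiding them from the graph stage.
    """
    truth: LabelVolume
    chambers_truth: LabelVolume | None = None
    kind: str = "oracle"


@dataclass
class TrainedBackend:
    """Backend wrapping a trained :class:`UNet` for one task."""
    net: UNet
    task: str                      # "chambers3d" or "bloodpool2d"
    coord_channels: bool = True
    loss_history: list = field(default_factory=list)
    kind: str = "trained"

    def save(self, path):
        self.net.save(path)
        with open(str(path) + ".json", "w") as fh:
            json.dump({"task": self.task, "coord_channels": self.coord_channels,
                       **self.net.descriptor()}, fh, indent=1)

    @classmethod
    def load(cls, path) -> "TrainedBackend":
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        return cls(net=UNet.load(path), task=meta["task"],
                   coord_channels=meta["coord_channels"])


def _coord_grids(shape):
    """Positional encoding: linear coordinates plus one sin/cos octave.

    The four chambers share one intensity, so the nets rely on position to
    tell them apart; the periodic features let a narrow net carve sharp
    position-dependent boundaries it cannot express from linear
    coordinates alone.
    """
    axes = [np.linspace(-1, 1, s, dtype=np.float32) for s in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    out = []
    for g in grids:
        out.append(g.astype(np.float32))
        out.append(np.sin(np.pi * g).astype(np.float32))
        out.append(np.cos(np.pi * g).astype(np.float32))
    return out


def build_input(intensity: np.ndarray, coord_channels: bool = True) -> np.ndarray:
    """Stack normalised intensity (and coordinate channels) as net input."""
    chans = [intensity.astype(np.float32) / INTENSITY_SCALE]
    if coord_channels:
        chans += _coord_grids(intensity.shape)
    return np.stack(chans, axis=0)


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def _oracle_crop_truth(backend: OracleBackend, roi: IntensityVolume) -> np.ndarray:
    """Locate the RoI inside the oracle's truth via the origins."""
    truth = backend.truth
    off = np.round((np.asarray(roi.origin) - np.asarray(truth.origin))
                   / np.asarray(truth.spacing)).astype(int)
    sl = tuple(slice(off[k], off[k] + roi.shape[k]) for k in range(3))
    sub = truth.data[sl]
    if sub.shape != roi.shape:
        raise ValueError("RoI does not lie inside the oracle's truth volume")
    return sub


def crop_roi(image: IntensityVolume, backend,
             margin: int = ROI_MARGIN) -> tuple[IntensityVolume, tuple[int, int, int]]:
    """Locate the heart and crop a region of interest around it.

    The image is resampled to a coarse 64-cubed grid, a binary foreground
    segmentation is produced by the backend, and the tight bounding box
    (plus ``margin`` coarse voxels) is mapped back to full resolution and
    cropped.  Returns the RoI and the voxel offset of its corner in the
    original grid.
    """
    if image.data.size == 0:
        raise ValueError("empty image")
    shape = np.asarray(image.shape)
    if backend.kind == "oracle":
        coarse = majority_downsample((backend.truth.data > 0).astype(np.int16),
                                     (ROI_GRID,) * 3) > 0
    else:
        # desk-scale coarse localisation: the contrast-filled blood pool is
        # by far the brightest tissue, so a fixed threshold on the
        # downsampled intensities bounds the heart region
        low = resample_intensity(image.data, (ROI_GRID,) * 3)
        coarse = low > 0.5 * INTENSITY_SCALE
    if not coarse.any():
        raise NoHeartFoundError("no heart found in the coarse segmentation")
    nz = np.argwhere(coarse)
    lo = np.maximum(nz.min(axis=0) - margin, 0)
    hi = np.minimum(nz.max(axis=0) + 1 + margin, ROI_GRID)
    lo_full = (lo * shape) // ROI_GRID
    hi_full = np.minimum(-(-hi * shape // ROI_GRID), shape)
    sl = tuple(slice(int(lo_full[k]), int(hi_full[k])) for k in range(3))
    roi = IntensityVolume(
        image.data[sl], image.spacing,
        tuple(image.origin[k] + lo_full[k] * image.spacing[k] for k in range(3)))
    return roi, tuple(int(v) for v in lo_full)


def segment_chambers_3d(roi: IntensityVolume, backend) -> LabelVolume:
    """Chambers + myocardium segmentation on a 64-cubed grid.

    The oracle backend majority-downsamples the ground truth (great-vessel
    codes map to background: vessels are the 2D stage's job); the trained
    backend resamples the RoI to the coarse grid and runs the 3D net.
    """
    out_spacing = tuple(roi.spacing[k] * roi.shape[k] / ROI_GRID for k in range(3))
    if backend.kind == "oracle":
        src = (backend.chambers_truth if backend.chambers_truth is not None
               else backend.truth)
        sub = _oracle_crop_truth(
            OracleBackend(truth=src), roi).copy()
        sub[np.isin(sub, (AO, PA))] = BACKGROUND
        lab = majority_downsample(sub, (ROI_GRID,) * 3)
    else:
        if backend.task != "chambers3d":
            raise BackendStateError(f"backend task {backend.task!r} cannot "
                                    "segment chambers")
        x = build_input(resample_intensity(roi.data, (ROI_GRID,) * 3),
                        backend.coord_channels)
        probs = backend.net.forward(x)
        lab = np.argmax(probs, axis=0).astype(np.int16)
    return LabelVolume(lab.astype(np.int16), out_spacing, roi.origin)


def bloodpool_oracle_classes(truth_data: np.ndarray) -> np.ndarray:
    """Interior/boundary blood-pool classes derived from a truth grid.

    Boundary voxels are blood-pool voxels with at least one
    non-blood-pool 8-neighbour within their axial slice.
    """
    bp = np.isin(truth_data, BLOODPOOL_CODES)
    interior = binary_erosion(bp, structure=np.ones((1, 3, 3), bool),
                              border_value=0)
    out = np.zeros(truth_data.shape, np.int16)
    out[bp] = BLOODPOOL_BOUNDARY
    out[interior] = BLOODPOOL_INTERIOR
    return out


def segment_bloodpool_2d(image: IntensityVolume, backend) -> LabelVolume:
    """Full-resolution blood-pool segmentation, slice by slice.

    Output classes: background, blood-pool interior, blood-pool boundary
    (codes 0/8/9).  The explicit boundary class is what later lets the
    smoothing + thinning stage separate abutting vessels.
    """
    if image.data.size == 0:
        raise ValueError("empty image")
    if backend.kind == "oracle":
        from .core import check_same_geometry
        check_same_geometry(image, backend.truth)
        out = bloodpool_oracle_classes(backend.truth.data)
    else:
        if backend.task != "bloodpool2d":
            raise BackendStateError(f"backend task {backend.task!r} cannot "
                                    "segment the blood pool")
        out = np.zeros(image.shape, np.int16)
        code_of = {0: BACKGROUND, 1: BLOODPOOL_INTERIOR, 2: BLOODPOOL_BOUNDARY}
        for z in range(image.shape[0]):
            x = build_input(image.data[z], backend.coord_channels)
            probs = backend.net.forward(x)
            cls = np.argmax(probs, axis=0)
            out[z] = np.vectorize(code_of.get)(cls)
    return LabelVolume(out, image.spacing, image.origin)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training hyper-parameters.

    The learning rate is ``lr_initial`` for the first 50% of epochs and
    ``lr_late`` afterwards.  Defaults follow the published schedule
    (2e-4 then 2e-5); epoch defaults are 6 (2D) and 480 (3D) when
    ``epochs`` is left unset, both freely overridable.
    """
    epochs: int | None = None
    lr_initial: float = 2e-4
    lr_late: float = 2e-5
    augment: bool = False
    seed: int = 0
    #: up to this many full training attempts with derived seeds; an
    #: attempt is accepted as soon as its worst per-class Dice on the
    #: training volumes is healthy, otherwise the best attempt is kept.
    #: A tiny net on a short budget occasionally starts in a basin where
    #: two same-intensity classes merge and never separate.
    restarts: int = 1
    #: global gradient-norm clip; guards against the rare late-training
    #: blow-up of a small net at an aggressive step size
    clip_norm: float = 2.0

    def __post_init__(self):
        if self.epochs is not None and self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr_initial <= 0 or self.lr_late <= 0:
            raise ValueError("learning rates must be positive")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")

    def resolved_epochs(self, dimensionality: str) -> int:
        if self.epochs is not None:
            return self.epochs
        return 6 if dimensionality == "2D" else 480

    def learning_rate(self, epoch: int, total_epochs: int) -> float:
        """Learning rate at 1-based ``epoch`` of ``total_epochs``."""
        if not 1 <= epoch <= total_epochs:
            raise ValueError("epoch out of range")
        return self.lr_initial if epoch <= 0.5 * total_epochs else self.lr_late


class _Adam:
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads, lr):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _onehot_grid(codes: np.ndarray, n_classes: int) -> np.ndarray:
    g = np.zeros((n_classes,) + codes.shape, np.float32)
    for c in range(n_classes):
        g[c] = codes == c
    return g


def _train_samples_3d(cases, coord_channels):
    samples = []
    for case in cases:
        oracle = OracleBackend(case.truth,
                               getattr(case, "chambers_truth", None))
        roi, _ = crop_roi(case.image, oracle)
        x = build_input(resample_intensity(roi.data, (ROI_GRID,) * 3),
                        coord_channels)
        target = segment_chambers_3d(roi, oracle).data
        fg = np.argwhere(target > 0)
        samples.append((x, _onehot_grid(target, CHAMBER_CLASSES), fg))
    return samples


def _train_samples_2d(cases, coord_channels, max_slices_per_case=24):
    samples = []
    for case in cases:
        classes = bloodpool_oracle_classes(case.truth.data)
        cls = np.zeros_like(classes)
        cls[classes == BLOODPOOL_INTERIOR] = 1
        cls[classes == BLOODPOOL_BOUNDARY] = 2
        has_fg = np.flatnonzero(cls.reshape(cls.shape[0], -1).any(axis=1))
        keep = has_fg[:: max(1, len(has_fg) // max_slices_per_case)]
        for z in keep:
            x = build_input(case.image.data[z], coord_channels)
            samples.append((x, _onehot_grid(cls[z], BLOODPOOL_CLASSES)))
    return samples


def train_unet(cases, config: TrainConfig, dimensionality: str = "3D",
               levels: int = 2, base_filters: int = 8,
               coord_channels: bool = True) -> TrainedBackend:
    """Optimise the combined Dice + cross-entropy loss on phantom cases.

    Deterministic for a given seed: seeded weight initialisation and a
    fixed sample order.  Returns a trained backend whose ``loss_history``
    holds the mean per-epoch loss.
    """
    if dimensionality not in ("2D", "3D"):
        raise ValueError("dimensionality must be '2D' or '3D'")
    if not cases:
        raise ValueError("need at least one training case")
    epochs = config.resolved_epochs(dimensionality)
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    rng = np.random.default_rng(config.seed)

    if dimensionality == "3D":
        volumes = _train_samples_3d(cases, coord_channels)
        n_classes, ndim, task = CHAMBER_CLASSES, 3, "chambers3d"
    else:
        volumes = _train_samples_2d(cases, coord_channels)
        n_classes, ndim, task = BLOODPOOL_CLASSES, 2, "bloodpool2d"

    patch = 32

    def run_epochs(state, first, last):
        net, opt, rng, history = state
        for epoch in range(first, last + 1):
            _one_epoch(net, opt, rng, history,
                       config.learning_rate(epoch, epochs), epoch)
        return state

    def _one_epoch(net, opt, rng, history, lr, epoch):
        losses = []
        if dimensionality == "3D":
            # several random patches per volume per epoch: many cheap Adam
            # steps instead of one expensive full-volume step.  Patches are
            # centred on foreground voxels (with jitter): the heart occupies
            # a few percent of the grid and uniform patches would be almost
            # entirely background.
            samples = []
            for x, g, fg in volumes:
                for _ in range(PATCHES_PER_EPOCH):
                    if len(fg):
                        c = fg[int(rng.integers(0, len(fg)))]
                        c = c + rng.integers(-8, 9, size=3)
                    else:
                        c = np.asarray(x.shape[1:]) // 2
                    lo = [int(np.clip(c[k] - patch // 2, 0,
                                      max(x.shape[1 + k] - patch, 0)))
                          for k in range(3)]
                    sl = (slice(None),) + tuple(
                        slice(lo[k], lo[k] + patch) for k in range(3))
                    samples.append((x[sl], g[sl]))
        else:
            samples = volumes
        for x, g in samples:
            if config.augment and rng.random() < 0.5:
                x = x[..., ::-1].copy()
                g = g[..., ::-1].copy()
            probs, cache = net.forward(x, want_cache=True)
            # patch-interior loss: a margin of each 3D patch is excluded so
            # the zero-padded patch border (absent at full-volume inference)
            # does not teach wrong boundary context
            margin = 4 if (dimensionality == "3D"
                           and min(probs.shape[1:]) > 16) else 0
            core = (slice(None),) + (slice(margin, -margin or None),) * (probs.ndim - 1)
            pc, gc = probs[core], g[core]
            n = int(np.prod(pc.shape[1:]))
            pf = pc.reshape(n_classes, n).T
            gf = gc.reshape(n_classes, n).T
            loss = combined_loss(pf, gf)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            losses.append(loss)
            # Dice part through the softmax Jacobian; cross-entropy part
            # analytically against the logits — (p - g)/(NC) keeps a
            # restoring gradient even where a class prob saturated to 0
            dprobs = dice_loss_grad(pf, gf)              # (n, C)
            inner = (dprobs * pf).sum(axis=1, keepdims=True)
            dcore = (pf * (dprobs - inner)
                     + (pf - gf) / (n * n_classes)).T.reshape(pc.shape)
            dlogits = np.zeros(probs.shape, np.float32)
            dlogits[core] = dcore
            grads = net.backward(dlogits, cache)
            gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if gnorm > config.clip_norm:
                scale = config.clip_norm / gnorm
                grads = {k: g * scale for k, g in grads.items()}
            opt.step(net.params, grads, lr)
        history.append(float(np.mean(losses)))

    def make_state(seed):
        net = UNet(ndim, volumes[0][0].shape[0], n_classes,
                   levels=levels, base_filters=base_filters, seed=seed)
        return (net, _Adam(net.params), np.random.default_rng(seed), [])

    def worst_class_dice(net):
        """Smallest per-class training Dice: detects merged/lost classes."""
        worst = 1.0
        for item in volumes:
            x, g = item[0], item[1]
            pred = np.argmax(net.forward(x), axis=0)
            truth = np.argmax(g, axis=0)
            for c in range(1, n_classes):
                t = truth == c
                if t.any():
                    p = pred == c
                    worst = min(worst, 2.0 * (p & t).sum()
                                / max(int(p.sum()) + int(t.sum()), 1))
        return worst

    n_restarts = config.restarts if dimensionality == "3D" else 1
    state, best_score = None, -1.0
    for attempt in range(n_restarts):
        cand = run_epochs(make_state(config.seed + 101 * attempt), 1, epochs)
        score = worst_class_dice(cand[0])
        if score > best_score:
            state, best_score = cand, score
        if best_score >= HEALTHY_WORST_DICE:
            break
    net, _, _, history = state
    return TrainedBackend(net=net, task=task, coord_channels=coord_channels,
                          loss_history=history)
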