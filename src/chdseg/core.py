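"""Label taxonomy, volume containers, and segmentation metrics.

The segmentation target is the seven-structure whole-heart taxonomy used
throughout the pipeline: four chambers (LV, RV, LA, RA), the ventricular
myocardium (Myo), and the two great arterial trunks (Ao, PA).  By
convention the venae cavae carry the RA code and the pulmonary veins carry
the LA code, since these venous structures are continuous with the atria
and their boundaries are ill-defined on CT angiography.  Two auxiliary
codes exist only for the 2D blood-pool stage (interior / boundary).

All volumes are indexed ``(z, y, x)`` with 0-based voxel coordinates;
geometry is half-open in voxel units.  Physical positions are
``origin + index * spacing`` in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

BACKGROUND = 0
LV = 1
RV = 2
LA = 3
RA = 4
MYO = 5
AO = 6
PA = 7

#: Auxiliary classes of the 2D blood-pool segmentation stage only.
BLOODPOOL_INTERIOR = 8
BLOODPOOL_BOUNDARY = 9

STRUCTURE_CODES = {"LV": LV, "RV": RV, "LA": LA, "RA": RA,
                   "Myo": MYO, "Ao": AO, "PA": PA}
STRUCTURE_NAMES = {v: k for k, v in STRUCTURE_CODES.items()}
FOREGROUND_CODES = (LV, RV, LA, RA, MYO, AO, PA)
CHAMBER_CODES = (LV, RV, LA, RA)
GREAT_VESSEL_CODES = (AO, PA)
#: Codes that belong to the contrast-filled blood pool (everything bright
#: on CTA; the myocardium is muscle, not blood pool).
BLOODPOOL_CODES = (LV, RV, LA, RA, AO, PA)
ALL_CODES = (BACKGROUND,) + FOREGROUND_CODES + (BLOODPOOL_INTERIOR,
                                                BLOODPOOL_BOUNDARY)

#: Vessel meta-categories used by the graph-matching stage.
VESSEL_CATEGORIES = ("Ao", "PA", "anomalous")
CATEGORY_TO_CODE = {"Ao": AO, "PA": PA}

#: Labelling conventions: venous structures merged into their atrium.
MERGED_CONVENTIONS = {"VC": RA, "PV": LA}

# Numerical constants (see docs/methods.md).
DICE_SMOOTH = 1e-6
PROB_CLAMP = 1e-7


class GeometryError(ValueError):
    """Two volumes that must share shape/spacing do not."""


# ---------------------------------------------------------------------------
# Volume containers
# ---------------------------------------------------------------------------

def _as_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(v) for v in spacing)
    if len(s) != 3 or any(v <= 0 for v in s):
        raise ValueError(f"spacing must be 3 strictly positive values, got {spacing!r}")
    return s


def _as_origin(origin) -> tuple[float, float, float]:
    o = tuple(float(v) for v in origin)
    if len(o) != 3:
        raise ValueError(f"origin must have 3 components, got {origin!r}")
    return o


@dataclass
class IntensityVolume:
    """3D real-valued grid of CT-like intensities (arbitrary units)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("IntensityVolume data must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("IntensityVolume contains non-finite values")
        self.spacing = _as_spacing(self.spacing)
        self.origin = _as_origin(self.origin)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelVolume:
    """3D integer grid of taxonomy codes with voxel spacing and origin."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LabelVolume data must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelVolume data must be integer-typed")
        self.data = self.data.astype(np.int16, copy=False)
        bad = np.setdiff1d(np.unique(self.data), np.asarray(ALL_CODES))
        if bad.size:
            raise ValueError(f"invalid taxonomy codes present: {bad.tolist()}")
        self.spacing = _as_spacing(self.spacing)
        self.origin = _as_origin(self.origin)

    @property
    def shape(self):
        return self.data.shape

    def mask(self, *codes: int) -> np.ndarray:
        """Boolean mask of voxels carrying any of ``codes``."""
        return np.isin(self.data, codes)


def check_same_geometry(a, b) -> None:
    """Raise :class:`GeometryError` unless the two volumes share shape and spacing."""
    if a.data.shape != b.data.shape:
        raise GeometryError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    if not np.allclose(a.spacing, b.spacing, rtol=1e-6):
        raise GeometryError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


# ---------------------------------------------------------------------------
# Probability / one-hot containers (flattened N voxels x C classes)
# ---------------------------------------------------------------------------

@dataclass
class ProbabilityMap:
    """Per-voxel class probabilities ``p[i, j]`` (N voxels, C classes).

    Each row is a probability vector: values in [0, 1] summing to 1 within
    1e-6.
    """

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2:
            raise ValueError("probs must be (N, C)")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("probabilities outside [0, 1]")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1 within 1e-6")

    @property
    def n_voxels(self):
        return self.probs.shape[0]

    @property
    def n_classes(self):
        return self.probs.shape[1]


@dataclass
class OneHotLabels:
    """Per-voxel one-hot ground-truth indicators ``g[i, j]``."""

    onehot: np.ndarray

    def __post_init__(self):
        self.onehot = np.asarray(self.onehot)
        if self.onehot.ndim != 2:
            raise ValueError("onehot must be (N, C)")
        vals = np.unique(self.onehot)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("one-hot values must be 0 or 1")
        if not np.all(self.onehot.sum(axis=1) == 1):
            raise ValueError("each voxel must carry exactly one class")
        self.onehot = self.onehot.astype(np.float64)

    @classmethod
    def from_codes(cls, codes: np.ndarray, n_classes: int) -> "OneHotLabels":
        codes = np.asarray(codes).ravel()
        g = np.zeros((codes.size, n_classes), dtype=np.int8)
        g[np.arange(codes.size), codes] = 1
        return cls(g)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def dice_from_masks(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap 2|P∩T|/(|P|+|T|) of two boolean masks.

    Returns 1.0 when both masks are empty (structure correctly absent).
    """
    p = int(np.count_nonzero(pred))
    t = int(np.count_nonzero(truth))
    if p + t == 0:
        return 1.0
    inter = int(np.count_nonzero(pred & truth))
    return 2.0 * inter / (p + t)


def dice_score(pred: LabelVolume, truth: LabelVolume, code: int) -> float:
    """Dice score for one structure code between two label volumes."""
    check_same_geometry(pred, truth)
    return dice_from_masks(pred.data == code, truth.data == code)


def combined_loss(p: ProbabilityMap | np.ndarray,
                  g: OneHotLabels | np.ndarray) -> float:
    """Combined Dice + cross-entropy segmentation loss.

    ``L = (1 - (1/C) * sum_j 2*sum_i p_ij g_ij / sum_i (p_ij + g_ij))
    + (1/(N*C)) * sum_ij -g_ij ln p_ij``.

    A smoothing constant (1e-6) is added to each per-class Dice numerator
    and denominator so that a class absent from both prediction and truth
    contributes ~1 (no penalty); probabilities are clamped to
    ``[1e-7, 1]`` before the logarithm.
    """
    pa = p.probs if isinstance(p, ProbabilityMap) else np.asarray(p, dtype=np.float64)
    ga = g.onehot if isinstance(g, OneHotLabels) else np.asarray(g, dtype=np.float64)
    if pa.shape != ga.shape:
        raise ValueError(f"shape mismatch: {pa.shape} vs {ga.shape}")
    n, c = pa.shape
    if n == 0 or c == 0:
        raise ValueError("need at least one voxel and one class")
    inter = (pa * ga).sum(axis=0)
    denom = (pa + ga).sum(axis=0)
    dice_term = 1.0 - np.mean((2.0 * inter + DICE_SMOOTH) / (denom + DICE_SMOOTH))
    pc = np.clip(pa, PROB_CLAMP, 1.0)
    ce_term = float(-(ga * np.log(pc)).sum() / (n * c))
    return float(dice_term + ce_term)


def dice_loss_grad(pa: np.ndarray, ga: np.ndarray) -> np.ndarray:
    """Gradient of the Dice term of :func:`combined_loss` w.r.t. the
    probabilities (same smoothing convention as the loss)."""
    pa = np.asarray(pa, dtype=np.float64)
    ga = np.asarray(ga, dtype=np.float64)
    _, c = pa.shape
    inter = (pa * ga).sum(axis=0)
    denom = (pa + ga).sum(axis=0)
    num = 2.0 * inter + DICE_SMOOTH
    den = denom + DICE_SMOOTH
    # d/dp_ij of -(1/C) * num_j/den_j
    return -(2.0 * ga * den - num) / (den ** 2) / c


def combined_loss_grad(pa: np.ndarray, ga: np.ndarray) -> np.ndarray:
    """Gradient of :func:`combined_loss` with respect to the probabilities.

    Same smoothing/clamping conventions as the loss itself.  Note: for
    training through a softmax, the cross-entropy part is better taken
    analytically against the logits (``(p - g)/(NC)``) — see the trainer —
    because the clamp zeroes this probability-space gradient exactly where
    a class has saturated to zero.
    """
    pa = np.asarray(pa, dtype=np.float64)
    ga = np.asarray(ga, dtype=np.float64)
    n, c = pa.shape
    pc = np.clip(pa, PROB_CLAMP, 1.0)
    dce = -(ga / pc) * (pa > PROB_CLAMP) / (n * c)
    return dice_loss_grad(pa, ga) + dce
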