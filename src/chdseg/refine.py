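"""Boundary refinement of low-resolution chamber labels with the
high-resolution blood pool, and isolation of the vessel-only blood pool.

The coarse 3D net runs on a 64-cubed grid and loses boundary detail; the
2D blood-pool segmentation is at full resolution.  Refinement removes the
chamber-claimed portion of the blood pool and adds the remaining
blood-pool voxels back to their surrounding chambers by a bounded,
competitive region growth.  Whatever the growth does not claim within K
iterations — the tubular great vessels — becomes the vessel pool handed
to the skeleton/graph stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate

from .core import CHAMBER_CODES, MYO, GeometryError, LabelVolume

DEFAULT_GROWTH_ITERS = 5

_FACES = np.zeros((3, 3, 3), np.int8)
_FACES[1, 1, 0] = _FACES[1, 1, 2] = 1
_FACES[1, 0, 1] = _FACES[1, 2, 1] = 1
_FACES[0, 1, 1] = _FACES[2, 1, 1] = 1


@dataclass
class RefinementResult:
    refined_labels: LabelVolume     # chambers + Myo at full resolution
    vessel_pool: np.ndarray         # blood-pool voxels left unclaimed


def competitive_grow(labels: np.ndarray, allowed: np.ndarray,
                     codes, iterations: int,
                     structure: np.ndarray = _FACES) -> np.ndarray:
    """Grow each label into ``allowed`` voxels by simultaneous dilation.

    One iteration claims every unlabeled allowed voxel adjacent (per
    ``structure``) to at least one labeled voxel.  All labels compete in
    the same iteration; a contested voxel goes to the label with more
    adjacent claimed voxels, then to the lowest code.  Growth is monotone
    in ``iterations``.
    """
    out = labels.copy()
    for _ in range(iterations):
        free = allowed & (out == 0)
        if not free.any():
            break
        best_count = np.zeros(out.shape, np.int16)
        winner = np.zeros(out.shape, np.int16)
        for code in codes:
            cnt = correlate((out == code).astype(np.int16), structure,
                            mode="constant")
            better = free & (cnt > best_count)
            winner[better] = code
            best_count[better] = cnt[better]
        claimed = winner > 0
        if not claimed.any():
            break
        out[claimed] = winner[claimed]
    return out


def refine_chambers(bloodpool: np.ndarray, chambers_lowres: LabelVolume,
                    iterations: int = DEFAULT_GROWTH_ITERS) -> RefinementResult:
    """Refine chamber boundaries with the full-resolution blood pool.

    ``chambers_lowres`` must already be upsampled (nearest-neighbour) to
    the blood-pool grid.  The remaining blood pool (blood pool minus
    chamber voxels) is added to its surrounding chambers by
    :func:`competitive_grow`; voxels still unclaimed after ``iterations``
    form the vessel pool.
    """
    bloodpool = np.asarray(bloodpool, bool)
    if bloodpool.shape != chambers_lowres.shape:
        raise GeometryError(
            f"blood pool {bloodpool.shape} vs chambers {chambers_lowres.shape}")
    lab = chambers_lowres.data
    chambers = np.where(np.isin(lab, CHAMBER_CODES), lab, 0).astype(np.int16)
    remaining = bloodpool & (chambers == 0)
    grown = competitive_grow(chambers, remaining, CHAMBER_CODES, iterations)
    vessel_pool = remaining & (grown == 0)
    refined = grown.copy()
    refined[lab == MYO] = np.where(grown[lab == MYO] == 0, MYO,
                                   grown[lab == MYO])
    return RefinementResult(
        refined_labels=LabelVolume(refined, chambers_lowres.spacing,
                                   chambers_lowres.origin),
        vessel_pool=vessel_pool)


def refine_myocardium(myo_lowres: np.ndarray,
                      refined_chambers: LabelVolume) -> np.ndarray:
    """Myocardium mask refined against the refined chambers.

    The upsampled myocardium simply loses every voxel a refined chamber
    claimed — chambers and myocardium share most of their boundary, so
    sharpening the chambers sharpens the shell.
    """
    myo_lowres = np.asarray(myo_lowres, bool)
    if myo_lowres.shape != refined_chambers.shape:
        raise GeometryError(
            f"myo {myo_lowres.shape} vs chambers {refined_chambers.shape}")
    claimed = np.isin(refined_chambers.data, CHAMBER_CODES)
    return myo_lowres & ~claimed
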