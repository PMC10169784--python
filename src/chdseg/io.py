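"""NIfTI / JSON / YAML / CSV I/O helpers.

Volumes travel as NIfTI (.nii / .nii.gz) with the affine carrying the
voxel spacing and origin; label volumes use integer codes, intensities
float32, probability maps a 4D NIfTI with class along the fourth axis.
"""

from __future__ import annotations

import hashlib
import json

import nibabel as nib
import numpy as np

from .core import IntensityVolume, LabelVolume


def _affine(spacing, origin):
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(vol, path) -> None:
    """Write an Intensity/LabelVolume as NIfTI."""
    if isinstance(vol, LabelVolume):
        data = vol.data.astype(np.int16)
    else:
        data = vol.data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def load_intensity(path) -> IntensityVolume:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(abs(aff[k, k])) for k in range(3))
    origin = tuple(float(aff[k, 3]) for k in range(3))
    return IntensityVolume(np.asarray(img.dataobj, dtype=np.float32),
                           spacing, origin)


def load_labels(path) -> LabelVolume:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(abs(aff[k, k])) for k in range(3))
    origin = tuple(float(aff[k, 3]) for k in range(3))
    return LabelVolume(np.asarray(img.dataobj).astype(np.int16),
                       spacing, origin)


def save_probability_map(probs4d: np.ndarray, spacing, origin, path) -> None:
    """4D probability NIfTI, class as the fourth axis."""
    img = nib.Nifti1Image(np.asarray(probs4d, np.float32),
                          _affine(spacing, origin))
    nib.save(img, str(path))


def save_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def load_json(path):
    with open(path) as fh:
        return json.load(fh)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
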