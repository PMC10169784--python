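"""Synthetic CHD-like cardiac phantoms with controllable vessel topology.

Real congenital-heart-disease CT angiography cannot be redistributed, so
the pipeline is exercised on parametric phantoms: four ellipsoidal
chambers, a myocardial shell around the ventricles, and tubular great
vessels swept along spline centerlines.  Five topology variants emulate the
anatomies the graph-matching stage must distinguish:

``normal``
    Ao from LV, PA trunk from RV bifurcating into LPA/RPA.
``swapped_origins``
    transposition-like: the arterial trunks swap their ventricular origins
    while keeping their distal courses, so the proximal segments cross.
``common_trunk``
    a single arterial trunk (Ao-coded) from which the PA branches arise.
``anomalous_vein``
    normal anatomy plus an anomalous venous channel draining to RA.
``sling``
    pulmonary-sling-like: the LPA originates from the RPA and wraps
    posteriorly.

Anomalous vessels are labeled with the structure they connect to (an
anomalous vein to RA carries the RA code), mirroring the ground-truth
convention that anomalous vessels are classified by their connections.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter

from .core import (BACKGROUND, MYO, CATEGORY_TO_CODE, STRUCTURE_CODES,
                   IntensityVolume, LabelVolume, VESSEL_CATEGORIES)

ANOMALY_FLAGS = ("normal", "swapped_origins", "common_trunk",
                 "anomalous_vein", "sling")

#: Intensity model (arbitrary CT-like units): blood pool is contrast-bright,
#: myocardium intermediate, background dark.
BLOOD_INTENSITY = 300.0
MYO_INTENSITY = 150.0
BACKGROUND_INTENSITY = 0.0
DEFAULT_NOISE_SIGMA = 20.0

_CHAMBER_ORDER = ("LV", "RV", "LA", "RA")


class RasterizationError(ValueError):
    """A vessel cannot be rasterized on the requested grid."""


@dataclass
class ChamberSpec:
    """Axis-aligned ellipsoidal chamber (center and semi-axes in mm)."""
    name: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]


@dataclass
class VesselSpec:
    """Tubular vessel swept along a spline centerline.

    ``attachment`` names the chamber or previously declared vessel the
    proximal end joins; the first control point must lie inside / on it so
    the rasterized tube is adjacent to its attachment.
    """
    name: str
    category: str                       # one of VESSEL_CATEGORIES
    control_points: list[tuple[float, float, float]]   # mm, (z, y, x)
    radii: list[float]                  # mm, one per control point
    attachment: str

    def __post_init__(self):
        if self.category not in VESSEL_CATEGORIES:
            raise ValueError(f"unknown vessel category {self.category!r}")
        if len(self.control_points) < 2:
            raise ValueError(f"vessel {self.name}: need >= 2 control points")
        if len(self.radii) != len(self.control_points):
            raise ValueError(f"vessel {self.name}: one radius per control point")
        if any(r <= 0 for r in self.radii):
            raise ValueError(f"vessel {self.name}: radii must be positive")


@dataclass
class AnatomySpec:
    """Parametric description of one phantom heart."""
    chambers: dict                      # name -> ChamberSpec
    myo_thickness: float
    vessels: list                       # list[VesselSpec], declaration order
    anomaly: str = "normal"
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    seed: int = 0

    def __post_init__(self):
        if self.anomaly not in ANOMALY_FLAGS:
            raise ValueError(f"unknown anomaly flag {self.anomaly!r}")
        known = set(self.chambers)
        for v in self.vessels:
            if v.attachment not in known:
                raise ValueError(
                    f"vessel {v.name} attaches to unknown {v.attachment!r}")
            known.add(v.name)

    # -- JSON round trip ----------------------------------------------------
    def to_json(self) -> str:
        d = {
            "chambers": {k: dataclasses.asdict(c) for k, c in self.chambers.items()},
            "myo_thickness": self.myo_thickness,
            "vessels": [dataclasses.asdict(v) for v in self.vessels],
            "anomaly": self.anomaly,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AnatomySpec":
        d = json.loads(text)
        return cls(
            chambers={k: ChamberSpec(name=c["name"],
                                     center=tuple(c["center"]),
                                     semi_axes=tuple(c["semi_axes"]))
                      for k, c in d["chambers"].items()},
            myo_thickness=d["myo_thickness"],
            vessels=[VesselSpec(name=v["name"], category=v["category"],
                                control_points=[tuple(p) for p in v["control_points"]],
                                radii=list(v["radii"]),
                                attachment=v["attachment"])
                     for v in d["vessels"]],
            anomaly=d["anomaly"],
            noise_sigma=d["noise_sigma"],
            seed=d["seed"],
        )

    def resolve_code(self, vessel: VesselSpec) -> int:
        """Taxonomy code a vessel's voxels carry in the ground truth.

        Ao/PA categories map to their own codes; anomalous vessels take the
        code of the structure they (transitively) attach to.
        """
        if vessel.category in CATEGORY_TO_CODE:
            return CATEGORY_TO_CODE[vessel.category]
        att = vessel.attachment
        if att in self.chambers:
            return STRUCTURE_CODES[att]
        for v in self.vessels:
            if v.name == att:
                return self.resolve_code(v)
        raise ValueError(f"unresolvable attachment {att!r}")


@dataclass
class PhantomCase:
    """One generated phantom: spec, image, ground truth, and truth graph.

    ``chambers_truth`` is the chamber-stage reference: the ground truth
    with every vessel voxel cleared.  The merge conventions fold anomalous
    veins into RA/LA in ``truth``, but the low-resolution chamber stage
    segments chambers proper — thin vessels are the blood-pool/graph
    stages' job — so its oracle must not claim them.
    """
    spec: AnatomySpec
    image: IntensityVolume
    truth: LabelVolume
    chambers_truth: LabelVolume = None
    truth_graph: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Canonical anatomy
# ---------------------------------------------------------------------------

def _base_chambers() -> dict:
    return {
        "LV": ChamberSpec("LV", (30.0, 58.0, 34.0), (13.0, 11.0, 10.0)),
        "RV": ChamberSpec("RV", (30.0, 58.0, 60.0), (12.0, 10.0, 10.0)),
        "LA": ChamberSpec("LA", (44.0, 30.0, 36.0), (9.0, 9.0, 8.0)),
        "RA": ChamberSpec("RA", (44.0, 30.0, 62.0), (9.0, 9.0, 9.0)),
    }


def _vessels_for(anomaly: str) -> list:
    ao_distal = [(68.0, 34.0, 44.0), (84.0, 32.0, 46.0)]
    pa_trunk_end = (70.0, 44.0, 62.0)
    lpa = VesselSpec("LPA", "PA",
                     [pa_trunk_end, (72.0, 46.0, 48.0), (73.0, 48.0, 34.0)],
                     [4.0, 3.5, 3.0], "PA")
    rpa = VesselSpec("RPA", "PA",
                     [pa_trunk_end, (72.0, 44.0, 76.0), (73.0, 46.0, 88.0)],
                     [4.0, 3.5, 3.0], "PA")
    if anomaly == "common_trunk":
        trunk = VesselSpec("trunk", "Ao",
                           [(36.0, 55.0, 40.0), (52.0, 46.0, 46.0),
                            (68.0, 36.0, 50.0), (84.0, 34.0, 50.0)],
                           [7.0, 7.0, 6.0, 6.0], "LV")
        lpa_t = VesselSpec("LPA", "PA",
                           [(60.0, 41.0, 48.0), (64.0, 48.0, 36.0)],
                           [3.5, 3.0], "trunk")
        rpa_t = VesselSpec("RPA", "PA",
                           [(60.0, 41.0, 48.0), (64.0, 46.0, 64.0),
                            (66.0, 48.0, 78.0)],
                           [3.5, 3.0, 3.0], "trunk")
        return [trunk, lpa_t, rpa_t]

    if anomaly == "swapped_origins":
        ao = VesselSpec("Ao", "Ao",
                        [(36.0, 55.0, 60.0), (52.0, 44.0, 52.0)] + ao_distal,
                        [6.0, 6.0, 5.5, 5.0], "RV")
        pa = VesselSpec("PA", "PA",
                        [(36.0, 55.0, 34.0), (50.0, 50.0, 44.0),
                         (62.0, 46.0, 56.0), pa_trunk_end],
                        [6.0, 6.0, 5.5, 5.0], "LV")
    else:
        ao = VesselSpec("Ao", "Ao",
                        [(36.0, 55.0, 34.0), (52.0, 44.0, 38.0)] + ao_distal,
                        [6.0, 6.0, 5.5, 5.0], "LV")
        pa = VesselSpec("PA", "PA",
                        [(36.0, 55.0, 60.0), (50.0, 50.0, 58.0),
                         (62.0, 46.0, 60.0), pa_trunk_end],
                        [6.0, 6.0, 5.5, 5.0], "RV")

    vessels = [ao, pa]
    if anomaly == "sling":
        lpa_s = VesselSpec("LPA", "PA",
                           [(72.0, 44.0, 76.0), (74.0, 54.0, 58.0),
                            (74.0, 52.0, 40.0)],
                           [3.5, 3.0, 3.0], "RPA")
        vessels += [rpa, lpa_s]
    else:
        vessels += [lpa, rpa]
    if anomaly == "anomalous_vein":
        vein = VesselSpec("anom_vein", "anomalous",
                          [(48.0, 28.0, 64.0), (66.0, 24.0, 72.0),
                           (82.0, 22.0, 78.0)],
                          [4.0, 3.5, 3.0], "RA")
        vessels.append(vein)
    return vessels


def canonical_spec(anomaly: str = "normal", seed: int = 0,
                   jitter: float = 0.0,
                   noise_sigma: float = DEFAULT_NOISE_SIGMA) -> AnatomySpec:
    """Build an :class:`AnatomySpec` for one anomaly flag.

    ``jitter`` (mm) randomly perturbs chamber centers and vessel control
    points (a global shift plus small per-point noise) and scales radii by
    up to +/-10%, deterministically from ``seed``.
    """
    if anomaly not in ANOMALY_FLAGS:
        raise ValueError(f"unknown anomaly flag {anomaly!r}")
    chambers = _base_chambers()
    vessels = _vessels_for(anomaly)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        shift = rng.uniform(-jitter, jitter, size=3)
        rscale = rng.uniform(0.9, 1.1)
        for c in chambers.values():
            c.center = tuple(np.asarray(c.center) + shift
                             + rng.uniform(-jitter / 3, jitter / 3, size=3))
            c.semi_axes = tuple(np.asarray(c.semi_axes)
                                * rng.uniform(0.95, 1.05, size=3))
        for v in vessels:
            pts = [tuple(np.asarray(p) + shift
                         + rng.uniform(-jitter / 3, jitter / 3, size=3))
                   for p in v.control_points]
            v.control_points = pts
            v.radii = [float(r * rscale) for r in v.radii]
    return AnatomySpec(chambers=chambers, myo_thickness=4.0, vessels=vessels,
                       anomaly=anomaly, noise_sigma=noise_sigma, seed=seed)


# ---------------------------------------------------------------------------
# Centerlines and rasterization
# ---------------------------------------------------------------------------

def sample_centerline(control_points, radii, step: float = 0.5):
    """Resample a vessel centerline at ~``step`` mm arc length.

    Piecewise-cubic through the control points (chord-length
    parameterized); linear for two-point vessels.  Returns ``(points,
    radii)`` arrays with radii linearly interpolated along arc length.
    """
    pts = np.asarray(control_points, dtype=float)
    rr = np.asarray(radii, dtype=float)
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    if chord[-1] <= 0:
        raise ValueError("degenerate centerline")
    if len(pts) >= 3:
        cs = CubicSpline(chord, pts, axis=0)
        tt = np.linspace(0, chord[-1], max(int(chord[-1] / (step / 2)), 8))
        fine = cs(tt)
    else:
        tt = np.linspace(0, chord[-1], max(int(chord[-1] / (step / 2)), 8))
        fine = pts[0] + (tt / chord[-1])[:, None] * (pts[1] - pts[0])
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(fine, axis=0), axis=1))])
    n_out = max(int(arc[-1] / step) + 1, 2)
    s_out = np.linspace(0, arc[-1], n_out)
    out = np.stack([np.interp(s_out, arc, fine[:, k]) for k in range(3)], axis=1)
    # radii are defined at control points along the chord parameterization
    r_fine = np.interp(tt, chord, rr)
    r_out = np.interp(s_out, arc, r_fine)
    return out, r_out


def _rasterize_tube(mask: np.ndarray, points: np.ndarray, radii: np.ndarray,
                    spacing, name: str) -> None:
    """Set tube voxels in ``mask`` (open tube: no spherical end caps)."""
    sp = np.asarray(spacing, dtype=float)
    if radii.min() < sp.min():
        raise RasterizationError(
            f"vessel {name!r}: radius {radii.min():.2f} mm below one voxel "
            f"({sp.min():.2f} mm)")
    shape = np.asarray(mask.shape)
    for i in range(len(points) - 1):
        p0, p1 = points[i], points[i + 1]
        r = max(radii[i], radii[i + 1])
        lo = np.maximum(np.floor((np.minimum(p0, p1) - r) / sp).astype(int), 0)
        hi = np.minimum(np.ceil((np.maximum(p0, p1) + r) / sp).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.meshgrid(*(np.arange(lo[k], hi[k]) * sp[k] for k in range(3)),
                                 indexing="ij")
        v = np.stack([zz, yy, xx], axis=-1) - p0
        d = p1 - p0
        L2 = float(d @ d)
        t = (v @ d) / L2
        perp = v - t[..., None] * d
        dist = np.linalg.norm(perp, axis=-1)
        rt = radii[i] + np.clip(t, 0, 1) * (radii[i + 1] - radii[i])
        # open tube: require the foot of the perpendicular inside the segment
        sel = (dist <= rt) & (t >= 0.0) & (t <= 1.0)
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= sel


def _ellipsoid_mask(shape, spacing, center, semi_axes) -> np.ndarray:
    sp = np.asarray(spacing, dtype=float)
    axes = [((np.arange(shape[k]) * sp[k] - center[k]) / semi_axes[k]) ** 2
            for k in range(3)]
    return (axes[0][:, None, None] + axes[1][None, :, None]
            + axes[2][None, None, :]) <= 1.0


def generate_phantom(spec: AnatomySpec, shape=(96, 96, 96),
                     spacing=(1.0, 1.0, 1.0)) -> PhantomCase:
    """Rasterize a phantom heart: ground-truth labels plus noisy intensities.

    Label precedence where shapes overlap: chambers > vessels > myocardium,
    which keeps the blood pool continuous across the valve planes.
    Deterministic for a given ``(spec, shape, spacing)``.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 32 for s in shape):
        raise ValueError("phantom grid must be at least 32 voxels per axis")
    sp = tuple(float(s) for s in spacing)

    chamber_masks = {name: _ellipsoid_mask(shape, sp, c.center, c.semi_axes)
                     for name, c in spec.chambers.items()}
    chamber_union = np.zeros(shape, bool)
    for m in chamber_masks.values():
        chamber_union |= m

    myo = np.zeros(shape, bool)
    for name in ("LV", "RV"):
        if name not in spec.chambers:
            continue
        c = spec.chambers[name]
        inflated = _ellipsoid_mask(shape, sp, c.center,
                                   tuple(a + spec.myo_thickness for a in c.semi_axes))
        myo |= inflated
    myo &= ~chamber_union

    vessel_masks = []
    truth_graph = []
    for v in spec.vessels:
        pts, rr = sample_centerline(v.control_points, v.radii)
        m = np.zeros(shape, bool)
        _rasterize_tube(m, pts, rr, sp, v.name)
        vessel_masks.append((v, m))
        coarse = slice(None, None, 4)   # truth graph stores ~2 mm samples
        truth_graph.append({
            "name": v.name, "category": v.category,
            "attachment": v.attachment, "code": int(spec.resolve_code(v)),
            "centerline_mm": pts[coarse].tolist(), "radii_mm": rr[coarse].tolist(),
        })

    labels = np.zeros(shape, np.int16)
    labels[myo] = MYO
    for v, m in vessel_masks:
        labels[m] = spec.resolve_code(v)
    for name in _CHAMBER_ORDER:
        if name in chamber_masks:
            labels[chamber_masks[name]] = STRUCTURE_CODES[name]

    chamber_labels = labels.copy()
    for _, m in vessel_masks:
        chamber_labels[m & ~chamber_union] = BACKGROUND

    for v, m in vessel_masks:
        if not np.any(m & ~chamber_union):
            raise RasterizationError(
                f"vessel {v.name!r} has no voxel outside the chambers")

    blood = chamber_union.copy()
    for _, m in vessel_masks:
        blood |= m
    intensity = np.full(shape, BACKGROUND_INTENSITY, np.float32)
    intensity[labels == MYO] = MYO_INTENSITY
    intensity[blood] = BLOOD_INTENSITY
    intensity = gaussian_filter(intensity, sigma=0.6)   # partial-volume blur
    rng = np.random.default_rng(spec.seed)
    intensity = intensity + rng.normal(0.0, spec.noise_sigma,
                                       size=shape).astype(np.float32)

    return PhantomCase(spec=spec,
                       image=IntensityVolume(intensity, sp),
                       truth=LabelVolume(labels, sp),
                       chambers_truth=LabelVolume(chamber_labels, sp),
                       truth_graph=truth_graph)


def phantom_suite(n: int, seed: int = 0, shape=(96, 96, 96),
                  spacing=(1.0, 1.0, 1.0), jitter: float = 2.0) -> list:
    """Deterministic suite of ``n`` phantoms cycling through all anomaly flags."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cases = []
    for i in range(n):
        flag = ANOMALY_FLAGS[i % len(ANOMALY_FLAGS)]
        case_seed = int((seed * 1_000_003 + i) % (2 ** 31 - 1))
        spec = canonical_spec(flag, seed=case_seed, jitter=jitter)
        cases.append(generate_phantom(spec, shape=shape, spacing=spacing))
    return cases
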