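"""EMD-based matching of candidate vessel graphs against a template
library, label transfer to voxels, and region growing of leftovers.

Each graph becomes a weighted point distribution: one bin per sampled
skeleton point, Euclidean ground distance between bin positions, and bin
weight r^3 — the volume scale of the blood pool around the point, so
thick trunks dominate the match and thin spurs barely matter.  Candidate
and template distributions are compared with the earth mover's distance
after frame normalization (translation to the weighted centroid, scaling
by the weighted RMS radius), which makes matching invariant to position
and global size while preserving shape and topology cues.

The template library encodes, per anatomy variant, the canonical course
of the great vessels with category-labeled key points (Ao / PA /
anomalous).  The best (candidate, template) pair classifies every
candidate edge; voxel labels follow by nearest-sample transfer, and
vessels thinned away by smoothing are recovered by region growing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import coo_matrix
from scipy.spatial.distance import cdist

from .core import AO, PA, CATEGORY_TO_CODE, LabelVolume, VESSEL_CATEGORIES
from .refine import competitive_grow
from .skeleton import VesselGraph

_CAT_ORDER = {c: i for i, c in enumerate(VESSEL_CATEGORIES)}
_N26 = np.ones((3, 3, 3), np.int8)
_N26[1, 1, 1] = 0


class DegenerateDistributionError(ValueError):
    """All radii are zero: the graph carries no mass."""


class EmptyLibraryError(ValueError):
    """The template library has no entries."""


# ---------------------------------------------------------------------------
# Point distributions
# ---------------------------------------------------------------------------

@dataclass
class PointDistribution:
    """Weighted point set: positions (n, 3) in the normalized frame,
    weights summing to 1; plus the frame (centroid, scale) that maps
    normalized coordinates back to millimetres."""
    positions: np.ndarray
    weights: np.ndarray
    centroid: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        self.weights = np.asarray(self.weights, float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise ValueError("weights must be >= 0 with at least one > 0")

    @property
    def normalized(self) -> bool:
        return abs(float(self.weights.sum()) - 1.0) <= 1e-9


def normalize_points(points_mm: np.ndarray, raw_weights: np.ndarray) -> PointDistribution:
    """Center on the weighted centroid, scale by weighted RMS radius,
    normalize mass to 1."""
    w = np.asarray(raw_weights, float)
    total = w.sum()
    if total <= 0:
        raise DegenerateDistributionError("all weights are zero")
    wn = w / total
    pts = np.asarray(points_mm, float)
    centroid = (wn[:, None] * pts).sum(axis=0)
    centered = pts - centroid
    rms = np.sqrt((wn * (centered ** 2).sum(axis=1)).sum())
    scale = rms if rms > 1e-9 else 1.0
    return PointDistribution(centered / scale, wn, centroid, scale)


def graph_to_distribution(graph: VesselGraph) -> PointDistribution:
    """One bin per edge-sample point with raw weight r^3, frame-normalized."""
    samples = graph.all_samples()
    if not samples:
        raise ValueError("graph has no sample points")
    sp = np.asarray(graph.spacing)
    pts = np.asarray([s.position for s in samples], float) * sp
    w = np.asarray([s.radius for s in samples], float) ** 3
    if not np.any(w > 0):
        raise DegenerateDistributionError("all sample radii are zero")
    return normalize_points(pts, w)


# ---------------------------------------------------------------------------
# Earth mover's distance (transport LP)
# ---------------------------------------------------------------------------

def emd(a: PointDistribution, b: PointDistribution) -> float:
    """Minimum-cost transport between two unit-mass point distributions
    under Euclidean ground distance (solved as a linear program)."""
    for d in (a, b):
        if not d.normalized:
            raise ValueError("distributions must be normalized to mass 1")
    cost = cdist(a.positions, b.positions)
    n, m = cost.shape
    # flow variables f_ij >= 0; row sums = a.w, column sums = b.w
    rows = np.repeat(np.arange(n), m)
    cols = np.tile(np.arange(m), n) + n
    var = np.arange(n * m)
    A = coo_matrix((np.ones(2 * n * m),
                    (np.concatenate([rows, cols]), np.concatenate([var, var]))),
                   shape=(n + m, n * m)).tocsr()[:-1]   # drop one redundant row
    b_eq = np.concatenate([a.weights, b.weights])[:-1]
    res = linprog(cost.ravel(), A_eq=A, b_eq=b_eq, bounds=(0, None),
                  method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


# ---------------------------------------------------------------------------
# Template library
# ---------------------------------------------------------------------------

@dataclass
class GraphTemplate:
    """Canonical vessel-connection template with category-labeled key points.

    ``samples``/``sample_weights`` are the template's own sampled point
    set (mm, with r^3 weights); ``keypoints`` carry the Ao / PA /
    anomalous category labels used for transfer; ``connections`` lists
    key-point index pairs joined by a vessel.
    """
    id: int
    tag: str
    keypoints: np.ndarray           # (k, 3) mm
    keypoint_categories: list       # len k, entries in VESSEL_CATEGORIES
    connections: list               # [(i, j), ...]
    samples: np.ndarray             # (n, 3) mm
    sample_weights: np.ndarray      # (n,) raw r^3
    anomalous_code: int | None = None   # structure an anomalous vessel joins

    def __post_init__(self):
        self.keypoints = np.asarray(self.keypoints, float)
        if len(self.keypoint_categories) != len(self.keypoints):
            raise ValueError("every key point needs a category")
        for c in self.keypoint_categories:
            if c not in VESSEL_CATEGORIES:
                raise ValueError(f"unknown category {c!r}")
        for i, j in self.connections:
            if not (0 <= i < len(self.keypoints) and 0 <= j < len(self.keypoints)):
                raise ValueError("connection references missing key point")

    def distribution(self) -> PointDistribution:
        return normalize_points(self.samples, self.sample_weights)

    def normalized_keypoints(self) -> np.ndarray:
        d = self.distribution()
        return (self.keypoints - d.centroid) / d.scale

    def to_dict(self) -> dict:
        return {"id": self.id, "tag": self.tag,
                "keypoints": [{"xyz": p.tolist(), "category": c}
                              for p, c in zip(self.keypoints,
                                              self.keypoint_categories)],
                "connections": [list(c) for c in self.connections],
                "samples": [{"xyz": p.tolist(), "w": float(w)}
                            for p, w in zip(self.samples, self.sample_weights)],
                "anomalous_code": self.anomalous_code}

    @classmethod
    def from_dict(cls, d: dict) -> "GraphTemplate":
        return cls(id=d["id"], tag=d["tag"],
                   keypoints=np.asarray([k["xyz"] for k in d["keypoints"]]),
                   keypoint_categories=[k["category"] for k in d["keypoints"]],
                   connections=[tuple(c) for c in d["connections"]],
                   samples=np.asarray([s["xyz"] for s in d["samples"]]),
                   sample_weights=np.asarray([s["w"] for s in d["samples"]]),
                   anomalous_code=d.get("anomalous_code"))


def save_library(templates, path) -> None:
    with open(path, "w") as fh:
        json.dump([t.to_dict() for t in templates], fh, indent=1)


def load_library(path):
    with open(path) as fh:
        return [GraphTemplate.from_dict(d) for d in json.load(fh)]


def build_default_library(k_ref: int = 2):
    """Build the template library from the canonical phantom anatomies.

    Each anomaly variant's canonical (unjittered, noise-free) phantom is
    run through the same vessel-pool extraction and skeletonization that
    produces candidate graphs, so templates live in the exact
    representation space candidates do — tube ends trimmed by thinning,
    vessel roots absorbed by chamber growth, radii from the distance
    transform.  The graph at smoothing scale ``k_ref`` (or the nearest
    available scale) supplies the sampled point set; every sample doubles
    as a category-labeled key point, with the category read off the
    nearest canonical centerline.
    """
    from .phantom import ANOMALY_FLAGS, canonical_spec, generate_phantom
    from .pipeline import extract_vessel_pool
    from .skeleton import candidate_graphs
    from .unet import OracleBackend

    templates = []
    for tid, flag in enumerate(ANOMALY_FLAGS):
        spec = canonical_spec(flag, noise_sigma=0.0)
        case = generate_phantom(spec)
        oracle = OracleBackend(case.truth, case.chambers_truth)
        refined, _, _ = extract_vessel_pool(case.image, oracle, oracle)
        cands = candidate_graphs(refined.vessel_pool, case.truth.spacing)
        graph = min(cands, key=lambda g: abs(g.provenance_k - k_ref))

        cl_pts, cl_cats = [], []
        anomalous_code = None
        for tg in case.truth_graph:
            cl_pts.append(np.asarray(tg["centerline_mm"]))
            cl_cats += [tg["category"]] * len(tg["centerline_mm"])
            if tg["category"] == "anomalous":
                anomalous_code = tg["code"]
        cl_pts = np.concatenate(cl_pts)

        sp = np.asarray(graph.spacing)
        samples = np.asarray([s.position for s in graph.all_samples()]) * sp
        weights = np.asarray([s.radius for s in graph.all_samples()]) ** 3
        nearest = np.argmin(cdist(samples, cl_pts), axis=1)
        kp_cats = [cl_cats[i] for i in nearest]

        connections = []
        cursor = 0
        for e in graph.edges:
            n = len(e.samples)
            connections += [(cursor + i, cursor + i + 1) for i in range(n - 1)]
            cursor += n

        templates.append(GraphTemplate(
            id=tid, tag=flag,
            keypoints=samples.copy(), keypoint_categories=kp_cats,
            connections=connections,
            samples=samples, sample_weights=weights,
            anomalous_code=anomalous_code))
    return templates


# ---------------------------------------------------------------------------
# Matching and label transfer
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    candidate: VesselGraph
    template: GraphTemplate
    emd_value: float
    edge_categories: list          # one category per candidate edge
    all_scores: dict = field(default_factory=dict)   # (k, template id) -> EMD


def _classify_edges(candidate: VesselGraph, dist: PointDistribution,
                    template: GraphTemplate):
    """Per-edge category by majority vote of nearest template key points."""
    kp = template.normalized_keypoints()
    cats = template.keypoint_categories
    out = []
    cursor = 0
    for e in candidate.edges:
        n = len(e.samples)
        pos = dist.positions[cursor:cursor + n]
        cursor += n
        nearest = np.argmin(cdist(pos, kp), axis=1)
        votes = {}
        for i in nearest:
            votes[cats[i]] = votes.get(cats[i], 0) + 1
        best = max(votes.items(), key=lambda kv: (kv[1], -_CAT_ORDER[kv[0]]))
        out.append(best[0])
    return out


def match_graphs(candidates, library) -> MatchResult:
    """Score every (candidate, template) pair by EMD; keep the minimum.

    Ties break deterministically toward the smaller smoothing scale, then
    the lower template id.  The winning template's key points classify
    every candidate edge.
    """
    if not candidates:
        raise ValueError("no candidate graphs")
    if not library:
        raise EmptyLibraryError("template library is empty")
    scores = {}
    best = None
    for cand in candidates:
        try:
            cdist_ = graph_to_distribution(cand)
        except (ValueError, DegenerateDistributionError):
            continue
        for tpl in sorted(library, key=lambda t: t.id):
            val = emd(cdist_, tpl.distribution())
            scores[(cand.provenance_k, tpl.id)] = val
            key = (val, cand.provenance_k, tpl.id)
            if best is None or key < best[0]:
                best = (key, cand, tpl, cdist_)
    if best is None:
        raise ValueError("no candidate graph yields a valid distribution")
    _, cand, tpl, dist = best
    return MatchResult(candidate=cand, template=tpl, emd_value=best[0][0],
                       edge_categories=_classify_edges(cand, dist, tpl),
                       all_scores=scores)


def transfer_labels(match: MatchResult, vessel_pool: np.ndarray,
                    spacing=(1.0, 1.0, 1.0)) -> LabelVolume:
    """Assign Ao/PA codes to vessel-pool voxels from the matched graph.

    Every vessel-pool voxel takes the category of the nearest edge-sample
    point (Euclidean, mm); anomalous-category voxels are re-coded to the
    structure the template says they connect to.  Voxels are only labeled
    where the chosen smoothing scale kept mask coverage — the nearest
    sample within twice its inscribed radius; the rest is left for
    :func:`grow_leftovers`.
    """
    vessel_pool = np.asarray(vessel_pool, bool)
    spacing = np.asarray(spacing, float)
    samples = match.candidate.all_samples()
    pos = np.asarray([s.position for s in samples], float) * spacing
    rad = np.asarray([s.radius for s in samples], float)
    cat_per_sample = []
    for e, cat in zip(match.candidate.edges, match.edge_categories):
        cat_per_sample += [cat] * len(e.samples)
    codes = np.asarray([
        CATEGORY_TO_CODE.get(c, match.template.anomalous_code or AO)
        for c in cat_per_sample], np.int16)

    vox = np.argwhere(vessel_pool)
    vox_mm = vox * spacing
    out = np.zeros(vessel_pool.shape, np.int16)
    chunk = 200_000
    for s0 in range(0, len(vox), chunk):
        d = cdist(vox_mm[s0:s0 + chunk], pos)
        j = np.argmin(d, axis=1)
        near = d[np.arange(len(j)), j]
        ok = near <= 2.0 * np.maximum(rad[j], spacing.max())
        sel = vox[s0:s0 + chunk][ok]
        out[sel[:, 0], sel[:, 1], sel[:, 2]] = codes[j[ok]]
    return LabelVolume(out, tuple(spacing))


def grow_leftovers(labels: LabelVolume, vessel_pool: np.ndarray):
    """Absorb unlabeled vessel-pool voxels by 26-connected label growth.

    Iterates until no unlabeled voxel touches a labeled one; contested
    voxels go to the label with more adjacent claimed voxels, then the
    lowest code.  Components with no labeled contact are returned as the
    unresolved mask.
    """
    vessel_pool = np.asarray(vessel_pool, bool)
    lab = labels.data.astype(np.int16).copy()
    lab[~vessel_pool] = 0
    present = [int(c) for c in np.unique(lab) if c != 0]
    if present:
        while True:
            before = int(np.count_nonzero(lab))
            lab = competitive_grow(lab, vessel_pool, present, 1, structure=_N26)
            if int(np.count_nonzero(lab)) == before:
                break
    unresolved = vessel_pool & (lab == 0)
    return LabelVolume(lab, labels.spacing, labels.origin), unresolved
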