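"""Vessel-pool smoothing, surface-thinning skeletonization, and
conversion of skeletons into attributed centerline graphs.

Abutting vessels (Ao against PA, or a sling branch against the trunk)
often merge into one connected component of the blood pool.  Smoothing
the mask with an all-ones 3x3x3 kernel and a majority threshold, applied
1..7 times, progressively separates such contacts; each scale yields a
candidate skeleton graph, and the matching stage picks the scale whose
graph best fits a template.

Every skeleton point carries the inscribed-sphere radius r — the
Euclidean distance-transform value of the *unsmoothed* vessel pool at
that point — which the matching stage turns into the r^3 bin weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve, distance_transform_edt
from skimage.morphology import skeletonize as _sk_skeletonize

SMOOTH_KMAX = 7
#: post-convolution majority threshold: keep voxels with >= 14 of the 27
#: neighbourhood (including self) inside the mask
SMOOTH_THRESHOLD = 14
DEFAULT_SAMPLE_SPACING = 2.0    # mm


class VesselPoolVanishedError(RuntimeError):
    """Every smoothing scale produced an empty mask or skeleton."""


@dataclass
class SkeletonPoint:
    """A sampled centerline point with its inscribed-sphere radius (mm)."""
    position: tuple[float, float, float]    # voxel coordinates (z, y, x)
    radius: float                           # mm

    def position_mm(self, spacing) -> np.ndarray:
        return np.asarray(self.position) * np.asarray(spacing)


@dataclass
class VesselEdge:
    u: int
    v: int
    samples: list    # list[SkeletonPoint] ordered from u to v


@dataclass
class VesselGraph:
    """Skeleton-derived graph: endpoint/branch nodes, centerline edges."""
    nodes: list                 # list[SkeletonPoint]; index == node id
    edges: list                 # list[VesselEdge]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance_k: int = 0       # smoothing scale that produced the graph

    @property
    def n_nodes(self):
        return len(self.nodes)

    @property
    def n_edges(self):
        return len(self.edges)

    def all_samples(self):
        """Every edge sample point, in deterministic order."""
        out = []
        for e in self.edges:
            out.extend(e.samples)
        return out

    def n_components(self) -> int:
        parent = list(range(self.n_nodes))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for e in self.edges:
            ra, rb = find(e.u), find(e.v)
            if ra != rb:
                parent[ra] = rb
        return len({find(i) for i in range(self.n_nodes)})

    # -- JSON ---------------------------------------------------------------
    def to_json(self) -> str:
        sp = np.asarray(self.spacing)
        return json.dumps({
            "provenance_k": self.provenance_k,
            "nodes": [{"id": i, "xyz_mm": (np.asarray(n.position) * sp).tolist(),
                       "r_mm": n.radius} for i, n in enumerate(self.nodes)],
            "edges": [{"u": e.u, "v": e.v,
                       "samples": [{"xyz_mm": (np.asarray(s.position) * sp).tolist(),
                                    "r_mm": s.radius} for s in e.samples]}
                      for e in self.edges],
        }, indent=1)


# ---------------------------------------------------------------------------
# Smoothing and thinning
# ---------------------------------------------------------------------------

_KERNEL = np.ones((3, 3, 3), np.int16)


def smooth_mask(mask: np.ndarray, k: int,
                threshold: int = SMOOTH_THRESHOLD) -> np.ndarray:
    """k rounds of all-ones 3x3x3 convolution + majority threshold."""
    if not 1 <= k <= SMOOTH_KMAX:
        raise ValueError(f"smoothing iterations must be in 1..{SMOOTH_KMAX}, got {k}")
    out = np.asarray(mask, bool)
    for _ in range(k):
        s = convolve(out.astype(np.int16), _KERNEL, mode="constant")
        out = s >= threshold
    return out


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """One-voxel-thick medial skeleton (surface thinning, 26-connected)."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        return np.zeros_like(mask)
    return _sk_skeletonize(mask).astype(bool)


# ---------------------------------------------------------------------------
# Graph extraction
# ---------------------------------------------------------------------------

_NEIGH26 = [np.array(d) for d in np.ndindex(3, 3, 3) if tuple(d) != (1, 1, 1)]
_NEIGH26 = [d - 1 for d in _NEIGH26]


def _adjacency(voxels: np.ndarray) -> dict:
    vox_set = {tuple(v): i for i, v in enumerate(voxels)}
    adj = {i: [] for i in range(len(voxels))}
    for i, v in enumerate(voxels):
        for d in _NEIGH26:
            j = vox_set.get(tuple(v + d))
            if j is not None and j != i:
                adj[i].append(j)
    return adj


def _arc_resample_indices(chain_pos, spacing, sample_spacing):
    """Indices of chain voxels at roughly ``sample_spacing`` mm arc steps,
    always keeping both ends."""
    pos = np.asarray(chain_pos, float) * np.asarray(spacing)
    if len(pos) <= 2:
        return list(range(len(pos)))
    seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    keep = [0]
    next_s = sample_spacing
    for i in range(1, len(pos) - 1):
        if arc[i] >= next_s:
            keep.append(i)
            next_s = arc[i] + sample_spacing
    keep.append(len(pos) - 1)
    return keep


def extract_graph(skeleton: np.ndarray, distance_map: np.ndarray,
                  sample_spacing: float = DEFAULT_SAMPLE_SPACING,
                  spacing=(1.0, 1.0, 1.0), provenance_k: int = 0) -> VesselGraph:
    """Convert a skeleton voxel set into an attributed centerline graph.

    Nodes are skeleton voxels whose 26-neighbour count differs from 2
    (endpoints and branch points); maximal degree-2 chains between nodes
    become edges, resampled at ``sample_spacing`` mm along the chain with
    the inscribed-sphere radius read off ``distance_map`` at each kept
    voxel.  A pure cycle gets one anchor node (its lexicographically
    smallest voxel) and a self-loop edge.
    """
    skeleton = np.asarray(skeleton, bool)
    voxels = np.argwhere(skeleton)
    spacing = tuple(float(s) for s in spacing)
    if voxels.size == 0:
        return VesselGraph([], [], spacing, provenance_k)
    # deterministic: argwhere is lexicographic
    adj = _adjacency(voxels)

    def mk_point(i):
        v = voxels[i]
        return SkeletonPoint(tuple(int(c) for c in v),
                             float(distance_map[tuple(v)]))

    node_ids = {}      # voxel index -> graph node id
    nodes = []

    def get_node(i):
        if i not in node_ids:
            node_ids[i] = len(nodes)
            nodes.append(mk_point(i))
        return node_ids[i]

    is_node = [len(adj[i]) != 2 for i in range(len(voxels))]
    for i in range(len(voxels)):
        if is_node[i]:
            get_node(i)

    edges = []
    seen_steps = set()    # directed (from_voxel, to_voxel) steps consumed

    def walk(start, first):
        """Follow a chain from node voxel ``start`` through ``first``."""
        chain = [start, first]
        prev, cur = start, first
        while not is_node[cur]:
            nxts = [n for n in adj[cur] if n != prev]
            if not nxts:       # dead end inside a chain (shouldn't happen)
                break
            prev, cur = cur, nxts[0]
            chain.append(cur)
        return chain

    for i in sorted(node_ids.keys()):
        for j in sorted(adj[i]):
            if (i, j) in seen_steps:
                continue
            chain = walk(i, j)
            for a, b in zip(chain[:-1], chain[1:]):
                seen_steps.add((a, b))
                seen_steps.add((b, a))
            end = chain[-1]
            if not is_node[end]:
                continue       # open chain fragment; ignore
            keep = _arc_resample_indices([voxels[c] for c in chain], spacing,
                                         sample_spacing)
            samples = [mk_point(chain[kk]) for kk in keep]
            edges.append(VesselEdge(get_node(i), get_node(end), samples))

    # pure cycles: every voxel degree 2 and untouched
    visited = {a for (a, _) in seen_steps}
    for i in range(len(voxels)):
        if is_node[i] or i in visited:
            continue
        # trace the cycle from its lexicographically smallest voxel
        cyc = [i]
        prev, cur = i, sorted(adj[i])[0]
        while cur != i:
            cyc.append(cur)
            nxts = [n for n in adj[cur] if n != prev]
            prev, cur = cur, nxts[0]
        smallest = min(cyc)
        pos = cyc.index(smallest)
        cyc = cyc[pos:] + cyc[:pos] + [smallest]
        for a, b in zip(cyc[:-1], cyc[1:]):
            seen_steps.add((a, b))
            seen_steps.add((b, a))
        visited.update(cyc)
        anchor = get_node(smallest)
        keep = _arc_resample_indices([voxels[c] for c in cyc], spacing,
                                     sample_spacing)
        samples = [mk_point(cyc[kk]) for kk in keep]
        edges.append(VesselEdge(anchor, anchor, samples))

    return VesselGraph(nodes, edges, spacing, provenance_k)


# ---------------------------------------------------------------------------
# Candidate graphs over smoothing scales
# ---------------------------------------------------------------------------

def _graphs_equivalent(a: VesselGraph, b: VesselGraph, tol_vox: float = 1.0) -> bool:
    if a.n_nodes != b.n_nodes or a.n_edges != b.n_edges:
        return False
    if a.n_nodes == 0:
        return True
    pa = np.sort(np.asarray([n.position for n in a.nodes], float), axis=0)
    pb = np.sort(np.asarray([n.position for n in b.nodes], float), axis=0)
    return bool(np.all(np.linalg.norm(pa - pb, axis=1) <= tol_vox))


def candidate_graphs(vessel_pool: np.ndarray, spacing=(1.0, 1.0, 1.0),
                     sample_spacing: float = DEFAULT_SAMPLE_SPACING,
                     kmax: int = SMOOTH_KMAX,
                     threshold: int = SMOOTH_THRESHOLD) -> list:
    """One candidate graph per smoothing scale k = 1..kmax, deduplicated.

    The inscribed-sphere distance map is computed once on the unsmoothed
    vessel pool, so sample radii always reflect the true vessel calibre.
    Scales whose smoothed mask (or skeleton) is empty are skipped;
    duplicate graphs keep the smallest k.
    """
    vessel_pool = np.asarray(vessel_pool, bool)
    if not vessel_pool.any():
        raise VesselPoolVanishedError("vessel pool is empty")
    dist = distance_transform_edt(vessel_pool, sampling=spacing)
    out = []
    mask = vessel_pool
    for k in range(1, kmax + 1):
        mask = smooth_mask(mask, 1, threshold=threshold)
        if not mask.any():
            break
        skel = skeletonize(mask)
        if not skel.any():
            continue
        g = extract_graph(skel, dist, sample_spacing, spacing, provenance_k=k)
        if not any(_graphs_equivalent(g, h) for h in out):
            out.append(g)
    if not out:
        raise VesselPoolVanishedError(
            "vessel pool vanished at every smoothing scale")
    return out
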