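"""Vectorization of binary tube volumes into vascular graphs.

The stages mirror a standard vessel-extraction pipeline: a homotopy-preserving
thinning produces a one-voxel-wide skeleton; branching voxels (>= 3 skeleton
neighbors in 26-connectivity, adjacent ones merged) and end voxels (exactly one
neighbor) become graph nodes; the voxel chains between them become edges whose
centerlines are the chain coordinates.  Radii are then estimated by sphere
expansion (grow a sphere at each centerline sample until more than 10% of its
volume lies outside the vessel mask), and remaining loose ends are joined by a
distance/angle matching schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import euler_number
from skimage.morphology import skeletonize as _sk_skeletonize

from .core_graph import Centerline, VascularGraph

__all__ = [
    "BinaryVolume",
    "Skeleton",
    "betti_numbers",
    "skeletonize",
    "skeleton_to_graph",
    "estimate_radii",
    "close_gaps",
    "read_tiff_volume",
    "write_tiff_volume",
    "prune_spurs",
    "merge_degree2_nodes",
    "vectorize_volume",
    "DEFAULT_GAP_SCHEDULE",
]

#: (reference distance µm, reference angle degrees) per reconnection pass:
#: small gaps first, then progressively larger gaps with looser angles.
DEFAULT_GAP_SCHEDULE = [(5.0, 30.0), (13.0, 35.0), (21.0, 40.0), (30.0, 45.0)]

_N26 = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                 for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)])


@dataclass
class BinaryVolume:
    """3D boolean voxel mask with isotropic spacing (µm) and µm origin."""

    data: np.ndarray
    voxel_size: float = 1.0
    origin: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("BinaryVolume requires a 3D array")
        self.origin = (np.zeros(3) if self.origin is None
                       else np.asarray(self.origin, dtype=float))

    @property
    def volume_fraction(self) -> float:
        return float(self.data.mean())


@dataclass
class Skeleton:
    """One-voxel-wide centerline mask (26-connectivity), subset of foreground."""

    data: np.ndarray
    voxel_size: float = 1.0
    origin: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        self.origin = (np.zeros(3) if self.origin is None
                       else np.asarray(self.origin, dtype=float))


def read_tiff_volume(path: str, voxel_size: float = 1.0) -> BinaryVolume:
    """Load a (z, y, x) TIFF stack as a binary volume (nonzero = foreground)."""
    import tifffile

    data = np.asarray(tifffile.imread(path))
    if data.ndim != 3:
        raise ValueError(f"{path!r} is not a 3D stack (shape {data.shape})")
    return BinaryVolume(data > 0, voxel_size=voxel_size)


def write_tiff_volume(volume: BinaryVolume, path: str) -> None:
    """Write a binary volume as an 8-bit TIFF stack (255 = foreground)."""
    import tifffile

    tifffile.imwrite(path, volume.data.astype(np.uint8) * 255)


def betti_numbers(mask: np.ndarray) -> tuple[int, int]:
    """(components, independent loops) of a voxel set, 26-connectivity.

    Loops are obtained from the Euler characteristic assuming no enclosed
    cavities (true for tubular structures): b1 = b0 − χ.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0, 0
    b0 = int(ndimage.label(mask, structure=np.ones((3, 3, 3)))[1])
    chi = int(euler_number(mask, connectivity=3))
    return b0, b0 - chi


def skeletonize(volume: BinaryVolume) -> Skeleton:
    """Homotopy-preserving 3D thinning to a one-voxel-wide skeleton."""
    if not volume.data.any():
        raise ValueError("cannot skeletonize an empty volume")
    sk = _sk_skeletonize(volume.data).astype(bool)
    return Skeleton(sk, voxel_size=volume.voxel_size, origin=volume.origin)


# ---------------------------------------------------------------------------
# skeleton -> graph

def skeleton_to_graph(skeleton: Skeleton, voxel_size: float | None = None) -> VascularGraph:
    """Convert a skeleton to a vascular graph.

    Branch voxels (>= 3 skeleton neighbors) become nodes, adjacent branch
    voxels collapsing to one node at their centroid; end voxels (1 neighbor)
    become end nodes; the voxel chains in between become edges whose
    centerline points are the chain coordinates in µm.  A pure voxel loop
    containing no branch voxel gets two artificial nodes (self-loops are
    forbidden) and is stored as two parallel edges.  Diameters are placeholder
    1 µm until :func:`estimate_radii`.
    """
    vsize = float(voxel_size if voxel_size is not None else skeleton.voxel_size)
    mask = skeleton.data
    coords = np.argwhere(mask)
    vox_set = {tuple(c) for c in coords}

    def neighbors(v):
        out = []
        for off in _N26:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if w in vox_set:
                out.append(w)
        return out

    degree = {v: len(neighbors(v)) for v in vox_set}

    # merge 26-adjacent branch voxels into one node at their centroid
    branch_mask = np.zeros_like(mask)
    for v, d in degree.items():
        if d >= 3:
            branch_mask[v] = True
    labels, _ = ndimage.label(branch_mask, structure=np.ones((3, 3, 3)))

    vg = VascularGraph(voxel_size=vsize)
    node_of_voxel: dict = {}
    next_id = 0
    for lab in range(1, labels.max() + 1):
        cluster = np.argwhere(labels == lab)
        centroid = cluster.mean(axis=0) * vsize + skeleton.origin
        vg.add_node(next_id, centroid, kind="branch")
        for c in cluster:
            node_of_voxel[tuple(c)] = next_id
        next_id += 1
    for v, d in degree.items():
        if d == 1:
            vg.add_node(next_id, np.array(v, float) * vsize + skeleton.origin, kind="end")
            node_of_voxel[v] = next_id
            next_id += 1

    def to_um(chain):
        return np.asarray(chain, float) * vsize + skeleton.origin

    def add_chain_edge(chain, na, nb):
        pts = to_um(chain) if len(chain) else np.empty((0, 3))
        # snap chain ends onto the (possibly centroid-merged) node coordinates
        pts = np.vstack([vg.node_position(na)[None, :], pts, vg.node_position(nb)[None, :]])
        keep = np.ones(len(pts), dtype=bool)
        for i in range(1, len(pts)):
            if np.allclose(pts[i], pts[i - 1]):
                keep[i] = False
        pts = pts[keep]
        if len(pts) < 2:
            pts = np.vstack([vg.node_position(na), vg.node_position(nb)])
            if np.allclose(pts[0], pts[1]):
                return
        vg.add_edge(na, nb, Centerline(pts, np.ones(len(pts))))

    visited_edges = set()  # undirected voxel steps already traced

    def step_key(a, b):
        return (a, b) if a <= b else (b, a)

    # trace chains starting from every node voxel
    for v in sorted(node_of_voxel):
        for w in neighbors(v):
            if step_key(v, w) in visited_edges:
                continue
            chain = [v]
            prev, cur = v, w
            visited_edges.add(step_key(prev, cur))
            while cur not in node_of_voxel:
                chain.append(cur)
                nxt = [x for x in neighbors(cur) if x != prev
                       and step_key(cur, x) not in visited_edges]
                if not nxt:
                    break
                # prefer face neighbors over diagonals for a tight chain
                nxt.sort(key=lambda x: (sum(abs(np.array(x) - np.array(cur))), x))
                prev, cur = cur, nxt[0]
                visited_edges.add(step_key(prev, cur))
            if cur in node_of_voxel:
                chain.append(cur)
                na, nb = node_of_voxel[v], node_of_voxel[cur]
                if na == nb and len(chain) > 2:
                    # cycle re-entering the same node: split with an artificial node
                    mid = len(chain) // 2
                    mv = chain[mid]
                    vg.add_node(next_id, np.array(mv, float) * vsize + skeleton.origin,
                                kind="branch")
                    node_of_voxel[mv] = next_id
                    add_chain_edge(chain[1:mid], na, next_id)
                    add_chain_edge(chain[mid + 1:-1], next_id, nb)
                    next_id += 1
                elif na != nb:
                    add_chain_edge(chain[1:-1], na, nb)

    # pure loops without any node voxel: insert two artificial nodes
    comp_labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    for lab in range(1, n_comp + 1):
        comp_voxels = [tuple(c) for c in np.argwhere(comp_labels == lab)]
        if any(v in node_of_voxel for v in comp_voxels):
            continue
        if len(comp_voxels) < 2:
            continue
        start = min(comp_voxels)
        chain = [start]
        prev, cur = start, None
        nb0 = neighbors(start)
        if not nb0:
            continue
        cur = min(nb0)
        while cur != start:
            chain.append(cur)
            nxt = [x for x in neighbors(cur) if x != prev]
            if not nxt:
                break
            nxt.sort(key=lambda x: (sum(abs(np.array(x) - np.array(cur))), x))
            prev, cur = cur, nxt[0]
        mid = len(chain) // 2
        for idx, vv in ((next_id, start), (next_id + 1, chain[mid])):
            vg.add_node(idx, np.array(vv, float) * vsize + skeleton.origin, kind="branch")
            node_of_voxel[vv] = idx
        add_chain_edge(chain[1:mid], next_id, next_id + 1)
        add_chain_edge(chain[mid + 1:], next_id + 1, next_id)
        next_id += 2

    vg.classify_node_kinds()
    return vg


# ---------------------------------------------------------------------------
# radius estimation by sphere expansion

def _sphere_offsets(r: float) -> np.ndarray:
    n = int(np.ceil(r))
    rng = np.arange(-n, n + 1)
    X, Y, Z = np.meshgrid(rng, rng, rng, indexing="ij")
    inside = X ** 2 + Y ** 2 + Z ** 2 <= r ** 2
    return np.stack([X[inside], Y[inside], Z[inside]], axis=1)


def _radius_at(point_vox, data, max_r: float, step: float = 0.25,
               outside_tol: float = 0.10, cache: dict | None = None) -> float | None:
    """Largest radius (voxels) whose sphere keeps <= 10% of voxels outside.

    Ties resolve toward the smaller radius (the last radius that satisfied
    the criterion is returned).  None if even the center voxel is background.
    """
    c = np.round(point_vox).astype(int)
    shape = data.shape
    if np.any(c < 0) or np.any(c >= shape) or not data[tuple(c)]:
        return None
    best = 0.5
    r = step * 2
    while r <= max_r:
        offs = cache.setdefault(r, _sphere_offsets(r)) if cache is not None \
            else _sphere_offsets(r)
        pts = c[None, :] + offs
        ok = np.all((pts >= 0) & (pts < np.array(shape)[None, :]), axis=1)
        inside_count = data[pts[ok, 0], pts[ok, 1], pts[ok, 2]].sum()
        outside = 1.0 - inside_count / len(offs)  # out-of-box counts as outside
        if outside > outside_tol:
            break
        best = r
        r += step
    return best


def estimate_radii(graph: VascularGraph, volume: BinaryVolume,
                   max_radius_vox: float = 64.0) -> VascularGraph:
    """Estimate per-sample diameters by sphere expansion in the voxel mask.

    Each centerline sample gets D(s) = 2 r(s)·voxel_size where r(s) is grown
    in 0.25-voxel steps until more than 10% of the sphere volume falls outside
    the vessel mask.  Samples whose center voxel lies in the background are
    flagged and inherit the nearest valid sample's radius.
    """
    data = volume.data
    vsize = volume.voxel_size
    cache: dict = {}
    for u, v, k, d in graph.g.edges(keys=True, data=True):
        cl = d["centerline"]
        radii = np.empty(len(cl.points))
        flagged = np.zeros(len(cl.points), dtype=bool)
        for i, p in enumerate(cl.points):
            p_vox = (p - volume.origin) / vsize
            r = _radius_at(p_vox, data, max_radius_vox, cache=cache)
            if r is None:
                flagged[i] = True
                radii[i] = np.nan
            else:
                radii[i] = r
        if np.all(flagged):
            radii[:] = 0.5  # fully outside: degenerate, flagged below
        elif flagged.any():
            valid = np.where(~flagged)[0]
            for i in np.where(flagged)[0]:
                radii[i] = radii[valid[np.argmin(np.abs(valid - i))]]
        diam = 2.0 * radii * vsize
        d["centerline"] = Centerline(cl.points, diam)
        d["mean_diameter"] = d["centerline"].mean_diameter
        if flagged.any():
            d["radius_flagged"] = int(flagged.sum())
    return graph


# ---------------------------------------------------------------------------
# graph cleanup

def prune_spurs(graph: VascularGraph, min_length: float) -> VascularGraph:
    """Remove terminal spur edges shorter than ``min_length`` (µm) attached to
    branch nodes — typical skeletonization artifacts at junctions."""
    changed = True
    while changed:
        changed = False
        for u, v, k, d in list(graph.g.edges(keys=True, data=True)):
            if d["length"] >= min_length:
                continue
            for end, other in ((u, v), (v, u)):
                if graph.g.degree(end) == 1 and graph.g.degree(other) >= 3 \
                        and graph.g.nodes[end].get("role", "none") == "none":
                    graph.g.remove_edge(u, v, key=k)
                    graph.g.remove_node(end)
                    changed = True
                    break
            if changed:
                break
    graph.classify_node_kinds()
    return graph


def merge_degree2_nodes(graph: VascularGraph) -> VascularGraph:
    """Fuse pass-through (degree-2, non-boundary) nodes, concatenating the two
    incident centerlines into one edge."""
    for n in [n for n in list(graph.g.nodes())
              if graph.g.degree(n) == 2
              and graph.g.nodes[n].get("role", "none") == "none"]:
        edges = list(graph.g.edges(n, keys=True, data=True))
        if len(edges) != 2:
            continue  # double edge to the same neighbor (cycle): keep
        (u1, v1, k1, d1), (u2, v2, k2, d2) = edges
        a = v1 if u1 == n else u1
        b = v2 if u2 == n else u2
        if a == b:
            continue  # two parallel edges to one neighbor (cycle): keep the node
        cl1, cl2 = d1["centerline"], d2["centerline"]
        pn = graph.node_position(n)
        if np.linalg.norm(cl1.points[0] - pn) < np.linalg.norm(cl1.points[-1] - pn):
            cl1 = cl1.reversed()  # orient cl1 to end at n
        if np.linalg.norm(cl2.points[-1] - pn) < np.linalg.norm(cl2.points[0] - pn):
            cl2 = cl2.reversed()  # orient cl2 to start at n
        pts = np.vstack([cl1.points, cl2.points[1:]])
        dia = np.concatenate([cl1.diameters, cl2.diameters[1:]])
        graph.g.remove_node(n)
        graph.add_edge(a, b, Centerline(pts, dia))
    graph.classify_node_kinds()
    return graph


# ---------------------------------------------------------------------------
# gap closing

def _end_tangent(graph: VascularGraph, node) -> np.ndarray | None:
    """Outward unit tangent at an end node, least-squares line fit over the
    last min(5, available) centerline points of its single incident edge."""
    edges = list(graph.g.edges(node, keys=True, data=True))
    if len(edges) != 1:
        return None
    u, v, k, d = edges[0]
    cl = d["centerline"]
    pn = graph.node_position(node)
    pts = cl.points
    if np.linalg.norm(pts[0] - pn) < np.linalg.norm(pts[-1] - pn):
        pts = pts[::-1]
    tail = pts[-min(5, len(pts)):]
    centered = tail - tail.mean(axis=0)
    if np.allclose(centered, 0):
        return None
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if np.dot(direction, pn - tail.mean(axis=0)) < 0:
        direction = -direction
    return direction / np.linalg.norm(direction)


def close_gaps(graph: VascularGraph,
               schedule=None) -> VascularGraph:
    """Join loose ends by a distance/angle matching schedule.

    Per (distance d, angle θ) pass, every pair of end nodes within d whose
    outward end-tangents each deviate at most θ degrees from the line joining
    them is connected by a straight edge (diameter = mean of the two end
    diameters), nearest pairs first, each end used at most once per pass.
    Added edges carry ``synthetic=True``.
    """
    schedule = DEFAULT_GAP_SCHEDULE if schedule is None else schedule
    for dist_ref, angle_ref in schedule:
        cos_min = np.cos(np.deg2rad(angle_ref))
        ends = [n for n, d in graph.g.nodes(data=True)
                if graph.g.degree(n) == 1 and d.get("role", "none") == "none"]
        tangents = {n: _end_tangent(graph, n) for n in ends}
        candidates = []
        for i, a in enumerate(ends):
            pa, ta = graph.node_position(a), tangents[a]
            if ta is None:
                continue
            for b in ends[i + 1:]:
                pb, tb = graph.node_position(b), tangents[b]
                if tb is None:
                    continue
                gap = np.linalg.norm(pb - pa)
                if gap == 0 or gap > dist_ref:
                    continue
                u = (pb - pa) / gap
                if np.dot(ta, u) >= cos_min and np.dot(tb, -u) >= cos_min:
                    candidates.append((gap, a, b))
        used = set()
        for gap, a, b in sorted(candidates, key=lambda t: (t[0], str(t[1]), str(t[2]))):
            if a in used or b in used:
                continue
            used.update((a, b))
            da = _end_diameter(graph, a)
            db = _end_diameter(graph, b)
            cl = Centerline.straight(graph.node_position(a), graph.node_position(b),
                                     0.5 * (da + db))
            graph.add_edge(a, b, cl, synthetic=True)
        graph.classify_node_kinds()
    return graph


def _end_diameter(graph: VascularGraph, node) -> float:
    u, v, k, d = next(iter(graph.g.edges(node, keys=True, data=True)))
    cl = d["centerline"]
    pn = graph.node_position(node)
    if np.linalg.norm(cl.points[0] - pn) <= np.linalg.norm(cl.points[-1] - pn):
        return float(cl.diameters[0])
    return float(cl.diameters[-1])


def synthetic_edge_fraction(graph: VascularGraph) -> float:
    """Fraction of edges added by gap closing."""
    n = graph.n_edges
    if n == 0:
        return 0.0
    return sum(1 for _, _, d in graph.g.edges(data=True) if d.get("synthetic")) / n


def vectorize_volume(volume: BinaryVolume, gap_schedule=None,
                     spur_length: float | None = None) -> VascularGraph:
    """Full vectorization: skeletonize → graph → prune spurs → merge
    pass-through nodes → estimate radii → close gaps."""
    sk = skeletonize(volume)
    vg = skeleton_to_graph(sk)
    if spur_length is None:
        # junction spurs scale with tube radius; 5 voxels removes them
        # without touching genuine branches at capillary length scales
        spur_length = 5.0 * volume.voxel_size
    prune_spurs(vg, spur_length)
    merge_degree2_nodes(vg)
    estimate_radii(vg, volume)
    close_gaps(vg, schedule=gap_schedule)
    return vg
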