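"""Synthetic micro-vascular networks with lobular community structure.

The generator emulates the organization of an adipose-tissue fat pad: a single
main feeding artery and draining vein, arterial and venous macro-vascular
trees (diameters >= 15 µm, tapering by Murray's law) that reach every lobule,
lobules built as jittered 3D capillary lattices joined by a controlled number
of inter-lobule bridge vessels, and a handful of secondary cut-open boundaries
(a scaled-down version of a whole organ's ~26 macro-vascular openings).

Core lobules are packed tightly in a central band along the tissue's long
axis while peripheral lobules are spread out, so that box-counted vascular
density contrasts core vs periphery (≈0.06 vs ≈0.02 by default, a ≈3× ratio).
A connected capillary lattice at aspect ratio 1/8 has a hard internal-density
floor, so the contrast is realized through regional packing, not through the
internal mesh density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_graph import Centerline, VascularGraph
from .vectorization import BinaryVolume

__all__ = [
    "SynthesisParams",
    "GroundTruth",
    "generate_lobular_network",
    "voxelize_network",
    "measure_region_densities",
    "perturb_diameters",
]


@dataclass(frozen=True)
class SynthesisParams:
    """Parameters of the synthetic lobular vasculature.

    ``lobule_size_modes`` are the two mean vessel counts of the bimodal
    meso-scale size distribution; ``density_core``/``density_periphery`` are
    the target box-counted volumetric vascular densities of the two regions;
    ``aspect_ratio_target`` is the mean vessel radius-to-length ratio D/2L.
    """

    seed: int = 0
    n_lobules: int = 32
    lobule_size_modes: tuple = (250, 800)
    core_fraction: float = 1.0 / 3.0
    density_core: float = 0.06
    density_periphery: float = 0.02
    capillary_diameter_range: tuple = (4.0, 9.0)
    aspect_ratio_target: float = 1.0 / 8.0
    murray_exponent: float = 3.0
    n_secondary_boundaries: int = 8
    bridges_per_pair: object = 3  # int, or {(i, j): count} for designed bridges
    terminal_macro_diameter: float = 15.0

    def __post_init__(self):
        for rho in (self.density_core, self.density_periphery):
            if not (0.0 < rho <= 0.25):
                raise ValueError("densities must lie in (0, 0.25]")
        if self.n_lobules < 1:
            raise ValueError("need at least one lobule")


@dataclass
class GroundTruth:
    """Designed labels of a generated network (oracle for clustering
    recovery): lobule per edge and node (macro vessels labeled 'macro',
    bridges 'bridge'), core/periphery region per node, and the designed
    inter-lobule bridge counts."""

    edge_lobule: dict = field(default_factory=dict)
    node_lobule: dict = field(default_factory=dict)
    node_region: dict = field(default_factory=dict)
    bridge_counts: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------

def _lattice_mesh(rng, n_edges_target, spacing, diam_range):
    """Jittered cubic-lattice capillary mesh: a random spanning tree plus
    random extra lattice edges up to the target count.  Returns (positions
    array, edge index pairs)."""
    s = max(3, round((n_edges_target / 1.5) ** (1.0 / 3.0)))
    while 3 * s * s * (s - 1) < n_edges_target and s < 40:
        s += 1
    idx = np.arange(s ** 3).reshape(s, s, s)
    pos = np.stack(np.meshgrid(*([np.arange(s)] * 3), indexing="ij"),
                   axis=-1).reshape(-1, 3).astype(float)
    pos = pos * spacing + rng.uniform(-0.2 * spacing, 0.2 * spacing, pos.shape)
    pairs = []
    for axis in range(3):
        a = np.moveaxis(idx, axis, 0)
        pairs.append(np.stack([a[:-1].ravel(), a[1:].ravel()], axis=1))
    pairs = np.concatenate(pairs, axis=0)
    order = rng.permutation(len(pairs))
    parent = np.arange(s ** 3)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree, extra = [], []
    for i in order:
        a, b = pairs[i]
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            tree.append(i)
        else:
            extra.append(i)
    n_edges = int(np.clip(n_edges_target, len(tree), len(pairs)))
    chosen = tree + extra[: n_edges - len(tree)]
    return pos, pairs[np.array(sorted(chosen))]


def generate_lobular_network(params: SynthesisParams):
    """Generate a synthetic lobular vascular network.

    Returns (VascularGraph, GroundTruth).  Deterministic: the same seed gives
    an identical graph.
    """
    rng = np.random.default_rng(params.seed)
    p = params
    d_lo, d_hi = p.capillary_diameter_range
    d_mean = 0.5 * (d_lo + d_hi)
    spacing = d_mean / (2.0 * p.aspect_ratio_target)  # mean vessel length

    n_core = int(round(p.core_fraction * p.n_lobules)) if p.n_lobules > 1 else 1
    n_core = min(max(n_core, 0), p.n_lobules)
    n_peri = p.n_lobules - n_core
    # placement order along x: periphery | core band | periphery
    regions = (["periphery"] * (n_peri - n_peri // 2) + ["core"] * n_core
               + ["periphery"] * (n_peri // 2))

    vg = VascularGraph()
    gt = GroundTruth()
    node_id = 0
    lobule_nodes: list[list[int]] = []
    cursor = 0.0
    max_cross = 0.0
    for li in range(p.n_lobules):
        mode = p.lobule_size_modes[li % len(p.lobule_size_modes)]
        target = max(3, int(round(mode * rng.uniform(0.9, 1.1))))
        pos, pairs = _lattice_mesh(rng, target, spacing, p.capillary_diameter_range)
        diams = rng.uniform(d_lo, d_hi, len(pairs))
        vol = float(sum(np.pi * (dd / 2) ** 2
                        * np.linalg.norm(pos[a] - pos[b])
                        for (a, b), dd in zip(pairs, diams)))
        rho = p.density_core if regions[li] == "core" else p.density_periphery
        # the lobule's tissue cell: cross-section set by the core density
        # (core cells are cubes), the regional contrast realized by the cell
        # length along the tissue's long axis
        cross = (vol / p.density_core) ** (1.0 / 3.0)
        x_len = vol / (rho * cross * cross)
        extent = pos.max(axis=0) - pos.min(axis=0)
        if np.any(extent > np.array([x_len, cross, cross])):
            raise ValueError(
                f"density target {rho} infeasible for lobule {li}: mesh extent "
                f"{extent.max():.0f} µm exceeds its {x_len:.0f}×{cross:.0f}² µm cell; "
                f"achievable density <= {vol / extent.prod():.3f}")
        center = np.array([cursor + x_len / 2.0,
                           rng.uniform(-0.05, 0.05) * cross,
                           rng.uniform(-0.05, 0.05) * cross])
        cursor += x_len
        max_cross = max(max_cross, cross)
        pos = pos - 0.5 * (pos.min(axis=0) + pos.max(axis=0)) + center

        ids = []
        for q in pos:
            vg.add_node(node_id, q)
            gt.node_lobule[node_id] = li
            gt.node_region[node_id] = regions[li]
            ids.append(node_id)
            node_id += 1
        for (a, b), dd in zip(pairs, diams):
            key = vg.add_edge(ids[a], ids[b],
                              Centerline.straight(pos[a], pos[b], dd, n=3))
            eid = vg.g.edges[ids[a], ids[b], key]["id"]
            gt.edge_lobule[eid] = li
        lobule_nodes.append(ids)

    # --- inter-lobule bridges -------------------------------------------
    if isinstance(p.bridges_per_pair, dict):
        pair_counts = {tuple(sorted(k)): v for k, v in p.bridges_per_pair.items()}
    else:
        pair_counts = {(i, i + 1): int(p.bridges_per_pair)
                       for i in range(p.n_lobules - 1)}
    def _facing(ids, axis, largest, frac=0.25):
        """Nodes on the lobule face: top-``frac`` of the coordinate range."""
        coords = np.array([vg.node_position(n)[axis] for n in ids])
        k = max(1, int(len(ids) * frac))
        order = np.argsort(coords)
        chosen = order[-k:] if largest else order[:k]
        return [ids[q] for q in chosen]

    for (i, j), count in sorted(pair_counts.items()):
        for _ in range(count):
            # bridge between the facing sides, avoiding paths through a mesh
            a = int(rng.choice(_facing(lobule_nodes[i], 0, largest=True)))
            b = int(rng.choice(_facing(lobule_nodes[j], 0, largest=False)))
            dd = rng.uniform(d_lo, d_hi)
            key = vg.add_edge(a, b, Centerline.straight(
                vg.node_position(a), vg.node_position(b), dd, n=3))
            eid = vg.g.edges[a, b, key]["id"]
            gt.edge_lobule[eid] = "bridge"
        gt.bridge_counts[(i, j)] = count

    # --- arterial and venous macro trees --------------------------------
    def grow_tree(side: float, label: str):
        """Binary tree over the lobules, one terminal per lobule; returns
        (root node id, root branch diameter)."""
        offset = 0.9 * max_cross  # lateral clearance beyond the lobule cells
        # enter each lobule at the mesh face nearest the tree so the junction
        # vessel does not cut through the capillary mesh
        attach = [int(rng.choice(_facing(ids, 1, largest=side > 0, frac=0.0)))
                  for ids in lobule_nodes]

        def rec(lob_ids):
            nonlocal node_id
            if len(lob_ids) == 1:
                mesh = attach[lob_ids[0]]
                pm = vg.node_position(mesh)
                t = node_id
                vg.add_node(t, pm + np.array([0.0, side * offset, 0.0]))
                gt.node_lobule[t] = "macro"
                gt.node_region[t] = regions[lob_ids[0]]
                node_id += 1
                _macro_edge(t, mesh, p.terminal_macro_diameter, label)
                return t, p.terminal_macro_diameter
            half = len(lob_ids) // 2
            (l, dl) = rec(lob_ids[:half])
            (r, dr) = rec(lob_ids[half:])
            m = p.murray_exponent
            dd = (dl ** m + dr ** m) ** (1.0 / m)
            pm = 0.5 * (vg.node_position(l) + vg.node_position(r))
            t = node_id
            vg.add_node(t, pm + np.array([0.0, side * offset * 0.6, 0.0]))
            gt.node_lobule[t] = "macro"
            gt.node_region[t] = "periphery"
            node_id += 1
            _macro_edge(t, l, dl, label)
            _macro_edge(t, r, dr, label)
            return t, dd

        def _macro_edge(a, b, diameter, lab):
            key = vg.add_edge(a, b, Centerline.straight(
                vg.node_position(a), vg.node_position(b), diameter, n=3))
            gt.edge_lobule[vg.g.edges[a, b, key]["id"]] = lab
            return key

        return rec(list(range(p.n_lobules)))

    art_root, art_d = grow_tree(+1.0, "macro_artery")
    ven_root, ven_d = grow_tree(-1.0, "macro_vein")

    # main boundary nodes next to the roots
    def add_boundary(tree_node, diameter, role, lab):
        nonlocal node_id
        pb = vg.node_position(tree_node) + np.array([-2.0 * spacing, 0.0, 0.0])
        b = node_id
        vg.add_node(b, pb, kind="boundary", role=role)
        gt.node_lobule[b] = "macro"
        gt.node_region[b] = "periphery"
        node_id += 1
        key = vg.add_edge(b, tree_node, Centerline.straight(
            pb, vg.node_position(tree_node), diameter, n=3))
        gt.edge_lobule[vg.g.edges[b, tree_node, key]["id"]] = lab
        return b

    add_boundary(art_root, art_d, "main_artery_inlet", "macro_artery")
    add_boundary(ven_root, ven_d, "main_vein_outlet", "macro_vein")

    # secondary cut-open boundaries on the macro trees
    n_sv = (p.n_secondary_boundaries + 1) // 2
    n_sa = p.n_secondary_boundaries - n_sv
    macro_art = [n for n, lab in gt.node_lobule.items()
                 if lab == "macro" and vg.g.nodes[n].get("role", "none") == "none"
                 and any(gt.edge_lobule[d["id"]] == "macro_artery"
                         for _, _, d in vg.g.edges(n, data=True))]
    macro_ven = [n for n, lab in gt.node_lobule.items()
                 if lab == "macro" and vg.g.nodes[n].get("role", "none") == "none"
                 and any(gt.edge_lobule[d["id"]] == "macro_vein"
                         for _, _, d in vg.g.edges(n, data=True))]
    for count, pool, role, lab in ((n_sv, macro_ven, "secondary_vein_inlet", "macro_vein"),
                                   (n_sa, macro_art, "secondary_artery_outlet", "macro_artery")):
        if count and not pool:
            continue
        chosen = rng.choice(pool, size=min(count, len(pool)), replace=False) \
            if count else []
        for t in np.sort(np.asarray(chosen, dtype=int)):
            add_boundary(int(t), p.terminal_macro_diameter,  # stub vessel
                         role, lab)

    vg.classify_node_kinds()
    vg.check_euler()
    return vg, gt


# ---------------------------------------------------------------------------

def voxelize_network(graph: VascularGraph, voxel_size: float, box) -> BinaryVolume:
    """Rasterize a network into a binary voxel mask.

    ``box`` = ((xmin, ymin, zmin), (xmax, ymax, zmax)) in µm.  The mask is the
    union of spheres of local radius D(s)/2 swept along every centerline.
    Every vessel (including its radius) must lie inside the box, and the
    voxel size must resolve the thinnest vessel (voxel_size <= min D / 2).
    """
    lo = np.asarray(box[0], dtype=float)
    hi = np.asarray(box[1], dtype=float)
    shape = np.maximum(np.round((hi - lo) / voxel_size).astype(int), 1)
    data = np.zeros(shape, dtype=bool)
    if graph.n_edges == 0:
        return BinaryVolume(data, voxel_size, origin=lo)

    min_d = min(float(d["centerline"].diameters.min())
                for _, _, d in graph.g.edges(data=True))
    if voxel_size > min_d / 2.0:
        raise ValueError(f"voxel_size {voxel_size} too coarse for minimum "
                         f"diameter {min_d} (need <= {min_d / 2})")

    for u, v, k, d in graph.g.edges(keys=True, data=True):
        cl = d["centerline"]
        if np.any(cl.points < lo) or np.any(cl.points > hi):
            raise ValueError(f"edge {d['id']} extends outside the box")
        # resample at half-voxel steps for a gap-free sweep
        s = cl.arclength
        n_samp = max(2, int(np.ceil(s[-1] / (voxel_size * 0.5))) + 1)
        ss = np.linspace(0.0, s[-1], n_samp)
        pts = np.stack([np.interp(ss, s, cl.points[:, i]) for i in range(3)], axis=1)
        rads = np.interp(ss, s, cl.diameters) / 2.0
        for q, r in zip(pts, rads):
            c = (q - lo) / voxel_size
            rv = r / voxel_size
            lo_i = np.maximum(np.floor(c - rv).astype(int), 0)
            hi_i = np.minimum(np.ceil(c + rv).astype(int) + 1, shape)
            if np.any(lo_i >= hi_i):
                continue
            xs = [np.arange(lo_i[a], hi_i[a]) for a in range(3)]
            X, Y, Z = np.meshgrid(*xs, indexing="ij")
            # voxel centers sit at integer coordinates
            ball = ((X - c[0]) ** 2 + (Y - c[1]) ** 2
                    + (Z - c[2]) ** 2) <= rv ** 2
            data[lo_i[0]:hi_i[0], lo_i[1]:hi_i[1], lo_i[2]:hi_i[2]] |= ball
    return BinaryVolume(data, voxel_size, origin=lo)


def measure_region_densities(graph: VascularGraph, ground_truth: GroundTruth,
                             box_width: float = 200.0) -> tuple[float, float]:
    """Box-counted vascular density of the core band vs the periphery.

    Boxes tile the lobule rod (the y/z extent of the capillary meshes, so the
    flanking macro trees do not dilute the estimate); a box belongs to the
    core when its center falls in the core lobules' x band.  Returns the two
    band means over all boxes, including empty ones.
    """
    mesh = [n for n, l in ground_truth.node_lobule.items() if l != "macro"]
    pos = np.array([graph.node_position(n) for n in mesh])
    core_x = np.array([graph.node_position(n)[0] for n in mesh
                       if ground_truth.node_region[n] == "core"])
    if core_x.size == 0 or core_x.size == len(mesh):
        raise ValueError("need both core and periphery lobules to compare")
    mids_all, vols_all = [], []
    for _, _, d in graph.g.edges(data=True):
        cl = d["centerline"]
        s = cl.arclength
        n = max(2, int(np.ceil(s[-1] / 2.0)) + 1)
        ss = np.linspace(0, s[-1], n)
        pts = np.stack([np.interp(ss, s, cl.points[:, i]) for i in range(3)], axis=1)
        dia = np.interp(ss, s, cl.diameters)
        mids = 0.5 * (pts[1:] + pts[:-1])
        dl = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        mids_all.append(mids)
        vols_all.append(np.pi * (0.25 * (dia[1:] + dia[:-1])) ** 2 * dl)
    mids = np.concatenate(mids_all)
    vols = np.concatenate(vols_all)
    sel = ((mids[:, 1] > pos[:, 1].min()) & (mids[:, 1] < pos[:, 1].max())
           & (mids[:, 2] > pos[:, 2].min()) & (mids[:, 2] < pos[:, 2].max()))
    mids, vols = mids[sel], vols[sel]
    lo, hi = mids.min(axis=0), mids.max(axis=0)
    nb = np.maximum(np.ceil((hi - lo) / box_width).astype(int), 1)
    idx = np.minimum(((mids - lo) / box_width).astype(int), nb - 1)
    acc = np.bincount(np.ravel_multi_index(idx.T, nb), weights=vols,
                      minlength=int(np.prod(nb))) / box_width ** 3
    cx = lo[0] + (np.arange(np.prod(nb)) // (nb[1] * nb[2])) * box_width + box_width / 2
    in_core = (cx > core_x.min()) & (cx < core_x.max())
    return float(acc[in_core].mean()), float(acc[~in_core].mean())


def perturb_diameters(graph: VascularGraph, relative_sigma: float,
                      seed: int) -> VascularGraph:
    """Multiply each edge's diameters by an independent factor
    max(ε, 1 + N(0, relative_sigma)); topology is unchanged.  Emulates
    segmentation errors in the radius estimation."""
    if relative_sigma < 0:
        raise ValueError("relative_sigma must be >= 0")
    out = graph.copy()
    if relative_sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    edges = sorted(out.g.edges(keys=True, data=True), key=lambda e: e[3]["id"])
    factors = np.maximum(0.05, 1.0 + rng.normal(0.0, relative_sigma, len(edges)))
    for (u, v, k, d), f in zip(edges, factors):
        cl = d["centerline"]
        d["centerline"] = Centerline(cl.points, cl.diameters * f)
        d["mean_diameter"] = d["centerline"].mean_diameter
        d["perturbation_factor"] = float(f)
    return out
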