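"""Multi-scale community analysis of vascular graphs.

Communities are found by seeded Louvain modularity optimization on one of
five edge-weight schemes: w_0 unweighted, w_1 Euclidean node distance,
w_2 centerline (geodesic) arclength, w_3 hydrodynamic resistance and
w_4 hydrodynamic conductance.  From a partition the community adjacency
graphs are derived — structural (bridging-vessel counts) and bi-functional
(directed exchange fluxes Q_{ci,cj}) — together with scaling of external vs
internal vessel counts, eigenvector centrality, authority/hub scores with a
core/periphery split, arterial/venous generation domains, box-counted
vascular density, bifurcation angles and the core-vs-periphery rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .core_graph import VascularGraph

__all__ = [
    "WEIGHT_SCHEMES",
    "assign_edge_weights",
    "cluster_communities",
    "CommunityPartition",
    "CommunityGraph",
    "build_community_graphs",
    "connectivity_scaling",
    "graph_features",
    "GenerationMap",
    "generation_domains",
    "vascular_density",
    "bifurcation_angles",
    "compare_regions",
    "modularity",
]

WEIGHT_SCHEMES = ("w_0", "w_1", "w_2", "w_3", "w_4")


def assign_edge_weights(graph: VascularGraph, scheme: str) -> VascularGraph:
    """Set the named weight on every edge (in place).

    w_0 ≡ 1, w_1 = Euclidean distance between the endpoints, w_2 = centerline
    arclength, w_3 = resistance, w_4 = conductance (w_3·w_4 = 1).
    """
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weight scheme {scheme!r}; use one of {WEIGHT_SCHEMES}")
    for u, v, k, d in graph.g.edges(keys=True, data=True):
        if scheme == "w_0":
            d[scheme] = 1.0
        elif scheme == "w_1":
            d[scheme] = float(np.linalg.norm(graph.node_position(u) - graph.node_position(v)))
        elif scheme == "w_2":
            d[scheme] = float(d["centerline"].length)
        else:
            if "resistance" not in d:
                raise ValueError(
                    f"edge {d.get('id')}: resistance required for {scheme} "
                    "(run hemodynamics.compute_resistances first)")
            d[scheme] = float(d["resistance"] if scheme == "w_3" else 1.0 / d["resistance"])
    return graph


@dataclass
class CommunityPartition:
    """Node partition with bookkeeping for connectivity scaling.

    ``node_community`` maps node → community id; an edge belongs to a
    community when both endpoints do, otherwise it is a bridging vessel.
    ``n_iv[c]`` counts internal vessels, ``n_ev_pairs[(ci, cj)]`` bridging
    vessels per community pair (each bridge counted once), ``n_ev[c]`` the
    per-community totals.
    """

    node_community: dict
    scheme: str = "w_0"
    modularity: float = float("nan")
    n_iv: dict = field(default_factory=dict)
    n_ev_pairs: dict = field(default_factory=dict)
    n_ev: dict = field(default_factory=dict)

    @classmethod
    def from_graph(cls, graph: VascularGraph, node_community: dict,
                   scheme: str = "w_0", modularity_value: float = float("nan")):
        part = cls(dict(node_community), scheme, modularity_value)
        comms = set(part.node_community.values())
        part.n_iv = {c: 0 for c in comms}
        part.n_ev = {c: 0 for c in comms}
        for u, v, k, d in graph.g.edges(keys=True, data=True):
            cu, cv = part.node_community[u], part.node_community[v]
            if cu == cv:
                part.n_iv[cu] += 1
            else:
                key = tuple(sorted((cu, cv), key=repr))
                part.n_ev_pairs[key] = part.n_ev_pairs.get(key, 0) + 1
                part.n_ev[cu] += 1
                part.n_ev[cv] += 1
        return part

    @classmethod
    def from_counts(cls, n_iv, n_ev):
        """Partition stub carrying only the per-community counts (for
        scaling analysis of externally supplied tables)."""
        part = cls(node_community={})
        part.n_iv = {i: int(a) for i, a in enumerate(n_iv)}
        part.n_ev = {i: int(b) for i, b in enumerate(n_ev)}
        return part

    @property
    def communities(self):
        return sorted(self.n_iv, key=repr)

    @property
    def n_communities(self) -> int:
        return len(set(self.node_community.values()) or self.n_iv)


def _collapsed(graph: VascularGraph, scheme: str) -> nx.Graph:
    """Simple weighted graph with parallel-edge weights summed (equivalent
    under the modularity quality function)."""
    g = nx.Graph()
    g.add_nodes_from(graph.g.nodes())
    for u, v, k, d in graph.g.edges(keys=True, data=True):
        w = d.get(scheme)
        if w is None:
            raise ValueError(f"edge {d.get('id')} lacks weight {scheme!r}")
        if g.has_edge(u, v):
            g[u][v]["weight"] += w
        else:
            g.add_edge(u, v, weight=w)
    return g


def modularity(graph: VascularGraph, node_community: dict, scheme: str = "w_0") -> float:
    """Weighted Newman modularity of a node partition."""
    g = _collapsed(graph, scheme)
    comms: dict = {}
    for n, c in node_community.items():
        comms.setdefault(c, set()).add(n)
    return nx.community.modularity(g, list(comms.values()), weight="weight")


def cluster_communities(graph: VascularGraph, scheme: str = "w_0",
                        resolution: float = 1.0, seed: int = 0,
                        invert_weights: bool = False) -> CommunityPartition:
    """Louvain community detection on the chosen weight scheme.

    Greedy modularity optimization (local moves + graph aggregation to a
    fixed point), deterministic for a given seed.  ``invert_weights`` uses
    1/w instead, for treating distance-like weights as dissimilarities.
    """
    assign_edge_weights(graph, scheme)
    g = _collapsed(graph, scheme)
    if invert_weights:
        for u, v, d in g.edges(data=True):
            d["weight"] = 1.0 / d["weight"]
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed)
    node_comm = {}
    # stable community ids: order by smallest member representation
    for ci, members in enumerate(sorted(comms, key=lambda s: repr(sorted(s, key=repr)))):
        for n in members:
            node_comm[n] = ci
    q = nx.community.modularity(g, comms, weight="weight", resolution=resolution)
    return CommunityPartition.from_graph(graph, node_comm, scheme, q)


# ---------------------------------------------------------------------------
# community graphs

@dataclass
class CommunityGraph:
    """Adjacency graph of the communities.

    ``structural`` is an undirected graph whose edge weight is the number of
    bridging vessels; ``functional`` a directed graph with the exchange flux
    Q_{ci,cj} on each arc (present only when a flow solution was supplied).
    Node attributes: centroid, vessel volume, vascular density, arterial
    fraction and filling time, when the inputs to compute them are available.
    """

    structural: nx.Graph
    functional: nx.DiGraph | None = None

    def structural_weight(self, ci, cj) -> int:
        return self.structural[ci][cj]["weight"]

    def flux(self, ci, cj) -> float:
        if self.functional is None:
            raise ValueError("no functional (flux) weights on this community graph")
        return self.functional[ci][cj]["flux"] if self.functional.has_edge(ci, cj) else 0.0


def build_community_graphs(graph: VascularGraph, partition: CommunityPartition,
                           flow=None, functional: bool = False) -> CommunityGraph:
    """Build structural (and optionally bi-functional) community graphs.

    Structural weight(ci, cj) = number of bridging vessels K_{ci,cj};
    functional arcs carry Q_{ci,cj} = Σ of |flux| over bridges directed
    ci → cj, requiring a FlowSolution.
    """
    if functional and flow is None:
        raise ValueError("functional community graph requested without a flow solution")
    nc = partition.node_community
    gs = nx.Graph()
    comms = sorted(set(nc.values()), key=repr)
    gs.add_nodes_from(comms)
    bridges: dict = {}
    for u, v, k, d in graph.g.edges(keys=True, data=True):
        cu, cv = nc[u], nc[v]
        if cu == cv:
            continue
        key = tuple(sorted((cu, cv), key=repr))
        bridges.setdefault(key, []).append((u, v, d))
        if gs.has_edge(*key):
            gs[key[0]][key[1]]["weight"] += 1
        else:
            gs.add_edge(*key, weight=1)

    # per-community attributes
    centroids: dict = {c: [] for c in comms}
    volumes: dict = {c: 0.0 for c in comms}
    for n, c in nc.items():
        centroids[c].append(graph.node_position(n))
    for u, v, k, d in graph.g.edges(keys=True, data=True):
        if nc[u] == nc[v]:
            volumes[nc[u]] += d["centerline"].volume
    for c in comms:
        pts = np.asarray(centroids[c])
        gs.nodes[c]["centroid"] = tuple(pts.mean(axis=0)) if len(pts) else (np.nan,) * 3
        gs.nodes[c]["vessel_volume"] = volumes[c]
        if len(pts) > 1:
            extent = np.maximum(pts.max(axis=0) - pts.min(axis=0), 1.0)
            gs.nodes[c]["vascular_density"] = volumes[c] / float(np.prod(extent))

    gf = None
    if functional:
        from .hemodynamics import intercommunity_fluxes
        gf = nx.DiGraph()
        gf.add_nodes_from(comms)
        for (ci, cj), q in intercommunity_fluxes(graph, nc, flow).items():
            gf.add_edge(ci, cj, flux=q)
    return CommunityGraph(gs, gf)


# ---------------------------------------------------------------------------
# connectivity scaling

def connectivity_scaling(partition: CommunityPartition):
    """Power-law scaling of external vs internal vessel counts.

    Least-squares slope s of log N_ev against log N_iv over communities;
    weak communities (strongly inter-connected) have 2/3 ≤ s ≤ 1, strong
    (weakly connected) s < 2/3, super-connected s > 1.  Returns a dict with
    the slope, its standard error, the classification, and the zero-intercept
    variant of the regression.
    """
    niv = np.array([partition.n_iv[c] for c in partition.communities], float)
    nev = np.array([partition.n_ev.get(c, 0) for c in partition.communities], float)
    ok = (niv > 0) & (nev > 0)
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 communities with N_iv > 0 and N_ev > 0, "
                         f"have {int(ok.sum())}")
    x, y = np.log(niv[ok]), np.log(nev[ok])
    res = scipy.stats.linregress(x, y)
    s = float(res.slope)
    s0 = float(np.dot(x, y) / np.dot(x, x))  # zero-offset variant
    if s < 2.0 / 3.0:
        cls = "strong"
    elif s <= 1.0:
        cls = "weak"
    else:
        cls = "super-connected"
    return dict(slope=s, stderr=float(res.stderr), intercept=float(res.intercept),
                slope_zero_intercept=s0, n_communities=int(ok.sum()), classification=cls)


# ---------------------------------------------------------------------------
# centrality, authority/hub, core/periphery

def graph_features(community_graph: CommunityGraph, authority_threshold: float = 0.04,
                   tol: float = 1e-10, max_iter: int = 10_000):
    """Eigenvector centrality, authority/hub scores and core/periphery labels.

    Centrality is the principal eigenvector (L¹-normalized, nonnegative) of
    the weighted structural adjacency; authority and hub come from power
    iteration of AᵀA and AAᵀ on the directed flux graph.  Communities with
    authority above the threshold form the core.  Disconnected structural
    graphs are reduced to their largest component (flagged in the output).
    """
    gs = community_graph.structural
    flagged = False
    if gs.number_of_nodes() == 0:
        raise ValueError("empty community graph")
    if not nx.is_connected(gs) and gs.number_of_nodes() > 1:
        flagged = True
        gs = gs.subgraph(max(nx.connected_components(gs), key=len))
    nodes = sorted(gs.nodes(), key=repr)
    A = nx.to_numpy_array(gs, nodelist=nodes, weight="weight")
    centrality = _power_iteration(A, tol, max_iter)

    auth = hub = None
    if community_graph.functional is not None:
        gf = community_graph.functional.subgraph(nodes)
        F = nx.to_numpy_array(gf, nodelist=nodes, weight="flux")
        auth = _power_iteration(F.T @ F, tol, max_iter)
        hub = _power_iteration(F @ F.T, tol, max_iter)

    out = dict(
        centrality={n: float(c) for n, c in zip(nodes, centrality)},
        authority={n: float(a) for n, a in zip(nodes, auth)} if auth is not None else None,
        hub={n: float(h) for n, h in zip(nodes, hub)} if hub is not None else None,
        reduced_to_largest_component=flagged,
    )
    scores = out["authority"] if out["authority"] is not None else out["centrality"]
    out["core"] = {n: scores[n] > authority_threshold for n in scores}
    return out


def _power_iteration(M: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    n = M.shape[0]
    if n == 1:
        return np.ones(1)
    # diagonal shift keeps the Perron vector but suppresses the ±λ
    # oscillation of bipartite adjacencies
    M = M + np.eye(n) * max(M.max(), 1e-300)
    x = np.full(n, 1.0 / n)
    for it in range(max_iter):
        y = M @ x
        s = y.sum()
        if s <= 0:
            return np.full(n, 1.0 / n)  # no flux / empty adjacency
        y /= s
        if np.abs(y - x).max() < tol:
            return y
        x = y
    gap = float(np.abs(M @ x - x * (x @ M @ x) / (x @ x)).max())
    raise RuntimeError(f"power iteration did not converge in {max_iter} "
                       f"iterations (residual ~{gap:.2e})")


# ---------------------------------------------------------------------------
# arterial / venous generation domains

@dataclass
class GenerationMap:
    """Per-edge generation numbers from the arterial and venous macro
    subgraphs, derived arterial/venous domain labels, and per-community
    arterial fractions."""

    edge_generation_artery: dict
    edge_generation_vein: dict
    edge_domain: dict
    unassigned: list


def generation_domains(graph: VascularGraph, arterial_macro: VascularGraph,
                       venous_macro: VascularGraph) -> GenerationMap:
    """Breadth-first generation numbers from each macro subgraph.

    Macro edges are generation 0; every vessel sharing a node with the
    current front gets the next generation, looped until exhaustion.  A
    vessel belongs to the arterial domain when it is closer (smaller
    generation) to the arterial macro network, ties going to the venous
    domain; vessels unreachable from both are reported as unassigned.
    """
    if arterial_macro.n_edges == 0 or venous_macro.n_edges == 0:
        raise ValueError("both macro subgraphs must be nonempty")

    def bfs_generations(macro: VascularGraph) -> dict:
        gen: dict = {}
        front_nodes = set()
        macro_ids = {d["id"] for _, _, d in macro.g.edges(data=True)}
        for u, v, k, d in graph.g.edges(keys=True, data=True):
            if d["id"] in macro_ids:
                gen[d["id"]] = 0
                front_nodes.update((u, v))
        level = 0
        while True:
            level += 1
            new_nodes = set()
            advanced = False
            for n in front_nodes:
                for u, v, k, d in graph.g.edges(n, keys=True, data=True):
                    if d["id"] not in gen:
                        gen[d["id"]] = level
                        new_nodes.update((u, v))
                        advanced = True
            if not advanced:
                break
            front_nodes = new_nodes
        return gen

    gen_a = bfs_generations(arterial_macro)
    gen_v = bfs_generations(venous_macro)
    domain: dict = {}
    unassigned = []
    for _, _, d in graph.g.edges(data=True):
        eid = d["id"]
        ga, gv = gen_a.get(eid), gen_v.get(eid)
        if ga is None and gv is None:
            unassigned.append(eid)
            domain[eid] = "unassigned"
        elif gv is None or (ga is not None and ga < gv):
            domain[eid] = "arterial"
        else:
            domain[eid] = "venous"
        d["generation_from_artery"] = np.inf if ga is None else ga
        d["generation_from_vein"] = np.inf if gv is None else gv
        d["domain"] = domain[eid]
    return GenerationMap(gen_a, gen_v, domain, unassigned)


def arterial_fraction(graph: VascularGraph, partition: CommunityPartition,
                      genmap: GenerationMap) -> dict:
    """Fraction of each community's vessels in the arterial domain."""
    counts: dict = {}
    arts: dict = {}
    nc = partition.node_community
    for u, v, k, d in graph.g.edges(keys=True, data=True):
        if nc.get(u) != nc.get(v) or u not in nc:
            continue
        c = nc[u]
        counts[c] = counts.get(c, 0) + 1
        if genmap.edge_domain.get(d["id"]) == "arterial":
            arts[c] = arts.get(c, 0) + 1
    return {c: arts.get(c, 0) / n for c, n in counts.items() if n > 0}


# ---------------------------------------------------------------------------
# morphometrics

def vascular_density(graph: VascularGraph, box_widths=(100.0, 200.0, 300.0, 400.0),
                     step: float = 2.0):
    """Box-counted volumetric vascular density distributions.

    The tissue bounding box is tiled by cubes of each width; density per box
    is the vessel lumen volume of the centerline pieces inside it divided by
    the box volume (centerlines are subdivided into <= ``step`` µm pieces
    assigned to the box containing their midpoint).  Returns
    {width: densities array over boxes}.
    """
    import warnings

    pts_all, vol_all = [], []
    for _, _, d in graph.g.edges(data=True):
        cl = d["centerline"]
        s = cl.arclength
        n = max(2, int(np.ceil(s[-1] / step)) + 1)
        ss = np.linspace(0, s[-1], n)
        pts = np.stack([np.interp(ss, s, cl.points[:, i]) for i in range(3)], axis=1)
        dia = np.interp(ss, s, cl.diameters)
        mids = 0.5 * (pts[1:] + pts[:-1])
        dl = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        area = np.pi * (0.5 * 0.5 * (dia[1:] + dia[:-1])) ** 2
        pts_all.append(mids)
        vol_all.append(area * dl)
    out: dict = {}
    if not pts_all:
        for w in box_widths:
            out[w] = np.zeros(1)
        return out
    mids = np.concatenate(pts_all)
    vols = np.concatenate(vol_all)
    lo = mids.min(axis=0)
    hi = mids.max(axis=0)
    for w in box_widths:
        n_boxes = np.maximum(np.ceil((hi - lo) / w).astype(int), 1)
        if np.all(n_boxes == 1) and np.any(hi - lo < w):
            warnings.warn(f"box width {w} exceeds tissue extent; single box")
        idx = np.minimum(((mids - lo) / w).astype(int), n_boxes - 1)
        flat = np.ravel_multi_index(idx.T, n_boxes)
        acc = np.bincount(flat, weights=vols, minlength=int(np.prod(n_boxes)))
        out[w] = acc / float(w ** 3)
    return out


def bifurcation_angles(graph: VascularGraph, fit_points: int = 5):
    """Branching angles φ₁, φ₂ at every degree-3 node.

    The parent branch is the one with the largest mean diameter; φᵢ is the
    angle between the parent tangent pointing INTO the node and daughter
    tangent i pointing OUT of it, in (0°, 180°] (a straight-through daughter
    gives 180°).  Returns (DataFrame of node, phi1, phi2; count of higher-
    degree junctions excluded).
    """
    rows = []
    n_higher = 0
    for n in graph.g.nodes():
        deg = graph.g.degree(n)
        if deg != 3:
            if deg > 3:
                n_higher += 1
            continue
        edges = list(graph.g.edges(n, keys=True, data=True))
        tangents, diams = [], []
        pn = graph.node_position(n)
        for u, v, k, d in edges:
            cl = d["centerline"]
            pts = cl.points
            if np.linalg.norm(pts[-1] - pn) < np.linalg.norm(pts[0] - pn):
                pts = pts[::-1]  # orient away from the node
            head = pts[: min(fit_points, len(pts))]
            centered = head - head.mean(axis=0)
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            t = vt[0]
            if np.dot(t, head[-1] - pn) < 0:
                t = -t
            tangents.append(t / np.linalg.norm(t))  # outgoing direction
            diams.append(d["mean_diameter"])
        parent = int(np.argmax(diams))
        # the parent tangent oriented into the node is the negation of its
        # outgoing direction, so the angle with an outgoing daughter is
        # measured between the two outgoing directions: straight-through
        # continuation gives 180 deg.
        t_parent = tangents[parent]
        phis = []
        for i, t in enumerate(tangents):
            if i == parent:
                continue
            cosang = np.clip(np.dot(t_parent, t), -1.0, 1.0)
            phis.append(float(np.degrees(np.arccos(cosang))))
        phis = sorted(phis)
        rows.append(dict(node=n, phi1=phis[0], phi2=phis[1]))
    return pd.DataFrame(rows), n_higher


def compare_regions(values_core, values_periphery):
    """Kruskal–Wallis rank-sum test (tie-corrected) between two regions.

    Returns (H statistic, p-value); identical samples give H = 0, p = 1.
    """
    a = np.asarray(values_core, float)
    b = np.asarray(values_periphery, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if np.array_equal(np.sort(a), np.sort(b)) and np.unique(a).size == 1:
        return 0.0, 1.0
    res = scipy.stats.kruskal(a, b)
    return float(res.statistic), float(res.pvalue)
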