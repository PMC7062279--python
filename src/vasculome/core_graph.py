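"""Spatial vascular-graph data model, validation, Laplacians and file I/O.

A vascular network is represented as an undirected multigraph whose nodes are
vessel bifurcations, endpoints or boundary (cut-open) vessels, with 3D
coordinates in micrometres, and whose edges are vessel segments carrying a
sampled centerline with per-sample diameters.  Parallel edges between the same
node pair are legitimate (anastomoses) and are kept, never merged; self-loops
are forbidden.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Centerline",
    "VascularGraph",
    "GraphValidationError",
    "build_graph",
    "laplacian",
    "extract_macro_subgraph",
    "read_graph",
    "write_graph",
]

NODE_KINDS = ("branch", "end", "boundary")
BOUNDARY_ROLES = (
    "main_artery_inlet",
    "main_vein_outlet",
    "secondary_vein_inlet",
    "secondary_artery_outlet",
    "none",
)


class GraphValidationError(ValueError):
    """Raised when a vascular graph violates a structural invariant."""


@dataclass
class Centerline:
    """Ordered 3D vessel centerline with per-sample diameters (µm).

    ``points`` is an (n, 3) array, ``diameters`` an (n,) array; n >= 2 and all
    diameters strictly positive.
    """

    points: np.ndarray
    diameters: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.diameters = np.asarray(self.diameters, dtype=float).ravel()
        if self.points.shape[0] < 2:
            raise GraphValidationError("centerline needs >= 2 points")
        if self.diameters.shape[0] != self.points.shape[0]:
            raise GraphValidationError("one diameter per centerline point required")
        if not np.all(self.diameters > 0):
            raise GraphValidationError("all centerline diameters must be > 0")

    @property
    def arclength(self) -> np.ndarray:
        """Cumulative point-to-point Euclidean arclength, arclength[0] = 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    @property
    def chord(self) -> float:
        """Euclidean end-to-end distance."""
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    @property
    def mean_diameter(self) -> float:
        return float(np.mean(self.diameters))

    @property
    def volume(self) -> float:
        """Vessel lumen volume, trapezoidal in cross-section area (µm³)."""
        area = np.pi * (self.diameters / 2.0) ** 2
        return float(np.trapezoid(area, self.arclength))

    def reversed(self) -> "Centerline":
        return Centerline(self.points[::-1].copy(), self.diameters[::-1].copy())

    @staticmethod
    def straight(p0, p1, diameter: float, n: int = 2) -> "Centerline":
        t = np.linspace(0.0, 1.0, max(2, n))[:, None]
        pts = np.asarray(p0, float)[None, :] * (1 - t) + np.asarray(p1, float)[None, :] * t
        return Centerline(pts, np.full(pts.shape[0], float(diameter)))

    def __eq__(self, other) -> bool:  # field-by-field, exact
        return (
            isinstance(other, Centerline)
            and self.points.shape == other.points.shape
            and np.array_equal(self.points, other.points)
            and np.array_equal(self.diameters, other.diameters)
        )


@dataclass
class VascularGraph:
    """Undirected spatial multigraph of vessel segments.

    Thin wrapper around :class:`networkx.MultiGraph`.  Node attributes:
    ``pos`` (3-tuple, µm), ``kind`` (branch|end|boundary), ``role`` (boundary
    role or "none").  Edge attributes: ``id`` (unique int), ``centerline``
    (:class:`Centerline`), ``length``, ``mean_diameter``, plus optional
    weights ``w_0``..``w_4``, ``resistance``, ``conductance``, ``community``,
    ``synthetic`` and generation numbers.
    """

    g: nx.MultiGraph = field(default_factory=nx.MultiGraph)
    voxel_size: float | None = None  # µm, isotropic, when image-derived

    # -- construction -----------------------------------------------------
    def add_node(self, node_id, pos, kind: str = "end", role: str = "none"):
        self.g.add_node(node_id, pos=tuple(float(v) for v in pos), kind=kind, role=role)

    def add_edge(self, a, b, centerline: Centerline, edge_id=None, **attrs) -> int:
        if a == b:
            raise GraphValidationError(f"self-loop edge ({a},{a}) is forbidden")
        for n in (a, b):
            if n not in self.g:
                raise GraphValidationError(f"edge endpoint {n!r} is not a node")
        attrs.pop("length", None)          # recomputed from the centerline
        attrs.pop("mean_diameter", None)
        if edge_id is None:
            edge_id = self._next_edge_id()
        elif isinstance(edge_id, (int, np.integer)):
            self._edge_id_counter = max(
                getattr(self, "_edge_id_counter", 0), int(edge_id) + 1)
        key = self.g.add_edge(
            a,
            b,
            id=edge_id,
            centerline=centerline,
            length=centerline.length,
            mean_diameter=centerline.mean_diameter,
            **attrs,
        )
        return key

    def _next_edge_id(self) -> int:
        nxt = getattr(self, "_edge_id_counter", None)
        if nxt is None:
            ids = [d.get("id", -1) for _, _, d in self.g.edges(data=True)]
            nxt = (max(ids) + 1) if ids else 0
        self._edge_id_counter = nxt + 1
        return nxt

    # -- views ------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def nodes(self):
        return self.g.nodes(data=True)

    def edges(self):
        return self.g.edges(keys=True, data=True)

    def node_position(self, n) -> np.ndarray:
        return np.asarray(self.g.nodes[n]["pos"], dtype=float)

    def positions(self) -> dict:
        return {n: np.asarray(d["pos"], float) for n, d in self.g.nodes(data=True)}

    def boundary_nodes(self, role: str | None = None) -> list:
        out = []
        for n, d in self.g.nodes(data=True):
            r = d.get("role", "none")
            if r != "none" and (role is None or r == role):
                out.append(n)
        return out

    def edge_by_id(self, edge_id):
        for u, v, k, d in self.g.edges(keys=True, data=True):
            if d.get("id") == edge_id:
                return u, v, k, d
        raise KeyError(f"no edge with id {edge_id}")

    def total_length(self) -> float:
        return float(sum(d["length"] for _, _, d in self.g.edges(data=True)))

    def total_volume(self) -> float:
        return float(sum(d["centerline"].volume for _, _, d in self.g.edges(data=True)))

    def copy(self) -> "VascularGraph":
        out = VascularGraph(self.g.copy(), voxel_size=self.voxel_size)
        for u, v, k, d in out.g.edges(keys=True, data=True):
            cl = d["centerline"]
            d["centerline"] = Centerline(cl.points.copy(), cl.diameters.copy())
        return out

    # -- invariants --------------------------------------------------------
    def classify_node_kinds(self) -> None:
        """Set node ``kind`` from degree (1 -> end, else branch); boundary
        roles override to kind = boundary."""
        for n, d in self.g.nodes(data=True):
            if d.get("role", "none") != "none":
                d["kind"] = "boundary"
            elif self.g.degree(n) == 1:
                d["kind"] = "end"
            else:
                d["kind"] = "branch"

    def check_euler(self) -> None:
        """Per-component cycle bookkeeping: |V| - |E| + cycles = 1 per
        component, cycles >= 0 (the Euler relation for graphs)."""
        for comp in nx.connected_components(self.g):
            sub = self.g.subgraph(comp)
            cycles = sub.number_of_edges() - sub.number_of_nodes() + 1
            if cycles < 0:
                raise GraphValidationError(
                    f"component with {sub.number_of_nodes()} nodes violates Euler relation"
                )
            if sub.number_of_nodes() - sub.number_of_edges() + cycles != 1:
                raise GraphValidationError("Euler relation violated")

    def validate(self, tol: float | None = None) -> None:
        """Check all structural invariants; raise GraphValidationError."""
        tol = tol if tol is not None else (self.voxel_size or 1.0)
        for u, v in self.g.edges():
            if u == v:
                raise GraphValidationError(f"self-loop edge ({u},{u}) is forbidden")
        for u, v, k, d in self.g.edges(keys=True, data=True):
            cl = d.get("centerline")
            if cl is None:
                raise GraphValidationError(f"edge {d.get('id')} lacks a centerline")
            pu, pv = self.node_position(u), self.node_position(v)
            d0 = min(np.linalg.norm(cl.points[0] - pu), np.linalg.norm(cl.points[0] - pv))
            d1 = min(np.linalg.norm(cl.points[-1] - pu), np.linalg.norm(cl.points[-1] - pv))
            if d0 > tol or d1 > tol:
                raise GraphValidationError(
                    f"edge {d.get('id')} centerline endpoints do not coincide "
                    f"with its node coordinates (off by {max(d0, d1):.3g} µm)"
                )
        self.check_euler()


# ---------------------------------------------------------------------------
# operations


def build_graph(node_table, edge_table) -> VascularGraph:
    """Build a VascularGraph from node and edge tables.

    ``node_table``: DataFrame or iterable of mappings with columns
    ``id, x, y, z`` and optional ``kind, role``.  ``edge_table``: columns
    ``id, node_a, node_b`` and either a ``centerline`` (:class:`Centerline`)
    column or ``mean_diameter`` (straight centerline synthesized).
    """
    nodes = pd.DataFrame(node_table)
    edges = pd.DataFrame(edge_table)
    for col in ("id", "x", "y", "z"):
        if col not in nodes.columns:
            raise GraphValidationError(f"node table missing column {col!r}")
    for col in ("id", "node_a", "node_b"):
        if col not in edges.columns:
            raise GraphValidationError(f"edge table missing column {col!r}")
    if nodes["id"].duplicated().any():
        dup = nodes.loc[nodes["id"].duplicated(), "id"].tolist()
        raise GraphValidationError(f"duplicate node ids: {dup}")

    vg = VascularGraph()
    for row in nodes.itertuples(index=False):
        vg.add_node(
            row.id,
            (row.x, row.y, row.z),
            kind=getattr(row, "kind", "end") or "end",
            role=getattr(row, "role", "none") or "none",
        )
    known = set(nodes["id"])
    for row in edges.itertuples(index=False):
        a, b = row.node_a, row.node_b
        if a == b:
            raise GraphValidationError(f"self-loop edge {row.id} ({a},{a}) rejected")
        for n in (a, b):
            if n not in known:
                raise GraphValidationError(f"edge {row.id} references unknown node {n!r}")
        cl = getattr(row, "centerline", None)
        if not isinstance(cl, Centerline):
            diam = float(getattr(row, "mean_diameter", 1.0))
            cl = Centerline.straight(vg.node_position(a), vg.node_position(b), diam)
        vg.add_edge(a, b, cl, edge_id=row.id)
    vg.classify_node_kinds()
    vg.check_euler()
    return vg


def laplacian(graph: VascularGraph, weight_name: str | None = "w_0", node_order=None):
    """Sparse symmetric graph Laplacian L = D - A with the named edge weight.

    Parallel-edge weights are summed.  ``weight_name=None`` means unit
    weights.  Returns (L in CSR format, node order list).
    """
    nodes = list(node_order) if node_order is not None else sorted(graph.g.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    rows, cols, vals = [], [], []
    missing = []
    for u, v, k, d in graph.g.edges(keys=True, data=True):
        if weight_name is None:
            w = 1.0
        else:
            w = d.get(weight_name)
            if w is None:
                missing.append(d.get("id"))
                continue
        i, j = index[u], index[v]
        rows += [i, j, i, j]
        cols += [j, i, i, j]
        vals += [-w, -w, w, w]
    if missing:
        raise GraphValidationError(
            f"weight {weight_name!r} missing on edges {sorted(missing)}"
        )
    n = len(nodes)
    L = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    L.sum_duplicates()
    return L, nodes


def extract_macro_subgraph(
    graph: VascularGraph, seed_boundary_nodes: Iterable, d_min: float = 15.0
) -> VascularGraph:
    """Edges reachable from the seeds through edges with mean diameter >= d_min.

    Traversal is blocked by thin edges (reachability, not filtering): a thick
    branch behind a thin bridge is excluded.
    """
    import warnings

    if d_min <= 0:
        raise ValueError("d_min must be > 0")
    seeds = list(seed_boundary_nodes)
    for s in seeds:
        if s not in graph.g:
            raise GraphValidationError(f"seed node {s!r} not in graph")
    sub = nx.MultiGraph()
    visited = set()
    stack = [s for s in seeds]
    while stack:
        n = stack.pop()
        if n in visited:
            continue
        visited.add(n)
        for u, v, k, d in graph.g.edges(n, keys=True, data=True):
            if d["mean_diameter"] >= d_min:
                other = v if u == n else u
                if not sub.has_edge(u, v, key=k):
                    for m in (u, v):
                        sub.add_node(m, **graph.g.nodes[m])
                    sub.add_edge(u, v, key=k, **d)
                if other not in visited:
                    stack.append(other)
    if sub.number_of_edges() == 0:
        warnings.warn("no edge with mean diameter >= d_min reachable from seeds")
    return VascularGraph(sub, voxel_size=graph.voxel_size)


# ---------------------------------------------------------------------------
# I/O

_EDGE_SCALARS = (
    "length",
    "mean_diameter",
    "resistance",
    "conductance",
    "w_0",
    "w_1",
    "w_2",
    "w_3",
    "w_4",
    "generation_from_artery",
    "generation_from_vein",
)


def write_graph(graph: VascularGraph, path: str, format: str = "graphml") -> None:
    """Write a graph as GraphML (single file) or CSV tables (directory).

    CSV dialect: ``nodes.csv`` (id,x,y,z,kind,role), ``edges.csv``
    (id,node_a,node_b,length,mean_diameter,...) with centerlines in the
    sidecar ``centerlines.csv`` (edge_id,point_index,x,y,z,diameter).
    """
    format = format.lower()
    if format == "graphml":
        g = nx.MultiGraph()
        for n, d in graph.g.nodes(data=True):
            x, y, z = d["pos"]
            g.add_node(n, x=float(x), y=float(y), z=float(z),
                       kind=d.get("kind", "end"), role=d.get("role", "none"))
        for u, v, k, d in graph.g.edges(keys=True, data=True):
            cl = d["centerline"]
            attrs = {"id": int(d["id"]),
                     "centerline_points": json.dumps(np.round(cl.points, 9).tolist()),
                     "centerline_diameters": json.dumps(np.round(cl.diameters, 9).tolist())}
            for name in _EDGE_SCALARS:
                if name in d:
                    attrs[name] = float(d[name])
            for name in ("community", "synthetic", "domain", "lobule"):
                if name in d:
                    attrs[name] = d[name] if not isinstance(d[name], (bool, np.bool_)) else bool(d[name])
            g.add_edge(u, v, key=k, **attrs)
        nx.write_graphml(g, path)
    elif format == "csv":
        os.makedirs(path, exist_ok=True)
        nrows = []
        for n, d in graph.g.nodes(data=True):
            x, y, z = d["pos"]
            nrows.append(dict(id=n, x=x, y=y, z=z,
                              kind=d.get("kind", "end"), role=d.get("role", "none")))
        pd.DataFrame(nrows).sort_values("id", kind="stable").to_csv(
            os.path.join(path, "nodes.csv"), index=False)
        erows, crows = [], []
        for u, v, k, d in graph.g.edges(keys=True, data=True):
            cl = d["centerline"]
            row = dict(id=d["id"], node_a=u, node_b=v,
                       length=d["length"], mean_diameter=d["mean_diameter"])
            for name in _EDGE_SCALARS[2:]:
                if name in d:
                    row[name] = d[name]
            if "synthetic" in d:
                row["synthetic"] = bool(d["synthetic"])
            erows.append(row)
            for i, (p, dia) in enumerate(zip(cl.points, cl.diameters)):
                crows.append(dict(edge_id=d["id"], point_index=i,
                                  x=p[0], y=p[1], z=p[2], diameter=dia))
        pd.DataFrame(erows).sort_values("id", kind="stable").to_csv(
            os.path.join(path, "edges.csv"), index=False)
        pd.DataFrame(crows).to_csv(os.path.join(path, "centerlines.csv"), index=False)
    else:
        raise ValueError(f"unknown format {format!r} (use 'graphml' or 'csv')")


def read_graph(path: str, format: str = "graphml") -> VascularGraph:
    """Read a graph written by :func:`write_graph`.

    GraphML files from foreign tools that lack centerline attributes load
    with straight-line centerlines synthesized from the node coordinates;
    those edges are flagged ``centerline_synthesized=True``.
    """
    format = format.lower()
    vg = VascularGraph()
    if format == "graphml":
        try:
            g = nx.read_graphml(path, force_multigraph=True)
        except Exception as exc:  # surface parse context
            raise GraphValidationError(f"malformed GraphML {path!r}: {exc}") from exc
        for n, d in g.nodes(data=True):
            try:
                pos = (float(d["x"]), float(d["y"]), float(d["z"]))
            except KeyError as exc:
                raise GraphValidationError(
                    f"node {n!r} missing coordinate attribute {exc}"
                ) from exc
            vg.add_node(_maybe_int(n), pos, kind=d.get("kind", "end"),
                        role=d.get("role", "none"))
        for u, v, k, d in g.edges(keys=True, data=True):
            u, v = _maybe_int(u), _maybe_int(v)
            attrs = {name: d[name] for name in _EDGE_SCALARS if name in d}
            for name in ("community", "synthetic", "domain", "lobule"):
                if name in d:
                    attrs[name] = d[name]
            if "centerline_points" in d:
                cl = Centerline(np.asarray(json.loads(d["centerline_points"]), float),
                                np.asarray(json.loads(d["centerline_diameters"]), float))
            else:
                diam = float(d.get("mean_diameter", 1.0))
                cl = Centerline.straight(vg.node_position(u), vg.node_position(v), diam)
                attrs["centerline_synthesized"] = True
            vg.add_edge(u, v, cl, edge_id=int(d.get("id", -1)) if "id" in d else None,
                        **attrs)
    elif format == "csv":
        npath = os.path.join(path, "nodes.csv")
        epath = os.path.join(path, "edges.csv")
        cpath = os.path.join(path, "centerlines.csv")
        nodes = pd.read_csv(npath)
        for col in ("id", "x", "y", "z"):
            if col not in nodes.columns:
                raise GraphValidationError(f"{npath}: missing column {col!r}")
        edges = pd.read_csv(epath)
        for col in ("id", "node_a", "node_b"):
            if col not in edges.columns:
                raise GraphValidationError(f"{epath}: missing column {col!r}")
        for row in nodes.itertuples(index=False):
            vg.add_node(row.id, (row.x, row.y, row.z),
                        kind=getattr(row, "kind", "end"),
                        role=getattr(row, "role", "none"))
        cl_by_edge: dict = {}
        if os.path.exists(cpath):
            cls = pd.read_csv(cpath)
            for eid, grp in cls.groupby("edge_id", sort=False):
                grp = grp.sort_values("point_index")
                cl_by_edge[eid] = Centerline(
                    grp[["x", "y", "z"]].to_numpy(float), grp["diameter"].to_numpy(float))
        for row in edges.itertuples(index=False):
            cl = cl_by_edge.get(row.id)
            attrs = {}
            if cl is None:
                cl = Centerline.straight(vg.node_position(row.node_a),
                                         vg.node_position(row.node_b),
                                         float(getattr(row, "mean_diameter", 1.0)))
                attrs["centerline_synthesized"] = True
            for name in _EDGE_SCALARS[2:] + ("community", "synthetic"):
                val = getattr(row, name, None)
                if val is not None and not (isinstance(val, float) and np.isnan(val)):
                    attrs[name] = val
            vg.add_edge(row.node_a, row.node_b, cl, edge_id=row.id, **attrs)
    else:
        raise ValueError(f"unknown format {format!r} (use 'graphml' or 'csv')")
    vg.classify_node_kinds()
    return vg


def _maybe_int(x):
    try:
        return int(x)
    except (TypeError, ValueError):
        return x
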