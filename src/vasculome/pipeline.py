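"""End-to-end pipeline orchestration.

Runs synthesize-or-load → (voxelize → vectorize) → flow → cluster → report
with a single global seed fanned out to every stochastic stage by fixed
offsets, structured per-stage logging, and a manifest recording the config
hash, fan-out seeds and a checksum for every data output, so identical
config + seed reproduce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd
import yaml

from . import community as cm
from . import hemodynamics as hd
from . import synthetic as sy
from .core_graph import VascularGraph, extract_macro_subgraph, read_graph, write_graph

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]

log = logging.getLogger("vasculome")

#: fixed per-stage seed offsets from the global seed
SEED_OFFSETS = {"synth": 0, "cluster": 1, "sensitivity": 2, "vectorize": 3}


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of a pipeline run (YAML/JSON serializable)."""

    out_dir: str = "vasculome_run"
    seed: int = 0
    # stage toggles
    synth: bool = True
    input_graph: str | None = None  # load instead of synthesizing
    vectorize: bool = False         # voxelize + re-vectorize (small networks)
    flow: bool = True
    cluster: bool = True
    report: bool = True
    # stage parameters
    synthesis: dict = dataclasses.field(default_factory=dict)
    voxel_size: float = 1.0
    gap_schedule: list | None = None
    viscosity: str = "invivo_esl"
    hematocrit: float = 0.45
    alpha: float = 0.35
    beta: float = 0.3125
    calibrate: bool = False
    alpha_grid: list = dataclasses.field(default_factory=lambda: [0.2, 0.35, 0.5])
    beta_grid: list = dataclasses.field(default_factory=lambda: [0.2, 0.3125, 0.5])
    schemes: list = dataclasses.field(default_factory=lambda: ["w_0"])
    functional_graphs: bool = True
    resolution: float = 1.0

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate(self) -> None:
        if not self.synth and not self.input_graph:
            raise ValueError("either synth must be enabled or input_graph given")
        if self.input_graph and not os.path.exists(self.input_graph):
            raise ValueError(f"input graph {self.input_graph!r} does not exist")
        functional = self.functional_graphs and self.cluster
        if functional and not self.flow:
            raise ValueError("functional community graphs require the flow stage")
        for s in self.schemes:
            if s not in cm.WEIGHT_SCHEMES:
                raise ValueError(f"unknown clustering scheme {s!r}")
        if {"w_3", "w_4"} & set(self.schemes) and not self.flow:
            raise ValueError("w_3/w_4 clustering requires the flow stage (resistances)")

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest = dict(config=config.to_dict(), config_hash=config.config_hash(),
                    seeds={k: config.seed + v for k, v in SEED_OFFSETS.items()},
                    stages={}, checksums={})
    state: dict = {}

    def record(stage: str, paths: list, t0: float, **extra):
        manifest["stages"][stage] = dict(
            outputs=[os.path.relpath(p, out) for p in paths],
            seconds=round(time.time() - t0, 3), **extra)
        for p in paths:
            manifest["checksums"][os.path.relpath(p, out)] = _checksum(p)

    stage_fns = [("synth", _stage_synth), ("vectorize", _stage_vectorize),
                 ("flow", _stage_flow), ("cluster", _stage_cluster),
                 ("report", _stage_report)]
    for name, fn in stage_fns:
        if not getattr(config, name if name != "synth" else "synth", False):
            if name == "synth" and config.input_graph:
                state["graph"] = read_graph(config.input_graph)
                log.info("loaded input graph: %d nodes, %d edges",
                         state["graph"].n_nodes, state["graph"].n_edges)
            continue
        t0 = time.time()
        log.info("stage %s: start", name)
        try:
            paths, extra = fn(config, state, out)
        except Exception as exc:
            manifest["stages"][name] = dict(failed=str(exc))
            _write_manifest(manifest, out)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        record(name, paths, t0, **extra)
        log.info("stage %s: done in %.1fs", name, time.time() - t0)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: str) -> None:
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# stages

def _stage_synth(config: PipelineConfig, state: dict, out: str):
    params = sy.SynthesisParams(seed=config.seed + SEED_OFFSETS["synth"],
                                **config.synthesis)
    vg, gt = sy.generate_lobular_network(params)
    state["graph"], state["ground_truth"] = vg, gt
    gdir = os.path.join(out, "graph_csv")
    write_graph(vg, gdir, format="csv")
    gml = os.path.join(out, "graph.graphml")
    write_graph(vg, gml, format="graphml")
    gt_path = os.path.join(out, "ground_truth.csv")
    gt_rows = []
    for u, v, k, d in vg.g.edges(keys=True, data=True):
        ru, rv = gt.node_region.get(u), gt.node_region.get(v)
        gt_rows.append(dict(edge_id=d["id"], lobule=gt.edge_lobule.get(d["id"]),
                            region=ru if ru == rv else "mixed"))
    pd.DataFrame(sorted(gt_rows, key=lambda r: r["edge_id"])).to_csv(gt_path, index=False)
    paths = [os.path.join(gdir, f) for f in ("nodes.csv", "edges.csv", "centerlines.csv")]
    return paths + [gml, gt_path], dict(n_nodes=vg.n_nodes, n_edges=vg.n_edges)


def _stage_vectorize(config: PipelineConfig, state: dict, out: str):
    from . import vectorization as vx

    vg = state["graph"]
    pos = np.array([p for p in vg.positions().values()])
    dmax = max(d["mean_diameter"] for _, _, d in vg.g.edges(data=True))
    lo = pos.min(axis=0) - 2 * dmax
    hi = pos.max(axis=0) + 2 * dmax
    vol = sy.voxelize_network(vg, config.voxel_size, (lo, hi))
    rec = vx.vectorize_volume(vol, gap_schedule=config.gap_schedule)
    state["graph"] = rec
    path = os.path.join(out, "vectorized.graphml")
    write_graph(rec, path, format="graphml")
    return [path], dict(n_nodes=rec.n_nodes, n_edges=rec.n_edges,
                        synthetic_fraction=vx.synthetic_edge_fraction(rec))


def _stage_flow(config: PipelineConfig, state: dict, out: str):
    vg = state["graph"]
    model = hd.ViscosityModel(kind=config.viscosity, hematocrit=config.hematocrit)
    hd.compute_resistances(vg, model)
    extra: dict = {}
    alpha, beta = config.alpha, config.beta
    paths = []
    if config.calibrate:
        alpha, beta, table = hd.calibrate_boundary_conditions(
            vg, config.alpha_grid, config.beta_grid, model)
        tpath = os.path.join(out, "calibration.csv")
        table.to_csv(tpath, index=False)
        paths.append(tpath)
        extra.update(alpha=alpha, beta=beta)
    bcs = hd.BoundaryConditionSet.from_graph(vg, alpha=alpha, beta=beta)
    sol = hd.solve_pressures(vg, bcs)
    state["flow"], state["bcs"] = sol, bcs
    ppath = os.path.join(out, "pressures.csv")
    pd.DataFrame(sorted(sol.pressures.items()), columns=["node", "pressure"]) \
        .to_csv(ppath, index=False)
    fpath = os.path.join(out, "fluxes.csv")
    pd.DataFrame([dict(edge_id=e, node_a=sol.orientation[e][0],
                       node_b=sol.orientation[e][1], flux=q)
                  for e, q in sorted(sol.fluxes.items())]).to_csv(fpath, index=False)
    extra["residual"] = sol.residual
    return paths + [ppath, fpath], extra


def _stage_cluster(config: PipelineConfig, state: dict, out: str):
    vg = state["graph"]
    seed = config.seed + SEED_OFFSETS["cluster"]
    paths, extra = [], {}
    state["partitions"] = {}
    state["community_graphs"] = {}
    for scheme in config.schemes:
        part = cm.cluster_communities(vg, scheme, resolution=config.resolution,
                                      seed=seed)
        state["partitions"][scheme] = part
        ppath = os.path.join(out, f"partition_{scheme}.csv")
        rows = [dict(edge_id=d["id"],
                     community=(part.node_community[u]
                                if part.node_community[u] == part.node_community[v]
                                else -1))
                for u, v, k, d in vg.g.edges(keys=True, data=True)]
        pd.DataFrame(sorted(rows, key=lambda r: r["edge_id"])) \
            .to_csv(ppath, index=False)
        paths.append(ppath)
        functional = config.functional_graphs and "flow" in state
        cg = cm.build_community_graphs(vg, part, flow=state.get("flow"),
                                       functional=functional)
        state["community_graphs"][scheme] = cg
        import networkx as nx

        gpath = os.path.join(out, f"community_graph_{scheme}.graphml")
        gout = nx.Graph()
        for n, d in cg.structural.nodes(data=True):
            gout.add_node(n, **{k: (json.dumps(v) if isinstance(v, tuple) else v)
                                for k, v in d.items()})
        for u, v, d in cg.structural.edges(data=True):
            attrs = dict(d)
            if cg.functional is not None:
                attrs["flux_ab"] = cg.flux(u, v)
                attrs["flux_ba"] = cg.flux(v, u)
            gout.add_edge(u, v, **attrs)
        nx.write_graphml(gout, gpath)
        paths.append(gpath)
        extra[f"n_communities_{scheme}"] = part.n_communities
        extra[f"modularity_{scheme}"] = round(part.modularity, 6)
        try:
            extra[f"slope_{scheme}"] = round(cm.connectivity_scaling(part)["slope"], 4)
        except ValueError:
            extra[f"slope_{scheme}"] = None
    return paths, extra


def _stage_report(config: PipelineConfig, state: dict, out: str):
    paths = write_report(state, out, schemes=config.schemes)
    return paths, {}


# ---------------------------------------------------------------------------
# report

def aspect_ratios(graph: VascularGraph) -> np.ndarray:
    """Per-edge aspect ratio D / 2L."""
    return np.array([d["mean_diameter"] / (2.0 * d["length"])
                     for _, _, d in graph.g.edges(data=True) if d["length"] > 0])


def write_report(state: dict, out: str, schemes=("w_0",)) -> list:
    """Summary tables and figures for a completed run.

    Sections whose inputs are missing (for example functional statistics
    without a flow stage) are skipped with a notice row.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out, exist_ok=True)
    vg: VascularGraph = state["graph"]
    rows = []
    paths = []
    ar = aspect_ratios(vg)
    rows.append(dict(section="morphometry", quantity="mean_aspect_ratio",
                     value=float(ar.mean())))
    dens = cm.vascular_density(vg)
    for w, dd in dens.items():
        nz = dd[dd > 0]
        rows.append(dict(section="morphometry", quantity=f"mean_density_box{int(w)}",
                         value=float(nz.mean()) if nz.size else 0.0))
    angles, _ = cm.bifurcation_angles(vg)

    partitions = state.get("partitions", {})
    if not partitions:
        rows.append(dict(section="clustering", quantity="notice",
                         value="no clustering stage output"))
    for scheme, part in partitions.items():
        if part.n_communities == 0:
            rows.append(dict(section="clustering", quantity=f"{scheme}_notice",
                             value="degenerate (empty) partition"))
            continue
        rows.append(dict(section="clustering", quantity=f"{scheme}_n_communities",
                         value=part.n_communities))
        rows.append(dict(section="clustering", quantity=f"{scheme}_modularity",
                         value=part.modularity))
        try:
            sc = cm.connectivity_scaling(part)
            rows.append(dict(section="clustering", quantity=f"{scheme}_slope",
                             value=sc["slope"]))
            rows.append(dict(section="clustering", quantity=f"{scheme}_class",
                             value=sc["classification"]))
        except ValueError as exc:
            rows.append(dict(section="clustering", quantity=f"{scheme}_slope_notice",
                             value=str(exc)))

    flow = state.get("flow")
    if flow is None:
        rows.append(dict(section="functional", quantity="notice",
                         value="no flow stage output; functional sections skipped"))
    else:
        rows.append(dict(section="functional", quantity="flow_residual",
                         value=flow.residual))
        gt = state.get("ground_truth")
        if gt is not None and partitions:
            scheme = next(iter(partitions))
            arrival, filling = hd.arrival_and_filling_times(
                vg, flow, partitions[scheme].node_community)
            finite = [t for t in filling.values() if np.isfinite(t)]
            if finite:
                rows.append(dict(section="functional",
                                 quantity=f"{scheme}_mean_filling_time",
                                 value=float(np.mean(finite))))

    summary = os.path.join(out, "summary.csv")
    pd.DataFrame(rows).to_csv(summary, index=False)
    paths.append(summary)

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    axes[0].hist(ar, bins=40, color="tab:red")
    axes[0].axvline(ar.mean(), color="k", ls="--")
    axes[0].set(title="aspect ratio D/2L", xlabel="D/2L")
    width = sorted(dens)[min(1, len(dens) - 1)]
    axes[1].hist(dens[width][dens[width] > 0], bins=40, color="tab:blue")
    axes[1].set(title=f"vascular density ({int(width)} µm boxes)", xlabel="density")
    if len(angles):
        axes[2].hist([angles["phi1"], angles["phi2"]], bins=30,
                     label=["φ1", "φ2"], histtype="step")
        axes[2].legend()
    axes[2].set(title="bifurcation angles", xlabel="degrees")
    fig.tight_layout()
    fig_path = os.path.join(out, "morphometry.png")
    fig.savefig(fig_path, dpi=120, metadata={"Software": None})
    plt.close(fig)
    paths.append(fig_path)

    if partitions:
        fig, ax = plt.subplots(figsize=(4, 3.5))
        for scheme, part in partitions.items():
            niv = [part.n_iv[c] for c in part.communities]
            nev = [part.n_ev.get(c, 0) for c in part.communities]
            ax.loglog(niv, nev, "o", ms=4, alpha=0.6, label=scheme)
        ax.set(xlabel="$N_{iv}$", ylabel="$N_{ev}$", title="connectivity scaling")
        ax.legend()
        fig.tight_layout()
        sp = os.path.join(out, "scaling.png")
        fig.savefig(sp, dpi=120, metadata={"Software": None})
        plt.close(fig)
        paths.append(sp)
    return paths
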