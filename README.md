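# vasculome

Whole-organ vascular network analysis: blood-flow modeling on spatial vascular
graphs and multi-scale community analysis of their structural and functional
organization.

Micro-vascular networks extracted from cleared-tissue microscopy are spatial
graphs `G_v = (V_v, E_v)`: nodes are vessel bifurcations and endpoints with 3D
coordinates, edges are vessel segments carrying sampled centerlines and
diameters `D(s)`. `vasculome` is for researchers who want to go from such a
graph (or from a binary tube volume, or from nothing — a synthetic generator
stands in for tissue data) to a quantitative picture of how the tissue is
organized and perfused:

- **Hemodynamics.** Each vessel is a Poiseuille resistor,
  `R = (128/π) ∫ µ(s)/D⁴(s) ds`, with µ the plasma-relative blood viscosity
  (either constant, or the empirical in-vivo law with the endothelial surface
  layer at hematocrit H = 0.45). Dimensionless Dirichlet pressures (main
  arterial inlet p = 1, main venous outlet p = 0, secondary cut-open
  boundaries at shared calibrated values α and β) close the conductance-
  weighted Laplacian system `L p = b`, giving nodal pressures and signed edge
  fluxes `Q_ij = C_ij (p_i − p_j)`. Effective two-terminal network resistance
  is available in its spectral form `R_ij = Σ_{k≥2} (ψ_{k,i} − ψ_{k,j})²/λ_k`.
- **Communities.** Seeded Louvain modularity optimization on five edge-weight
  schemes (w₀ unweighted, w₁ Euclidean distance, w₂ centerline arclength,
  w₃ resistance, w₄ conductance) partitions the network into vascular
  communities; from a partition come the structural community graph (bridging
  vessel counts), the bi-functional community graph (directed exchange fluxes
  Q_ci,cj), the scaling `N_ev ~ N_iv^s` of external vs internal vessel counts
  (strong communities s < 2/3, weak 2/3 ≤ s ≤ 1), authority/hub and
  eigenvector centrality with a core/periphery split, arterial/venous
  generation domains, box-counted vascular density, bifurcation angles, and
  Kruskal–Wallis region comparisons.
- **Vectorization.** Small binary tube volumes are converted to graphs by
  homotopy-preserving skeletonization, branch/end voxel classification,
  sphere-expansion radius estimation (grow until 10% of the sphere leaves the
  mask) and a distance/angle loose-end reconnection schedule
  (5 µm/30° up to 30 µm/45°).
- **Synthetic vasculature.** A seeded generator emulating an adipose fat pad:
  arterial and venous macro-trees (≥ 15 µm, Murray-law tapering) feeding
  capillary-lattice lobules with bimodal sizes, designed inter-lobule bridges,
  a dense core band vs a sparse periphery, and mean vessel aspect ratio
  D/2L ≈ 1/8.

## Worked example

```python
import vasculome as vm

# a synthetic fat-pad-like network: ~17k vessels in 32 lobules
graph, truth = vm.generate_lobular_network(vm.SynthesisParams(seed=1))

vm.compute_resistances(graph, vm.ViscosityModel("invivo_esl", hematocrit=0.45))
bcs = vm.BoundaryConditionSet.from_graph(graph, alpha=0.35, beta=0.3125)
flow = vm.solve_pressures(graph, bcs)
print(f"{graph.n_edges} vessels, flow residual {flow.residual:.2e}")

part = vm.cluster_communities(graph, "w_0", seed=0)
print(f"{part.n_communities} communities, modularity {part.modularity:.3f}")

from vasculome.synthetic import measure_region_densities
core, peri = measure_region_densities(graph, truth)
print(f"core density {core:.4f} vs periphery {peri:.4f} ({core/peri:.1f}x)")
```

prints

```
17220 vessels, flow residual 3.05e-14
33 communities, modularity 0.949
core density 0.0166 vs periphery 0.0060 (2.8x)
```

The flow residual is the worst interior-node flux imbalance relative to the
largest flux — mass conservation to solver precision. The 33 communities
found without any weighting track the 32 designed lobules (adjusted Rand
index 0.985 against the ground truth; the extra community is the macro-tree
skeleton). The box-counted density contrast between the central band around
the feeding artery and the periphery is close to the designed 3× ratio.

The same analysis runs from a shell:

```sh
vasculome run --config config.yaml --seed 1 --out results/
```

writing graph tables (GraphML + CSV), pressures/fluxes, partitions, community
graphs, a summary table, figures and a checksummed manifest; identical config
and seed reproduce identical manifests.

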