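# Methods

## The vascular graph

A network is an undirected spatial multigraph: nodes carry 3D coordinates in
micrometres, edges carry a sampled centerline (ordered points with per-sample
diameters). Parallel edges between the same node pair are kept — capillary
anastomoses produce genuine parallel paths — and their weights are summed
wherever a Laplacian or a modularity null model needs a simple graph; this is
mathematically equivalent to treating them separately in both cases.
Self-loops are forbidden. Coordinates assume 0-based voxel indexing with
voxel centers at integer coordinates; isotropic spacing is carried as
metadata. Structural invariants checked after construction: centerline
endpoints coincide with node coordinates within one voxel, and per connected
component the cycle count satisfies |V| − |E| + cycles = 1.

File formats: GraphML with declared attribute keys (centerlines serialized as
JSON arrays), or CSV tables `nodes.csv` (id,x,y,z,kind,role) and `edges.csv`
(id,node_a,node_b,length,mean_diameter,…) with a `centerlines.csv` sidecar
(edge_id,point_index,x,y,z,diameter). Foreign GraphML without centerlines
loads with straight-line centerlines synthesized from node coordinates,
flagged per edge.

## Blood-flow model

Vessels have small aspect ratio (radius/length ≈ 1/8 on average), so each is
a 1D resistor under the lubrication approximation:

    R = (128/π) ∫ µ(s) / D⁴(s) ds

integrated by the trapezoidal rule over the centerline samples, which
captures local taper. Viscosity µ is plasma-relative. Two models:

- `constant` — µ ≡ scale, for closed-form verification.
- `invivo_esl` — the published empirical in-vivo law including the
  endothelial surface layer (ESL): the in-vitro relative viscosity
  η(D, H) evaluated at the ESL-narrowed effective diameter
  D_eff = D − 2 w_eff(D), rescaled by (D/D_eff)⁴. ESL width parameters:
  D_off = 2.4 µm, D_crit = 10.5 µm, D_50 = 100 µm, amplitude 1.1 µm,
  decay 0.03 /µm, peak factor 0.6, w_max = 2.6 µm. Discharge hematocrit is
  held constant at H = 0.45 throughout the network (hematocrit phase
  separation at bifurcations is deliberately not modeled; it has a small
  effect on perfusion). The law is undefined below D = 1.2 µm and raises.

Pressures are dimensionless — the data never anchor an absolute pressure
scale, so fluxes are reported in µm³ per unit time per unit pressure. The
main arterial inlet is fixed at p = 1 and the main venous outlet at p = 0;
every secondary cut-open vein inlet shares a pressure α and every secondary
artery outlet shares β, with 0 < β ≤ α < 1. Dirichlet conditions are
imposed by row elimination (boundary values are exact, no penalty terms);
the interior block of the conductance-weighted Laplacian is solved by sparse
LU below 10⁵ unknowns and conjugate gradients (rtol 1e−12) above. The
reported residual is the worst interior net flux over the largest edge flux.

**Calibration of (α, β).** For each grid pair with β ≤ α the flow is solved,
perfusion domains are traced, and the ratio volume(main-artery domain) /
Σ volume(secondary-vein domains) is computed; the returned pair maximizes
this ratio (it suppresses spurious perfusion by cut-open veins). Ties keep
the first grid pair scanned. Pairs whose vein domains are all empty are
recorded as +∞ and excluded from the argmax unless all are.

**Perfusion domains.** From each inlet a walk follows the flow direction; at
a diverging bifurcation only the single largest-|flux| outgoing edge is
continued (strict argmax, ties broken by smallest edge id). Nodes reached by
several inlets belong to the inlet delivering the largest entering flux. A
domain's perfusion volume is Σ π(D/2)²L over its walk's edges. The
predominant-branch rule is a design choice: the alternative of following
every branch above a flux share is a one-line change (`outgoing` selection)
but the strict rule keeps domains unambiguous.

**Effective resistance.** R_ij = Σ_{k≥2} (ψ_{k,i} − ψ_{k,j})²/λ_k from the
eigenpairs of the conductance-weighted Laplacian, computed by full
eigendecomposition up to 2000 nodes; larger graphs use the mathematically
identical grounded unit-current solve. Disconnected pairs raise (infinite
resistance).

**Kinetics.** Transit time of a perfused edge is τ = lumen volume / |Q|;
edges with |Q| below 1e−9 of the maximum are treated as unperfused. A node's
arrival time is the shortest Σ τ over flow-directed paths from the main
arterial inlet (Dijkstra); a community's filling time is max − min arrival
over its perfused nodes. This volume-over-flux plug-flow contract is the
package's own re-specification of perfusion kinetics; it ignores in-vessel
dispersion and assumes each vessel fills at its steady flux.

**Sensitivity to segmentation errors.** Each repetition multiplies every
edge's diameters by an independent factor max(0.05, 1 + N(0, σ)), re-solves
the flow and recomputes inter-community exchanges; the per-pair relative
quadratic error is sqrt(mean (Q′ − Q)²)/Q, and pairs whose exchange falls
below 1e−12 of the maximum flux are counted as vanished.

## Community analysis

Edge weights: w₀ ≡ 1, w₁ Euclidean end-to-end distance, w₂ centerline
arclength, w₃ hydrodynamic resistance, w₄ conductance (w₃·w₄ = 1). The
weights enter the modularity quality function exactly as defined; because
clustering on a dissimilarity is unconventional, an `invert_weights` option
is provided but off by default. Partitions come from seeded Louvain
optimization (local moves plus aggregation to a fixed point; resolution 1.0
by default — the appropriate resolution is data-dependent and unreported for
tissue data, so the canonical default is used). Community ids are
canonicalized by sorted membership so a given seed yields a stable labeling.
Communities are defined on nodes; an edge whose endpoints disagree is a
bridging vessel, counted once per community pair in N_ev and never in N_iv.

The structural community graph weighs each community pair by its bridging
vessel count; the bi-functional graph carries directed exchange fluxes
Q_ci,cj = Σ of |Q_k| over bridges flowing c_i → c_j. The connectivity scaling
fits log N_ev against log N_iv by least squares (a zero-intercept variant is
also reported); slopes below 2/3 mark strong (weakly coupled) communities,
2/3–1 weak ones, above 1 super-connected ones — 2/3 is the surface-to-volume
bound.

Eigenvector centrality is the principal eigenvector of the weighted
structural adjacency; authority and hub scores come from power iteration of
AᵀA and AAᵀ on the directed flux graph (tolerance 1e−10, cap 10⁴ iterations;
a positive diagonal shift suppresses the ±λ oscillation of bipartite
adjacencies without changing the Perron vector). All scores are normalized
to unit sum — the only normalization under which a universal core threshold
is meaningful — and communities with authority above 0.04 form the core.
Disconnected community graphs are reduced to their largest component and
flagged.

Arterial/venous domains: the macro subgraphs are the edges reachable from
the arterial (resp. venous) boundaries through vessels of mean diameter
≥ 15 µm; breadth-first generation numbers spread outward from each (macro
edges are generation 0). A vessel is arterial when it is closer — smaller
generation — to the arterial macro network, ties going to venous. (The
"closer" convention is the physically meaningful one; an edge equidistant
from both trees is arbitrarily venous, which only affects the knife-edge
ties.) Per community, the arterial fraction is the share of its internal
vessels labeled arterial.

Morphometrics: box-counted vascular density tiles the bounding box with
cubes (default widths 100–400 µm), assigning ≤ 2 µm centerline pieces by
midpoint; bifurcation angles at degree-3 nodes measure each daughter's
outgoing tangent against the parent's (the largest-diameter branch), so a
straight-through continuation reads 180°; tangents come from a least-squares
line fit of the five nearest centerline samples. Region comparisons use the
tie-corrected Kruskal–Wallis rank-sum test.

## Vectorization of binary volumes

Skeletonization uses 3D homotopy-preserving thinning (Lee's algorithm), so
components and loops of the mask are preserved — verified via Betti numbers
(b0 from 26-connected labeling, b1 = b0 − χ, valid for tubular masks with no
cavities). Skeleton voxels with ≥ 3 neighbors in 26-connectivity are branch
voxels (adjacent ones merge into one node at their centroid), voxels with
one neighbor are end nodes, and the voxel chains between them become edges.
A pure voxel loop with no branch voxel receives two artificial nodes and is
stored as two parallel edges, since self-loops are forbidden.

Radii: at each centerline sample a sphere grows in 0.25-voxel steps until
more than 10% of its voxels fall outside the mask; ties resolve to the
smaller radius; D(s) = 2r. Samples whose center voxel is background are
flagged and inherit the nearest valid sample's radius. Near junctions the
inscribed sphere is legitimately larger than the tube radius, so per-vessel
diameters should be read at mid-vessel samples.

Loose ends are reconnected by an explicit distance/angle matching schedule —
default (5 µm, 30°), (13 µm, 35°), (21 µm, 40°), (30 µm, 45°) — replacing
iterative tensor voting with a contract that is directly testable: per pass,
two end nodes within the reference distance whose outward end tangents
(least-squares fit of the last ≤ 5 centerline points) each deviate at most
the reference angle from their connecting line are joined by a straight
edge with the mean of the two end diameters, nearest pairs first, each end
used once per pass. Added edges are flagged synthetic and their fraction is
reported; on clean synthetic volumes it is ≈ 0.

The full wrapper also prunes terminal spurs shorter than 5 voxels (junction
artifacts of thinning scale with tube radius) and fuses pass-through
degree-2 nodes. Round-trip comparisons against a source graph must therefore
fuse the source's degree-2 chain nodes as well, since those are not
topological nodes.

## Synthetic vasculature

The generator emulates an adipose fat pad at reduced scale. Each of
`n_lobules` (default 32) lobules is a jittered cubic capillary lattice:
lattice spacing is 4× the mean capillary diameter so the mean aspect ratio
D/2L lands at the 1/8 the tissue exhibits; capillary diameters are uniform
in 4–9 µm; a random spanning tree guarantees internal connectivity and random
extra lattice edges bring the vessel count to the lobule's target size,
drawn ±10% around one of two bimodal size modes (250 and 800 vessels),
reflecting the two robust meso-scale community sizes seen in tissue.
Arterial and venous binary trees (built by recursive bisection of the lobule
sequence, entering each lobule at the mesh face nearest the tree so macro
vessels do not cut through capillary meshes) have 15 µm terminals and taper
upward by Murray's law with exponent 3, the standard vascular assumption.
One main arterial inlet and one main venous outlet plus 8 secondary
boundaries (half vein inlets, half artery outlets, stubs on the macro trees)
scale down the ~26 cut macro-vessels of a whole organ. Adjacent lobules are
joined by a controlled number of bridge capillaries (default 3 per adjacent
pair, or an explicit per-pair map) between their facing sides.

Density contrast: a connected capillary lattice at aspect ratio 1/8 has an
internal volumetric density floor near 0.05, so core (0.06) versus periphery
(0.02) cannot be realized inside the meshes themselves. Instead — as in the
tissue, where sparse peripheral lobules sit in fat — every lobule's tissue
cell has the cross-section its vascular volume implies at core density
(core cells are cubes), and the peripheral cells are stretched along the
tissue's long axis until their density target is met. Core lobules occupy a
contiguous central band of the resulting rod, peripheral ones flank it. The
box-density estimator restricted to the rod then separates the regions at
close to the designed 3× ratio (the measured absolute densities are diluted
by the empty cross-section corners, equally in both regions).

What the generator does not emulate: real fat-pad morphometry (exact
diameter and length distributions, curved centerlines — synthetic vessels
are straight, so w₁ = w₂), lymph nodes, pulsatile flow, or imaging artifacts
other than the diameter perturbation model. Tests passing on these networks
therefore establish the correctness and calibration of the analysis
machinery, not tissue-specific conclusions.

Determinism: one `numpy` Generator seeded from `SynthesisParams.seed` drives
every draw in a fixed order; the same seed reproduces the graph bit for bit.
The pipeline fans a single global seed out to stages by fixed offsets
(synth +0, cluster +1, sensitivity +2, vectorize +3) so stages are
independently reproducible.

## Problem sizes and defaults

Default synthetic networks have ≈ 1.7 × 10⁴ vessels — large enough for
meaningful community statistics, small enough that a full pipeline run
(synthesis, flow, clustering on several weights, report) takes seconds on
one CPU. Voxelization-based round trips use single-lobule networks of ~30
vessels at 1 µm voxels with 7–8 µm capillaries (radius ≥ 3 voxels, where
radius estimation is reliable). Boundary-condition calibration and
sensitivity analyses run on 8-lobule networks with 8 secondary boundaries
over 5×5 (α, β) grids and 20 perturbation repetitions.

## Known limitations

- Louvain is a greedy heuristic; optimality is only verified exhaustively at
  toy sizes, and very large sparse lobules can in principle be split by the
  resolution limit.
- The perfusion-domain walk claims a single path per inlet; broad domains
  fed through near-equal splits are under-counted by design.
- Radius estimation biases small near junctions' absorbed samples and the
  skeleton erodes tube ends by about one radius, so total length is
  systematically a few percent off at small network sizes.
- The voxel rasterizer places voxel centers at integer coordinates; masks
  built with half-voxel symmetry can defeat the thinning step of
  scikit-image (empty skeletons), which the integer convention avoids.
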