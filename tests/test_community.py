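import itertools

import networkx as nx
import numpy as np
import pytest

from vasculome.community import (
    CommunityPartition,
    assign_edge_weights,
    bifurcation_angles,
    build_community_graphs,
    cluster_communities,
    compare_regions,
    connectivity_scaling,
    generation_domains,
    graph_features,
    modularity,
    vascular_density,
)
from vasculome.core_graph import Centerline, VascularGraph, extract_macro_subgraph

from conftest import set_unit_conductances, straight_graph


def clique_graph(cliques, bridges):
    """VascularGraph of node cliques plus explicit bridge edges."""
    nodes = {}
    rng = np.random.default_rng(0)
    for ci, members in enumerate(cliques):
        for n in members:
            nodes[n] = (100.0 * ci + rng.uniform(0, 30),
                        rng.uniform(0, 30), 0.0)
    edges = [(a, b) for members in cliques
             for a, b in itertools.combinations(members, 2)]
    edges += bridges
    return straight_graph(nodes, edges)


class TestEdgeWeights:
    def test_weight_definitions(self):
        vg = VascularGraph()
        vg.add_node(0, (0, 0, 0))
        vg.add_node(1, (30, 0, 0))
        pts = np.array([[0, 0, 0], [15, 10, 0], [30, 0, 0]], float)
        vg.add_edge(0, 1, Centerline(pts, np.full(3, 6.0)))
        set_unit_conductances(vg, 0.25)
        for scheme in ("w_0", "w_1", "w_2", "w_3", "w_4"):
            assign_edge_weights(vg, scheme)
        d = next(iter(vg.g.edges(data=True)))[2]
        assert d["w_0"] == 1.0
        assert d["w_1"] == pytest.approx(30.0)
        assert d["w_2"] >= d["w_1"]            # arc >= chord
        assert d["w_3"] * d["w_4"] == pytest.approx(1.0)

    def test_straight_vessel_w1_equals_w2(self):
        vg = straight_graph({0: (0, 0, 0), 1: (40, 0, 0)}, [(0, 1)])
        assign_edge_weights(vg, "w_1")
        assign_edge_weights(vg, "w_2")
        d = next(iter(vg.g.edges(data=True)))[2]
        assert d["w_1"] == pytest.approx(d["w_2"])

    def test_unknown_scheme_rejected(self):
        vg = straight_graph({0: (0, 0, 0), 1: (40, 0, 0)}, [(0, 1)])
        with pytest.raises(ValueError, match="unknown weight scheme"):
            assign_edge_weights(vg, "w_9")

    def test_resistance_required_for_w3(self):
        vg = straight_graph({0: (0, 0, 0), 1: (40, 0, 0)}, [(0, 1)])
        with pytest.raises(ValueError, match="resistance required"):
            assign_edge_weights(vg, "w_3")


class TestClustering:
    def test_single_clique_one_community(self):
        vg = clique_graph([list(range(6))], [])
        part = cluster_communities(vg, "w_0", seed=0)
        assert part.n_communities == 1

    def test_ring_of_six_cliques(self):
        cliques = [list(range(5 * i, 5 * i + 5)) for i in range(6)]
        bridges = [(5 * i, 5 * ((i + 1) % 6) + 1) for i in range(6)]
        vg = clique_graph(cliques, bridges)
        part = cluster_communities(vg, "w_0", seed=0)
        assert part.n_communities == 6
        found = {frozenset(n for n, c in part.node_community.items() if c == ci)
                 for ci in set(part.node_community.values())}
        assert found == {frozenset(c) for c in cliques}
        planted = {n: i for i, c in enumerate(cliques) for n in c}
        assert part.modularity >= modularity(vg, planted) - 1e-9

    def test_seeded_determinism(self):
        vg = clique_graph([list(range(5)), list(range(5, 10))], [(0, 5)])
        p1 = cluster_communities(vg, "w_0", seed=3)
        p2 = cluster_communities(vg, "w_0", seed=3)
        assert p1.node_community == p2.node_community

    def test_invert_weights_option(self):
        vg = clique_graph([list(range(5)), list(range(5, 10))], [(0, 5)])
        set_unit_conductances(vg, 2.0)
        part = cluster_communities(vg, "w_3", seed=0, invert_weights=True)
        assert part.n_communities >= 1  # option exercised without error


class TestCommunityGraphs:
    def test_planted_bridges_give_structural_weights(self):
        from vasculome.synthetic import SynthesisParams, generate_lobular_network

        vg, gt = generate_lobular_network(SynthesisParams(
            seed=4, n_lobules=3, lobule_size_modes=(30, 30),
            n_secondary_boundaries=0, bridges_per_pair={(0, 1): 5, (1, 2): 1}))
        nc = {n: (l if l != "macro" else "macro") for n, l in gt.node_lobule.items()}
        part = CommunityPartition.from_graph(vg, nc)
        cg = build_community_graphs(vg, part)
        assert cg.structural_weight(0, 1) == 5
        assert cg.structural_weight(1, 2) == 1
        assert not cg.structural.has_edge(0, 2)

    def test_boundary_free_community_conserves_flux(self):
        from vasculome.hemodynamics import (
            BoundaryConditionSet, intercommunity_fluxes, solve_pressures)
        from vasculome.synthetic import SynthesisParams, generate_lobular_network

        vg, gt = generate_lobular_network(SynthesisParams(
            seed=5, n_lobules=3, lobule_size_modes=(40, 40),
            n_secondary_boundaries=0))
        set_unit_conductances(vg)
        sol = solve_pressures(vg, BoundaryConditionSet.from_graph(vg))
        nc = {n: (l if l != "macro" else "macro") for n, l in gt.node_lobule.items()}
        q = intercommunity_fluxes(vg, nc, sol)
        max_q = sol.max_flux()
        for c in (0, 1, 2):  # lobules contain no boundary nodes
            inflow = sum(v for (a, b), v in q.items() if b == c)
            outflow = sum(v for (a, b), v in q.items() if a == c)
            assert inflow == pytest.approx(outflow, abs=1e-9 * max_q)

    def test_single_community_graph_trivial(self):
        vg = clique_graph([list(range(5))], [])
        part = CommunityPartition.from_graph(vg, {n: 0 for n in range(5)})
        cg = build_community_graphs(vg, part)
        assert cg.structural.number_of_nodes() == 1
        assert cg.structural.number_of_edges() == 0

    def test_functional_without_flow_rejected(self):
        vg = clique_graph([list(range(5))], [])
        part = CommunityPartition.from_graph(vg, {n: 0 for n in range(5)})
        with pytest.raises(ValueError, match="without a flow"):
            build_community_graphs(vg, part, functional=True)


class TestConnectivityScaling:
    def test_designed_half_power_exponent(self):
        niv = np.array([2 ** k for k in range(4, 13)])  # 16 .. 4096
        nev = np.round(niv ** 0.5)
        res = connectivity_scaling(CommunityPartition.from_counts(niv, nev))
        assert res["slope"] == pytest.approx(0.50, abs=0.02)
        assert res["classification"] == "strong"

    def test_equal_counts_slope_one_weak(self):
        niv = np.array([10, 40, 160, 640])
        res = connectivity_scaling(CommunityPartition.from_counts(niv, niv))
        assert res["slope"] == pytest.approx(1.0, abs=1e-12)
        assert res["slope_zero_intercept"] == pytest.approx(1.0, abs=1e-12)
        assert res["classification"] == "weak"

    def test_super_connected_classification(self):
        niv = np.array([10, 40, 160, 640])
        res = connectivity_scaling(CommunityPartition.from_counts(niv, niv ** 1.3))
        assert res["classification"] == "super-connected"

    def test_too_few_communities_rejected(self):
        with pytest.raises(ValueError, match=">= 3 communities"):
            connectivity_scaling(CommunityPartition.from_counts([10, 20], [5, 8]))


class TestGraphFeatures:
    def _community_graph(self, gs, gf=None):
        from vasculome.community import CommunityGraph

        return CommunityGraph(gs, gf)

    def test_star_center_has_largest_centrality(self):
        gs = nx.star_graph(4)
        nx.set_edge_attributes(gs, 1.0, "weight")
        out = graph_features(self._community_graph(gs))
        c = out["centrality"]
        assert all(c[0] > c[i] for i in range(1, 5))
        assert sum(c.values()) == pytest.approx(1.0)

    def test_ring_symmetry_equal_scores(self):
        gs = nx.cycle_graph(6)
        nx.set_edge_attributes(gs, 1.0, "weight")
        out = graph_features(self._community_graph(gs))
        scores = list(out["centrality"].values())
        assert np.allclose(scores, scores[0])

    def test_authority_matches_svd_oracle(self):
        rng = np.random.default_rng(8)
        gf = nx.gnp_random_graph(30, 0.2, seed=4, directed=True)
        for u, v, d in gf.edges(data=True):
            d["flux"] = float(rng.uniform(0.1, 5.0))
        gs = nx.Graph(gf.to_undirected())
        nx.set_edge_attributes(gs, 1.0, "weight")
        out = graph_features(self._community_graph(gs, gf))
        nodes = sorted(gs.nodes())
        F = nx.to_numpy_array(gf, nodelist=nodes, weight="flux")
        _, _, vt = np.linalg.svd(F)
        authority = np.abs(vt[0])
        authority /= authority.sum()
        got = np.array([out["authority"][n] for n in nodes])
        assert np.allclose(got, authority, atol=1e-8)

    def test_core_threshold_on_unit_sum_scores(self):
        gs = nx.star_graph(3)
        nx.set_edge_attributes(gs, 1.0, "weight")
        out = graph_features(self._community_graph(gs), authority_threshold=0.3)
        assert out["core"][0] is True
        assert sum(out["core"].values()) == 1


class TestGenerationDomains:
    def test_hand_counted_chain(self):
        # A(macro) - v1 - v2 - V(macro): generations 1/3 on the first vessel
        vg = straight_graph(
            {0: (0, 0, 0), 1: (50, 0, 0), 2: (100, 0, 0),
             3: (150, 0, 0), 4: (200, 0, 0)},
            [(0, 1, 20.0), (1, 2, 6.0), (2, 3, 6.0), (3, 4, 20.0)],
            roles={0: "main_artery_inlet", 4: "main_vein_outlet"})
        art = extract_macro_subgraph(vg, [0])
        ven = extract_macro_subgraph(vg, [4])
        gm = generation_domains(vg, art, ven)
        # first capillary: one step from the arterial macro, two from venous
        caps = sorted((d["generation_from_artery"], d["generation_from_vein"],
                       gm.edge_domain[d["id"]])
                      for _, _, d in vg.g.edges(data=True) if d["mean_diameter"] < 15)
        assert caps[0] == (1, 2, "arterial")
        assert caps[-1] == (2, 1, "venous")

    def test_tie_goes_to_venous(self):
        vg = straight_graph(
            {0: (0, 0, 0), 1: (50, 0, 0), 2: (100, 0, 0), 3: (150, 0, 0)},
            [(0, 1, 20.0), (1, 2, 6.0), (2, 3, 20.0)],
            roles={0: "main_artery_inlet", 3: "main_vein_outlet"})
        art = extract_macro_subgraph(vg, [0])
        ven = extract_macro_subgraph(vg, [3])
        gm = generation_domains(vg, art, ven)
        mid = next(d["id"] for _, _, d in vg.g.edges(data=True)
                   if d["mean_diameter"] < 15)
        assert gm.edge_domain[mid] == "venous"

    def test_unreachable_edge_reported(self):
        vg = straight_graph(
            {0: (0, 0, 0), 1: (50, 0, 0), 2: (0, 500, 0), 3: (50, 500, 0)},
            [(0, 1, 20.0), (2, 3, 6.0)],
            roles={0: "main_artery_inlet", 1: "main_vein_outlet"})
        art = extract_macro_subgraph(vg, [0])
        ven = extract_macro_subgraph(vg, [1])
        gm = generation_domains(vg, art, ven)
        assert len(gm.unassigned) == 1

    def test_arterial_fraction_all_first_generation(self):
        from vasculome.community import arterial_fraction

        vg = straight_graph(
            {0: (0, 0, 0), 1: (50, 0, 0), 2: (100, 0, 0),
             3: (150, 0, 0), 4: (200, 0, 0)},
            [(0, 1, 20.0), (1, 2, 6.0), (2, 3, 6.0), (3, 4, 20.0)],
            roles={0: "main_artery_inlet", 4: "main_vein_outlet"})
        gm = generation_domains(vg, extract_macro_subgraph(vg, [0]),
                                extract_macro_subgraph(vg, [4]))
        part = CommunityPartition.from_graph(
            vg, {0: "m", 1: "c", 2: "c", 3: "m", 4: "m"})
        frac = arterial_fraction(vg, part, gm)
        assert frac["c"] == 1.0  # its single internal vessel is arterial


class TestVascularDensity:
    def test_empty_graph_zero(self):
        out = vascular_density(VascularGraph())
        assert all(np.all(v == 0) for v in out.values())

    def test_single_corner_tube_localized(self):
        vg = straight_graph({0: (10, 10, 10), 1: (90, 10, 10)}, [(0, 1, 8.0)])
        with pytest.warns(UserWarning):
            out = vascular_density(vg, box_widths=(500.0,))
        dens = vascular_density(vg, box_widths=(50.0,))[50.0]
        assert np.count_nonzero(dens) <= 2  # only boxes the tube crosses

    def test_uniform_lattice_matches_analytic(self):
        # cubic lattice of tubes: density = 3 pi r^2 a / a^3 per unit cell
        a, dia, n = 50.0, 6.0, 5
        nodes, edges = {}, []
        idx = lambda i, j, k: i * n * n + j * n + k
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    nodes[idx(i, j, k)] = (a * i, a * j, a * k)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    if i + 1 < n:
                        edges.append((idx(i, j, k), idx(i + 1, j, k)))
                    if j + 1 < n:
                        edges.append((idx(i, j, k), idx(i, j + 1, k)))
                    if k + 1 < n:
                        edges.append((idx(i, j, k), idx(i, j, k + 1)))
        vg = straight_graph(nodes, edges, diameter=dia)
        dens = vascular_density(vg, box_widths=(100.0,))[100.0]
        # finite lattice: 3 n^2 (n-1) vessels of length a in an ((n-1)a)^3 box
        expected = (3 * n * n * (n - 1)) * np.pi * (dia / 2) ** 2 * a / (a * (n - 1)) ** 3
        assert np.mean(dens) == pytest.approx(expected, rel=0.05)
        # variance shrinks with box width
        small = vascular_density(vg, box_widths=(50.0,))[50.0]
        assert np.var(dens) <= np.var(small) + 1e-12


class TestBifurcationAngles:
    def _y(self, d1_angle, d2_angle, parent_dia=10.0):
        def ray(angle_deg, r=60.0):
            a = np.deg2rad(angle_deg)
            return (r * np.cos(a), r * np.sin(a), 0.0)

        vg = straight_graph(
            {0: (-60.0, 0, 0), 1: (0.0, 0, 0), 2: ray(d1_angle), 3: ray(d2_angle)},
            [(0, 1, parent_dia), (1, 2, 6.0), (1, 3, 6.0)])
        return vg

    def test_straight_through_daughter_is_180(self):
        df, _ = bifurcation_angles(self._y(0.0, 120.0))
        assert df.iloc[0]["phi2"] == pytest.approx(180.0, abs=1e-6)

    def test_symmetric_y_both_120(self):
        df, _ = bifurcation_angles(self._y(60.0, -60.0))
        assert df.iloc[0]["phi1"] == pytest.approx(120.0, abs=1e-6)
        assert df.iloc[0]["phi2"] == pytest.approx(120.0, abs=1e-6)

    def test_degree_four_excluded_and_counted(self):
        vg = self._y(60.0, -60.0)
        vg.add_node(4, (0.0, 0.0, 60.0))
        vg.add_edge(1, 4, Centerline.straight((0, 0, 0), (0, 0, 60), 6.0))
        df, n_higher = bifurcation_angles(vg)
        assert len(df) == 0 and n_higher == 1


class TestCompareRegions:
    def test_identical_samples(self):
        h, p = compare_regions([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert h == 0.0 and p == 1.0

    def test_separated_groups_exact_rank_statistic(self):
        # ranks 1..6, R1 = 6, R2 = 15 -> H = 12/42 * (12 + 75) - 21 = 27/7
        h, p = compare_regions([1, 2, 3], [10, 11, 12])
        assert h == pytest.approx(27.0 / 7.0, rel=1e-12)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 30), rng.normal(1, 1, 25)
        h1, _ = compare_regions(a, b)
        h2, _ = compare_regions(np.exp(a), np.exp(b))
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            compare_regions([], [1.0])


class TestPartitionInvariants:
    def test_bridges_counted_once_per_pair(self, default_network):
        vg, _ = default_network
        part = cluster_communities(vg, "w_0", seed=0)
        n_bridges = sum(1 for u, v, k, d in vg.g.edges(keys=True, data=True)
                        if part.node_community[u] != part.node_community[v])
        assert sum(part.n_ev_pairs.values()) == n_bridges
        assert sum(part.n_iv.values()) + n_bridges == vg.n_edges

    def test_functional_weights_give_at_least_structural_counts(self, default_network):
        from vasculome.hemodynamics import compute_resistances

        vg, _ = default_network
        compute_resistances(vg)
        n_structural = max(cluster_communities(vg, s, seed=0).n_communities
                           for s in ("w_0", "w_1", "w_2"))
        n_functional = min(cluster_communities(vg, s, seed=0).n_communities
                           for s in ("w_3", "w_4"))
        assert n_functional >= n_structural

    def test_flow_orientation_changes_counts_by_less_than_5pc(self, default_network):
        # clustering the flow-oriented graph (edges directed along the solved
        # fluxes) yields nearly the same number of communities as undirected
        from vasculome.hemodynamics import BoundaryConditionSet, solve_pressures

        vg, _ = default_network
        n_undirected = cluster_communities(vg, "w_3", seed=0).n_communities
        sol = solve_pressures(vg, BoundaryConditionSet.from_graph(vg))
        dg = nx.DiGraph()
        dg.add_nodes_from(vg.g.nodes())
        for u, v, k, d in vg.g.edges(keys=True, data=True):
            a, b = sol.orientation[d["id"]]
            src, dst = (a, b) if sol.fluxes[d["id"]] >= 0 else (b, a)
            w = dg[src][dst]["weight"] + d["resistance"] \
                if dg.has_edge(src, dst) else d["resistance"]
            dg.add_edge(src, dst, weight=w)
        comms = nx.community.louvain_communities(dg, weight="weight", seed=0)
        assert abs(len(comms) - n_undirected) / n_undirected < 0.05
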