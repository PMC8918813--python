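"""Idealized network construction and the Poiseuille pressure/flow/WSS solve."""

import dataclasses
from collections import Counter
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from vesseldyn.flow_model import (FlowParameters, VesselNetwork,
                                  build_idealized_network, class_diameter_functions,
                                  edge_conductance, simulate_timecourse,
                                  solve_pressures)

UNIFORM_FNS = {"DA": lambda t: 25e-6, "DLAV": lambda t: 8e-6,
               "aISV": lambda t: 7e-6, "vISV": lambda t: 8e-6}


def dense_oracle_pressures(network: VesselNetwork, params: FlowParameters,
                           t: float) -> dict:
    """Independent brute-force solve: full system with Dirichlet rows."""
    nodes = sorted(network.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    b = np.zeros(n)
    fixed = {}
    for node, kind in network.boundary_nodes.items():
        fixed[node] = {"inlet": params.p_da_in,
                       "outlet": params.outlet_pressure(network),
                       "sink": params.p_pcv}[kind]
    for u, v, data in network.graph.edges(data=True):
        D = network.edge_diameter(data, t)
        G = (params.conductance_floor if D == 0.0
             else np.pi * D**4 / (128 * params.mu * data["length"]))
        for a, o in ((u, v), (v, u)):
            if a not in fixed:
                A[index[a], index[a]] += G
                A[index[a], index[o]] -= G
    for node, p in fixed.items():
        A[index[node], index[node]] = 1.0
        b[index[node]] = p
    sol = np.linalg.solve(A, b)
    return {node: sol[i] for node, i in index.items()}


class TestConstruction:
    def test_default_build_counts(self):
        net = build_idealized_network(75.0, 100.0)
        classes = Counter(d["vessel_class"] for _, _, d in net.graph.edges(data=True))
        assert classes["aISV"] == 15 and classes["vISV"] == 15
        kinds = Counter(net.boundary_nodes.values())
        assert kinds == {"inlet": 1, "outlet": 1, "sink": 15}

    def test_minimal_single_aisv(self):
        net = build_idealized_network(75.0, 100.0, n_isv=1)
        classes = Counter(d["vessel_class"] for _, _, d in net.graph.edges(data=True))
        assert classes == {"DA": 2, "aISV": 1}
        assert Counter(net.boundary_nodes.values()) == {"inlet": 1, "outlet": 1}

    def test_four_isv_hand_enumeration(self):
        net = build_idealized_network(75.0, 100.0, n_isv=4)
        assert net.n_nodes == 10
        assert net.graph.number_of_edges() == 10
        classes = Counter(d["vessel_class"] for _, _, d in net.graph.edges(data=True))
        assert classes == {"DA": 3, "DLAV": 3, "aISV": 2, "vISV": 2}

    def test_zero_isv_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            build_idealized_network(75.0, 100.0, n_isv=0)

    def test_connected_with_positive_diameters(self):
        net = build_idealized_network(75.0, 100.0, diameter_fn=UNIFORM_FNS)
        assert net.is_connected()


class TestConductance:
    def test_closed_form_exact(self):
        # high-precision oracle: G * 128 mu L / D^4 must equal pi exactly
        D, L, mu = 7e-6, 100e-6, 3.5e-3
        G = edge_conductance(D, L, mu)
        ratio = G * 128 * Fraction(35, 10_000) * Fraction(1, 10_000) / Fraction(7, 10**6) ** 4
        assert float(ratio) == pytest.approx(np.pi, rel=1e-12)
        assert G == pytest.approx(1.6837e-16, rel=1e-4)

    def test_zero_diameter_floor(self):
        assert edge_conductance(0.0, 1e-4, 3.5e-3) == 1e-30

    def test_quartic_scaling(self):
        g1 = edge_conductance(5e-6, 1e-4, 3.5e-3)
        g2 = edge_conductance(10e-6, 1e-4, 3.5e-3)
        assert g2 / g1 == pytest.approx(16.0, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            edge_conductance(-1e-6, 1e-4, 3.5e-3)
        with pytest.raises(ValueError):
            edge_conductance(1e-6, 0.0, 3.5e-3)


def two_node_net(d1=10e-6, d2=10e-6, L=1e-3):
    g = nx.Graph()
    g.add_node("a", pos=(0.0, 0.0), boundary="inlet")
    g.add_node("m", pos=(L, 0.0))
    g.add_node("b", pos=(2 * L, 0.0), boundary="sink")
    g.add_edge("a", "m", eid=0, vessel_class="DA", length=L, orient=("a", "m"),
               diameter=d1)
    g.add_edge("m", "b", eid=1, vessel_class="DA", length=L, orient=("m", "b"),
               diameter=d2)
    return VesselNetwork(graph=g)


class TestSolve:
    def test_single_edge_between_boundaries(self):
        g = nx.Graph()
        g.add_node("a", pos=(0.0, 0.0), boundary="inlet")
        g.add_node("b", pos=(1e-3, 0.0), boundary="sink")
        g.add_edge("a", "b", eid=0, vessel_class="DA", length=1e-3,
                   orient=("a", "b"), diameter=10e-6)
        sol = solve_pressures(VesselNetwork(graph=g), FlowParameters(), 0.0)
        assert sol.node_pressures == {"a": 201.3, "b": 0.0}
        assert sol.edges["Q"].iloc[0] > 0

    def test_series_midpoint_is_mean(self):
        sol = solve_pressures(two_node_net(), FlowParameters(), 0.0)
        assert sol.node_pressures["m"] == pytest.approx(201.3 / 2, rel=1e-12)

    def test_worked_single_vessel_wss(self):
        # D = 10 um, L = 1 mm, dp = 100 Pa  ->  tau = D dp / 4L = 0.25 Pa
        params = dataclasses.replace(FlowParameters(), p_da_in=100.0)
        g = nx.Graph()
        g.add_node("a", pos=(0.0, 0.0), boundary="inlet")
        g.add_node("b", pos=(1e-3, 0.0), boundary="sink")
        g.add_edge("a", "b", eid=0, vessel_class="aISV", length=1e-3,
                   orient=("a", "b"), diameter=10e-6)
        sol = solve_pressures(VesselNetwork(graph=g), params, 0.0)
        assert sol.edges["tau"].iloc[0] == pytest.approx(0.25, rel=1e-12)

    def test_orientation_reversal_negates_q_only(self):
        net = two_node_net()
        sol = solve_pressures(net, FlowParameters(), 0.0)
        for _, _, data in net.graph.edges(data=True):
            data["orient"] = (data["orient"][1], data["orient"][0])
        rev = solve_pressures(net, FlowParameters(), 0.0)
        np.testing.assert_allclose(rev.edges["Q"], -sol.edges["Q"], rtol=1e-12)
        np.testing.assert_allclose(rev.edges["tau"], sol.edges["tau"], rtol=1e-12)

    def test_matches_dense_oracle_and_kirchhoff(self):
        net = build_idealized_network(75.0, 100.0, n_isv=4, diameter_fn=UNIFORM_FNS)
        params = dataclasses.replace(
            FlowParameters(), da_outlet_pressure=lambda n, p: p.p_da_in)  # flat DA
        sol = solve_pressures(net, params, 30.0)
        oracle = dense_oracle_pressures(net, params, 30.0)
        for node, p in oracle.items():
            assert sol.node_pressures[node] == pytest.approx(p, rel=1e-10, abs=1e-12)
        assert sol.kirchhoff_residual(net) <= 1e-12

    def test_symmetric_network_equalizes_classes(self):
        # zero DA gradient + equipotential DA/DLAV trunks: every ISV of a
        # class sees the same boundary pressures, so |Q| and tau coincide
        params = dataclasses.replace(
            FlowParameters(), da_outlet_pressure=lambda n, p: p.p_da_in)
        fns = dict(UNIFORM_FNS)
        fns["DA"] = fns["DLAV"] = lambda t: 5e-3
        net = build_idealized_network(75.0, 100.0, n_isv=8, diameter_fn=fns)
        sol = solve_pressures(net, params, 30.0)
        for cls in ("aISV", "vISV"):
            sub = sol.edges.loc[sol.edges["vessel_class"] == cls]
            np.testing.assert_allclose(sub["tau"], sub["tau"].iloc[0], rtol=1e-9)
            np.testing.assert_allclose(sub["Q"].abs(), sub["Q"].abs().iloc[0],
                                       rtol=1e-9)

    def test_floored_edge_reports_zero_wss(self):
        sol = solve_pressures(two_node_net(d2=0.0), FlowParameters(), 0.0)
        assert sol.edges.loc[sol.edges["D"] == 0.0, "tau"].iloc[0] == 0.0


class TestTimecourse:
    def test_constant_diameters_constant_wss(self):
        net = build_idealized_network(75.0, 100.0, n_isv=6, diameter_fn=UNIFORM_FNS)
        _, summary = simulate_timecourse(net, FlowParameters(), np.arange(26.0, 44.1, 3.0))
        for _, sub in summary.groupby("vessel_class"):
            np.testing.assert_allclose(sub["mean_tau"], sub["mean_tau"].iloc[0],
                                       rtol=1e-12)

    def test_visv_growth_raises_aisv_wss(self):
        # enlarging veins increases flow through the whole network, raising
        # arterial WSS although arterial diameters never change
        fns = dict(UNIFORM_FNS)
        fns["vISV"] = lambda t: (8.0 + 8.0 * (t - 26.0) / 18.0) * 1e-6
        net = build_idealized_network(75.0, 100.0, n_isv=10, diameter_fn=fns)
        _, summary = simulate_timecourse(net, FlowParameters(), [26.0, 44.0])
        a = summary[summary["vessel_class"] == "aISV"].sort_values("t")
        assert a["mean_tau"].iloc[-1] > a["mean_tau"].iloc[0]

    def test_uniform_viscosity_rescale_leaves_wss_unchanged(self):
        net = build_idealized_network(75.0, 100.0, n_isv=6, diameter_fn=UNIFORM_FNS)
        times = np.arange(26.0, 44.1, 6.0)
        _, s1 = simulate_timecourse(net, FlowParameters(), times)
        _, s3 = simulate_timecourse(
            net, dataclasses.replace(FlowParameters(), mu=3 * 3.5e-3), times)
        np.testing.assert_allclose(s3["mean_tau"], s1["mean_tau"], rtol=1e-12)

    def test_vein_dilation_never_decreases_inlet_flow(self):
        def inlet_flow(net, t=30.0):
            sol = solve_pressures(net, FlowParameters(), t)
            mask = (sol.edges["u"] == "da_in") | (sol.edges["v"] == "da_in")
            return abs(float(sol.edges.loc[mask, "Q"].iloc[0]))

        net = build_idealized_network(75.0, 100.0, n_isv=6, diameter_fn=UNIFORM_FNS)
        base = inlet_flow(net)
        for u, v, data in net.graph.edges(data=True):
            if data["vessel_class"] == "vISV":
                data["diameter"] = 12e-6
                break
        assert inlet_flow(net) >= base

    def test_diameter_functions_from_table(self, default_embryo):
        _, _, diameters, _ = default_embryo
        fns = class_diameter_functions(diameters)
        assert set(fns) == {"DA", "DLAV", "aISV", "vISV"}
        assert 0 < fns["aISV"](44.0) < 20e-6  # metres, single-digit um scale
        net = build_idealized_network(75.0, 100.0, n_isv=30, diameter_fn=fns)
        sol = solve_pressures(net, FlowParameters(), 35.0)
        assert sol.kirchhoff_residual(net) <= 1e-12
        assert (sol.edges["tau"] >= 0).all()
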