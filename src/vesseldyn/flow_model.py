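"""Idealized intersegmental-vessel network haemodynamics.

The trunk vasculature is represented as a graph: a dorsal aorta (DA) chain
from an inlet through the arterial ISV base nodes to an outlet, a DLAV chain
across all ISV apices, arterial ISVs connecting DA to DLAV and venous ISVs
draining the DLAV into terminal sink nodes standing in for the PCV.  Each
edge carries a per-class diameter function over developmental time.  Flow is
laminar Poiseuille flow: the conductance of edge j is

    G_j = pi D_j^4 / (128 mu L_j),

nodal pressures solve the flow-balance (Kirchhoff) linear system with
Dirichlet pressures at the boundary nodes (DA inlet 201.3 Pa, DA outlet set
by dissipating the inlet pressure over the 2 mm body length, every venous
terminal at the 0 Pa PCV sink), and per-edge flow and wall shear stress are

    Q_j = G_j (p_u - p_v),      tau_j = 32 mu |Q_j| / (pi D_j^3) = D_j |dp_j| / (4 L_j).

Edges with no diameter measurement (D = 0 sentinel) keep the system
invertible through a 1e-30 conductance floor and report tau = 0.  All
internal arithmetic is strict SI (m, Pa, s); micrometre diameters are
converted once at ingest because the D^4 dependence makes unit slips
catastrophic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .track_model import DiameterTable

__all__ = [
    "FlowParameters",
    "VesselNetwork",
    "FlowSolution",
    "build_idealized_network",
    "edge_conductance",
    "class_diameter_functions",
    "solve_pressures",
    "flow_and_wss",
    "simulate_timecourse",
]

UM = 1e-6  # micrometres -> metres


@dataclass(frozen=True)
class FlowParameters:
    """Physical parameters of the flow model (SI units)."""

    mu: float = 3.5e-3             # dynamic viscosity of blood, kg m^-1 s^-1
    p_da_in: float = 201.3         # DA inlet pressure, Pa
    p_pcv: float = 0.0             # venous sink pressure, Pa
    l_fish: float = 2e-3           # body length dissipating the DA gradient, m
    conductance_floor: float = 1e-30  # keeps [G] invertible for D = 0 edges
    da_outlet_pressure: Callable[["VesselNetwork", "FlowParameters"], float] | None = None

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.conductance_floor <= 0 or self.l_fish <= 0:
            raise ValueError("mu, l_fish and conductance_floor must be positive")
        if self.p_da_in <= self.p_pcv:
            raise ValueError("inlet pressure must exceed the sink pressure")

    def outlet_pressure(self, network: "VesselNetwork") -> float:
        """DA outlet pressure: the inlet gradient applied to the modelled DA span."""
        if self.da_outlet_pressure is not None:
            return float(self.da_outlet_pressure(network, self))
        return self.p_da_in * (1.0 - network.da_length / self.l_fish)


@dataclass
class VesselNetwork:
    """Vessel graph with boundary conditions and per-class diameter functions.

    ``graph`` is an undirected networkx graph whose nodes carry ``pos`` (m)
    and optionally ``boundary`` ("inlet" | "outlet" | "sink"); edges carry
    ``eid``, ``vessel_class``, ``length`` (m) and optionally a fixed
    ``diameter`` (m).  ``diameter_fn`` maps a vessel class to a callable
    t -> diameter in metres; a fixed edge diameter overrides it.
    """

    graph: nx.Graph
    diameter_fn: dict[str, Callable[[float], float]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edges(self) -> list[tuple]:
        return sorted(self.graph.edges(data=True), key=lambda e: e[2]["eid"])

    @property
    def boundary_nodes(self) -> dict:
        return {n: d["boundary"] for n, d in self.graph.nodes(data=True)
                if d.get("boundary")}

    @property
    def da_length(self) -> float:
        return sum(d["length"] for _, _, d in self.graph.edges(data=True)
                   if d["vessel_class"] == "DA")

    def edge_diameter(self, data: dict, t: float) -> float:
        if "diameter" in data:
            return float(data["diameter"])
        fn = self.diameter_fn.get(data["vessel_class"])
        if fn is None:
            raise KeyError(f"no diameter function for class {data['vessel_class']!r}")
        return float(fn(t))

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)


@dataclass
class FlowSolution:
    """Pressures, flows and wall shear stresses at one time point."""

    t: float
    node_pressures: dict
    edges: pd.DataFrame  # eid, u, v, vessel_class, D, L, G, dp, Q, tau

    def kirchhoff_residual(self, network: VesselNetwork) -> float:
        """Max interior-node flow imbalance relative to the largest |Q|."""
        imbalance: dict = {n: 0.0 for n in network.graph.nodes}
        for row in self.edges.itertuples():
            imbalance[row.u] -= row.Q   # Q > 0 flows u -> v
            imbalance[row.v] += row.Q
        boundary = network.boundary_nodes
        interior = [abs(q) for n, q in imbalance.items() if n not in boundary]
        qmax = float(self.edges["Q"].abs().max())
        if qmax == 0.0:
            return 0.0
        return max(interior, default=0.0) / qmax


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def class_diameter_functions(
    diameters: DiameterTable,
) -> dict[str, Callable[[float], float]]:
    """Mean-diameter-per-class interpolants (input um -> output metres).

    Linear interpolation on the measurement grid, clamped at the ends; times
    with a 0 sentinel mean are dropped so the flow model's floor handles them.
    """
    fns: dict[str, Callable[[float], float]] = {}
    means = diameters.class_mean()
    for cls, sub in means.groupby("vessel_class"):
        t = sub["t"].to_numpy(dtype=float)
        d = sub["diameter"].to_numpy(dtype=float) * UM
        order = np.argsort(t)
        t, d = t[order], d[order]
        fns[str(cls)] = (lambda tt, t=t, d=d:
                         float(np.interp(tt, t, d)))
    return fns


def build_idealized_network(
    isv_spacing: float,
    isv_length: float,
    n_isv: int = 30,
    first_class: str = "aISV",
    diameter_fn: dict[str, Callable[[float], float]] | None = None,
) -> VesselNetwork:
    """Build the idealized alternating aISV/vISV trunk network.

    ``isv_spacing`` and ``isv_length`` are in micrometres (converted to SI).
    The default 30-ISV build has 15 aISVs bridging DA to DLAV and 15 vISVs
    draining the DLAV into terminal sink nodes; boundary nodes are exactly
    the DA inlet, the DA outlet and the venous terminals.
    """
    if n_isv < 1:
        raise ValueError("need at least one ISV")
    if first_class not in ("aISV", "vISV"):
        raise ValueError("first_class must be 'aISV' or 'vISV'")
    spacing = isv_spacing * UM
    length = isv_length * UM
    g = nx.Graph()
    eid = 0

    def add_edge(u, v, cls):
        nonlocal eid
        pu, pv = np.asarray(g.nodes[u]["pos"]), np.asarray(g.nodes[v]["pos"])
        g.add_edge(u, v, eid=eid, vessel_class=cls,
                   length=float(np.linalg.norm(pu - pv)), orient=(u, v))
        eid += 1

    classes = ["aISV", "vISV"]
    off = classes.index(first_class)
    g.add_node("da_in", pos=(0.0, 0.0), boundary="inlet")
    prev_da = "da_in"
    last_a_x = 0.0
    for k in range(n_isv):
        cls = classes[(k + off) % 2]
        x = spacing * (k + 1)
        apex = f"apex_{k + 1:02d}"
        g.add_node(apex, pos=(x, length))
        if cls == "aISV":
            base = f"base_{k + 1:02d}"
            g.add_node(base, pos=(x, 0.0))
            add_edge(prev_da, base, "DA")
            add_edge(base, apex, "aISV")
            prev_da = base
            last_a_x = x
        else:
            sink = f"sink_{k + 1:02d}"
            g.add_node(sink, pos=(x, 0.0), boundary="sink")
            add_edge(apex, sink, "vISV")
    out_x = last_a_x + spacing if last_a_x > 0 else spacing
    g.add_node("da_out", pos=(out_x, 0.0), boundary="outlet")
    add_edge(prev_da, "da_out", "DA")
    for k in range(n_isv - 1):
        add_edge(f"apex_{k + 1:02d}", f"apex_{k + 2:02d}", "DLAV")
    return VesselNetwork(graph=g, diameter_fn=dict(diameter_fn or {}))


# ---------------------------------------------------------------------------
# physics
# ---------------------------------------------------------------------------

def edge_conductance(D: float, L: float, mu: float,
                     conductance_floor: float = 1e-30) -> float:
    """Poiseuille conductance pi D^4 / (128 mu L); floor for the D = 0 sentinel."""
    if D < 0 or L <= 0 or mu <= 0:
        raise ValueError("need D >= 0, L > 0, mu > 0")
    if D == 0.0:
        return conductance_floor
    return np.pi * D**4 / (128.0 * mu * L)


def _boundary_pressures(network: VesselNetwork, params: FlowParameters) -> dict:
    out = {}
    for node, kind in network.boundary_nodes.items():
        if kind == "inlet":
            out[node] = params.p_da_in
        elif kind == "outlet":
            out[node] = params.outlet_pressure(network)
        elif kind == "sink":
            out[node] = params.p_pcv
        else:
            raise ValueError(f"unknown boundary kind {kind!r} at {node}")
    return out


def solve_pressures(
    network: VesselNetwork,
    params: FlowParameters = FlowParameters(),
    t: float = 0.0,
    dense: bool = False,
) -> FlowSolution:
    """Solve the nodal flow-balance system at time ``t`` and derive Q and tau.

    Interior pressures solve sum_j G_j (p_i - p_k) = 0 at every interior node
    with Dirichlet boundary pressures; a sparse symmetric solve with a dense
    fallback.  The conductance floor guards conditioning.
    """
    g = network.graph
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    fixed = _boundary_pressures(network, params)
    if not fixed:
        raise ValueError("network has no boundary nodes; pressures undetermined")

    edge_rows = []
    for u, v, data in network.edges:
        u0, v0 = data.get("orient", (u, v))
        D = network.edge_diameter(data, t)
        G = edge_conductance(D, data["length"], params.mu, params.conductance_floor)
        edge_rows.append((data["eid"], u0, v0, data["vessel_class"], D,
                          data["length"], G))

    n = len(nodes)
    interior = [i for i, node in enumerate(nodes) if node not in fixed]
    pressures = np.zeros(n)
    for node, p in fixed.items():
        pressures[index[node]] = p

    if interior:
        pos = {i: k for k, i in enumerate(interior)}
        rows, cols, vals = [], [], []
        b = np.zeros(len(interior))
        for _, u0, v0, _, _, _, G in edge_rows:
            iu, iv = index[u0], index[v0]
            for a, other in ((iu, iv), (iv, iu)):
                if a in pos:
                    rows.append(pos[a]); cols.append(pos[a]); vals.append(G)
                    if other in pos:
                        rows.append(pos[a]); cols.append(pos[other]); vals.append(-G)
                    else:
                        b[pos[a]] += G * pressures[other]
        A = sp.csr_matrix((vals, (rows, cols)), shape=(len(interior), len(interior)))
        if dense:
            sol = np.linalg.solve(A.toarray(), b)
        else:
            try:
                sol = spla.spsolve(A.tocsc(), b)
            except Exception:
                sol = np.linalg.solve(A.toarray(), b)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError(
                f"singular flow system at t={t}: {len(interior)} interior nodes, "
                f"{len(edge_rows)} edges"
            )
        pressures[interior] = sol

    return flow_and_wss(pressures, index, edge_rows, params, t)


def flow_and_wss(pressures, node_index, edge_rows, params: FlowParameters,
                 t: float) -> FlowSolution:
    """Per-edge pressure drop, flow Q = G dp and wall shear stress tau."""
    recs = []
    for eid, u0, v0, cls, D, L, G in edge_rows:
        dp = pressures[node_index[u0]] - pressures[node_index[v0]]
        Q = G * dp
        floored = D == 0.0 or G <= params.conductance_floor
        tau = 0.0 if floored else 32.0 * params.mu * abs(Q) / (np.pi * D**3)
        recs.append((eid, u0, v0, cls, D, L, G, dp, Q, tau))
    edges = pd.DataFrame(recs, columns=["eid", "u", "v", "vessel_class", "D", "L",
                                        "G", "dp", "Q", "tau"])
    node_p = {n: float(pressures[i]) for n, i in node_index.items()}
    return FlowSolution(t=float(t), node_pressures=node_p, edges=edges)


def simulate_timecourse(
    network: VesselNetwork,
    params: FlowParameters = FlowParameters(),
    times: np.ndarray | None = None,
) -> tuple[list[FlowSolution], pd.DataFrame]:
    """Re-solve the network over developmental time; per-class WSS summary.

    Returns the per-time solutions and a tidy frame of class-mean |Q| and tau
    (the conductance matrix is reassembled from the diameter functions at
    every time point).
    """
    if times is None:
        raise ValueError("provide the diameter-measurement time grid")
    sols = []
    rows = []
    for t in np.asarray(times, dtype=float):
        sol = solve_pressures(network, params, t)
        sols.append(sol)
        for cls, sub in sol.edges.groupby("vessel_class"):
            rows.append((t, cls, float(sub["tau"].mean()),
                         float(sub["Q"].abs().mean()), len(sub)))
    summary = pd.DataFrame(rows, columns=["t", "vessel_class", "mean_tau",
                                          "mean_abs_Q", "n_edges"])
    return sols, summary
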