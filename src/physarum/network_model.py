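"""Deterministic adaptive flow-network model of *Physarum polycephalum*.

The plasmodium's tube network is represented as a graph whose edges carry
a length ``L`` and a lumped conductivity ``D`` (tube radius and protoplasm
viscosity enter only through ``D``).  Fluid driven between two food-source
nodes follows a Poiseuille/Kirchhoff flow, and each tube adapts its
conductivity to the flux it carries,

    dD_ij/dt = f(|Q_ij|) - delta * D_ij,

with a saturating (sigmoidal) response

    f(Q) = (1 + eps) * Q**mu / (eps + Q**mu).

Tubes carrying large flux are reinforced while unused tubes decay, which
is the mechanism by which the organism prunes a maze down to a short path
between the food sources.  The module also provides the reduction of this
dynamics to two competing paths, the starting point of the stochastic
decision model in :mod:`physarum.twopath_sde`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Hashable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ResponseParams",
    "TubeNetwork",
    "FlowSolution",
    "AdaptationResult",
    "response_f",
    "solve_flows",
    "adapt_network",
    "two_path_rhs",
    "integrate_two_path",
    "two_path_network",
    "maze_network",
    "read_network",
    "write_network",
    "SingularFlowError",
]

Node = Hashable


class SingularFlowError(RuntimeError):
    """Raised when the food sources are not connected by conducting tubes."""


@dataclass(frozen=True)
class ResponseParams:
    """Parameters of the conductivity adaptation law.

    epsilon
        Saturation parameter of the sigmoidal response (the ratio gamma/alpha
        of the underlying three-parameter form; only this combination matters).
        ``epsilon < 1/4`` puts the two-path system in its tristable regime.
    mu
        Response exponent; ``mu = 2`` throughout the canonical experiments.
    delta
        Tube decay (thinning) rate, setting the relaxation time ``1/delta``.
    """

    epsilon: float = 0.2
    mu: float = 2.0
    delta: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.mu <= 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")


def response_f(q, params: ResponseParams):
    """Sigmoidal flux response f(Q) = (1+eps) Q^mu / (eps + Q^mu).

    Monotone increasing on Q >= 0, with f(0) = 0, f(1) = 1 and saturation
    level 1 + eps as Q -> infinity.  Callers pass the absolute flux.
    """
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr < 0):
        raise ValueError("response_f requires Q >= 0 (pass |Q|)")
    qm = q_arr**params.mu
    denom = params.epsilon + qm
    out = np.divide(
        (1.0 + params.epsilon) * qm,
        denom,
        out=np.zeros_like(qm),
        where=denom > 0,
    )
    return out if out.ndim else float(out)


@dataclass
class TubeNetwork:
    """A tube network: edges with lengths and conductivities plus two sources.

    ``source`` is the inflow food source (net inflow ``source_strength``) and
    ``sink`` the outflow one; total volume is conserved (S1 + S2 = 0).
    Parallel edges are allowed (the two-path system is exactly a pair of
    parallel tubes between the food sources).
    """

    edges: list[tuple[Node, Node]]
    lengths: np.ndarray
    conductivities: np.ndarray
    source: Node
    sink: Node
    source_strength: float = 1.0

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.conductivities = np.asarray(self.conductivities, dtype=float)
        n = len(self.edges)
        if self.lengths.shape != (n,) or self.conductivities.shape != (n,):
            raise ValueError("lengths/conductivities must match the edge list")
        if np.any(self.lengths <= 0):
            raise ValueError("all tube lengths must be strictly positive")
        if np.any(self.conductivities < 0):
            raise ValueError("conductivities must be non-negative")
        if self.source == self.sink:
            raise ValueError("the two food-source nodes must be distinct")
        nodes = self.nodes
        if self.source not in nodes or self.sink not in nodes:
            raise ValueError("source and sink must appear in the edge list")

    @classmethod
    def from_edges(
        cls,
        edges: Sequence[tuple[Node, Node, float, float]],
        source: Node,
        sink: Node,
        source_strength: float = 1.0,
    ) -> "TubeNetwork":
        """Build from ``(i, j, length, conductivity)`` tuples."""
        pairs = [(u, v) for u, v, _, _ in edges]
        lengths = np.array([e[2] for e in edges], dtype=float)
        conds = np.array([e[3] for e in edges], dtype=float)
        return cls(pairs, lengths, conds, source, sink, source_strength)

    @property
    def nodes(self) -> list[Node]:
        seen: dict[Node, None] = {}
        for u, v in self.edges:
            seen.setdefault(u)
            seen.setdefault(v)
        return list(seen)

    def with_conductivities(self, conductivities: np.ndarray) -> "TubeNetwork":
        return replace(self, conductivities=np.asarray(conductivities, float))

    def to_graph(self, min_conductivity: float = 0.0) -> nx.MultiGraph:
        """networkx view keeping edges with D > ``min_conductivity``."""
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for (u, v), length, cond in zip(
            self.edges, self.lengths, self.conductivities
        ):
            if cond > min_conductivity:
                g.add_edge(u, v, length=length, conductivity=cond)
        return g


@dataclass
class FlowSolution:
    """Node pressures (sink grounded at 0) and signed per-edge fluxes."""

    pressures: dict[Node, float]
    fluxes: np.ndarray
    edges: list[tuple[Node, Node]]

    def flux_of(self, u: Node, v: Node) -> float:
        """Signed flux on the first edge (u, v); sign flips with orientation."""
        for k, (a, b) in enumerate(self.edges):
            if (a, b) == (u, v):
                return float(self.fluxes[k])
            if (a, b) == (v, u):
                return -float(self.fluxes[k])
        raise KeyError((u, v))


def solve_flows(net: TubeNetwork) -> FlowSolution:
    """Solve the Kirchhoff node-balance system for the steady Poiseuille flow.

    Edge conductances are ``D_ij / L_ij``; net flux is ``+S0`` at the source,
    ``-S0`` at the sink and zero elsewhere.  The sink pressure is fixed to 0
    (the gauge does not affect fluxes).  Nodes outside the conducting
    component of the source are assigned pressure 0; their edges carry no
    flux.
    """
    nodes = net.nodes
    index = {n: k for k, n in enumerate(nodes)}
    n = len(nodes)
    g = net.conductivities / net.lengths

    # connectivity through conducting tubes only
    live = nx.Graph()
    live.add_nodes_from(nodes)
    for (u, v), gk in zip(net.edges, g):
        if gk > 0:
            live.add_edge(u, v)
    if not nx.has_path(live, net.source, net.sink):
        raise SingularFlowError(
            "source and sink are not connected through conducting tubes"
        )
    component = nx.node_connected_component(live, net.source)

    lap = np.zeros((n, n))
    iu = np.array([index[u] for u, _ in net.edges])
    iv = np.array([index[v] for _, v in net.edges])
    np.add.at(lap, (iu, iu), g)
    np.add.at(lap, (iv, iv), g)
    np.add.at(lap, (iu, iv), -g)
    np.add.at(lap, (iv, iu), -g)

    rhs = np.zeros(n)
    rhs[index[net.source]] = net.source_strength
    rhs[index[net.sink]] = -net.source_strength

    free = sorted(
        index[m] for m in component if m != net.sink
    )
    p = np.zeros(n)
    if free:
        sub = lap[np.ix_(free, free)]
        p[free] = np.linalg.solve(sub, rhs[free])

    fluxes = g * (p[iu] - p[iv])
    pressures = {m: float(p[index[m]]) for m in nodes}
    return FlowSolution(pressures, fluxes, list(net.edges))


@dataclass
class AdaptationResult:
    """Sampled conductivity trajectory of :func:`adapt_network`."""

    times: np.ndarray
    conductivities: np.ndarray  # shape (n_samples, n_edges)
    edges: list[tuple[Node, Node]]
    final: TubeNetwork

    def to_frame(self) -> pd.DataFrame:
        """Tidy (t, edge, D) frame."""
        labels = [f"{u}-{v}" for u, v in self.edges]
        rows = []
        for t, row in zip(self.times, self.conductivities):
            for lab, d in zip(labels, row):
                rows.append((t, lab, d))
        return pd.DataFrame(rows, columns=["t", "edge", "D"])


def adapt_network(
    net: TubeNetwork,
    params: ResponseParams,
    dt: float | None = None,
    t_end: float = 50.0,
    record_every: int = 10,
) -> AdaptationResult:
    """Integrate the network adaptation dynamics by explicit Euler stepping.

    Alternates a steady-flow solve with the conductivity update
    ``D += dt * (f(|Q|) - delta D)``, clipping D at zero.  ``dt`` defaults to
    ``0.01 / delta``, well below the relaxation time.
    """
    if dt is None:
        dt = 0.01 / params.delta
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    n_steps = int(round(t_end / dt))
    d = net.conductivities.astype(float).copy()
    times = [0.0]
    states = [d.copy()]
    current = net
    for k in range(n_steps):
        current = net.with_conductivities(d)
        sol = solve_flows(current)
        d = d + dt * (response_f(np.abs(sol.fluxes), params) - params.delta * d)
        np.clip(d, 0.0, None, out=d)
        if (k + 1) % record_every == 0 or k == n_steps - 1:
            times.append((k + 1) * dt)
            states.append(d.copy())
    return AdaptationResult(
        np.asarray(times), np.vstack(states), list(net.edges),
        net.with_conductivities(d),
    )


def two_path_rhs(
    D1,
    D2,
    params: ResponseParams,
    L1: float = 1.0,
    L2: float = 1.0,
):
    """Deterministic drift of the two-path reduction.

    dD_i/dt = -delta D_i + f( (D_i/L_i) / (D_1/L_1 + D_2/L_2) ): the flux
    argument is the conductance share of branch i (total flux normalised
    to 1).  Broadcasts over arrays of states.
    """
    d1 = np.asarray(D1, dtype=float)
    d2 = np.asarray(D2, dtype=float)
    c1 = d1 / L1
    c2 = d2 / L2
    total = c1 + c2
    if np.any(total <= 0):
        raise ValueError("two_path_rhs undefined at D1 = D2 = 0")
    f1 = response_f(c1 / total, params)
    f2 = response_f(c2 / total, params)
    r1 = -params.delta * d1 + f1
    r2 = -params.delta * d2 + f2
    if np.ndim(D1) == 0 and np.ndim(D2) == 0:
        return float(r1), float(r2)
    return r1, r2


def integrate_two_path(
    D1_0,
    D2_0,
    params: ResponseParams,
    L1: float = 1.0,
    L2: float = 1.0,
    dt: float | None = None,
    t_end: float = 50.0,
):
    """Euler integration of :func:`two_path_rhs`, vectorised over initial states.

    Returns the terminal ``(D1, D2)``.  Conductivities are clipped at zero.
    """
    if dt is None:
        dt = 0.01 / params.delta
    d1 = np.asarray(D1_0, dtype=float).copy()
    d2 = np.asarray(D2_0, dtype=float).copy()
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        r1, r2 = two_path_rhs(d1, d2, params, L1, L2)
        d1 = np.clip(d1 + dt * np.asarray(r1), 0.0, None)
        d2 = np.clip(d2 + dt * np.asarray(r2), 0.0, None)
    return d1, d2


# ---------------------------------------------------------------------------
# canonical small networks


def two_path_network(
    D1: float = 0.5,
    D2: float = 1.0,
    L1: float = 1.0,
    L2: float = 1.0,
    source_strength: float = 1.0,
) -> TubeNetwork:
    """Two parallel tubes between the food sources N1 and N2."""
    return TubeNetwork.from_edges(
        [("N1", "N2", L1, D1), ("N1", "N2", L2, D2)],
        source="N1",
        sink="N2",
        source_strength=source_strength,
    )


def maze_network(D0: float = 1.0) -> TubeNetwork:
    """Small planar maze with several N1-N2 routes of distinct total length.

    Synthetic stand-in for the classic maze-solving arena: a handful of
    junction nodes with a unique shortest route (N1-a-b-N2, total length 4)
    competing against two longer detours and a cross-link.  With uniform
    initial conductivities the adaptation dynamics should retain only the
    shortest route.
    """
    edges = [
        ("N1", "a", 1.0, D0),
        ("a", "b", 1.0, D0),
        ("b", "N2", 2.0, D0),
        ("N1", "c", 2.0, D0),
        ("c", "b", 2.0, D0),
        ("a", "d", 2.0, D0),
        ("d", "N2", 3.0, D0),
        ("c", "d", 1.0, D0),
    ]
    return TubeNetwork.from_edges(edges, source="N1", sink="N2")


# ---------------------------------------------------------------------------
# text I/O: "# {json header}" line followed by "i j L D" rows


def write_network(net: TubeNetwork, path: str | Path) -> None:
    header = {
        "N1": str(net.source),
        "N2": str(net.sink),
        "S0": net.source_strength,
    }
    lines = ["# " + json.dumps(header)]
    for (u, v), length, cond in zip(net.edges, net.lengths, net.conductivities):
        lines.append(f"{u} {v} {float(length)!r} {float(cond)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_network(path: str | Path) -> TubeNetwork:
    text = Path(path).read_text().strip().splitlines()
    if not text or not text[0].startswith("#"):
        raise ValueError("network file must start with a '# {json}' header")
    header = json.loads(text[0].lstrip("# "))
    edges = []
    for line in text[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        u, v, length, cond = line.split()
        edges.append((u, v, float(length), float(cond)))
    return TubeNetwork.from_edges(
        edges,
        source=header["N1"],
        sink=header["N2"],
        source_strength=float(header.get("S0", 1.0)),
    )
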