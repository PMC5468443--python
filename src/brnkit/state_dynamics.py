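"""Asynchronous qualitative dynamics of a logical network.

Under the asynchronous unit-step semantics, every entity whose focal level
differs from its current level is "called" to move one level toward it, and
each such call yields one outgoing transition of the state.  A state with no
calls is a stable state (deadlock).  Attractors are the terminal strongly
connected components of the resulting state transition digraph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import networkx as nx

from .logical_model import LogicalNetwork, Parameterization, State, focal

__all__ = [
    "StateGraph",
    "AttractorReport",
    "successors",
    "build_state_graph",
    "stable_states",
    "attractors",
    "export_state_graph",
    "state_graph_summary",
]

DEFAULT_STATE_CAP = 10**6


@dataclass
class StateGraph:
    """The full asynchronous state transition graph of (network, K).

    ``graph`` is a :class:`networkx.DiGraph` whose nodes are level tuples in
    ``network.entity_order``; nodes are inserted in lexicographic order and
    out-edges in entity order, so iteration order is deterministic.
    """

    network: LogicalNetwork
    K: Parameterization
    graph: nx.DiGraph
    betweenness: dict[State, float] | None = field(default=None, repr=False)

    @property
    def n_states(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def states(self) -> list[State]:
        return list(self.graph.nodes)


@dataclass
class AttractorReport:
    """Terminal SCCs of a state graph, classified stable vs cyclic."""

    attractors: list[frozenset[State]]
    kinds: list[str]  # "stable" | "cyclic", parallel to ``attractors``

    @property
    def n_attractors(self) -> int:
        return len(self.attractors)

    def stable(self) -> list[State]:
        return [next(iter(a)) for a, k in zip(self.attractors, self.kinds)
                if k == "stable"]


def successors(network: LogicalNetwork, K: Parameterization,
               state) -> set[State]:
    """Asynchronous successors: one per entity called toward its focal level.

    Empty iff the state is stable.
    """
    state = network.check_state(state)
    out = set()
    for i, name in enumerate(network.entity_order):
        target = focal(network, K, state, name)
        if target != state[i]:
            step = 1 if target > state[i] else -1
            out.add(state[:i] + (state[i] + step,) + state[i + 1:])
    return out


def _all_states(network: LogicalNetwork):
    ranges = [range(m + 1) for m in network.max_levels()]
    return product(*ranges)


def build_state_graph(network: LogicalNetwork, K: Parameterization,
                      cap: int = DEFAULT_STATE_CAP) -> StateGraph:
    """Exhaustively enumerate all states and asynchronous transitions."""
    n = network.n_states()
    if n > cap:
        raise ValueError(f"state space has {n} states, exceeding the cap {cap}; "
                         "raise `cap` explicitly to proceed")
    g = nx.DiGraph()
    for state in _all_states(network):
        g.add_node(state)
    for state in g.nodes:
        for i, name in enumerate(network.entity_order):
            target = focal(network, K, state, name)
            if target != state[i]:
                step = 1 if target > state[i] else -1
                g.add_edge(state, state[:i] + (state[i] + step,) + state[i + 1:])
    return StateGraph(network, K, g)


def stable_states(sg: StateGraph) -> list[State]:
    """States with no outgoing transition (focal = current for every entity)."""
    return [s for s in sg.graph.nodes if sg.graph.out_degree(s) == 0]


def attractors(sg: StateGraph) -> AttractorReport:
    """Terminal SCCs of the state graph.

    A singleton terminal SCC without a self-loop is a stable state; any other
    terminal SCC is a cyclic attractor.
    """
    g = sg.graph
    cond = nx.condensation(g)
    comps, kinds = [], []
    for cid in sorted(cond.nodes):
        if cond.out_degree(cid) == 0:
            members = frozenset(cond.nodes[cid]["members"])
            if len(members) == 1 and not g.has_edge(*(2 * list(members))):
                kinds.append("stable")
            else:
                kinds.append("cyclic")
            comps.append(members)
    order = sorted(range(len(comps)), key=lambda i: sorted(comps[i]))
    return AttractorReport([comps[i] for i in order], [kinds[i] for i in order])


def _node_id(state: State) -> str:
    return "".join(str(v) for v in state)


def export_state_graph(sg: StateGraph, fmt: str, path: str | Path) -> None:
    """Write the state graph as GraphML or DOT.

    Node ids concatenate the levels (e.g. ``"101110"``); each node carries a
    ``stable`` flag and, when computed, its betweenness centrality.
    """
    stable = set(stable_states(sg))
    if fmt == "graphml":
        h = nx.DiGraph()
        for s in sg.graph.nodes:
            attrs = {"stable": s in stable}
            if sg.betweenness is not None:
                attrs["betweenness"] = float(sg.betweenness[s])
            h.add_node(_node_id(s), **attrs)
        for u, v in sg.graph.edges:
            h.add_edge(_node_id(u), _node_id(v))
        nx.write_graphml(h, path)
    elif fmt == "dot":
        lines = ["digraph state_graph {"]
        for s in sg.graph.nodes:
            extra = ', peripheries=2, style=bold' if s in stable else ""
            label = _node_id(s)
            if sg.betweenness is not None:
                label += f"\\nb={sg.betweenness[s]:g}"
            lines.append(f'  "{_node_id(s)}" [label="{label}"{extra}];')
        for u, v in sg.graph.edges:
            lines.append(f'  "{_node_id(u)}" -> "{_node_id(v)}";')
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown export format {fmt!r} (graphml or dot)")


def state_graph_summary(sg: StateGraph) -> dict:
    rep = attractors(sg)
    return {
        "n_states": sg.n_states,
        "n_edges": sg.n_edges,
        "stable_states": [_node_id(s) for s in stable_states(sg)],
        "n_attractors": rep.n_attractors,
    }


def write_summary(sg: StateGraph, path: str | Path) -> None:
    Path(path).write_text(json.dumps(state_graph_summary(sg), indent=2) + "\n")
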