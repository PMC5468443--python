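"""Graph-theoretic analysis of the state graph: betweenness centrality,
elementary-circuit enumeration and selection of the most significant
qualitative cycle.

States with high betweenness lie on many shortest paths of the dynamics and
are read as the system's most frequently visited expression configurations;
the qualitative cycle whose member states have the highest centrality is
taken as the dominant homeostatic loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .state_dynamics import StateGraph

__all__ = [
    "QualitativeCycle",
    "betweenness",
    "elementary_cycles",
    "select_cycle",
    "CycleRanking",
]

log = logging.getLogger(__name__)

DEFAULT_MAX_COUNT = 10**5
DEFAULT_MAX_LEN = 20


@dataclass(frozen=True)
class QualitativeCycle:
    """An elementary circuit of the state graph.

    ``states`` are pairwise distinct; each consecutive pair (and last→first)
    is a state-graph edge differing in exactly one entity by one level.
    Cycles are canonicalized to start at their lexicographically smallest
    state so equal circuits compare equal regardless of enumeration order.
    """

    states: tuple

    @staticmethod
    def from_states(states) -> "QualitativeCycle":
        states = tuple(tuple(s) for s in states)
        if len(set(states)) != len(states):
            raise ValueError("cycle states must be pairwise distinct")
        k = min(range(len(states)), key=lambda i: states[i])
        return QualitativeCycle(states[k:] + states[:k])

    def __len__(self):
        return len(self.states)

    def transitions(self) -> list[tuple[int, int]]:
        """Per step: (index of the changing entity, direction ±1)."""
        out = []
        for a, b in zip(self.states, self.states[1:] + self.states[:1]):
            diff = [(i, b[i] - a[i]) for i in range(len(a)) if a[i] != b[i]]
            if len(diff) != 1 or abs(diff[0][1]) != 1:
                raise ValueError(f"invalid cycle step {a} -> {b}: must change "
                                 "exactly one entity by one level")
            out.append(diff[0])
        return out

    def validate(self, sg: StateGraph) -> None:
        """Check every step is an edge of the state graph."""
        self.transitions()
        for a, b in zip(self.states, self.states[1:] + self.states[:1]):
            if not sg.graph.has_edge(a, b):
                raise ValueError(f"cycle step {a} -> {b} is not a transition "
                                 "of the state graph")


def betweenness(sg: StateGraph) -> dict:
    """Directed, unnormalized shortest-path betweenness (endpoints excluded).

    The result is cached on the state graph for later export.
    """
    b = nx.betweenness_centrality(sg.graph, normalized=False)
    sg.betweenness = b
    return b


def elementary_cycles(sg: StateGraph, max_count: int = DEFAULT_MAX_COUNT,
                      max_len: int = DEFAULT_MAX_LEN) -> list[QualitativeCycle]:
    """All elementary circuits up to length ``max_len``, canonicalized and
    sorted by (length, states); truncated with a warning at ``max_count``."""
    cycles = []
    for nodes in nx.simple_cycles(sg.graph, length_bound=max_len):
        cycles.append(QualitativeCycle.from_states(nodes))
        if len(cycles) >= max_count:
            log.warning("cycle enumeration truncated at %d circuits", max_count)
            break
    cycles.sort(key=lambda c: (len(c), c.states))
    return cycles


@dataclass
class CycleRanking:
    """Full ranking of circuits by the chosen betweenness aggregation."""

    scoring: str
    ranked: list[tuple[QualitativeCycle, float]]  # best first

    @property
    def best(self) -> QualitativeCycle:
        return self.ranked[0][0]

    def rank_of(self, cycle: QualitativeCycle) -> int:
        """1-based rank of ``cycle``; raises if absent."""
        for i, (c, _) in enumerate(self.ranked):
            if c == cycle:
                return i + 1
        raise ValueError("cycle not in ranking")


def select_cycle(sg: StateGraph, cycles: list[QualitativeCycle],
                 scoring: str = "sum") -> CycleRanking:
    """Rank circuits by summed (default) or mean betweenness of their states.

    Summed scoring measures the total centrality mass the loop carries —
    the circuit threading the most shortest-path traffic; mean scoring,
    which normalizes away cycle length, is available as an option.  Ties
    break toward the longer cycle, then the lexicographically smallest
    canonical state sequence.
    """
    if not cycles:
        raise ValueError("no cycles to rank")
    if scoring not in ("mean", "sum"):
        raise ValueError(f"scoring must be 'mean' or 'sum', got {scoring!r}")
    b = sg.betweenness if sg.betweenness is not None else betweenness(sg)

    def score(c: QualitativeCycle) -> float:
        total = sum(b[s] for s in c.states)
        return total / len(c) if scoring == "mean" else total

    scored = [(c, score(c)) for c in cycles]
    scored.sort(key=lambda cs: (-cs[1], -len(cs[0]), cs[0].states))
    return CycleRanking(scoring, scored)
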