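"""Synthetic networks, digraphs and cycles with known ground truth.

These generators make every stage of the pipeline testable without the
packaged mTOR model: canonical feedback circuits whose attractor structure
is classical (positive feedback gives multistationarity, negative feedback
oscillation), seeded random multivalued networks small enough for
brute-force oracles, random digraphs for CTL/centrality oracles, and random
alternating-event cycles to stress the delay projection.
"""

from __future__ import annotations

import random
from itertools import combinations, product

import networkx as nx

from .logical_model import (Entity, Interaction, LogicalNetwork,
                            Parameterization, ParameterSpec, regulators)
from .state_graph_analysis import QualitativeCycle

__all__ = ["toy_circuits", "random_brn", "random_digraph",
           "random_cycle_instance"]


def _full_specs(entities, interactions):
    """Complete parameter specs with full ranges [0..max] per target."""
    net = LogicalNetwork(list(entities), list(interactions))
    specs = []
    for e in entities:
        regs = regulators(net, e.name)
        for r in range(len(regs) + 1):
            for combo in combinations(regs, r):
                specs.append(ParameterSpec(e.name, frozenset(combo),
                                           tuple(range(e.max_level + 1))))
    return specs


def _network(entities, interactions, K_entries) -> tuple[LogicalNetwork,
                                                         Parameterization]:
    net = LogicalNetwork(list(entities), list(interactions),
                         _full_specs(entities, interactions))
    K = Parameterization({(t, frozenset(res)): v for t, res, v in K_entries})
    net.selected = K
    return net, K


def toy_circuits() -> dict[str, tuple[LogicalNetwork, Parameterization]]:
    """Canonical feedback circuits with known dynamics.

    - ``mutual_activation``: x and y activate each other, parameters favor
      agreement — a positive circuit with exactly two stable states
      (0,0) and (1,1).
    - ``negative_loop``: x activates y, y inhibits x — a negative circuit
      with no stable state and a single 4-state cyclic attractor.
    - ``self_degrading``: one unregulated entity decaying to 0 — a single
      stable state.
    """
    x, y = Entity("x"), Entity("y")
    out = {}
    out["mutual_activation"] = _network(
        [x, y],
        [Interaction("x", "y", "+"), Interaction("y", "x", "+")],
        [("x", [], 0), ("x", ["y"], 1), ("y", [], 0), ("y", ["x"], 1)],
    )
    out["negative_loop"] = _network(
        [x, y],
        [Interaction("x", "y", "+"), Interaction("y", "x", "-")],
        # resource of x is the *absence* of its inhibitor y
        [("x", [], 0), ("x", ["y"], 1), ("y", [], 0), ("y", ["x"], 1)],
    )
    out["self_degrading"] = _network([x], [], [("x", [], 0)])
    return out


def random_brn(n_entities: int, density: float = 0.4, max_level: int = 1,
               seed: int = 0, snoussi: bool = False
               ) -> tuple[LogicalNetwork, Parameterization]:
    """A seeded random signed network with complete specs and a random
    (optionally Snoussi-monotone) parameterization.

    Intended for exhaustive testing: keep ``n_entities <= 8``.
    """
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    if n_entities > 8:
        raise ValueError("random_brn is meant for exhaustive analysis; "
                         "use n_entities <= 8")
    rng = random.Random(seed)
    names = [f"g{i}" for i in range(n_entities)]
    entities = [Entity(n, max_level) for n in names]
    interactions = []
    for src in names:
        for tgt in names:
            if rng.random() < density:
                interactions.append(Interaction(
                    src, tgt, rng.choice("+-"), rng.randint(1, max_level)))
    specs = _full_specs(entities, interactions)
    net = LogicalNetwork(entities, interactions, specs)
    K = Parameterization()
    for name in names:
        regs = regulators(net, name)
        subsets = [frozenset(c) for r in range(len(regs) + 1)
                   for c in combinations(regs, r)]
        subsets.sort(key=lambda s: (len(s), sorted(s)))
        for sub in subsets:
            lo = 0
            if snoussi:
                smaller = [K[(name, s)] for s in subsets
                           if s < sub and (name, s) in K]
                lo = max(smaller, default=0)
            K[(name, sub)] = rng.randint(lo, max_level)
    net.selected = K
    return net, K


def random_digraph(n: int, p: float, seed: int = 0) -> nx.DiGraph:
    """Seeded Erdős–Rényi digraph whose nodes are 1-tuples of levels, so it
    is shaped like a (one-entity) state graph for CTL/centrality oracles."""
    g = nx.gnp_random_graph(n, p, seed=seed, directed=True)
    return nx.relabel_nodes(g, {i: (i,) for i in g.nodes})


def random_cycle_instance(n_entities: int, length: int | None = None,
                          seed: int = 0):
    """A random Boolean single-step cycle in which every entity rises once
    and falls once, plus its timing system.

    Rejection-samples event interleavings until all visited states are
    pairwise distinct (always quick for the small sizes used in tests).
    Returns ``(cycle, events, constants, timing_system)``.
    """
    from .delay_kernel import build_timing_system, cycle_events

    if n_entities < 1:
        raise ValueError("need at least one entity")
    if length is None:
        length = 2 * n_entities
    if length != 2 * n_entities:
        raise ValueError("length must be twice the entity count (one rise "
                         "and one fall per entity)")
    rng = random.Random(seed)
    names = [f"g{i}" for i in range(n_entities)]
    for _ in range(10_000):
        events = [(i, +1) for i in range(n_entities)] + \
                 [(i, -1) for i in range(n_entities)]
        rng.shuffle(events)
        # initial level: 1 iff the entity's fall precedes its rise
        first = {}
        for i, step in events:
            first.setdefault(i, step)
        state = tuple(1 if first[i] < 0 else 0 for i in range(n_entities))
        states, ok = [state], True
        for i, step in events:
            if not 0 <= state[i] + step <= 1:
                ok = False
                break
            state = state[:i] + (state[i] + step,) + state[i + 1:]
            states.append(state)
        if not ok or states[-1] != states[0]:
            continue
        states = states[:-1]
        if len(set(states)) != len(states):
            continue
        cycle = QualitativeCycle.from_states(states)
        evs, constants = cycle_events(cycle, names)
        system = build_timing_system(evs, len(cycle), constants)
        return cycle, evs, constants, system
    raise RuntimeError("could not sample a distinct-state cycle; "
                       "try another seed")
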