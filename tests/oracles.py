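"""Independent brute-force oracles used to cross-check the engines.

Everything here is deliberately naive (explicit enumeration, transitive
closure, all-pairs path counting) and shares no code path with the
implementations under test.
"""

from collections import deque
from itertools import product

import networkx as nx

from brnkit import ctl_engine as ce


def naive_state_graph(network, K):
    """Re-derive the asynchronous state graph from first principles:
    re-evaluates the resource rule per interaction directly."""
    edges = set()
    maxes = [network.entity(n).max_level for n in network.entity_order]
    idx = {n: i for i, n in enumerate(network.entity_order)}
    for state in product(*(range(m + 1) for m in maxes)):
        for i, name in enumerate(network.entity_order):
            omega = set()
            for ia in network.interactions:
                if ia.target != name:
                    continue
                active = state[idx[ia.source]] >= ia.threshold
                if (ia.sign == "+" and active) or (ia.sign == "-" and not active):
                    omega.add(ia.source)
            target_level = K[(name, frozenset(omega))]
            if target_level > state[i]:
                edges.add((state, state[:i] + (state[i] + 1,) + state[i + 1:]))
            elif target_level < state[i]:
                edges.add((state, state[:i] + (state[i] - 1,) + state[i + 1:]))
    nodes = set(product(*(range(m + 1) for m in maxes)))
    return nodes, edges


def naive_betweenness(g: nx.DiGraph):
    """Unnormalized directed betweenness by explicit all-pairs shortest-path
    counting (BFS distances + path-count composition)."""
    nodes = list(g.nodes)
    dist, sigma = {}, {}
    for s in nodes:
        d = {s: 0}
        sig = {s: 1}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in g.successors(u):
                if v not in d:
                    d[v] = d[u] + 1
                    sig[v] = 0
                    q.append(v)
                if d[v] == d[u] + 1:
                    sig[v] += sig[u]
        dist[s], sigma[s] = d, sig
    bet = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            if s == t or t not in dist[s]:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                if (v in dist[s] and t in dist[v]
                        and dist[s][v] + dist[v][t] == dist[s][t]):
                    bet[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    return bet


def _succ_total(g, s):
    succ = list(g.successors(s))
    return succ if succ else [s]


def naive_ctl(g: nx.DiGraph, entity_index, formula):
    """CTL semantics via explicit reachability/closure instead of fixpoints.

    EF uses graph reachability, EG searches for a lasso inside the
    satisfaction set, EU a backward BFS through the left-hand set.
    """
    nodes = set(g.nodes)
    rec = lambda f: naive_ctl(g, entity_index, f)
    if isinstance(formula, ce.Bool):
        return set(nodes) if formula.value else set()
    if isinstance(formula, ce.Atom):
        i = entity_index[formula.entity]
        op = formula.op
        return {s for s in nodes
                if (s[i] == formula.level if op == "="
                    else s[i] <= formula.level if op == "<="
                    else s[i] >= formula.level)}
    if isinstance(formula, ce.Not):
        return nodes - rec(formula.arg)
    if isinstance(formula, ce.And):
        return rec(formula.left) & rec(formula.right)
    if isinstance(formula, ce.Or):
        return rec(formula.left) | rec(formula.right)
    if isinstance(formula, ce.Implies):
        return (nodes - rec(formula.left)) | rec(formula.right)
    if isinstance(formula, ce.EX):
        S = rec(formula.arg)
        return {s for s in nodes if any(t in S for t in _succ_total(g, s))}
    if isinstance(formula, ce.AX):
        S = rec(formula.arg)
        return {s for s in nodes if all(t in S for t in _succ_total(g, s))}
    if isinstance(formula, ce.EF):
        S = rec(formula.arg)
        return {s for s in nodes
                if s in S or any(t in S for t in nx.descendants(g, s))}
    if isinstance(formula, ce.AG):
        return nodes - rec(ce.EF(ce.Not(formula.arg)))
    if isinstance(formula, ce.EG):
        # lasso search: stay in S forever (totalized self-loops on deadlocks)
        S = rec(formula.arg)
        h = nx.DiGraph()
        h.add_nodes_from(S)
        for s in S:
            for t in _succ_total(g, s):
                if t in S:
                    h.add_edge(s, t)
        on_cycle = set()
        for scc in nx.strongly_connected_components(h):
            scc = set(scc)
            if len(scc) > 1 or any(h.has_edge(s, s) for s in scc):
                on_cycle |= scc
        out = set(on_cycle)
        for s in S:
            if s not in out and out & (nx.descendants(h, s) if s in h else set()):
                out.add(s)
        return out
    if isinstance(formula, ce.AF):
        return nodes - rec(ce.EG(ce.Not(formula.arg)))
    if isinstance(formula, ce.EU):
        phi, psi = rec(formula.left), rec(formula.right)
        out = set(psi)
        frontier = deque(psi)
        while frontier:
            t = frontier.popleft()
            for s in g.predecessors(t):
                if s in phi and s not in out:
                    out.add(s)
                    frontier.append(s)
        # totalized deadlock self-loops add nothing for EU beyond psi itself
        return out
    if isinstance(formula, ce.AU):
        phi, psi = formula.left, formula.right
        bad = rec(ce.EU(ce.Not(psi), ce.And(ce.Not(phi), ce.Not(psi))))
        never = rec(ce.EG(ce.Not(psi)))
        return nodes - (bad | never)
    raise TypeError(formula)


def random_formula(rng, max_level, depth=3):
    """A random CTL formula over a single entity ``x`` with levels up to
    ``max_level``."""
    if depth == 0 or rng.random() < 0.3:
        return ce.Atom("x", rng.choice(["=", "<=", ">="]),
                       rng.randint(0, max_level))
    kind = rng.randint(0, 9)
    sub = lambda: random_formula(rng, max_level, depth - 1)
    if kind == 0:
        return ce.Not(sub())
    if kind == 1:
        return ce.And(sub(), sub())
    if kind == 2:
        return ce.Or(sub(), sub())
    if kind == 3:
        return ce.EX(sub())
    if kind == 4:
        return ce.AX(sub())
    if kind == 5:
        return ce.EF(sub())
    if kind == 6:
        return ce.AF(sub())
    if kind == 7:
        return ce.EG(sub())
    if kind == 8:
        return ce.AG(sub())
    return ce.EU(sub(), sub()) if rng.random() < 0.5 else ce.AU(sub(), sub())
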