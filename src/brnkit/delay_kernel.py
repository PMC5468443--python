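"""Parametric delay analysis of qualitative cycles (invariance kernel).

A qualitative cycle is refined into a linear hybrid timing model: the system
dwells for a duration ``d_i >= 0`` in each cycle location, and each entity's
*production delay* ``δ+`` (time to rise one level) or *degradation delay*
``|δ−|`` (time to fall) equals the total dwell time between that entity's
consecutive level-change events.  Each entity's clock runs continuously and
resets only at the entity's own events, so a delay spans all locations
between two of its events; the *period* ``π(x) = δx+ + |δx−|`` then equals
the full cycle period for every oscillating entity.

Existentially eliminating the dwell times (exact Fourier–Motzkin) yields the
delay-only constraints characterizing the cycle's invariance kernel: the
set of delay valuations under which the hybrid trajectory can follow the
cycle forever.  Pairwise forced orderings between delays are read off the
kernel as a relation matrix.

Entities constant along the cycle carry no delay symbols.  Dwell times are
non-strict (``d_i >= 0``, zero-duration locations admitted) while delays are
strictly positive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .polyhedra import (EQ, LE, LT, LinearConstraint, canonical_set, entails,
                        feasible as _poly_feasible, project)
from .state_graph_analysis import QualitativeCycle

__all__ = [
    "DelaySymbol", "CycleEvent", "TimingSystem", "KernelConstraintSet",
    "RelationMatrix", "cycle_events", "build_timing_system",
    "project_delay_constraints", "feasible", "relation_matrix",
    "simulate_cycle", "parse_constraint", "read_constraints",
    "write_constraints",
]

PRODUCTION = "+"
DEGRADATION = "-"


@dataclass(frozen=True)
class DelaySymbol:
    """A production (δ+) or degradation (|δ−|) delay of one entity.

    Degradation delays are handled as magnitudes, so every symbol is a
    strictly positive real.
    """

    entity: str
    kind: str  # "+" or "-"

    def __post_init__(self):
        if self.kind not in (PRODUCTION, DEGRADATION):
            raise ValueError(f"delay kind must be '+' or '-', got {self.kind!r}")

    @property
    def name(self) -> str:
        return f"d{self.entity}{self.kind}"

    def __str__(self):
        return self.name


@dataclass(frozen=True)
class CycleEvent:
    """A level change of one entity at a given cycle transition.

    ``position`` is the 1-based index of the transition (fired when leaving
    location ``position``); ``direction`` is +1 (rise) or -1 (fall).
    """

    entity: str
    direction: int
    position: int

    @property
    def delay(self) -> DelaySymbol:
        return DelaySymbol(self.entity,
                           PRODUCTION if self.direction > 0 else DEGRADATION)


@dataclass
class TimingSystem:
    """The linear timing system of a cycle.

    One equation per event: the dwell times strictly between the entity's
    previous event and this one sum to the matching delay symbol.  Together
    with ``d_i >= 0`` and ``δ > 0`` this defines the feasible timings of the
    cycle; its projection onto the delays is the invariance kernel.
    """

    n_locations: int
    events: list[CycleEvent]
    constant_entities: dict[str, int]
    equations: list[LinearConstraint]

    @property
    def duration_vars(self) -> list[str]:
        return [f"d_{i}" for i in range(1, self.n_locations + 1)]

    @property
    def delay_symbols(self) -> list[DelaySymbol]:
        seen, out = set(), []
        for ev in self.events:
            if ev.delay not in seen:
                seen.add(ev.delay)
                out.append(ev.delay)
        return out

    def all_constraints(self) -> list[LinearConstraint]:
        """Equations plus d_i >= 0 and δ > 0."""
        cons = list(self.equations)
        for d in self.duration_vars:
            cons.append(LinearConstraint.make({d: -1}, 0, LE))
        cons.extend(_positivity(self.delay_symbols))
        return cons


def _positivity(symbols: Iterable[DelaySymbol]) -> list[LinearConstraint]:
    return [LinearConstraint.make({s.name: -1}, 0, LT) for s in symbols]


def cycle_events(cycle: QualitativeCycle, entity_names: Sequence[str],
                 ) -> tuple[list[CycleEvent], dict[str, int]]:
    """Per-transition (entity, direction) events of a cycle.

    Returns the ordered event list and the entities constant along the cycle
    (mapped to their constant level); constant entities take no part in the
    timing system.  Raises if any entity's events fail to alternate
    rise/fall around the cycle.
    """
    transitions = cycle.transitions()
    events = [CycleEvent(entity_names[i], step, pos + 1)
              for pos, (i, step) in enumerate(transitions)]
    moving = {ev.entity for ev in events}
    constants = {entity_names[i]: cycle.states[0][i]
                 for i in range(len(entity_names))
                 if entity_names[i] not in moving}
    for name in moving:
        dirs = [ev.direction for ev in events if ev.entity == name]
        for a, b in zip(dirs, dirs[1:] + dirs[:1]):
            if a == b:
                raise ValueError(f"events of {name} do not alternate "
                                 "rise/fall around the cycle")
    return events, constants


def _window(prev_pos: int, pos: int, n: int) -> list[int]:
    """Locations strictly after ``prev_pos`` up to ``pos`` (cyclic, 1-based)."""
    out, i = [], prev_pos % n + 1
    while True:
        out.append(i)
        if i == pos:
            return out
        i = i % n + 1


def build_timing_system(events: Sequence[CycleEvent], n_locations: int,
                        constant_entities: Mapping[str, int] | None = None
                        ) -> TimingSystem:
    """One equation per event: ``d_{k+1} + ... + d_j = δ`` where ``k`` and
    ``j`` are the entity's previous and current event transitions."""
    by_entity: dict[str, list[CycleEvent]] = {}
    for ev in sorted(events, key=lambda e: e.position):
        by_entity.setdefault(ev.entity, []).append(ev)
    equations = []
    for name, evs in by_entity.items():
        if len(evs) < 2:
            raise ValueError(f"entity {name} has a single event; its period "
                             "cannot close around the cycle")
        for prev, cur in zip(evs[-1:] + evs[:-1], evs):
            terms: dict[str, Fraction] = {
                f"d_{i}": Fraction(1)
                for i in _window(prev.position, cur.position, n_locations)}
            terms[cur.delay.name] = Fraction(-1)
            equations.append(LinearConstraint.make(terms, 0, EQ))
    return TimingSystem(n_locations, list(events),
                        dict(constant_entities or {}), equations)


@dataclass
class KernelConstraintSet:
    """Delay-only constraints equivalent to ``∃ d >= 0`` satisfying the
    timing equations (with ``δ > 0`` as implicit domain)."""

    symbols: list[DelaySymbol]
    constraints: list[LinearConstraint]

    def with_positivity(self) -> list[LinearConstraint]:
        return list(self.constraints) + _positivity(self.symbols)

    def entails(self, c: LinearConstraint) -> bool:
        return entails(self.with_positivity(), c)

    def contains(self, point: Mapping[str, Fraction | int]) -> bool:
        """Membership of a positive delay valuation in the kernel."""
        if any(Fraction(point[s.name]) <= 0 for s in self.symbols):
            return False
        return all(c.evaluate(point) for c in self.constraints)

    def __iter__(self):
        return iter(self.constraints)

    def __len__(self):
        return len(self.constraints)


def project_delay_constraints(system: TimingSystem) -> KernelConstraintSet:
    """Exact existential elimination of all dwell times, then redundancy
    pruning against the positivity domain."""
    cons = project(system.all_constraints(), system.duration_vars)
    positivity = _positivity(system.delay_symbols)
    cons = [c for c in cons if c not in positivity]
    cons = canonical_set(cons, context=positivity)
    leftover = {v for c in cons for v in c.variables()} - \
        {s.name for s in system.delay_symbols}
    if leftover:
        raise AssertionError(f"duration variables survived projection: {leftover}")
    return KernelConstraintSet(system.delay_symbols, cons)


def feasible(constraints: Iterable[LinearConstraint],
             extra: Iterable[LinearConstraint] = (),
             symbols: Iterable[DelaySymbol] = ()
             ) -> tuple[bool, dict[str, Fraction] | None]:
    """Exact feasibility of ``constraints ∧ extra`` (with δ > 0 for any
    ``symbols`` given), returning a rational witness when satisfiable."""
    cons = list(constraints) + list(extra) + _positivity(symbols)
    return _poly_feasible(cons)


# -- relation matrix -----------------------------------------------------

FORCED_LE, FORCED_GE, FORCED_EQ, FREE = "<=", ">=", "=", "free"


@dataclass
class RelationMatrix:
    """Pairwise forced orderings between delay symbols under a kernel.

    ``relations[(a, b)]`` (for symbols a, b in ``symbols`` order) is
    ``"<="`` when the kernel forces a <= b, ``">="`` when it forces b <= a,
    ``"="`` when both, and ``"free"`` when neither.
    """

    symbols: list[DelaySymbol]
    relations: dict[tuple[str, str], str]

    def relation(self, a: DelaySymbol | str, b: DelaySymbol | str) -> str:
        a = a.name if isinstance(a, DelaySymbol) else a
        b = b.name if isinstance(b, DelaySymbol) else b
        if a == b:
            return FORCED_EQ
        if (a, b) in self.relations:
            return self.relations[(a, b)]
        inverse = {FORCED_LE: FORCED_GE, FORCED_GE: FORCED_LE}
        r = self.relations[(b, a)]
        return inverse.get(r, r)

    def forced_pairs(self) -> list[tuple[str, str, str]]:
        return [(a, b, r) for (a, b), r in sorted(self.relations.items())
                if r != FREE]

    def to_dataframe(self) -> pd.DataFrame:
        names = [s.name for s in self.symbols]
        display = {FORCED_LE: "<=", FORCED_GE: ">=", FORCED_EQ: "=",
                   FREE: "<=, >="}
        data = [[display[self.relation(r, c)] if names.index(c) <= i else ""
                 for c in names]
                for i, r in enumerate(names)]
        return pd.DataFrame(data, index=names, columns=names)


def relation_matrix(constraints: KernelConstraintSet | Sequence[LinearConstraint],
                    symbols: Sequence[DelaySymbol] | None = None
                    ) -> RelationMatrix:
    """Decide, for every symbol pair, whether the constraints force an order.

    ``a <= b`` is forced iff the constraints conjoined with ``a > b`` are
    infeasible (exact check)."""
    if isinstance(constraints, KernelConstraintSet):
        symbols = constraints.symbols if symbols is None else list(symbols)
        base = constraints.with_positivity()
    else:
        if symbols is None:
            raise ValueError("symbols required for a raw constraint list")
        base = list(constraints) + _positivity(symbols)
    relations = {}
    for i, a in enumerate(symbols):
        for b in symbols[i + 1:]:
            gt, _ = _poly_feasible(
                base + [LinearConstraint.make({b.name: 1, a.name: -1}, 0, LT)])
            lt, _ = _poly_feasible(
                base + [LinearConstraint.make({a.name: 1, b.name: -1}, 0, LT)])
            if not gt and not lt:
                rel = FORCED_EQ
            elif not gt:
                rel = FORCED_LE    # a > b impossible
            elif not lt:
                rel = FORCED_GE
            else:
                rel = FREE
            relations[(a.name, b.name)] = rel
    return RelationMatrix(list(symbols), relations)


# -- numeric oracle ------------------------------------------------------

def simulate_cycle(delays: Mapping[str, Fraction | int | str],
                   system: TimingSystem
                   ) -> tuple[bool, dict[str, Fraction] | None]:
    """Solve the timing equations for the dwell times at a numeric delay
    valuation; feasible iff a nonnegative schedule exists.

    Exact rational Gaussian elimination; if the equation system is
    underdetermined the residual nonnegativity problem is decided by
    Fourier–Motzkin.  Serves as an independent numeric check of
    :func:`project_delay_constraints`.
    """
    delays = {k: Fraction(v) for k, v in delays.items()}
    for s in system.delay_symbols:
        if s.name not in delays:
            raise ValueError(f"missing delay value for {s.name}")
        if delays[s.name] <= 0:
            return False, None
    dvars = system.duration_vars
    ncols = len(dvars)
    col = {v: j for j, v in enumerate(dvars)}
    # rows: [A | b] for A d = b with delays substituted
    rows = []
    for eq in system.equations:
        row = [Fraction(0)] * (ncols + 1)
        for v, c in eq.terms:
            if v in col:
                row[col[v]] = c
            else:
                row[ncols] -= c * delays[v]   # move delay term to rhs
        row[ncols] -= eq.const
        rows.append(row)

    # forward elimination with partial (first-nonzero) pivoting
    pivots: list[tuple[int, int]] = []
    r = 0
    for j in range(ncols):
        pr = next((i for i in range(r, len(rows)) if rows[i][j] != 0), None)
        if pr is None:
            continue
        rows[r], rows[pr] = rows[pr], rows[r]
        piv = rows[r][j]
        rows[r] = [x / piv for x in rows[r]]
        for i in range(len(rows)):
            if i != r and rows[i][j] != 0:
                f = rows[i][j]
                rows[i] = [x - f * y for x, y in zip(rows[i], rows[r])]
        pivots.append((r, j))
        r += 1
    for i in range(r, len(rows)):
        if rows[i][ncols] != 0:
            return False, None   # inconsistent equations at this valuation

    free_cols = [j for j in range(ncols) if j not in {c for _, c in pivots}]
    if not free_cols:
        schedule = {}
        for i, j in pivots:
            schedule[dvars[j]] = rows[i][ncols]
        if any(v < 0 for v in schedule.values()):
            return False, None
        return True, schedule

    # underdetermined: express pivot vars in the free ones, require all >= 0
    residual = []
    for i, j in pivots:
        # d_j = rhs - sum(free terms) >= 0  ->  sum(free terms) - rhs <= 0
        terms = {dvars[f]: rows[i][f] for f in free_cols if rows[i][f] != 0}
        residual.append(LinearConstraint.make(terms, -rows[i][ncols], LE))
    for f in free_cols:
        residual.append(LinearConstraint.make({dvars[f]: -1}, 0, LE))
    ok, w = _poly_feasible(residual)
    if not ok:
        return False, None
    w = {v: w.get(v, Fraction(0)) for v in (dvars[f] for f in free_cols)}
    schedule = dict(w)
    for i, j in pivots:
        schedule[dvars[j]] = rows[i][ncols] - sum(
            rows[i][f] * w[dvars[f]] for f in free_cols)
    return True, schedule


# -- constraint text format ---------------------------------------------

_TERM_RE = re.compile(
    r"\s*(?P<sign>[+-])?\s*(?:(?P<coef>\d+(?:/\d+)?)\s*\*?\s*)?"
    r"(?P<sym>pi\(\s*[A-Za-z_]\w*\s*\)|d[A-Za-z_]\w*[+-])\s*|"
    r"\s*(?P<csign>[+-])?\s*(?P<const>\d+(?:/\d+)?)\s*")


def _parse_side(text: str) -> tuple[dict[str, Fraction], Fraction]:
    """Parse one side of a constraint into (terms, constant)."""
    terms: dict[str, Fraction] = {}
    const = Fraction(0)
    pos = 0
    first = True
    while pos < len(text):
        m = _TERM_RE.match(text, pos)
        if not m or m.end() == pos:
            raise ValueError(f"cannot parse term at {text[pos:]!r}")
        if m.group("const") is not None:
            sign = m.group("csign")
            if sign is None and not first:
                raise ValueError(f"missing +/- before {m.group('const')!r}")
            const += Fraction(m.group("const")) * (-1 if sign == "-" else 1)
        else:
            sign = m.group("sign")
            if sign is None and not first:
                raise ValueError(f"missing +/- before {m.group('sym')!r}")
            k = Fraction(m.group("coef") or 1) * (-1 if sign == "-" else 1)
            sym = m.group("sym").replace(" ", "")
            if sym.startswith("pi("):
                entity = sym[3:-1]
                for suffix in (PRODUCTION, DEGRADATION):
                    name = f"d{entity}{suffix}"
                    terms[name] = terms.get(name, Fraction(0)) + k
            else:
                terms[sym] = terms.get(sym, Fraction(0)) + k
        pos = m.end()
        first = False
    return terms, const


def parse_constraint(line: str) -> LinearConstraint:
    """Parse e.g. ``dFOXO+ <= dmTORC1- + dAkt-`` or
    ``pi(FOXO) + dPI3K- <= pi(Akt) + pi(mTORC1)``.

    ``pi(X)`` abbreviates ``dX+ + dX-``; relations are ``<=``, ``>=``, ``=``
    (and strict ``<``, ``>``).
    """
    m = re.search(r"(<=|>=|=|<|>)", line)
    if not m:
        raise ValueError(f"no relation in constraint {line!r}")
    rel_txt = m.group(1)
    lhs, lconst = _parse_side(line[:m.start()])
    rhs, rconst = _parse_side(line[m.end():])
    terms = dict(lhs)
    for v, c in rhs.items():
        terms[v] = terms.get(v, Fraction(0)) - c
    const = lconst - rconst
    if rel_txt in (">=", ">"):
        terms = {v: -c for v, c in terms.items()}
        const = -const
        rel = LE if rel_txt == ">=" else LT
    else:
        rel = {"<=": LE, "<": LT, "=": EQ}[rel_txt]
    return LinearConstraint.make(terms, const, rel).canonical()


def read_constraints(path: str | Path) -> list[LinearConstraint]:
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append(parse_constraint(line))
    return out


def write_constraints(constraints: Iterable[LinearConstraint],
                      path: str | Path) -> None:
    Path(path).write_text(
        "".join(str(c) + "\n" for c in constraints))
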