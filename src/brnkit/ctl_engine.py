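"""CTL model checking over qualitative state graphs.

Formulas are checked by standard backward fixpoint labeling: ``EX`` is a
single pre-image step, ``E[φ U ψ]`` a least fixpoint, ``EG`` a greatest
fixpoint; the universal operators are derived by duality.

Path semantics are over maximal paths with a *total* transition relation:
a deadlock (stable) state is treated as looping on itself, so ``AG φ`` can
hold at a stable φ-state and ``EF(AG φ)`` is satisfiable at fixpoints.
This matches symbolic checkers that totalize the relation and is the
convention under which stability properties of regulatory networks are
normally phrased.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .logical_model import LogicalNetwork

__all__ = [
    "CTLFormula", "Atom", "Bool", "Not", "And", "Or", "Implies",
    "EX", "EF", "EG", "EU", "AX", "AF", "AG", "AU",
    "parse_ctl", "read_formulas", "sat_states", "model_satisfies",
    "CTLSyntaxError",
]


class CTLSyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# -- AST -----------------------------------------------------------------

class CTLFormula:
    def __and__(self, other): return And(self, other)
    def __or__(self, other): return Or(self, other)
    def __invert__(self): return Not(self)


@dataclass(frozen=True)
class Atom(CTLFormula):
    entity: str
    op: str  # '=', '<=', '>='
    level: int

    def __str__(self):
        return f"{self.entity} {'=' if self.op == '=' else self.op} {self.level}"


@dataclass(frozen=True)
class Bool(CTLFormula):
    value: bool

    def __str__(self):
        return "true" if self.value else "false"


@dataclass(frozen=True)
class Not(CTLFormula):
    arg: CTLFormula

    def __str__(self):
        return f"!({self.arg})"


@dataclass(frozen=True)
class _Binary(CTLFormula):
    left: CTLFormula
    right: CTLFormula


class And(_Binary):
    def __str__(self):
        return f"({self.left} & {self.right})"


class Or(_Binary):
    def __str__(self):
        return f"({self.left} | {self.right})"


class Implies(_Binary):
    def __str__(self):
        return f"({self.left} -> {self.right})"


@dataclass(frozen=True)
class _Unary(CTLFormula):
    arg: CTLFormula


class EX(_Unary):
    def __str__(self): return f"EX({self.arg})"


class EF(_Unary):
    def __str__(self): return f"EF({self.arg})"


class EG(_Unary):
    def __str__(self): return f"EG({self.arg})"


class AX(_Unary):
    def __str__(self): return f"AX({self.arg})"


class AF(_Unary):
    def __str__(self): return f"AF({self.arg})"


class AG(_Unary):
    def __str__(self): return f"AG({self.arg})"


class EU(_Binary):
    def __str__(self): return f"E[{self.left} U {self.right}]"


class AU(_Binary):
    def __str__(self): return f"A[{self.left} U {self.right}]"


# -- parser --------------------------------------------------------------

_TOKEN_RE = re.compile(r"""
    \s*(?:
      (?P<arrow>->|→|=>|⇒)
    | (?P<le><=|≤)
    | (?P<ge>>=|≥)
    | (?P<eq>=)
    | (?P<and>&&|&|∧)
    | (?P<or>\|\||\||∨)
    | (?P<not>!|¬|~)
    | (?P<lpar>\()
    | (?P<rpar>\))
    | (?P<lbra>\[)
    | (?P<rbra>\])
    | (?P<int>\d+)
    | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
    )""", re.VERBOSE)

_TEMPORAL1 = {"EX": EX, "EF": EF, "EG": EG, "AX": AX, "AF": AF, "AG": AG}


def _tokenize(text: str):
    pos, tokens = 0, []
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == m.start():
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise CTLSyntaxError(f"unexpected character {stripped[0]!r}", pos)
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    tokens.append(("end", "", len(text)))
    return tokens


class _Parser:
    """Recursive descent; precedence (low→high): -> | & unary."""

    def __init__(self, text: str, network: LogicalNetwork | None):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0
        self.network = network

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str):
        tok = self.next()
        if tok[0] != kind:
            raise CTLSyntaxError(f"expected {kind}, got {tok[1]!r}", tok[2])
        return tok

    def parse(self) -> CTLFormula:
        f = self.implication()
        tok = self.peek()
        if tok[0] != "end":
            raise CTLSyntaxError(f"trailing input {tok[1]!r}", tok[2])
        return f

    def implication(self) -> CTLFormula:
        left = self.disjunction()
        if self.peek()[0] == "arrow":
            self.next()
            return Implies(left, self.implication())  # right-associative
        return left

    def disjunction(self) -> CTLFormula:
        f = self.conjunction()
        while self.peek()[0] == "or":
            self.next()
            f = Or(f, self.conjunction())
        return f

    def conjunction(self) -> CTLFormula:
        f = self.unary()
        while self.peek()[0] == "and":
            self.next()
            f = And(f, self.unary())
        return f

    def unary(self) -> CTLFormula:
        kind, value, pos = self.peek()
        if kind == "not":
            self.next()
            return Not(self.unary())
        if kind == "lpar":
            self.next()
            f = self.implication()
            self.expect("rpar")
            return f
        if kind == "name":
            if value in _TEMPORAL1:
                self.next()
                self.expect("lpar")
                f = self.implication()
                self.expect("rpar")
                return _TEMPORAL1[value](f)
            if value in ("E", "A"):
                self.next()
                self.expect("lbra")
                left = self.implication()
                u = self.expect("name")
                if u[1] != "U":
                    raise CTLSyntaxError("expected 'U' in until formula", u[2])
                right = self.implication()
                self.expect("rbra")
                return (EU if value == "E" else AU)(left, right)
            if value in ("true", "TRUE", "True"):
                self.next()
                return Bool(True)
            if value in ("false", "FALSE", "False"):
                self.next()
                return Bool(False)
            return self.atom()
        raise CTLSyntaxError(f"unexpected token {value!r}", pos)

    def atom(self) -> CTLFormula:
        name = self.expect("name")
        kind, value, pos = self.next()
        if kind not in ("eq", "le", "ge"):
            raise CTLSyntaxError("expected '=', '<=' or '>=' after entity "
                                 f"{name[1]!r}", pos)
        level = self.expect("int")
        op = {"eq": "=", "le": "<=", "ge": ">="}[kind]
        atom = Atom(name[1], op, int(level[1]))
        if self.network is not None:
            ent = self.network.entity(atom.entity)  # raises on unknown names
            if not 0 <= atom.level <= ent.max_level:
                raise CTLSyntaxError(
                    f"level {atom.level} out of range for {atom.entity} "
                    f"(max {ent.max_level})", level[2])
        return atom


def parse_ctl(text: str, network: LogicalNetwork | None = None) -> CTLFormula:
    """Parse an ASCII CTL formula, e.g. ``AG(PTEN = 1) -> EF(Akt = 0)``.

    When ``network`` is given, atoms are checked against its entities and
    level ranges.
    """
    return _Parser(text, network).parse()


def read_formulas(path: str | Path,
                  network: LogicalNetwork | None = None) -> list[CTLFormula]:
    """Read one formula per line; blank lines and ``#`` comments are skipped."""
    formulas = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            formulas.append(parse_ctl(line, network))
    return formulas


# -- fixpoint labeling ---------------------------------------------------

def _atom_sat(graph: nx.DiGraph, index: dict[str, int], atom: Atom):
    i = index[atom.entity]
    if atom.op == "=":
        return {s for s in graph.nodes if s[i] == atom.level}
    if atom.op == "<=":
        return {s for s in graph.nodes if s[i] <= atom.level}
    return {s for s in graph.nodes if s[i] >= atom.level}


def _succ_total(graph: nx.DiGraph, s):
    """Successors with deadlocks totalized by a self-loop."""
    succ = list(graph.successors(s))
    return succ if succ else [s]


def _pre_exists(graph: nx.DiGraph, S: set) -> set:
    """{s : some (totalized) successor of s is in S}."""
    out = set()
    for s in graph.nodes:
        if any(t in S for t in _succ_total(graph, s)):
            out.add(s)
    return out


def sat_graph(graph: nx.DiGraph, entity_index: dict[str, int],
              formula: CTLFormula) -> set:
    """Satisfaction set of ``formula`` on a raw digraph of level tuples."""
    nodes = set(graph.nodes)
    rec = lambda f: sat_graph(graph, entity_index, f)

    if isinstance(formula, Bool):
        return set(nodes) if formula.value else set()
    if isinstance(formula, Atom):
        return _atom_sat(graph, entity_index, formula)
    if isinstance(formula, Not):
        return nodes - rec(formula.arg)
    if isinstance(formula, And):
        return rec(formula.left) & rec(formula.right)
    if isinstance(formula, Or):
        return rec(formula.left) | rec(formula.right)
    if isinstance(formula, Implies):
        return (nodes - rec(formula.left)) | rec(formula.right)
    if isinstance(formula, EX):
        return _pre_exists(graph, rec(formula.arg))
    if isinstance(formula, AX):
        return nodes - _pre_exists(graph, nodes - rec(formula.arg))
    if isinstance(formula, EF):
        return rec(EU(Bool(True), formula.arg))
    if isinstance(formula, AF):
        return rec(AU(Bool(True), formula.arg))
    if isinstance(formula, EG):
        # greatest fixpoint: Z = sat(φ) ∩ pre∃(Z)
        Z = rec(formula.arg)
        while True:
            Z2 = Z & _pre_exists(graph, Z)
            if Z2 == Z:
                return Z
            Z = Z2
    if isinstance(formula, AG):
        return nodes - rec(EF(Not(formula.arg)))
    if isinstance(formula, EU):
        # least fixpoint: Z = sat(ψ) ∪ (sat(φ) ∩ pre∃(Z))
        phi, psi = rec(formula.left), rec(formula.right)
        Z = set(psi)
        while True:
            Z2 = Z | (phi & _pre_exists(graph, Z))
            if Z2 == Z:
                return Z
            Z = Z2
    if isinstance(formula, AU):
        # A[φ U ψ] = ¬E[¬ψ U (¬φ ∧ ¬ψ)] ∧ ¬EG(¬ψ)
        phi, psi = formula.left, formula.right
        bad = rec(EU(Not(psi), And(Not(phi), Not(psi))))
        never = rec(EG(Not(psi)))
        return nodes - (bad | never)
    raise TypeError(f"unknown CTL node {formula!r}")


def sat_states(sg, formula: CTLFormula) -> set:
    """Exact CTL satisfaction set on a :class:`StateGraph`."""
    index = {n: i for i, n in enumerate(sg.network.entity_order)}
    return sat_graph(sg.graph, index, formula)


def model_satisfies(sg, formula: CTLFormula, existential: bool = False) -> bool:
    """Model-level satisfaction.

    Default is universal over all states (the formula must hold everywhere);
    ``existential=True`` asks instead whether some state satisfies it.
    """
    sat = sat_states(sg, formula)
    if existential:
        return bool(sat)
    return len(sat) == sg.graph.number_of_nodes()
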