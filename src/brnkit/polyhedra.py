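"""Exact rational linear constraints and Fourier–Motzkin projection.

Everything here runs on :class:`fractions.Fraction` — feasibility,
entailment and projection answers are exact decisions, never floating-point
approximations.  Systems in this package are tiny (tens of variables), so
the classical double-description-free Fourier–Motzkin procedure with
equality back-substitution is entirely adequate.

A constraint is stored in the homogeneous form ``terms · x + const REL 0``
with ``REL`` one of ``<=``, ``<`` or ``=``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd
from typing import Iterable, Mapping, Sequence

__all__ = ["LinearConstraint", "eliminate_variable", "project",
           "feasible", "entails", "canonical_set"]

LE, LT, EQ = "<=", "<", "="


def _frac(x) -> Fraction:
    return x if isinstance(x, Fraction) else Fraction(x)


@dataclass(frozen=True)
class LinearConstraint:
    """``sum(terms[v] * v) + const  REL  0`` with REL in {<=, <, =}."""

    terms: tuple[tuple[str, Fraction], ...]
    const: Fraction
    rel: str

    @staticmethod
    def make(terms: Mapping[str, Fraction | int], const=0,
             rel: str = LE) -> "LinearConstraint":
        if rel not in (LE, LT, EQ):
            raise ValueError(f"bad relation {rel!r}")
        clean = {v: _frac(c) for v, c in terms.items() if c != 0}
        return LinearConstraint(tuple(sorted(clean.items())), _frac(const), rel)

    # -- helpers ---------------------------------------------------------

    def coeff(self, var: str) -> Fraction:
        for v, c in self.terms:
            if v == var:
                return c
        return Fraction(0)

    def variables(self) -> set[str]:
        return {v for v, _ in self.terms}

    def is_ground(self) -> bool:
        return not self.terms

    def ground_true(self) -> bool:
        assert self.is_ground()
        if self.rel == LE:
            return self.const <= 0
        if self.rel == LT:
            return self.const < 0
        return self.const == 0

    def scaled(self, k: Fraction) -> "LinearConstraint":
        """Multiply by k > 0 (direction preserved)."""
        assert k > 0
        return LinearConstraint.make({v: c * k for v, c in self.terms},
                                     self.const * k, self.rel)

    def evaluate(self, point: Mapping[str, Fraction | int]) -> bool:
        val = self.const + sum(c * _frac(point[v]) for v, c in self.terms)
        if self.rel == LE:
            return val <= 0
        if self.rel == LT:
            return val < 0
        return val == 0

    def lhs_value(self, point: Mapping[str, Fraction | int]) -> Fraction:
        return self.const + sum(c * _frac(point[v]) for v, c in self.terms)

    def negation(self) -> list["LinearConstraint"]:
        """Constraints whose disjunction is the negation of self.

        For inequalities the negation is a single constraint; for an
        equality it is the pair (lhs < 0, lhs > 0).
        """
        neg_terms = {v: -c for v, c in self.terms}
        if self.rel == LE:   # not(e <= 0)  ==  e > 0  ==  -e < 0
            return [LinearConstraint.make(neg_terms, -self.const, LT)]
        if self.rel == LT:   # not(e < 0)   ==  -e <= 0
            return [LinearConstraint.make(neg_terms, -self.const, LE)]
        return [LinearConstraint.make(dict(self.terms), self.const, LT),
                LinearConstraint.make(neg_terms, -self.const, LT)]

    def canonical(self) -> "LinearConstraint":
        """Integer coefficients with gcd 1; equalities get a positive
        leading coefficient."""
        if not self.terms:
            c = self.const
            if c != 0:
                c = Fraction(1 if c > 0 else -1)
            return LinearConstraint((), c, self.rel)
        denoms = [c.denominator for _, c in self.terms] + [self.const.denominator]
        lcm = 1
        for d in denoms:
            lcm = lcm * d // gcd(lcm, d)
        ints = [c * lcm for _, c in self.terms] + [self.const * lcm]
        g = 0
        for x in ints:
            g = gcd(g, int(x))
        g = g or 1
        scale = Fraction(lcm, g)
        out = self.scaled(scale)
        if out.rel == EQ and out.terms and out.terms[0][1] < 0:
            out = LinearConstraint(tuple((v, -c) for v, c in out.terms),
                                   -out.const, EQ)
        return out

    def __str__(self) -> str:
        if not self.terms:
            lhs = str(self.const)
            return f"{lhs} {self.rel} 0"
        parts = []
        for v, c in self.terms:
            if c == 1:
                t = v
            elif c == -1:
                t = f"-{v}"
            else:
                t = f"{c}*{v}"
            parts.append(t)
        lhs = " + ".join(parts).replace("+ -", "- ")
        rhs = -self.const
        return f"{lhs} {self.rel} {rhs}"


def _substitute(con: LinearConstraint, var: str,
                expr_terms: Mapping[str, Fraction], expr_const: Fraction
                ) -> LinearConstraint:
    """Replace ``var`` by the affine expression ``expr`` in ``con``."""
    a = con.coeff(var)
    if a == 0:
        return con
    terms = {v: c for v, c in con.terms if v != var}
    for v, c in expr_terms.items():
        terms[v] = terms.get(v, Fraction(0)) + a * c
    return LinearConstraint.make(terms, con.const + a * expr_const, con.rel)


def eliminate_variable(constraints: Sequence[LinearConstraint],
                       var: str) -> list[LinearConstraint]:
    """Existentially eliminate ``var``: equality substitution when possible,
    otherwise one Fourier–Motzkin step."""
    eqs = [c for c in constraints if c.rel == EQ and c.coeff(var) != 0]
    if eqs:
        # var = -(rest + const)/a from the first equality
        eq = eqs[0]
        a = eq.coeff(var)
        expr_terms = {v: -c / a for v, c in eq.terms if v != var}
        expr_const = -eq.const / a
        out = [_substitute(c, var, expr_terms, expr_const)
               for c in constraints if c is not eq]
        return _simplify(out)

    upper, lower, rest = [], [], []
    for c in constraints:
        a = c.coeff(var)
        if a > 0:
            upper.append(c)       # var <= ...
        elif a < 0:
            lower.append(c)       # var >= ...
        else:
            rest.append(c)
    for lo in lower:
        for up in upper:
            a_lo, a_up = -lo.coeff(var), up.coeff(var)
            terms = {v: c * a_lo for v, c in up.terms if v != var}
            for v, c in lo.terms:
                if v != var:
                    terms[v] = terms.get(v, Fraction(0)) + c * a_up
            const = up.const * a_lo + lo.const * a_up
            rel = LT if LT in (lo.rel, up.rel) else LE
            rest.append(LinearConstraint.make(terms, const, rel))
    return _simplify(rest)


def _simplify(constraints: Iterable[LinearConstraint]
              ) -> list[LinearConstraint]:
    """Canonicalize, drop trivially-true ground constraints, dedupe."""
    out, seen = [], set()
    for c in constraints:
        c = c.canonical()
        if c.is_ground() and c.ground_true():
            continue
        if c not in seen:
            seen.add(c)
            out.append(c)
    return out


def project(constraints: Sequence[LinearConstraint],
            eliminate: Sequence[str]) -> list[LinearConstraint]:
    """Existentially eliminate all variables in ``eliminate`` (in order)."""
    cons = _simplify(constraints)
    for var in eliminate:
        cons = eliminate_variable(cons, var)
    return cons


def _choose_value(lowers: list[tuple[Fraction, str]],
                  uppers: list[tuple[Fraction, str]]) -> Fraction:
    """A value satisfying strict/non-strict lower and upper bounds that are
    known (by FM feasibility) to be jointly satisfiable."""
    lo = max(lowers, default=None, key=lambda t: t[0])
    up = min(uppers, default=None, key=lambda t: t[0])
    if lo is None and up is None:
        return Fraction(0)
    if lo is None:
        return up[0] - 1 if up[1] == LT else up[0]
    if up is None:
        return lo[0] + 1 if lo[1] == LT else lo[0]
    if lo[0] == up[0]:
        return lo[0]  # feasibility guarantees both bounds are non-strict
    return (lo[0] + up[0]) / 2


def feasible(constraints: Sequence[LinearConstraint]
             ) -> tuple[bool, dict[str, Fraction] | None]:
    """Exact feasibility with a rational witness when satisfiable."""
    cons = _simplify(constraints)
    variables = sorted({v for c in cons for v in c.variables()})
    return _feasible_rec(cons, variables)


def _feasible_rec(cons, variables):
    if any(c.is_ground() and not c.ground_true() for c in cons):
        return False, None
    if not variables:
        return True, {}
    var = variables[-1]
    eqs = [c for c in cons if c.rel == EQ and c.coeff(var) != 0]
    reduced = eliminate_variable(cons, var)
    ok, witness = _feasible_rec(reduced, variables[:-1])
    if not ok:
        return False, None
    if eqs:
        eq = eqs[0]
        a = eq.coeff(var)
        value = (-eq.const - sum(c * witness[v] for v, c in eq.terms
                                 if v != var)) / a
    else:
        lowers, uppers = [], []
        for c in cons:
            a = c.coeff(var)
            if a == 0:
                continue
            bound = -(c.const + sum(cc * witness[v] for v, cc in c.terms
                                    if v != var)) / a
            if a > 0:
                uppers.append((bound, c.rel))
            else:
                lowers.append((bound, c.rel))
        value = _choose_value(lowers, uppers)
    witness = dict(witness)
    witness[var] = value
    return True, witness


def entails(constraints: Sequence[LinearConstraint],
            c: LinearConstraint) -> bool:
    """True iff every point of ``constraints`` satisfies ``c``.

    Checked as infeasibility of ``constraints ∧ ¬c`` (for equalities, of
    both strict half-spaces)."""
    for neg in c.negation():
        ok, _ = feasible(list(constraints) + [neg])
        if ok:
            return False
    return True


def canonical_set(constraints: Sequence[LinearConstraint],
                  context: Sequence[LinearConstraint] = ()
                  ) -> list[LinearConstraint]:
    """Canonicalize, dedupe and greedily drop constraints entailed by the
    remaining ones (together with ``context``).  Idempotent."""
    cons = _simplify(constraints)
    cons.sort(key=lambda c: (c.rel, c.terms, c.const))
    kept = list(cons)
    for c in list(cons):
        others = [k for k in kept if k is not c]
        if entails(others + list(context), c):
            kept = others
    return kept
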