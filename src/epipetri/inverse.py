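"""Inverse construction: a representing Petri net for any polynomial ODE system.

Each monomial of each equation, written as ``f * alpha * x^m`` with ``f`` a
signed integer and ``alpha`` a (positive) parameter function, becomes one
transition ``z_{i,j}`` of a net whose rate equations reproduce the system
exactly.  ``j`` ranks the distinct exponent tuples in ascending lexicographic
order, so transition names are reproducible.  The raw construction carries
catalytic round trips (equal-count in/out arc pairs) for every variable that
appears in a monomial but is not the equation's own; :func:`simplify` merges
transitions that share a rate and an input signature and deletes no-ops,
recovering the hand-drawn nets of the standard models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import sympy

from ._symbols import make_symbol
from .core import Arc, Compartment, ODESystem, PetriNet, Transition, rate_equations

__all__ = [
    "MonomialTerm",
    "DecompositionError",
    "decompose_ode",
    "build_petri",
    "simplify",
    "invert_ode",
]


class DecompositionError(ValueError):
    """Raised for non-polynomial input or a term whose integer/parameter
    factorization would require a negative output arc count."""


@dataclass(frozen=True)
class MonomialTerm:
    """One monomial ``f * alpha * x^exponents`` of equation ``equation_index``.

    ``column`` is the rank of the exponent tuple in the global ordering; the
    output count of the induced transition is ``n_i = int_factor + exponents[i]``
    at the equation's own variable.
    """

    equation_index: int
    column: int
    exponents: tuple[int, ...]
    int_factor: int
    param: sympy.Expr

    @property
    def n_own(self) -> int:
        return self.int_factor + self.exponents[self.equation_index]


def _split_coefficient(coeff: sympy.Expr) -> tuple[int, sympy.Expr]:
    """Factor a monomial coefficient as (signed integer) * (parameter function).

    The integer carries the sign and the integer content; the remainder is the
    rate.  ``-(mu+psi)`` gives ``(-1, mu+psi)``; ``3*beta/2`` gives
    ``(3, beta/2)``; a purely numeric ``-3/2`` gives ``(-3, 1/2)``.
    """
    coeff = sympy.factor_terms(sympy.together(coeff))
    num, rest = coeff.as_coeff_Mul()
    if not num.is_Rational or num == 0:
        # irrational numeric factor or unsplittable: push everything into rest
        num, rest = sympy.Integer(1), coeff
    f = int(sympy.sign(num) * sympy.numer(abs(num)))
    alpha = rest / sympy.denom(abs(num))
    if f == 0:
        raise DecompositionError(f"zero integer factor in coefficient {coeff}")
    return f, sympy.nsimplify(alpha)


def decompose_ode(ode: ODESystem) -> list[MonomialTerm]:
    """Break every right-hand side into :class:`MonomialTerm` rows.

    Exponent tuples are ranked by ascending plain lexicographic order on
    ``(m_1, ..., m_k)``; terms across equations that share a tuple share a
    column.  Raises :class:`DecompositionError` for non-polynomial input or
    when ``int_factor + m_i < 0`` (the term cannot be realized with
    nonnegative arc counts).
    """
    xs = ode.variables
    k = len(xs)
    raw: list[tuple[int, tuple[int, ...], sympy.Expr]] = []
    for i, rhs in enumerate(ode.rhs):
        expr = sympy.expand(sympy.sympify(rhs))
        if expr == 0:
            continue
        try:
            poly = sympy.Poly(expr, *xs)
        except sympy.PolynomialError as exc:
            raise DecompositionError(
                f"equation {i} ({xs[i]}') is not polynomial in the variables: {expr}"
            ) from exc
        for exps, coeff in poly.terms():
            raw.append((i, tuple(int(e) for e in exps), coeff))
    tuples = sorted({e for _, e, _ in raw})
    col = {e: j + 1 for j, e in enumerate(tuples)}  # 1-based like z_{i,j}
    terms: list[MonomialTerm] = []
    for i, exps, coeff in raw:
        f, alpha = _split_coefficient(coeff)
        term = MonomialTerm(i, col[exps], exps, f, alpha)
        if term.n_own < 0:
            raise DecompositionError(
                f"term {coeff}*{sympy.Mul(*[x**e for x, e in zip(xs, exps)])} of equation "
                f"{i} has output count f + m = {term.n_own} < 0"
            )
        terms.append(term)
    terms.sort(key=lambda t: (t.equation_index, t.column))
    return terms


def build_petri(terms: Sequence[MonomialTerm], ode: ODESystem) -> PetriNet:
    """Assemble the representing net from a term table.

    Transition ``z_{i,j}``: rate ``alpha_{i,j}``; inputs ``m_{s,j}`` arcs from
    every variable ``x_s`` in the monomial; outputs ``n_{i,j}`` arcs to its own
    variable plus catalytic returns ``m_{s,j}`` arcs to every other ``x_s`` —
    so foreign variables act as catalysts and the net effect on ``x_i`` is
    exactly ``f * alpha * x^m``.
    """
    xs = ode.variables
    comps = [Compartment(x.name) for x in xs]
    transitions: list[Transition] = []
    arcs: list[Arc] = []
    params: dict[str, str] = dict(ode.parameters)
    for term in terms:
        i = term.equation_index
        name = f"z_{i + 1}_{term.column}"
        transitions.append(Transition(name, term.param))
        for p in term.param.free_symbols:
            params.setdefault(p.name, "rate")
        for s, m_s in enumerate(term.exponents):
            if m_s:
                arcs.append(Arc(xs[s].name, name, m_s))
        if term.n_own:
            arcs.append(Arc(name, xs[i].name, term.n_own))
        for s, m_s in enumerate(term.exponents):
            if s != i and m_s:
                arcs.append(Arc(name, xs[s].name, m_s))
    return PetriNet(comps, transitions, arcs, params, dict(ode.constraints), name="inverse")


def simplify(net: PetriNet) -> PetriNet:
    """Merge/cancel pass; the rate equations are invariant.

    Transitions with the same rate expression and the same input vector are
    replaced by a single transition whose outputs are the inputs plus the
    summed net stoichiometry (nonnegative by construction for inverse-built
    nets); transitions whose net stoichiometry vanishes everywhere are
    deleted.  Only weight-1 transitions participate; weighted ones are kept
    untouched.  Idempotent.
    """
    from .core import multiplicities

    ci = {c.name: i for i, c in enumerate(net.compartments)}
    m, n = multiplicities(net)
    weighted = {
        a.source if a.source not in ci else a.target
        for a in net.arcs
        if a.weight != 1
    }
    groups: dict[tuple, list[int]] = {}
    order: list[tuple] = []
    for j, t in enumerate(net.transitions):
        if t.name in weighted:
            key = ("solo", j)
        else:
            inputs = tuple(m[i][j] for i in range(len(ci)))
            key = ("merge", sympy.srepr(sympy.sympify(t.rate)), inputs)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(j)

    new_transitions: list[Transition] = []
    new_arcs: list[Arc] = []
    comp_names = net.compartment_names
    for key in order:
        members = groups[key]
        j0 = members[0]
        t0 = net.transitions[j0]
        if key[0] == "solo":
            new_transitions.append(t0)
            new_arcs.extend(
                a for a in net.arcs if a.source == t0.name or a.target == t0.name
            )
            continue
        inputs = [m[i][j0] for i in range(len(ci))]
        net_change = [
            sum(n[i][j] - m[i][j] for j in members) for i in range(len(ci))
        ]
        if all(d == 0 for d in net_change):
            continue  # no-op transition(s)
        outputs = [inp + d for inp, d in zip(inputs, net_change)]
        if any(o < 0 for o in outputs):
            # cannot realize merged outputs; keep members as-is
            for j in members:
                t = net.transitions[j]
                new_transitions.append(t)
                new_arcs.extend(a for a in net.arcs if t.name in (a.source, a.target))
            continue
        new_transitions.append(t0)
        for i, cname in enumerate(comp_names):
            if inputs[i]:
                new_arcs.append(Arc(cname, t0.name, inputs[i]))
            if outputs[i]:
                new_arcs.append(Arc(t0.name, cname, outputs[i]))
    return PetriNet(
        net.compartments, new_transitions, new_arcs, net.parameters, net.constraints,
        name=net.name,
    )


def invert_ode(ode: ODESystem, simplify_net: bool = True) -> PetriNet:
    """Convenience composition: decompose, build, optionally simplify."""
    net = build_petri(decompose_ode(ode), ode)
    return simplify(net) if simplify_net else net
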