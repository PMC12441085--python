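"""Petri-net and ODE-system data model plus the forward map (rate equations).

A stochastic Petri net is a bipartite multigraph: compartments (places) hold
populations, transitions fire at mass-action rates.  With ``m[i][j]`` arcs
from compartment ``x_i`` into transition ``z_j`` and ``n[i][j]`` arcs back,
a transition with rate constant ``r_j`` contributes

    w_ij * r_j * (n_ij - m_ij) * prod_s x_s ** m_sj

to ``x_i'(t)``; summing over transitions yields the rate equations.  Arc
weights ``w_ij`` (default 1) carry branching probabilities such as the p /
(1-p) split of an exposed compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import sympy

from ._symbols import (
    ExpressionError,
    PositivityRegistry,
    make_symbol,
    make_var,
    parse_expression,
)

__all__ = [
    "Compartment",
    "Transition",
    "Arc",
    "PetriNet",
    "ODESystem",
    "Diagnostic",
    "multiplicities",
    "weight_matrix",
    "rate_equations",
    "stoichiometry",
    "validate",
]


@dataclass(frozen=True)
class Compartment:
    """A place of the net; ``name`` doubles as the ODE variable name."""

    name: str
    display: Optional[str] = None


@dataclass(frozen=True)
class Transition:
    """A reaction/event with a symbolic rate constant (positive by convention)."""

    name: str
    rate: sympy.Expr


@dataclass(frozen=True)
class Arc:
    """A directed bundle of ``multiplicity`` parallel arrows between one
    compartment and one transition, carrying a symbolic ``weight``."""

    source: str
    target: str
    multiplicity: int = 1
    weight: sympy.Expr = sympy.Integer(1)


@dataclass
class ODESystem:
    """An ordered polynomial vector field x'(t) = rhs(x)."""

    variables: list[sympy.Symbol]
    rhs: list[sympy.Expr]
    parameters: dict[str, str] = field(default_factory=dict)
    constraints: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[sympy.Symbol, sympy.Expr]:
        return dict(zip(self.variables, self.rhs))

    def __getitem__(self, var) -> sympy.Expr:
        if isinstance(var, str):
            var = next(v for v in self.variables if v.name == var)
        return self.as_dict()[var]


class PetriNet:
    """A stochastic Petri net with declared, disjoint parameter/variable
    namespaces.

    Parameters
    ----------
    compartments, transitions, arcs:
        The net structure.  Transition rates and arc weights are sympy
        expressions over the declared parameters (never over variables;
        population-dependent denominators such as a mixing total are declared
        as parameter-like symbols and substituted at evaluation time).
    parameters:
        mapping name -> kind in {"rate", "probability", "quantity"}.
    constraints:
        sign-analysis substitutions, e.g. ``{"alpha": "delta + alpha_excess"}``
        to encode alpha > delta.
    """

    def __init__(
        self,
        compartments: Sequence[Compartment],
        transitions: Sequence[Transition],
        arcs: Sequence[Arc],
        parameters: Optional[Mapping[str, str]] = None,
        constraints: Optional[Mapping[str, str]] = None,
        name: str = "",
    ) -> None:
        self.compartments = list(compartments)
        self.transitions = list(transitions)
        self.arcs = list(arcs)
        self.parameters = dict(parameters or {})
        self.constraints = dict(constraints or {})
        self.name = name
        self._symbols = {c.name: make_var(c.name) for c in self.compartments}
        self._symbols.update({p: make_symbol(p) for p in self.parameters})

    # -- construction helpers ---------------------------------------------
    @classmethod
    def build(
        cls,
        compartments: Sequence[str | Compartment],
        transitions: Sequence[tuple[str, str] | Transition],
        arcs: Sequence[tuple | Arc],
        parameters: Optional[Mapping[str, str]] = None,
        constraints: Optional[Mapping[str, str]] = None,
        name: str = "",
    ) -> "PetriNet":
        """Assemble a net from plain strings; rates and weights are parsed
        under the declared parameter namespace."""
        comps = [c if isinstance(c, Compartment) else Compartment(c) for c in compartments]
        params = dict(parameters or {})
        ns = {c.name: make_var(c.name) for c in comps}
        ns.update({p: make_symbol(p) for p in params})
        trans = []
        for t in transitions:
            if isinstance(t, Transition):
                trans.append(t)
            else:
                tname, rate = t
                trans.append(Transition(tname, parse_expression(rate, ns)))
        built_arcs = []
        for a in arcs:
            if isinstance(a, Arc):
                built_arcs.append(a)
            else:
                src, tgt, *rest = a
                mult = rest[0] if len(rest) >= 1 else 1
                weight = parse_expression(rest[1], ns) if len(rest) >= 2 else sympy.Integer(1)
                built_arcs.append(Arc(src, tgt, int(mult), weight))
        return cls(comps, trans, built_arcs, params, constraints, name=name)

    # -- lookups -----------------------------------------------------------
    @property
    def compartment_names(self) -> list[str]:
        return [c.name for c in self.compartments]

    @property
    def transition_names(self) -> list[str]:
        return [t.name for t in self.transitions]

    def var(self, name: str) -> sympy.Symbol:
        """The sympy symbol of a compartment or declared parameter."""
        return self._symbols[name]

    @property
    def variables(self) -> list[sympy.Symbol]:
        return [self._symbols[c.name] for c in self.compartments]

    def symbol_table(self) -> dict[str, sympy.Symbol]:
        return dict(self._symbols)

    def transition(self, name: str) -> Transition:
        for t in self.transitions:
            if t.name == name:
                return t
        raise KeyError(name)

    def registry(self) -> PositivityRegistry:
        return PositivityRegistry(self._symbols, self.parameters, self.constraints)

    def parse(self, text) -> sympy.Expr:
        return parse_expression(text, self._symbols)

    # -- structural edits (used by tests to build mutants) -----------------
    def with_arcs(self, extra: Sequence[Arc], name: Optional[str] = None) -> "PetriNet":
        return PetriNet(
            self.compartments,
            self.transitions,
            self.arcs + list(extra),
            self.parameters,
            self.constraints,
            name=name or self.name,
        )

    def without_arc(self, source: str, target: str) -> "PetriNet":
        kept = [a for a in self.arcs if not (a.source == source and a.target == target)]
        if len(kept) == len(self.arcs):
            raise KeyError(f"no arc {source} -> {target}")
        return PetriNet(
            self.compartments, self.transitions, kept, self.parameters, self.constraints,
            name=self.name,
        )

    def with_transition(
        self, transition: Transition, arcs: Sequence[Arc], parameters: Optional[Mapping[str, str]] = None
    ) -> "PetriNet":
        params = dict(self.parameters)
        params.update(parameters or {})
        return PetriNet(
            self.compartments,
            self.transitions + [transition],
            self.arcs + list(arcs),
            params,
            self.constraints,
            name=self.name,
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<PetriNet {self.name or '?'}: {len(self.compartments)} compartments, "
            f"{len(self.transitions)} transitions, {len(self.arcs)} arcs>"
        )


@dataclass(frozen=True)
class Diagnostic:
    """A single validation finding; ``severity`` is ``error`` or ``warning``."""

    code: str
    message: str
    severity: str = "error"


def _index_maps(net: PetriNet) -> tuple[dict[str, int], dict[str, int]]:
    ci = {c.name: i for i, c in enumerate(net.compartments)}
    ti = {t.name: j for j, t in enumerate(net.transitions)}
    return ci, ti


def multiplicities(net: PetriNet) -> tuple[list[list[int]], list[list[int]]]:
    """The k x l integer matrices (m, n): ``m[i][j]`` arrows from compartment
    i into transition j, ``n[i][j]`` arrows back out."""
    ci, ti = _index_maps(net)
    k, l = len(ci), len(ti)
    m = [[0] * l for _ in range(k)]
    n = [[0] * l for _ in range(k)]
    for arc in net.arcs:
        if arc.source in ci and arc.target in ti:
            m[ci[arc.source]][ti[arc.target]] += arc.multiplicity
        elif arc.source in ti and arc.target in ci:
            n[ci[arc.target]][ti[arc.source]] += arc.multiplicity
        else:
            raise ExpressionError(
                f"arc {arc.source} -> {arc.target} does not join a compartment and a transition"
            )
    return m, n


def weight_matrix(net: PetriNet) -> list[list[sympy.Expr]]:
    """Effective weight ``w[i][j]``: the product of the weights of every arc
    (in either direction) between compartment i and transition j; 1 when no
    weighted arc is present."""
    ci, ti = _index_maps(net)
    w = [[sympy.Integer(1)] * len(ti) for _ in range(len(ci))]
    for arc in net.arcs:
        if arc.source in ci and arc.target in ti:
            i, j = ci[arc.source], ti[arc.target]
        else:
            i, j = ci[arc.target], ti[arc.source]
        w[i][j] = w[i][j] * arc.weight
    return w


def rate_equations(net: PetriNet) -> ODESystem:
    """The (weighted) mass-action ODE system induced by the net, with every
    right-hand side stored in expanded canonical polynomial form."""
    m, n = multiplicities(net)
    w = weight_matrix(net)
    xs = net.variables
    k = len(xs)
    rhs = []
    for i in range(k):
        total = sympy.Integer(0)
        for j, t in enumerate(net.transitions):
            delta = n[i][j] - m[i][j]
            if delta == 0:
                continue
            monomial = sympy.Integer(1)
            for s in range(k):
                if m[s][j]:
                    monomial *= xs[s] ** m[s][j]
            total += w[i][j] * t.rate * delta * monomial
        rhs.append(sympy.expand(total))
    return ODESystem(list(xs), rhs, dict(net.parameters), dict(net.constraints))


def stoichiometry(net: PetriNet) -> list[list[int]]:
    """The k x l integer matrix n - m; each column is the net population
    change of one transition firing."""
    m, n = multiplicities(net)
    return [[n[i][j] - m[i][j] for j in range(len(row))] for i, row in enumerate(m)]


def validate(net: PetriNet) -> list[Diagnostic]:
    """Structural diagnostics; an empty list means the net invariants hold."""
    out: list[Diagnostic] = []
    cnames = net.compartment_names
    tnames = net.transition_names
    seen: set[str] = set()
    for name in cnames + tnames:
        if not name:
            out.append(Diagnostic("empty-name", "empty compartment/transition name"))
        if name in seen:
            out.append(Diagnostic("duplicate-name", f"duplicate name {name!r}"))
        seen.add(name)
    cset, tset = set(cnames), set(tnames)
    vars_ = set(net.variables)
    for arc in net.arcs:
        src_c, tgt_c = arc.source in cset, arc.target in cset
        src_t, tgt_t = arc.source in tset, arc.target in tset
        if not ((src_c and tgt_t) or (src_t and tgt_c)):
            out.append(
                Diagnostic(
                    "dangling-arc",
                    f"arc {arc.source!r} -> {arc.target!r} must join one compartment and one transition",
                )
            )
        if arc.multiplicity < 1:
            out.append(
                Diagnostic(
                    "nonpositive-multiplicity",
                    f"arc {arc.source!r} -> {arc.target!r} has multiplicity {arc.multiplicity}",
                )
            )
    for t in net.transitions:
        if t.rate == 0:
            out.append(Diagnostic("zero-rate", f"transition {t.name!r} has zero rate"))
        if set(sympy.sympify(t.rate).free_symbols) & vars_:
            out.append(
                Diagnostic(
                    "variable-in-rate",
                    f"transition {t.name!r} rate depends on a compartment variable; "
                    "declare the quantity as a parameter-like symbol instead",
                    severity="warning",
                )
            )
    return out
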