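"""Geometric R0: infection paths, expected crossing times, the matrix of flows.

The (i, k) entry of the next-generation matrix is the expected number of new
infections in disease compartment i caused by one individual introduced in
compartment k.  On the Petri net that expectation decomposes over *infection
paths*: walks k -> ... -> j through infection-module transitions, closed by
exactly one infection-process (contact) transition that deposits the new
infection in i.  Each path contributes S(gamma) * E(gamma):

* E(gamma) — the expected time spent crossing the path: the product of the
  traversed progression rates divided by the product, over every compartment
  visited before the final one, of that compartment's total exit rate.  The
  contact transition contributes to neither product (its catalytic return
  arc cancels its consumption).
* S(gamma) — the susceptible flow through the contact transition at the
  disease-free equilibrium: its rate times its net output into the
  destination times the DFE values of its non-disease inputs (exactly that
  transition's contribution to the F-matrix entry).

Summing over paths reconstructs F V^{-1} entrywise.  The construction needs
each traversed compartment to have well-defined exponential exit clocks:
single-arc, no-return exit transitions, and no susceptible inflow into them
(:func:`check_assumption7`); nets violating this (e.g. a shedding transition
that returns the infectious individual) make the method refuse rather than
approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import sympy

from .core import PetriNet, multiplicities, weight_matrix
from .kmmodules import DFE, KMPartition
from .ngm import FV_matrices, next_generation_matrix

__all__ = [
    "InfectionPath",
    "FlowMatrix",
    "FlowsNotApplicable",
    "check_assumption7",
    "enumerate_paths",
    "expected_time",
    "susceptible_flow",
    "matrix_of_flows",
    "verify_corollary9",
]


class FlowsNotApplicable(ValueError):
    """The net violates the exit-clock structure the path expectation needs."""


@dataclass(frozen=True)
class InfectionPath:
    """A path: compartments x_{i_1} .. x_{i_k} (all disease), transitions
    z_{i_1} .. z_{i_{k-1}} with the final one the unique contact transition."""

    compartments: tuple[str, ...]
    transitions: tuple[str, ...]

    @property
    def source(self) -> str:
        return self.compartments[0]

    @property
    def destination(self) -> str:
        return self.compartments[-1]

    @property
    def contact_transition(self) -> str:
        return self.transitions[-1]


@dataclass
class FlowMatrix:
    """The s x s matrix of flows with its per-entry path decomposition."""

    order: tuple[str, ...]
    M: sympy.Matrix
    decomposition: dict[tuple[str, str], list[tuple[InfectionPath, sympy.Expr, sympy.Expr]]] = field(
        default_factory=dict
    )


class _Ctx:
    """Precomputed indices shared by the path routines."""

    def __init__(self, net: PetriNet, part: KMPartition):
        part.validate_against(net)
        self.net = net
        self.part = part
        self.m, self.n = multiplicities(net)
        self.w = weight_matrix(net)
        self.ci = {c: i for i, c in enumerate(net.compartment_names)}
        self.ti = {t: j for j, t in enumerate(net.transition_names)}
        self.disease = list(part.s_i)

    def exit_set(self, x: str) -> list[str]:
        """Z_x: transitions drawn by exactly one arc from x with no return."""
        i = self.ci[x]
        return [
            z
            for z, j in self.ti.items()
            if self.m[i][j] == 1 and self.n[i][j] == 0
        ]

    def exit_rate(self, x: str) -> sympy.Expr:
        i = self.ci[x]
        total = sympy.Integer(0)
        for z in self.exit_set(x):
            j = self.ti[z]
            total += self.w[i][j] * self.net.transition(z).rate
        return total


def check_assumption7(net: PetriNet, part: KMPartition) -> list[str]:
    """Diagnostics for the exit-clock structure; empty list means the flows
    method applies.

    Flags: (a) an infection-module transition with a return arc to a disease
    source compartment; (b) a multi-arc draw from a disease compartment into
    an infection-module transition; (c) susceptible/non-disease inflow into an
    infection-module transition (also a G1 violation).
    """
    ctx = _Ctx(net, part)
    issues: list[str] = []
    disease = set(part.s_i)
    for z in part.t_i:
        j = ctx.ti[z]
        for x in net.compartment_names:
            i = ctx.ci[x]
            if x in disease:
                if ctx.m[i][j] and ctx.n[i][j]:
                    issues.append(
                        f"transition {z} both consumes and returns {x} "
                        "(return arc breaks the exit clock)"
                    )
                if ctx.m[i][j] > 1:
                    issues.append(f"transition {z} draws {ctx.m[i][j]} arcs from {x}")
            elif ctx.m[i][j]:
                issues.append(f"non-disease compartment {x} feeds infection transition {z}")
    return issues


def enumerate_paths(
    net: PetriNet, part: KMPartition, dst: str, src: str
) -> list[InfectionPath]:
    """All infection paths from introduction compartment ``src`` to
    new-infection compartment ``dst``.

    Interior compartments are distinct; the destination (a newly created
    individual) is unrestricted, which yields the loop entries of the
    diagonal.  The contact transition is always last: new infections are the
    endpoint of a path, never a waypoint.
    """
    ctx = _Ctx(net, part)
    issues = check_assumption7(net, part)
    if issues:
        raise FlowsNotApplicable("; ".join(issues))
    disease = set(part.s_i)
    if dst not in disease or src not in disease:
        raise ValueError("src and dst must be disease compartments")
    out: list[InfectionPath] = []

    def extend(comps: list[str], trans: list[str]) -> None:
        x = comps[-1]
        i = ctx.ci[x]
        # close with a contact transition depositing the new infection in dst
        for z in part.t_ip:
            j = ctx.ti[z]
            if ctx.m[i][j] >= 1 and ctx.n[ctx.ci[dst]][j] > ctx.m[ctx.ci[dst]][j]:
                out.append(InfectionPath(tuple(comps) + (dst,), tuple(trans) + (z,)))
        # or continue through the infection module
        for z in part.t_i:
            j = ctx.ti[z]
            if ctx.m[i][j] == 1 and ctx.n[i][j] == 0:
                for y in part.s_i:
                    if ctx.n[ctx.ci[y]][j] >= 1 and y not in comps:
                        extend(comps + [y], trans + [z])

    extend([src], [])
    return out


def expected_time(net: PetriNet, part: KMPartition, path: InfectionPath) -> sympy.Expr:
    """E(gamma): product of traversed progression weights*rates over the
    product of total exit rates of every compartment before the destination.
    The contact transition contributes to neither product."""
    ctx = _Ctx(net, part)
    numerator = sympy.Integer(1)
    for l, z in enumerate(path.transitions[:-1]):  # all but the contact transition
        j = ctx.ti[z]
        src_i = ctx.ci[path.compartments[l]]
        nxt_i = ctx.ci[path.compartments[l + 1]]
        numerator *= ctx.w[src_i][j] * ctx.w[nxt_i][j] * net.transition(z).rate
    denominator = sympy.Integer(1)
    for x in path.compartments[:-1]:
        exits = ctx.exit_rate(x)
        if exits == 0:
            raise FlowsNotApplicable(
                f"compartment {x} on the path has an empty exit set; the "
                "expected waiting time is ill-posed"
            )
        denominator *= exits
    return sympy.cancel(numerator / denominator)


def susceptible_flow(
    net: PetriNet, part: KMPartition, path: InfectionPath, dfe: DFE
) -> sympy.Expr:
    """S(gamma): the contact transition's new-infection coefficient into the
    destination, evaluated at the DFE."""
    ctx = _Ctx(net, part)
    z = path.contact_transition
    j = ctx.ti[z]
    dst_i = ctx.ci[path.destination]
    delta = ctx.n[dst_i][j] - ctx.m[dst_i][j]
    disease = set(part.s_i)
    flow = ctx.w[dst_i][j] * net.transition(z).rate * delta
    for y in net.compartment_names:
        if y in disease:
            continue
        yi = ctx.ci[y]
        if ctx.m[yi][j]:
            flow *= net.var(y) ** ctx.m[yi][j]
    return dfe.subs(flow)


def matrix_of_flows(net: PetriNet, part: KMPartition, dfe: DFE) -> FlowMatrix:
    """M[i][j] = sum over paths introduced in x_j with new infections in x_i
    of S(gamma) * E(gamma)."""
    order = tuple(part.s_i)
    s = len(order)
    M = sympy.zeros(s, s)
    decomposition: dict[tuple[str, str], list] = {}
    for i, dst in enumerate(order):
        for j, src in enumerate(order):
            paths = enumerate_paths(net, part, dst=dst, src=src)
            entries = []
            total = sympy.Integer(0)
            for p in paths:
                S = susceptible_flow(net, part, p, dfe)
                E = expected_time(net, part, p)
                entries.append((p, S, E))
                total += S * E
            M[i, j] = sympy.cancel(sympy.together(total))
            decomposition[(dst, src)] = entries
    return FlowMatrix(order, M, decomposition)


def verify_corollary9(
    net: PetriNet, part: KMPartition, dfe: DFE
) -> tuple[bool, sympy.Matrix]:
    """Entrywise symbolic equality of the matrix of flows and F V^{-1};
    returns (verdict, residual matrix)."""
    flow = matrix_of_flows(net, part, dfe)
    F, V = FV_matrices(net, part, dfe)
    K = next_generation_matrix(F, V)
    residual = (flow.M - K).applyfunc(lambda e: sympy.simplify(sympy.cancel(sympy.together(e))))
    return residual.is_zero_matrix is True, residual
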