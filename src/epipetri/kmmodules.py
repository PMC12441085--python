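"""Kermack-McKendrick module partition and the geometric assumption checkers.

An epidemic Petri net decomposes into three disjoint sub-nets: the
*susceptible* module (demography of the healthy population), the
*infection-process* module (the contact transitions that create new
infections), and the *infection* module (the disease compartments and their
progression/removal transitions).  Declaring this partition localizes the
next-generation-matrix computation: four structural conditions G1-G4 on the
arc multiplicities guarantee the classical sign conditions on the
new-infection and net-outflow terms, and G5 (a locally asymptotically stable
disease-free equilibrium of the net with the infection module removed)
completes the hypotheses under which the spectral radius of F V^{-1} is an
outbreak threshold.

The partition is modeling intent, not syntax, so it is user-declared input.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import sympy

from ._symbols import PositivityRegistry
from .core import ODESystem, PetriNet, multiplicities, rate_equations, weight_matrix

__all__ = [
    "KMPartition",
    "DFE",
    "GCheckReport",
    "PartitionError",
    "DFEError",
    "check_G1",
    "check_G2",
    "check_G3",
    "check_G4",
    "check_G5",
    "check_all",
    "disease_free_system",
    "find_dfe",
    "suggest_partition",
]


class PartitionError(ValueError):
    """Partition inconsistent with the net."""


class DFEError(ValueError):
    """No usable disease-free equilibrium (ambiguous, absent, or invalid)."""


@dataclass(frozen=True)
class KMPartition:
    """The three disjoint compartment subsets and transition subsets.

    ``s_i`` is ordered: it fixes the row/column order of the F and V matrices.
    The union need not cover the whole net (e.g. the recovered compartment
    typically belongs to no module).
    """

    s_s: tuple[str, ...] = ()
    s_ip: tuple[str, ...] = ()
    s_i: tuple[str, ...] = ()
    t_s: tuple[str, ...] = ()
    t_ip: tuple[str, ...] = ()
    t_i: tuple[str, ...] = ()

    def validate_against(self, net: PetriNet) -> None:
        cset = set(net.compartment_names)
        tset = set(net.transition_names)
        for label, group, universe in (
            ("compartment", (self.s_s, self.s_ip, self.s_i), cset),
            ("transition", (self.t_s, self.t_ip, self.t_i), tset),
        ):
            all_members = [x for g in group for x in g]
            unknown = [x for x in all_members if x not in universe]
            if unknown:
                raise PartitionError(f"unknown {label}(s) in partition: {unknown}")
            if len(set(all_members)) != len(all_members):
                raise PartitionError(f"{label} subsets of the partition are not disjoint")

    def disease_variables(self, net: PetriNet) -> list[sympy.Symbol]:
        return [net.var(x) for x in self.s_i]


@dataclass(frozen=True)
class DFE:
    """A disease-free equilibrium: disease compartments at zero, the rest at
    symbols or solved values; ``substitutions`` are declared-symbol rewrites
    (e.g. a mixing total A -> S, or a population size N -> Lambda/mu) applied
    after the assignment."""

    assignment: dict[sympy.Symbol, sympy.Expr]
    substitutions: dict[sympy.Symbol, sympy.Expr] = field(default_factory=dict)
    mode: str = "keep-symbolic"

    def subs(self, expr: sympy.Expr) -> sympy.Expr:
        out = sympy.sympify(expr).subs(self.assignment)
        if self.substitutions:
            out = out.subs(self.substitutions)
        return sympy.cancel(sympy.together(out))


@dataclass
class GCheckReport:
    """Outcome of one structural check with the offending tuples on failure."""

    name: str
    passed: bool
    witnesses: list[tuple] = field(default_factory=list)
    detail: str = ""

    def __bool__(self) -> bool:
        return self.passed


def _indexed(net: PetriNet, part: KMPartition):
    part.validate_against(net)
    m, n = multiplicities(net)
    ci = {c: i for i, c in enumerate(net.compartment_names)}
    ti = {t: j for j, t in enumerate(net.transition_names)}
    return m, n, ci, ti


def check_G1(net: PetriNet, part: KMPartition) -> GCheckReport:
    """No arrows between susceptible-module transitions and disease
    compartments; no arrows from non-disease compartments into
    infection-module transitions."""
    m, n, ci, ti = _indexed(net, part)
    witnesses = []
    for x in part.s_i:
        for z in part.t_s:
            if m[ci[x]][ti[z]] or n[ci[x]][ti[z]]:
                witnesses.append((x, z))
    disease = set(part.s_i)
    for x in net.compartment_names:
        if x in disease:
            continue
        for z in part.t_i:
            if m[ci[x]][ti[z]]:
                witnesses.append((x, z))
    return GCheckReport("G1", not witnesses, witnesses)


def check_G2(net: PetriNet, part: KMPartition) -> GCheckReport:
    """No immigration into the disease compartments: an infection-process
    transition with no disease input must have no disease output."""
    m, n, ci, ti = _indexed(net, part)
    witnesses = []
    for z in part.t_ip:
        j = ti[z]
        if all(m[ci[x]][j] == 0 for x in part.s_i):
            for x in part.s_i:
                if n[ci[x]][j]:
                    witnesses.append((x, z))
    return GCheckReport("G2", not witnesses, witnesses)


def check_G3(net: PetriNet, part: KMPartition) -> GCheckReport:
    """No disappearance of infected individuals through the infection process,
    and no cross-compartment consumption inside the infection module.

    Concretely: (a) for every infection-process transition, n >= m at every
    disease compartment (contacts return the infectious individual); (b) for
    every infection-module transition z and disease compartment x_i, if z
    consumes from some *other* disease compartment then n >= m at x_i (this
    is what makes the off-diagonal of V nonpositive).  A transition's own
    source compartment is exempt: progression out of a compartment is the
    diagonal of V, not a disappearance.
    """
    m, n, ci, ti = _indexed(net, part)
    witnesses = []
    for z in part.t_ip:
        j = ti[z]
        for x in part.s_i:
            if n[ci[x]][j] < m[ci[x]][j]:
                witnesses.append((x, z))
    for z in part.t_i:
        j = ti[z]
        inputs = [x for x in part.s_i if m[ci[x]][j]]
        for x in part.s_i:
            if any(y != x for y in inputs) and n[ci[x]][j] < m[ci[x]][j]:
                witnesses.append((x, z))
    return GCheckReport("G3", not witnesses, witnesses)


def check_G4(
    net: PetriNet, part: KMPartition, registry: Optional[PositivityRegistry] = None
) -> GCheckReport:
    """Positive outflow of the disease compartments: for every
    infection-module transition, the weighted net consumption
    sum_i w_ij (m_ij - n_ij) over disease compartments is >= 0.

    Weights enter because a branching transition splits one individual into
    probability-weighted outputs that sum to at most one.
    """
    m, n, ci, ti = _indexed(net, part)
    w = weight_matrix(net)
    registry = registry or net.registry()
    witnesses = []
    for z in part.t_i:
        j = ti[z]
        total = sympy.Integer(0)
        for x in part.s_i:
            i = ci[x]
            total += w[i][j] * (m[i][j] - n[i][j])
        verdict = registry.is_nonnegative(total)
        if verdict is not True:
            witnesses.append((z, sympy.simplify(total)))
    return GCheckReport("G4", not witnesses, witnesses)


def check_all(net: PetriNet, part: KMPartition) -> dict[str, GCheckReport]:
    reg = net.registry()
    return {
        "G1": check_G1(net, part),
        "G2": check_G2(net, part),
        "G3": check_G3(net, part),
        "G4": check_G4(net, part, reg),
    }


def disease_free_system(net: PetriNet, part: KMPartition) -> ODESystem:
    """Rate equations of the non-disease compartments with every disease
    variable set to zero (the demographic system left after removing the
    infection module)."""
    part.validate_against(net)
    ode = rate_equations(net)
    disease = set(part.disease_variables(net))
    zero = {x: sympy.Integer(0) for x in disease}
    variables, rhs = [], []
    for x, expr in zip(ode.variables, ode.rhs):
        if x in disease:
            continue
        variables.append(x)
        rhs.append(sympy.expand(expr.subs(zero)))
    return ODESystem(variables, rhs, ode.parameters, ode.constraints)


def find_dfe(
    net: PetriNet,
    part: KMPartition,
    mode: str = "keep-symbolic",
    assignment: Optional[Mapping] = None,
    substitutions: Optional[Mapping] = None,
) -> DFE:
    """Locate (or accept) the disease-free equilibrium.

    ``keep-symbolic``
        non-disease compartments stay as their own symbols — the convention
        under which R0 formulas read e.g. beta*S/alpha.
    ``symbolic-solve``
        solve g(0, y) = 0 for the non-disease compartments; requires a unique
        solution, otherwise raises :class:`DFEError`.
    ``user-supplied``
        validate that the given assignment annihilates g(0, y) symbolically.
    """
    part.validate_against(net)
    disease = part.disease_variables(net)
    out: dict[sympy.Symbol, sympy.Expr] = {x: sympy.Integer(0) for x in disease}
    subs = {
        net.var(k) if isinstance(k, str) else k: net.parse(v) if isinstance(v, str) else sympy.sympify(v)
        for k, v in (substitutions or {}).items()
    }
    dfs = disease_free_system(net, part)
    if mode == "keep-symbolic":
        for x in dfs.variables:
            out[x] = x
    elif mode == "symbolic-solve":
        sols = sympy.solve(dfs.rhs, dfs.variables, dict=True)
        sols = [s for s in sols if all(v.free_symbols.isdisjoint(dfs.variables) for v in s.values())]
        if len(sols) != 1:
            raise DFEError(
                f"disease-free system has {len(sols)} closed-form equilibria; "
                "supply the DFE explicitly (mode='user-supplied')"
            )
        sol = sols[0]
        for x in dfs.variables:
            out[x] = sympy.cancel(sol.get(x, x))
    elif mode == "user-supplied":
        if assignment is None:
            raise DFEError("mode='user-supplied' needs an assignment")
        for k, v in assignment.items():
            sym = net.var(k) if isinstance(k, str) else k
            out[sym] = net.parse(v) if isinstance(v, str) else sympy.sympify(v)
        for x, expr in zip(dfs.variables, dfs.rhs):
            residual = sympy.simplify(sympy.sympify(expr).subs(out).subs(subs))
            if residual != 0:
                raise DFEError(f"supplied point is not an equilibrium: {x}' = {residual}")
    else:
        raise DFEError(f"unknown DFE mode {mode!r}")
    return DFE(out, subs, mode)


def check_G5(
    net: PetriNet,
    part: KMPartition,
    dfe: DFE,
    param_ranges: Optional[Mapping[str, tuple[float, float]]] = None,
    n_samples: int = 8,
    tol: float = 1e-9,
    seed: int = 20250916,
) -> GCheckReport:
    """Local asymptotic stability of the DFE of the disease-free system.

    For each of ``n_samples`` positive parameter assignments (log-uniform over
    the given ranges, default [1e-2, 1e1]; probability-kind parameters uniform
    in (0.05, 0.95)), the Jacobian of g(0, y) at the DFE must have all
    eigenvalue real parts < -tol.  Fails with the offending sample as witness.
    """
    import numpy as np

    dfs = disease_free_system(net, part)
    if not dfs.variables:
        return GCheckReport("G5", True, detail="no non-disease compartments")
    jac = sympy.Matrix(dfs.rhs).jacobian(sympy.Matrix(dfs.variables))
    jac_at = jac.subs(dfe.assignment)
    if dfe.substitutions:
        jac_at = jac_at.subs(dfe.substitutions)
    free = sorted(
        (s for s in jac_at.free_symbols if s not in dfs.variables), key=lambda s: s.name
    )
    unresolved = [s for s in jac_at.free_symbols if s in dfs.variables]
    if unresolved:
        raise DFEError(
            f"Jacobian still contains compartment variables {unresolved}; "
            "use a solved or user-supplied DFE for the stability check"
        )
    rng = random.Random(seed)
    ranges = dict(param_ranges or {})
    witnesses = []
    fn = sympy.lambdify(free, jac_at, "numpy")
    for _ in range(n_samples):
        sample = {}
        for s in free:
            kind = net.parameters.get(s.name, "rate")
            if kind == "probability":
                sample[s] = rng.uniform(0.05, 0.95)
            else:
                lo, hi = ranges.get(s.name, (1e-2, 1e1))
                sample[s] = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi))
        J = np.asarray(fn(*[sample[s] for s in free]), dtype=float)
        eigs = np.linalg.eigvals(J)
        if not (eigs.real < -tol).all():
            witnesses.append((tuple(sorted((s.name, round(v, 6)) for s, v in sample.items())),
                              tuple(np.round(eigs.real, 9))))
    return GCheckReport("G5", not witnesses, witnesses,
                        detail=f"{n_samples} samples, tol={tol}")


def suggest_partition(net: PetriNet) -> dict[str, list[str]]:
    """Advisory heuristic only: transitions whose inputs mix disease-looking
    and other compartments are infection-process candidates.  With no disease
    annotation available the heuristic flags transitions with >= 2 distinct
    input compartments; the user declares the actual partition."""
    m, n = multiplicities(net)
    candidates = []
    for j, t in enumerate(net.transitions):
        inputs = [i for i in range(len(net.compartments)) if m[i][j]]
        if len(inputs) >= 2:
            candidates.append(t.name)
    return {"infection_process_candidates": candidates}
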