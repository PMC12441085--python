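"""Next-generation matrix: new-infection/outflow terms, F, V, K = F V^{-1}, R0.

With the KM partition declared, the rate equation of every disease compartment
splits exactly as x_i' = calF_i - calV_i, where calF sums the
infection-process transitions (new infections) and calV the infection-module
transitions (progression, recovery, death).  F and V are the Jacobians of
those terms over the disease compartments at the disease-free equilibrium;
R0 is the spectral radius of K = F V^{-1}, and K's (i, k) entry is the
expected number of new infections in compartment i caused by one individual
introduced in compartment k.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import sympy

from ._symbols import PositivityRegistry, symbolic_equal, symbolic_zero
from .core import PetriNet, multiplicities, rate_equations, weight_matrix
from .kmmodules import DFE, KMPartition, PartitionError

__all__ = [
    "NGMResult",
    "SingularVError",
    "calF",
    "calV",
    "verify_splitting",
    "FV_matrices",
    "structure_checks",
    "next_generation_matrix",
    "r0",
    "ngm_analysis",
    "threshold_check",
    "integrate_rate_equations",
]


class SingularVError(ValueError):
    """V is symbolically singular; the next-generation matrix needs a
    nonsingular outflow matrix."""


def _fv_terms(net: PetriNet, part: KMPartition, which: str) -> list[sympy.Expr]:
    part.validate_against(net)
    m, n = multiplicities(net)
    w = weight_matrix(net)
    ci = {c: i for i, c in enumerate(net.compartment_names)}
    ti = {t: j for j, t in enumerate(net.transition_names)}
    xs = net.variables
    disease_idx = [ci[x] for x in part.s_i]
    out = []
    for x in part.s_i:
        i = ci[x]
        total = sympy.Integer(0)
        if which == "F":
            for z in part.t_ip:
                j = ti[z]
                delta = n[i][j] - m[i][j]
                if delta == 0:
                    continue
                monomial = sympy.Mul(*[xs[s] ** m[s][j] for s in range(len(xs)) if m[s][j]])
                total += w[i][j] * net.transition(z).rate * delta * monomial
        else:
            for z in part.t_i:
                j = ti[z]
                delta = m[i][j] - n[i][j]
                if delta == 0:
                    continue
                # G1 confines infection-module inputs to disease compartments,
                # so the monomial runs over disease variables only.
                monomial = sympy.Mul(*[xs[s] ** m[s][j] for s in disease_idx if m[s][j]])
                total += w[i][j] * net.transition(z).rate * delta * monomial
        out.append(sympy.expand(total))
    return out


def calF(net: PetriNet, part: KMPartition) -> list[sympy.Expr]:
    """New-infection terms, one per disease compartment (ordered as s_i)."""
    return _fv_terms(net, part, "F")


def calV(net: PetriNet, part: KMPartition, check: bool = True) -> list[sympy.Expr]:
    """Net-outflow terms; with ``check`` on, verifies the exact splitting
    x_i' = calF_i - calV_i against the rate equations and raises
    :class:`PartitionError` naming the stray term otherwise."""
    V = _fv_terms(net, part, "V")
    if check:
        F = _fv_terms(net, part, "F")
        ode = rate_equations(net).as_dict()
        for x, Fi, Vi in zip(part.s_i, F, V):
            stray = sympy.expand(ode[net.var(x)] - (Fi - Vi))
            if stray != 0:
                raise PartitionError(
                    f"rate equation of disease compartment {x} has terms outside "
                    f"calF - calV: {stray} (partition inconsistent with the net)"
                )
    return V


def verify_splitting(net: PetriNet, part: KMPartition) -> bool:
    """True iff x_i' = calF_i - calV_i holds symbolically for every disease
    compartment."""
    try:
        calV(net, part, check=True)
    except PartitionError:
        return False
    return True


def FV_matrices(
    net: PetriNet,
    part: KMPartition,
    dfe: DFE,
    F_terms: Optional[Sequence[sympy.Expr]] = None,
    V_terms: Optional[Sequence[sympy.Expr]] = None,
) -> tuple[sympy.Matrix, sympy.Matrix]:
    """Jacobians of calF and calV over the disease compartments, evaluated at
    the disease-free equilibrium."""
    xs = part.disease_variables(net)
    F_terms = list(F_terms) if F_terms is not None else calF(net, part)
    V_terms = list(V_terms) if V_terms is not None else calV(net, part)
    s = len(xs)
    F = sympy.zeros(s, s)
    V = sympy.zeros(s, s)
    for i in range(s):
        for j in range(s):
            F[i, j] = dfe.subs(sympy.diff(F_terms[i], xs[j]))
            V[i, j] = dfe.subs(sympy.diff(V_terms[i], xs[j]))
    return F, V


@dataclass
class StructureFlags:
    """Sign-structure verdicts for F and V under the positivity registry.
    ``None`` means the sign could not be decided symbolically."""

    F_nonnegative: Optional[bool]
    V_Z_pattern: Optional[bool]
    V_colsums_nonneg: Optional[bool]
    V_nonsingular: bool
    F_rank: int

    def all_pass(self) -> bool:
        return bool(
            self.F_nonnegative and self.V_Z_pattern and self.V_colsums_nonneg and self.V_nonsingular
        )


def structure_checks(
    F: sympy.Matrix, V: sympy.Matrix, registry: PositivityRegistry
) -> StructureFlags:
    """F entrywise nonnegative; V with the Z sign pattern (off-diagonal <= 0)
    and nonnegative column sums (the M-matrix certificate that follows from
    the positive-outflow condition); V nonsingular."""
    s = F.shape[0]
    f_ok: Optional[bool] = True
    z_ok: Optional[bool] = True
    cs_ok: Optional[bool] = True
    for i in range(s):
        for j in range(s):
            r = registry.is_nonnegative(F[i, j])
            f_ok = r if (f_ok is True and r is not True) else f_ok
            if i != j:
                r = registry.is_nonpositive(V[i, j])
                z_ok = r if (z_ok is True and r is not True) else z_ok
    for j in range(s):
        col = sum(V[i, j] for i in range(s))
        r = registry.is_nonnegative(col)
        cs_ok = r if (cs_ok is True and r is not True) else cs_ok
    det = sympy.cancel(sympy.together(V.det()))
    nonsingular = not symbolic_zero(det)
    return StructureFlags(f_ok, z_ok, cs_ok, nonsingular, F.rank())


def next_generation_matrix(F: sympy.Matrix, V: sympy.Matrix) -> sympy.Matrix:
    """K = F V^{-1}, simplified entrywise; row = compartment receiving the new
    infections, column = compartment of introduction."""
    det = sympy.cancel(sympy.together(V.det()))
    if symbolic_zero(det):
        raise SingularVError(
            "V is singular; the next-generation matrix requires a nonsingular "
            "outflow matrix"
        )
    K = F * V.inv()
    return K.applyfunc(lambda e: sympy.cancel(sympy.together(e)))


def _dominant_numeric(candidates: list[sympy.Expr], registry: PositivityRegistry,
                      seed: int = 11, tol: float = 1e-10) -> sympy.Expr:
    """Pick the spectral-radius eigenvalue by numeric sampling, preferring the
    positive real candidate on modulus ties (Perron root)."""
    rng = random.Random(seed)
    syms = sorted(
        {s for c in candidates for s in registry.transform(c).free_symbols},
        key=lambda s: s.name,
    )
    scores = [0.0] * len(candidates)
    positive_real = [True] * len(candidates)
    for _ in range(3):
        vals = {s: 10.0 ** rng.uniform(-1, 1) for s in syms}
        mags = []
        for idx, c in enumerate(candidates):
            z = complex(registry.transform(c).subs(vals).evalf())
            mags.append(abs(z))
            if not (abs(z.imag) <= tol * (1 + abs(z)) and z.real > -tol):
                positive_real[idx] = False
        for idx, mag in enumerate(mags):
            scores[idx] += mag
    best = max(scores)
    top = [i for i, sc in enumerate(scores) if sc >= best - tol * (1 + best)]
    for i in top:
        if positive_real[i]:
            return candidates[i]
    return candidates[top[0]]


def r0(K: sympy.Matrix, registry: Optional[PositivityRegistry] = None) -> sympy.Expr:
    """Spectral radius of the next-generation matrix.

    Rank-one K has a single nonzero eigenvalue equal to its trace; otherwise
    the characteristic polynomial is solved and the dominant root selected
    under the positivity assumptions (numeric sampling breaks ties).
    """
    K = K.applyfunc(lambda e: sympy.cancel(sympy.together(e)))
    if K.is_zero_matrix:
        return sympy.Integer(0)
    if K.rank() == 1:
        return sympy.cancel(sympy.together(K.trace()))
    eigs = [sympy.cancel(sympy.together(lam)) for lam, mult in K.eigenvals().items()]
    nonzero = [lam for lam in eigs if not symbolic_zero(lam)]
    if not nonzero:
        return sympy.Integer(0)
    if len(nonzero) == 1:
        return nonzero[0]
    if registry is None:
        registry = PositivityRegistry(
            {s.name: s for lam in nonzero for s in lam.free_symbols}, {}
        )
    return _dominant_numeric(nonzero, registry)


@dataclass
class NGMResult:
    """Everything the next-generation route computes, with diagnostics."""

    disease_compartments: tuple[str, ...]
    calF: list[sympy.Expr]
    calV: list[sympy.Expr]
    F: sympy.Matrix
    V: sympy.Matrix
    K: sympy.Matrix
    r0: sympy.Expr
    flags: StructureFlags
    dfe: DFE


def ngm_analysis(net: PetriNet, part: KMPartition, dfe: DFE) -> NGMResult:
    """Full pipeline: terms, matrices, structural flags, K, R0."""
    F_terms = calF(net, part)
    V_terms = calV(net, part)  # verifies the splitting
    F, V = FV_matrices(net, part, dfe, F_terms, V_terms)
    reg = net.registry()
    flags = structure_checks(F, V, reg)
    K = next_generation_matrix(F, V)
    rho = r0(K, reg)
    return NGMResult(tuple(part.s_i), F_terms, V_terms, F, V, K, rho, flags, dfe)


# ---------------------------------------------------------------------------
# numeric threshold verification


def integrate_rate_equations(
    net: PetriNet,
    params: Mapping[str, float],
    x0: Mapping[str, float],
    t_span: tuple[float, float],
    n_eval: int = 200,
):
    """Integrate the mass-action ODEs at a numeric parameter point.

    Returns the scipy solution object; raises RuntimeError on solver failure.
    """
    from scipy.integrate import solve_ivp

    ode = rate_equations(net)
    subs = {net.var(k): sympy.Float(v) for k, v in params.items()}
    rhs = [sympy.sympify(e).subs(subs) for e in ode.rhs]
    leftover = {s for e in rhs for s in e.free_symbols} - set(ode.variables)
    if leftover:
        raise ValueError(f"missing numeric values for {sorted(s.name for s in leftover)}")
    fn = sympy.lambdify(ode.variables, rhs, "numpy")
    y0 = [float(x0.get(v.name, 0.0)) for v in ode.variables]
    sol = solve_ivp(
        lambda t, y: np.asarray(fn(*y), dtype=float),
        t_span,
        y0,
        method="LSODA",
        t_eval=np.linspace(*t_span, n_eval),
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    sol.variable_names = [v.name for v in ode.variables]
    return sol


def threshold_check(
    net: PetriNet,
    part: KMPartition,
    params: Mapping[str, float],
    dfe_values: Mapping[str, float],
    perturbation: float = 1e-3,
    horizon: Optional[float] = None,
    stability_factor: float = 1e-2,
) -> dict:
    """Outbreak-threshold verdict by direct integration from a perturbed DFE.

    Disease coordinates are nudged by ``perturbation`` times the DFE scale;
    the trajectory is integrated over ``horizon`` (default 10 / |slowest
    F - V eigenvalue|).  Verdict ``stable`` if the final disease norm drops
    below ``stability_factor`` times the initial one, ``unstable`` if it
    grows.  The verdict is cross-checked against the eigenvalue criterion on
    F - V and the numeric R0.
    """
    assignment = {net.var(x): sympy.Integer(0) for x in part.s_i}
    assignment.update({net.var(k): sympy.Float(v) for k, v in dfe_values.items()})
    dfe = DFE(assignment, mode="user-supplied")
    F, V = FV_matrices(net, part, dfe)
    subs = {net.var(k): sympy.Float(v) for k, v in params.items()}
    Fn = np.array(F.subs(subs).evalf(), dtype=float)
    Vn = np.array(V.subs(subs).evalf(), dtype=float)
    r0_num = float(max(abs(np.linalg.eigvals(Fn @ np.linalg.inv(Vn)))))
    fv_eigs = np.linalg.eigvals(Fn - Vn)
    eig_stable = bool((fv_eigs.real < 0).all())
    if horizon is None:
        slowest = min(abs(fv_eigs.real))
        horizon = 10.0 / max(slowest, 1e-3)
    scale = max(max(dfe_values.values()), 1.0)
    x0 = dict(dfe_values)
    for x in part.s_i:
        x0[x] = x0.get(x, 0.0) + perturbation * scale
    sol = integrate_rate_equations(net, params, x0, (0.0, float(horizon)))
    names = sol.variable_names
    didx = [names.index(x) for x in part.s_i]
    disease0 = np.linalg.norm(sol.y[didx, 0])
    disease1 = np.linalg.norm(sol.y[didx, -1])
    if disease1 < stability_factor * disease0:
        verdict = "stable"
    elif disease1 > disease0:
        verdict = "unstable"
    else:
        verdict = "inconclusive"
    return {
        "verdict": verdict,
        "r0": r0_num,
        "eigenvalue_criterion_stable": eig_stable,
        "consistent": bool(
            (verdict == "stable") == (r0_num < 1.0) and eig_stable == (r0_num < 1.0)
        )
        if verdict != "inconclusive"
        else False,
        "initial_disease_norm": float(disease0),
        "final_disease_norm": float(disease1),
        "horizon": float(horizon),
    }
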