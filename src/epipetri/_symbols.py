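"""Shared symbolic machinery: expression parsing, positivity reasoning, equality.

Rate parameters are sympy symbols created with ``positive=True`` (every rate
constant is a positive quantity); compartment variables are ``nonnegative``
so that equilibria on the boundary of the orthant — the disease-free
equilibrium in particular — remain admissible.  Parameters declared with kind
``probability`` additionally live in (0, 1); sign queries encode this by
substituting p -> 1/(1+u) with u a fresh positive symbol, which is exact and
keeps sympy's assumption engine decidable on the expressions that arise here.
"""

from __future__ import annotations

from typing import Mapping, Optional

import sympy
from sympy.parsing.sympy_parser import (
    parse_expr as _sympy_parse,
    standard_transformations,
    convert_xor,
)

__all__ = [
    "make_symbol",
    "parse_expression",
    "ExpressionError",
    "PositivityRegistry",
    "symbolic_equal",
    "symbolic_zero",
]

_PARSE_TRANSFORMATIONS = standard_transformations + (convert_xor,)

# Minimal parser namespace: numbers and symbol construction only.  The sympy
# default would capture identifiers like ``beta``, ``gamma``, ``E`` or ``I``
# as special functions/constants instead of model symbols.
_PARSE_GLOBALS = {
    "Integer": sympy.Integer,
    "Float": sympy.Float,
    "Rational": sympy.Rational,
    "Symbol": sympy.Symbol,
    "Function": sympy.Function,
}

#: parameter kinds understood by the registry
PARAM_KINDS = ("rate", "probability", "quantity")


class ExpressionError(ValueError):
    """Raised when an expression string violates the declared grammar
    (unknown identifiers, non-arithmetic constructs)."""


def make_symbol(name: str) -> sympy.Symbol:
    """A positive real symbol; every parameter goes through here so
    assumptions are consistent across the package."""
    return sympy.Symbol(name, positive=True)


def make_var(name: str) -> sympy.Symbol:
    """A nonnegative real symbol for compartment variables: populations live
    on the closed positive orthant, and equilibria (the DFE in particular)
    sit on its boundary."""
    return sympy.Symbol(name, nonnegative=True)


def parse_expression(text: str | int | float, symbols: Mapping[str, sympy.Symbol]) -> sympy.Expr:
    """Parse an expression string under the declared grammar.

    Grammar: identifiers, ``+ - * / ^``, integer and rational literals.
    Every identifier must be a key of *symbols*; anything else is an error so
    that typos in model files cannot silently introduce new parameters.
    """
    if isinstance(text, (int, float)):
        return sympy.nsimplify(text, rational=True)
    try:
        expr = _sympy_parse(
            str(text),
            local_dict=dict(symbols),
            global_dict=dict(_PARSE_GLOBALS),
            transformations=_PARSE_TRANSFORMATIONS,
            evaluate=True,
        )
    except Exception as exc:  # sympy raises a zoo of exception types
        raise ExpressionError(f"cannot parse expression {text!r}: {exc}") from exc
    stray = expr.free_symbols - set(symbols.values())
    if stray:
        names = ", ".join(sorted(s.name for s in stray))
        raise ExpressionError(f"undeclared symbol(s) {names} in expression {text!r}")
    if expr.has(sympy.Function):
        raise ExpressionError(f"functions are not part of the expression grammar: {text!r}")
    return expr


class PositivityRegistry:
    """Positivity / range assumptions for the symbols of a net.

    Parameters
    ----------
    parameters:
        mapping name -> kind, kind in {"rate", "probability", "quantity"}.
        Rates and quantities are positive reals; probabilities lie in (0, 1).
    constraints:
        mapping name -> expression string over other parameters, used purely
        for sign analysis (e.g. ``alpha = delta + alpha_excess`` encodes the
        ordering alpha > delta).  The right-hand side may introduce fresh
        auxiliary symbols, which are taken positive.
    """

    def __init__(
        self,
        symbols: Mapping[str, sympy.Symbol],
        parameters: Mapping[str, str],
        constraints: Optional[Mapping[str, str]] = None,
    ) -> None:
        self.symbols = dict(symbols)
        self.parameters = dict(parameters)
        self.constraints = dict(constraints or {})
        self._subs = self._build_substitutions()

    def _build_substitutions(self) -> dict[sympy.Symbol, sympy.Expr]:
        subs: dict[sympy.Symbol, sympy.Expr] = {}
        aux_ns = dict(self.symbols)
        # ordering constraints first: alpha -> delta + alpha_excess
        for name, rhs in self.constraints.items():
            sym = self.symbols.get(name)
            if sym is None:
                raise ExpressionError(f"constraint for undeclared parameter {name!r}")
            rhs_expr = _sympy_parse(
                str(rhs), local_dict=aux_ns, global_dict=dict(_PARSE_GLOBALS),
                transformations=_PARSE_TRANSFORMATIONS,
            )
            fresh = {
                s
                for s in rhs_expr.free_symbols
                if s.name not in self.symbols
            }
            for s in fresh:
                pos = make_symbol(s.name)
                rhs_expr = rhs_expr.subs(s, pos)
                aux_ns[s.name] = pos
            subs[sym] = rhs_expr
        # probabilities: p -> 1/(1+u), u > 0  <=>  p in (0,1)
        for name, kind in self.parameters.items():
            if kind == "probability":
                sym = self.symbols[name]
                u = make_symbol(f"_{name}_aux")
                subs[sym] = 1 / (1 + u)
        return subs

    def transform(self, expr: sympy.Expr) -> sympy.Expr:
        """Rewrite *expr* so that every remaining free symbol is positive and
        unconstrained; sign questions become decidable assumption queries."""
        return sympy.together(sympy.expand(sympy.sympify(expr).subs(self._subs)))

    # -- sign queries ------------------------------------------------------
    def _query(self, expr: sympy.Expr, attr: str) -> Optional[bool]:
        e = self.transform(expr)
        for candidate in (e, sympy.cancel(e), sympy.factor(e), sympy.simplify(e)):
            res = getattr(candidate, attr)
            if res is not None:
                return res
        return None

    def is_nonnegative(self, expr) -> Optional[bool]:
        return self._query(expr, "is_nonnegative")

    def is_nonpositive(self, expr) -> Optional[bool]:
        return self._query(expr, "is_nonpositive")

    def is_zero(self, expr) -> Optional[bool]:
        return self._query(expr, "is_zero")

    # -- numeric sampling --------------------------------------------------
    def sample_point(self, expr: sympy.Expr, rng) -> dict[sympy.Symbol, float]:
        """A random positive assignment for the free symbols of the
        *transformed* expression (log-uniform over [1e-2, 1e1])."""
        e = self.transform(expr)
        return {
            s: float(10.0 ** rng.uniform(-2, 1))
            for s in sorted(e.free_symbols, key=lambda s: s.name)
        }

    def numeric_samples(self, expr: sympy.Expr, rng, n: int = 8) -> list[float]:
        e = self.transform(expr)
        syms = sorted(e.free_symbols, key=lambda s: s.name)
        fn = sympy.lambdify(syms, e, "numpy") if syms else None
        out = []
        for _ in range(n):
            vals = [10.0 ** rng.uniform(-2, 1) for _ in syms]
            out.append(float(fn(*vals)) if fn else float(e))
        return out


def symbolic_zero(expr: sympy.Expr) -> bool:
    """Robust zero test: expand, cancel over a common denominator, then
    simplify with forced power collection (needed for square-root forms)."""
    e = sympy.expand(sympy.sympify(expr))
    if e == 0:
        return True
    e = sympy.cancel(sympy.together(e))
    if e == 0:
        return True
    e = sympy.simplify(sympy.powsimp(e, force=True))
    return e == 0


def symbolic_equal(a, b) -> bool:
    """Equality by subtract-and-simplify to zero."""
    return symbolic_zero(sympy.sympify(a) - sympy.sympify(b))
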