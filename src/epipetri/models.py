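"""Model library: the classic compartmental epidemic models as packaged nets
with their KM partitions and golden symbolic data, plus a seeded random
polynomial-ODE generator for round-trip property testing.

Each fixture file carries the net, the declared partition, the DFE
convention, and ``golden`` blocks (ODE right-hand sides and, where the model
has them, F, V, K and R0) stored as parseable expression strings so tests
can diff symbolic output against the literature values.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import sympy

from ._symbols import make_symbol, make_var
from .core import ODESystem, PetriNet
from .kmmodules import DFE, KMPartition, find_dfe
from .netio import parse_net

__all__ = ["Fixture", "FIXTURE_NAMES", "fixture", "random_ode"]

#: every packaged model, in presentation order
FIXTURE_NAMES = (
    "water",
    "malthus",
    "sir",
    "sis",
    "sirs",
    "seir",
    "seair",
    "scir",
    "siwr",
    "malaria",
    "vaccination1",
    "vaccination2",
    "quarantine",
    "saika_bora_seir",
    "table6_seir_variant",
)


@dataclass
class Fixture:
    """A packaged model with its golden symbolic data."""

    name: str
    net: PetriNet
    partition: Optional[KMPartition]
    dfe_spec: dict = field(default_factory=dict)
    golden_ode: Optional[dict[str, sympy.Expr]] = None
    golden_F: Optional[sympy.Matrix] = None
    golden_V: Optional[sympy.Matrix] = None
    golden_K: Optional[sympy.Matrix] = None
    golden_R0: Optional[sympy.Expr] = None
    flags: dict = field(default_factory=dict)

    def dfe(self) -> DFE:
        """The fixture's disease-free equilibrium under its declared mode."""
        if self.partition is None:
            raise ValueError(f"fixture {self.name!r} has no KM partition")
        spec = self.dfe_spec or {}
        return find_dfe(
            self.net,
            self.partition,
            mode=spec.get("mode", "keep-symbolic"),
            assignment=spec.get("assignment"),
            substitutions=spec.get("substitutions"),
        )


def _parse_matrix(rows, net: PetriNet) -> sympy.Matrix:
    return sympy.Matrix([[net.parse(e) for e in row] for row in rows])


def fixture(name: str) -> Fixture:
    """Load a packaged model by name; raises KeyError for unknown names."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    text = resources.files("epipetri").joinpath(f"fixtures/{name}.json").read_text()
    net, part, extras = parse_net(text)
    golden = extras.get("golden", {})
    fx = Fixture(name, net, part, extras.get("dfe", {}))
    if "ode" in golden:
        fx.golden_ode = {v: net.parse(e) for v, e in golden["ode"].items()}
    for key in ("F", "V", "K"):
        if key in golden:
            setattr(fx, f"golden_{key}", _parse_matrix(golden[key], net))
    if "R0" in golden:
        fx.golden_R0 = net.parse(golden["R0"])
    fx.flags = golden.get("flags", {})
    return fx


def random_ode(
    k: int, max_degree: int = 3, n_terms: int = 6, seed: int = 0
) -> ODESystem:
    """A reproducible random polynomial system that is representable by a net.

    Each term is ``f * a_t * x^m`` with a fresh positive parameter ``a_t``,
    integer factor ``f`` drawn from +-{1,2,3} constrained to ``f + m_i >= 0``
    (so the induced transition has nonnegative output counts), and exponents
    summing to at most ``max_degree``.
    """
    if k < 1:
        raise ValueError("need at least one variable")
    rng = random.Random(seed)
    xs = [make_var(f"x{i + 1}") for i in range(k)]
    rhs = [sympy.Integer(0)] * k
    params: dict[str, str] = {}
    for t in range(n_terms):
        i = rng.randrange(k)
        degree = rng.randint(0, max_degree)
        exps = [0] * k
        for _ in range(degree):
            exps[rng.randrange(k)] += 1
        candidates = [v for v in (-3, -2, -1, 1, 2, 3) if v >= -exps[i]]
        f = rng.choice(candidates)
        a = make_symbol(f"a{t + 1}")
        params[a.name] = "rate"
        monomial = sympy.Mul(*[x ** e for x, e in zip(xs, exps) if e])
        rhs[i] = sympy.expand(rhs[i] + f * a * monomial)
    return ODESystem(xs, rhs, params)
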