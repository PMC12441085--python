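"""Graph-theoretic R0: life-cycle graph and the fertility-loop formula.

The projection matrix A = F + (I - V) over the disease compartments defines a
weighted digraph: an edge j -> i for every nonzero a_ij, tagged *fertility*
when it comes from F (new infections) and *survival* when it comes from
I - V (staying alive / progressing).  When the next-generation matrix has a
single non-zero eigenvalue, R0 equals the sum over fertility loops (simple
cycles containing at least one fertility edge) of

    L * det(V without the loop's rows/columns) / det(V),

with L the product of the loop's edge weights.  This is the algebraic
counterpart of the graphical Gaussian-elimination reduction of life-cycle
graphs used in structured-population models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import sympy

from ._symbols import PositivityRegistry, symbolic_zero

__all__ = [
    "LifeCycleGraph",
    "Loop",
    "NotSingleEigenvalue",
    "life_cycle_graph",
    "fertility_loops",
    "r0_fertility",
]


class NotSingleEigenvalue(ValueError):
    """The fertility-loop formula needs F V^{-1} with exactly one non-zero
    eigenvalue (e.g. a vector-host model with a square-root R0 is excluded)."""


@dataclass(frozen=True)
class Edge:
    src: int
    dst: int
    weight: sympy.Expr
    tag: str  # "fertility" | "survival"


@dataclass
class LifeCycleGraph:
    """Vertices 0..s-1 (disease compartments in partition order) and tagged
    weighted edges of A = F + (I - V)."""

    s: int
    edges: list[Edge]

    def out_edges(self, v: int) -> list[Edge]:
        return [e for e in self.edges if e.src == v]


@dataclass(frozen=True)
class Loop:
    """A simple cycle with a tag choice per step; ``states`` is the set of
    traversed vertices, ``weight`` the product of chosen edge weights."""

    edges: tuple[Edge, ...]

    @property
    def states(self) -> frozenset[int]:
        return frozenset(e.src for e in self.edges)

    @property
    def weight(self) -> sympy.Expr:
        return sympy.Mul(*[e.weight for e in self.edges])

    @property
    def is_fertility(self) -> bool:
        return any(e.tag == "fertility" for e in self.edges)


def life_cycle_graph(F: sympy.Matrix, V: sympy.Matrix) -> LifeCycleGraph:
    """Build the tagged digraph; symbolic zeros are detected after
    simplification, and an (i, j) slot with both a fertility and a survival
    contribution yields two parallel edges."""
    if F.shape != V.shape or F.shape[0] != F.shape[1]:
        raise ValueError("F and V must be square matrices of equal size")
    s = F.shape[0]
    S = sympy.eye(s) - V
    edges: list[Edge] = []
    for i in range(s):
        for j in range(s):
            f = sympy.cancel(sympy.together(F[i, j]))
            if not symbolic_zero(f):
                edges.append(Edge(j, i, f, "fertility"))
            g = sympy.cancel(sympy.together(S[i, j]))
            if not symbolic_zero(g):
                edges.append(Edge(j, i, g, "survival"))
    return LifeCycleGraph(s, edges)


def _simple_vertex_cycles(g: LifeCycleGraph) -> list[tuple[int, ...]]:
    """Simple cycles as canonical vertex tuples (rotated to the smallest
    vertex), via the elementary-circuits algorithm on the collapsed digraph."""
    dg = nx.DiGraph()
    dg.add_nodes_from(range(g.s))
    dg.add_edges_from({(e.src, e.dst) for e in g.edges})
    cycles = []
    for cyc in nx.simple_cycles(dg):
        k = cyc.index(min(cyc))
        cycles.append(tuple(cyc[k:] + cyc[:k]))
    return sorted(set(cycles))


def fertility_loops(g: LifeCycleGraph) -> list[Loop]:
    """All simple cycles with >= 1 fertility edge, expanded over the parallel
    fertility/survival edge choices at every step."""
    by_pair: dict[tuple[int, int], list[Edge]] = {}
    for e in g.edges:
        by_pair.setdefault((e.src, e.dst), []).append(e)
    loops: list[Loop] = []
    for cyc in _simple_vertex_cycles(g):
        steps = [
            by_pair[(cyc[t], cyc[(t + 1) % len(cyc)])] for t in range(len(cyc))
        ]
        for choice in itertools.product(*steps):
            loop = Loop(tuple(choice))
            if loop.is_fertility:
                loops.append(loop)
    return loops


def _nonzero_eigenvalues(K: sympy.Matrix) -> list[sympy.Expr]:
    eigs = []
    for lam, mult in K.eigenvals().items():
        lam = sympy.cancel(sympy.together(lam))
        if not symbolic_zero(lam):
            eigs.append(lam)
    return eigs


def r0_fertility(F: sympy.Matrix, V: sympy.Matrix) -> sympy.Expr:
    """R0 by summing fertility loops of the life-cycle graph.

    Requires V nonsingular and F V^{-1} with a single non-zero eigenvalue
    (raises :class:`NotSingleEigenvalue` otherwise, e.g. for vector-host
    transmission where R0 is a geometric mean of two half-cycles).
    """
    det_V = sympy.cancel(sympy.together(V.det()))
    if symbolic_zero(det_V):
        raise ValueError("V is singular; the loop formula divides by det(V)")
    K = (F * V.inv()).applyfunc(lambda e: sympy.cancel(sympy.together(e)))
    nonzero = _nonzero_eigenvalues(K)
    if len(nonzero) != 1:
        raise NotSingleEigenvalue(
            f"F V^(-1) has {len(nonzero)} non-zero eigenvalues; the "
            "fertility-loop sum applies only to the single-eigenvalue case"
        )
    g = life_cycle_graph(F, V)
    total = sympy.Integer(0)
    s = F.shape[0]
    for loop in fertility_loops(g):
        keep = [i for i in range(s) if i not in loop.states]
        minor = V[keep, keep].det() if keep else sympy.Integer(1)
        total += loop.weight * minor / det_V
    return sympy.cancel(sympy.together(total))
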