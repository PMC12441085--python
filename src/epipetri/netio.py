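"""Native JSON schema for nets (with optional KM partition and DFE block),
plus DOT export.

Schema (version 1)::

    {
      "schema": 1,
      "name": "sir",
      "compartments": ["S", "I", "R"],            # or {"name": ..., "display": ...}
      "parameters": {"beta": "rate", "p": "probability", "N": "quantity"},
      "constraints": {"alpha": "delta + alpha_excess"},   # sign-analysis only
      "transitions": [{"name": "infect", "rate": "beta"}],
      "arcs": [{"source": "S", "target": "infect",
                "multiplicity": 1, "weight": "1"}],
      "km_partition": {"susceptible": {"compartments": [...], "transitions": [...]},
                       "infection_process": {...}, "infection": {...}},
      "dfe": {"mode": "keep-symbolic" | "symbolic-solve" | "user-supplied",
              "assignment": {"S": "q*N"}, "substitutions": {"N": "Lambda/mu"}}
    }

Expression strings use identifiers, ``+ - * / ^``, integer and rational
literals.  Parsing validates every identifier against the declared
compartment/parameter namespaces and reports located errors.
"""

from __future__ import annotations

import json
from typing import Any, Optional

import sympy

from ._symbols import ExpressionError
from .core import Arc, Compartment, PetriNet, Transition, validate
from .kmmodules import KMPartition

__all__ = ["ParseError", "parse_net", "serialize_net", "to_dot"]

SCHEMA_VERSION = 1


class ParseError(ValueError):
    """Schema violation with a location hint."""


def _require(cond: bool, where: str, msg: str) -> None:
    if not cond:
        raise ParseError(f"{where}: {msg}")


def parse_net(doc: str | dict) -> tuple[PetriNet, Optional[KMPartition], dict]:
    """Parse a net document (JSON text or an already-loaded dict).

    Returns ``(net, partition_or_None, extras)`` where *extras* carries the
    optional ``dfe`` and ``golden`` blocks untouched.
    """
    if isinstance(doc, str):
        try:
            doc = json.loads(doc)
        except json.JSONDecodeError as exc:
            raise ParseError(f"not valid JSON: {exc}") from exc
    _require(isinstance(doc, dict), "document", "top level must be an object")
    _require(doc.get("schema", SCHEMA_VERSION) == SCHEMA_VERSION, "schema",
             f"unsupported schema version {doc.get('schema')!r}")

    comps = []
    for idx, c in enumerate(doc.get("compartments", [])):
        if isinstance(c, str):
            comps.append(c)
        elif isinstance(c, dict) and "name" in c:
            comps.append(Compartment(c["name"], c.get("display")))
        else:
            raise ParseError(f"compartments[{idx}]: expected a name or an object with 'name'")

    parameters = doc.get("parameters", {})
    _require(isinstance(parameters, dict), "parameters", "must map name -> kind")
    constraints = doc.get("constraints", {})

    transitions = []
    for idx, t in enumerate(doc.get("transitions", [])):
        _require(isinstance(t, dict) and "name" in t and "rate" in t,
                 f"transitions[{idx}]", "needs 'name' and 'rate'")
        transitions.append((t["name"], t["rate"]))

    arcs = []
    for idx, a in enumerate(doc.get("arcs", [])):
        _require(isinstance(a, dict) and "source" in a and "target" in a,
                 f"arcs[{idx}]", "needs 'source' and 'target'")
        arcs.append((a["source"], a["target"], a.get("multiplicity", 1), a.get("weight", "1")))

    try:
        net = PetriNet.build(
            comps, transitions, arcs, parameters, constraints, name=doc.get("name", "")
        )
    except ExpressionError as exc:
        raise ParseError(str(exc)) from exc

    problems = [d for d in validate(net) if d.severity == "error"]
    if problems:
        raise ParseError("; ".join(d.message for d in problems))

    part = None
    if "km_partition" in doc:
        blocks = doc["km_partition"]
        def grab(key: str, field: str) -> tuple[str, ...]:
            return tuple(blocks.get(key, {}).get(field, []))
        part = KMPartition(
            s_s=grab("susceptible", "compartments"),
            s_ip=grab("infection_process", "compartments"),
            s_i=grab("infection", "compartments"),
            t_s=grab("susceptible", "transitions"),
            t_ip=grab("infection_process", "transitions"),
            t_i=grab("infection", "transitions"),
        )
        part.validate_against(net)

    extras = {k: doc[k] for k in ("dfe", "golden") if k in doc}
    return net, part, extras


def serialize_net(
    net: PetriNet, part: Optional[KMPartition] = None, extras: Optional[dict] = None
) -> dict:
    """Lossless inverse of :func:`parse_net` (up to key order)."""
    doc: dict[str, Any] = {
        "schema": SCHEMA_VERSION,
        "name": net.name,
        "compartments": [
            c.name if c.display is None else {"name": c.name, "display": c.display}
            for c in net.compartments
        ],
        "parameters": dict(net.parameters),
        "transitions": [{"name": t.name, "rate": str(t.rate)} for t in net.transitions],
        "arcs": [
            {
                "source": a.source,
                "target": a.target,
                "multiplicity": a.multiplicity,
                **({"weight": str(a.weight)} if a.weight != 1 else {}),
            }
            for a in net.arcs
        ],
    }
    if net.constraints:
        doc["constraints"] = dict(net.constraints)
    if part is not None:
        doc["km_partition"] = {
            "susceptible": {"compartments": list(part.s_s), "transitions": list(part.t_s)},
            "infection_process": {"compartments": list(part.s_ip), "transitions": list(part.t_ip)},
            "infection": {"compartments": list(part.s_i), "transitions": list(part.t_i)},
        }
    if extras:
        doc.update(extras)
    return doc


_MODULE_OF = ("susceptible", "infection_process", "infection")


def to_dot(net: PetriNet, part: Optional[KMPartition] = None) -> str:
    """DOT digraph: circles for compartments, squares for transitions,
    multiplicities as edge labels, KM modules as cluster subgraphs."""
    lines = ["digraph petri {", "  rankdir=LR;"]

    def comp_node(name: str) -> str:
        disp = next((c.display for c in net.compartments if c.name == name), None)
        label = disp or name
        return f'  "{name}" [shape=circle, style=filled, fillcolor=lightyellow, label="{label}"];'

    def trans_node(name: str) -> str:
        rate = net.transition(name).rate
        return (
            f'  "{name}" [shape=square, style=filled, fillcolor=lightblue, '
            f'label="{rate}"];'
        )

    in_cluster: set[str] = set()
    if part is not None:
        groups = {
            "susceptible": (part.s_s, part.t_s),
            "infection_process": (part.s_ip, part.t_ip),
            "infection": (part.s_i, part.t_i),
        }
        for key in _MODULE_OF:
            cs, ts = groups[key]
            if not cs and not ts:
                continue
            lines.append(f"  subgraph cluster_{key} {{")
            lines.append(f'    label="{key}";')
            for c in cs:
                lines.append("  " + comp_node(c))
                in_cluster.add(c)
            for t in ts:
                lines.append("  " + trans_node(t))
                in_cluster.add(t)
            lines.append("  }")
    for c in net.compartments:
        if c.name not in in_cluster:
            lines.append(comp_node(c.name))
    for t in net.transitions:
        if t.name not in in_cluster:
            lines.append(trans_node(t.name))
    for a in net.arcs:
        attrs = []
        if a.multiplicity != 1:
            attrs.append(f'label="{a.multiplicity}"')
        if a.weight != 1:
            attrs.append(f'taillabel="{a.weight}"')
        suffix = f" [{', '.join(attrs)}]" if attrs else ""
        lines.append(f'  "{a.source}" -> "{a.target}"{suffix};')
    lines.append("}")
    return "\n".join(lines)
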