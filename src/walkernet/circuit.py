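"""Grid-embedded DSD (DNA strand displacement) circuit graphs.

A walker circuit is a planar undirected graph of *anchorages* tethered to
an origami lattice.  Each anchorage occupies an integer grid position and
has one of five roles: the unique INIT anchorage where the walker starts,
NORM anchorages forming linear tracks, FORK/JOIN junctions, and FINAL
anchorages which report a truth value.  Non-final anchorages carry either
a literal over the circuit's Boolean input variables (the anchorage is
*blocked* when the literal evaluates to false) or the empty label ε, which
makes the anchorage unblockable.

This module provides the validated in-memory model, a YAML file format
with round-trip I/O, and Boolean evaluation of labels and of the circuit's
target function.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "GridPoint",
    "VertexType",
    "Label",
    "EPSILON",
    "Vertex",
    "Circuit",
    "CircuitValidationError",
    "BooleanExpr",
    "load_circuit",
    "save_circuit",
    "evaluate_label",
    "blocked_vertices",
    "evaluate_function",
]

Assignment = Mapping[str, bool]


class CircuitValidationError(ValueError):
    """A circuit file or object violates a structural invariant."""


@dataclass(frozen=True, order=True)
class GridPoint:
    """1-based grid coordinates: ``x`` is the row, ``y`` the column."""

    x: int
    y: int

    def __post_init__(self) -> None:
        if self.x < 1 or self.y < 1:
            raise CircuitValidationError(
                f"grid coordinates are 1-based, got ({self.x}, {self.y})"
            )


class VertexType:
    INIT = "INIT"
    NORM = "NORM"
    FORK = "FORK"
    JOIN = "JOIN"
    FINAL = "FINAL"

    ALL = (INIT, NORM, FORK, JOIN, FINAL)


@dataclass(frozen=True)
class Label:
    """A literal over the input variables, or the empty label ε.

    ``variable is None`` encodes ε; otherwise ``negated`` selects between
    ``v`` and ``!v``.
    """

    variable: str | None = None
    negated: bool = False

    @property
    def is_epsilon(self) -> bool:
        return self.variable is None

    @staticmethod
    def parse(text: str) -> "Label":
        text = text.strip()
        if text in ("eps", "ε", ""):
            return EPSILON
        if text.startswith("!"):
            return Label(text[1:].strip(), True)
        return Label(text, False)

    def __str__(self) -> str:
        if self.is_epsilon:
            return "eps"
        return ("!" if self.negated else "") + self.variable


EPSILON = Label()


@dataclass(frozen=True)
class Vertex:
    id: str
    position: GridPoint
    vtype: str
    label: Label = EPSILON
    output: bool | None = None  # present iff vtype == FINAL


# --------------------------------------------------------------------------
# Boolean expressions: variables, !, &, |, parentheses.  Precedence ! > & > |.


class BooleanExpr:
    """A parsed Boolean expression over named variables."""

    _TOKEN = re.compile(r"\s*([A-Za-z_]\w*|[!&|()])")

    def __init__(self, text: str):
        self.text = text
        self._ast = self._parse(text)
        self.variables = frozenset(self._collect(self._ast))

    def evaluate(self, assignment: Assignment) -> bool:
        missing = self.variables - set(assignment)
        if missing:
            raise KeyError(f"assignment missing variables: {sorted(missing)}")
        return self._eval(self._ast, assignment)

    # -- recursive descent ------------------------------------------------

    @classmethod
    def _tokenise(cls, text: str) -> list[str]:
        tokens, pos = [], 0
        while pos < len(text):
            m = cls._TOKEN.match(text, pos)
            if not m:
                if text[pos:].strip():
                    raise ValueError(f"bad token in expression at: {text[pos:]!r}")
                break
            tokens.append(m.group(1))
            pos = m.end()
        return tokens

    @classmethod
    def _parse(cls, text: str):
        tokens = cls._tokenise(text)
        if not tokens:
            raise ValueError("empty Boolean expression")
        ast, rest = cls._parse_or(tokens)
        if rest:
            raise ValueError(f"trailing tokens in expression: {rest}")
        return ast

    @classmethod
    def _parse_or(cls, toks):
        left, toks = cls._parse_and(toks)
        while toks and toks[0] == "|":
            right, toks = cls._parse_and(toks[1:])
            left = ("or", left, right)
        return left, toks

    @classmethod
    def _parse_and(cls, toks):
        left, toks = cls._parse_not(toks)
        while toks and toks[0] == "&":
            right, toks = cls._parse_not(toks[1:])
            left = ("and", left, right)
        return left, toks

    @classmethod
    def _parse_not(cls, toks):
        if not toks:
            raise ValueError("unexpected end of expression")
        if toks[0] == "!":
            inner, toks = cls._parse_not(toks[1:])
            return ("not", inner), toks
        if toks[0] == "(":
            inner, toks = cls._parse_or(toks[1:])
            if not toks or toks[0] != ")":
                raise ValueError("unbalanced parentheses")
            return inner, toks[1:]
        if toks[0] in ("&", "|", ")"):
            raise ValueError(f"unexpected token {toks[0]!r}")
        return ("var", toks[0]), toks[1:]

    @classmethod
    def _collect(cls, node) -> Iterable[str]:
        kind = node[0]
        if kind == "var":
            yield node[1]
        elif kind == "not":
            yield from cls._collect(node[1])
        else:
            yield from cls._collect(node[1])
            yield from cls._collect(node[2])

    @classmethod
    def _eval(cls, node, a: Assignment) -> bool:
        kind = node[0]
        if kind == "var":
            return bool(a[node[1]])
        if kind == "not":
            return not cls._eval(node[1], a)
        if kind == "and":
            return cls._eval(node[1], a) and cls._eval(node[2], a)
        return cls._eval(node[1], a) or cls._eval(node[2], a)


# --------------------------------------------------------------------------


@dataclass
class Circuit:
    """A validated DSD graph with its target Boolean function.

    ``declared_edges`` (the intended edge set) is optional: when absent the
    intended adjacency is taken to be the short-distance neighbourhood of
    the embedding; when present it is used for degree validation only.
    """

    vertices: dict[str, Vertex]
    inputs: tuple[str, ...]
    function: BooleanExpr
    declared_edges: frozenset[frozenset[str]] | None = None

    _by_position: dict[GridPoint, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- convenience accessors -------------------------------------------

    @property
    def init_vertex(self) -> Vertex:
        return next(v for v in self.vertices.values() if v.vtype == VertexType.INIT)

    @property
    def final_vertices(self) -> list[Vertex]:
        return [v for v in self.vertices.values() if v.vtype == VertexType.FINAL]

    def sorted_vertices(self) -> list[Vertex]:
        """Vertices in lexicographic (x, y) order — the canonical order used
        for deterministic unfolding and indexing."""
        return sorted(self.vertices.values(), key=lambda v: (v.position, v.id))

    def assignments(self) -> list[dict[str, bool]]:
        """All 2^|In| input assignments, in binary counting order."""
        out = []
        n = len(self.inputs)
        for bits in range(1 << n):
            out.append(
                {v: bool((bits >> (n - 1 - i)) & 1) for i, v in enumerate(self.inputs)}
            )
        return out

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        inits = [v for v in self.vertices.values() if v.vtype == VertexType.INIT]
        if len(inits) != 1:
            raise CircuitValidationError(
                f"exactly one INIT vertex required, found {len(inits)}: "
                f"{[v.id for v in inits]} (multiple INIT)" if inits else
                "exactly one INIT vertex required, found none"
            )
        if not self.final_vertices:
            raise CircuitValidationError("at least one FINAL vertex required")
        if not inits[0].label.is_epsilon:
            raise CircuitValidationError(
                f"INIT vertex {inits[0].id!r} must be labelled eps"
            )
        seen: dict[GridPoint, str] = {}
        for v in self.vertices.values():
            if v.vtype not in VertexType.ALL:
                raise CircuitValidationError(f"vertex {v.id!r}: bad type {v.vtype!r}")
            if v.position in seen:
                raise CircuitValidationError(
                    f"vertices {seen[v.position]!r} and {v.id!r} share position "
                    f"({v.position.x}, {v.position.y})"
                )
            seen[v.position] = v.id
            if v.vtype == VertexType.FINAL:
                if v.output is None:
                    raise CircuitValidationError(
                        f"FINAL vertex {v.id!r} must declare an output truth value"
                    )
                if not v.label.is_epsilon:
                    raise CircuitValidationError(
                        f"FINAL vertex {v.id!r} must not carry a label"
                    )
            else:
                if v.output is not None:
                    raise CircuitValidationError(
                        f"non-FINAL vertex {v.id!r} must not declare an output"
                    )
            if not v.label.is_epsilon and v.label.variable not in self.inputs:
                raise CircuitValidationError(
                    f"vertex {v.id!r}: label variable {v.label.variable!r} "
                    f"not among inputs {self.inputs}"
                )
        object.__setattr__(self, "_by_position", seen)
        extra = self.function.variables - set(self.inputs)
        if extra:
            raise CircuitValidationError(
                f"function references variables outside the input set: {sorted(extra)}"
            )
        if self.declared_edges is not None:
            self._validate_degrees()

    def _validate_degrees(self) -> None:
        expected = {
            VertexType.INIT: 1,
            VertexType.FINAL: 1,
            VertexType.NORM: 2,
            VertexType.FORK: 3,
            VertexType.JOIN: 3,
        }
        degree: dict[str, int] = {vid: 0 for vid in self.vertices}
        for edge in self.declared_edges:
            pair = sorted(edge)
            if len(pair) != 2:
                raise CircuitValidationError(f"malformed edge {pair}")
            for vid in pair:
                if vid not in self.vertices:
                    raise CircuitValidationError(f"edge references unknown vertex {vid!r}")
                degree[vid] += 1
        for vid, deg in degree.items():
            want = expected[self.vertices[vid].vtype]
            if deg != want:
                raise CircuitValidationError(
                    f"vertex {vid!r} ({self.vertices[vid].vtype}) has declared "
                    f"degree {deg}, expected {want}"
                )

    def structurally_equal(self, other: "Circuit") -> bool:
        return (
            self.inputs == other.inputs
            and self.function.text == other.function.text
            and self.declared_edges == other.declared_edges
            and set(self.vertices) == set(other.vertices)
            and all(self.vertices[k] == other.vertices[k] for k in self.vertices)
        )


# --------------------------------------------------------------------------
# Label / function evaluation and blocking.


def evaluate_label(label: Label, assignment: Assignment) -> bool:
    """Evaluate a vertex label under an input assignment.

    ε is always true (the anchorage is unblockable); a literal evaluates to
    the (possibly negated) value of its variable.
    """
    if label.is_epsilon:
        return True
    if label.variable not in assignment:
        raise KeyError(f"unknown variable {label.variable!r}")
    value = bool(assignment[label.variable])
    return (not value) if label.negated else value


def blocked_vertices(circuit: Circuit, assignment: Assignment) -> set[str]:
    """Ids of the anchorages blocked under ``assignment``.

    Exactly the non-FINAL vertices whose label evaluates to false; FINAL
    and ε-labelled vertices never block.
    """
    return {
        v.id
        for v in circuit.vertices.values()
        if v.vtype != VertexType.FINAL and not evaluate_label(v.label, assignment)
    }


def evaluate_function(circuit: Circuit, assignment: Assignment) -> bool:
    """Evaluate the circuit's target Boolean function; defines which FINAL
    anchorage is the correct result for ``assignment``."""
    return circuit.function.evaluate(assignment)


# --------------------------------------------------------------------------
# File I/O.  The on-disk format is a small YAML document:
#
#   inputs: [x, y, z]
#   function: "x | y | z"
#   vertices:
#     - {id: v0, x: 1, y: 1, type: INIT, label: eps}
#     - {id: f1, x: 1, y: 7, type: FINAL, out: T}
#   edges: [[v0, f1], ...]        # optional


_VERTEX_KEYS = {"id", "x", "y", "type", "label", "out"}


def _vertex_from_record(rec: dict) -> Vertex:
    if not isinstance(rec, dict):
        raise CircuitValidationError(f"vertex record must be a mapping, got {rec!r}")
    unknown = set(rec) - _VERTEX_KEYS
    if unknown:
        raise CircuitValidationError(f"vertex record has unknown keys {sorted(unknown)}")
    for key in ("id", "x", "y", "type"):
        if key not in rec:
            raise CircuitValidationError(f"vertex record missing {key!r}: {rec}")
    out = rec.get("out")
    if out is not None:
        if out not in ("T", "F", True, False):
            raise CircuitValidationError(f"vertex {rec['id']!r}: out must be T or F")
        out = out in ("T", True)
    return Vertex(
        id=str(rec["id"]),
        position=GridPoint(int(rec["x"]), int(rec["y"])),
        vtype=str(rec["type"]),
        label=Label.parse(str(rec.get("label", "eps"))),
        output=out,
    )


def circuit_from_dict(doc: dict) -> Circuit:
    if not isinstance(doc, dict):
        raise CircuitValidationError("circuit document must be a mapping")
    for key in ("inputs", "function", "vertices"):
        if key not in doc:
            raise CircuitValidationError(f"circuit document missing {key!r}")
    vertices: dict[str, Vertex] = {}
    for rec in doc["vertices"]:
        v = _vertex_from_record(rec)
        if v.id in vertices:
            raise CircuitValidationError(f"duplicate vertex id {v.id!r}")
        vertices[v.id] = v
    edges = None
    if doc.get("edges") is not None:
        edges = frozenset(frozenset(map(str, e)) for e in doc["edges"])
    return Circuit(
        vertices=vertices,
        inputs=tuple(str(i) for i in doc["inputs"]),
        function=BooleanExpr(str(doc["function"])),
        declared_edges=edges,
    )


def circuit_to_dict(circuit: Circuit) -> dict:
    doc: dict = {
        "inputs": list(circuit.inputs),
        "function": circuit.function.text,
        "vertices": [],
    }
    for v in circuit.sorted_vertices():
        rec: dict = {
            "id": v.id,
            "x": v.position.x,
            "y": v.position.y,
            "type": v.vtype,
        }
        if not v.label.is_epsilon:
            rec["label"] = str(v.label)
        if v.vtype == VertexType.FINAL:
            rec["out"] = "T" if v.output else "F"
        doc["vertices"].append(rec)
    if circuit.declared_edges is not None:
        doc["edges"] = sorted(sorted(e) for e in circuit.declared_edges)
    return doc


def load_circuit(path: str | Path) -> Circuit:
    """Load and validate a circuit file.

    Raises ``CircuitValidationError`` naming the violated invariant, or a
    YAML parse error for malformed files.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return circuit_from_dict(doc)


def save_circuit(circuit: Circuit, path: str | Path) -> None:
    """Write a circuit file such that ``load_circuit`` round-trips it."""
    with open(path, "w") as fh:
        yaml.safe_dump(circuit_to_dict(circuit), fh, sort_keys=False)
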