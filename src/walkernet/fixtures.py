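"""Packaged example circuits and a seeded random-circuit generator.

Three circuits ship as data files: a six-vertex toy circuit on a 7x8
grid, and two layouts of the three-input OR circuit (x|y|z) — a compact
"naive" layout with avoidable short-distance leaks and a spread-out
"optimised" layout.  The two OR layouts are reconstructions of published
origami-tile designs: the figures defining them are available only
graphically, so coordinates were transcribed and then validated against
the circuits' known structural counts (see the test suite).

The generator lays random binary decision trees (or OR-chains with
joins) on the grid with configurable branch separation.  Tracks are
placed with an anchorage pitch of 2 grid units and junction fan-outs
chosen so that the short-distance sub-graph has exactly the intended
degree structure; cross-branch proximity below the long-range radius is
then confined to the cones around junctions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .circuit import (
    BooleanExpr,
    Circuit,
    GridPoint,
    Label,
    Vertex,
    VertexType,
    circuit_from_dict,
)

import yaml

__all__ = [
    "GeneratorParams",
    "toy_circuit",
    "naive_layout",
    "optimised_layout",
    "random_circuit",
]


def _load_packaged(name: str) -> Circuit:
    text = resources.files("walkernet.data").joinpath(name).read_text()
    return circuit_from_dict(yaml.safe_load(text))


def toy_circuit() -> Circuit:
    """Six anchorages on a 7x8 grid: one fork deciding a single input."""
    return _load_packaged("toy.yaml")


def naive_layout() -> Circuit:
    """Compact layout of the x|y|z circuit, with short-distance leaks."""
    return _load_packaged("naive.yaml")


def optimised_layout() -> Circuit:
    """Spread-out layout of the x|y|z circuit with leakage reduced."""
    return _load_packaged("optimised.yaml")


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the random layout generator.

    ``track_length`` bounds (inclusive) the number of track anchorages
    per segment; ``branch_separation`` is the vertical clearance between
    sibling sub-circuits in grid units.  The same seed always yields the
    same circuit.
    """

    n_inputs: int = 3
    max_depth: int = 3
    track_length: tuple[int, int] = (2, 4)
    branch_separation: int = 12
    allow_joins: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("need at least one input variable")
        if self.max_depth < 1:
            raise ValueError("max_depth must be at least 1")
        lo, hi = self.track_length
        if lo < 1 or hi < lo:
            raise ValueError("track_length bounds must satisfy 1 <= lo <= hi")
        if self.branch_separation < 4:
            raise ValueError("branch separation below 4 breaks short-band degrees")


class _Builder:
    """Accumulates vertices; shifts coordinates to the positive quadrant
    on finish."""

    def __init__(self) -> None:
        self.records: list[dict] = []
        self._n = 0

    def add(self, x: int, y: int, vtype: str, label: str = "eps",
            out: bool | None = None) -> str:
        vid = f"v{self._n}"
        self._n += 1
        rec = {"id": vid, "x": x, "y": y, "type": vtype}
        if label != "eps":
            rec["label"] = label
        if out is not None:
            rec["out"] = "T" if out else "F"
        self.records.append(rec)
        return vid

    def build(self, inputs: list[str], function: str) -> Circuit:
        min_x = min(r["x"] for r in self.records)
        min_y = min(r["y"] for r in self.records)
        for r in self.records:
            r["x"] += 1 - min_x
            r["y"] += 1 - min_y
        return circuit_from_dict(
            {"inputs": inputs, "function": function, "vertices": self.records}
        )


def _tree_circuit(p: GeneratorParams, rng: np.random.Generator) -> Circuit:
    depth = min(p.max_depth, p.n_inputs)
    variables = [f"x{i + 1}" for i in range(p.n_inputs)]
    outputs = [bool(rng.integers(0, 2)) for _ in range(1 << depth)]
    if not any(outputs):
        outputs[0] = True
    if all(outputs):
        outputs[-1] = False

    cubes = []
    for leaf, out in enumerate(outputs):
        if not out:
            continue
        lits = []
        for d in range(depth):
            taken_true = not ((leaf >> (depth - 1 - d)) & 1)
            lits.append(variables[d] if taken_true else f"!{variables[d]}")
        cubes.append("(" + " & ".join(lits) + ")")
    function = " | ".join(cubes)

    b = _Builder()

    def track_len() -> int:
        lo, hi = p.track_length
        return int(rng.integers(lo, hi + 1))

    def subtree_height(d: int) -> int:
        if d == depth:
            return p.branch_separation
        return 2 * subtree_height(d + 1)

    def grow(d: int, leaf_base: int, row: int, col: int, label: str) -> None:
        """Horizontal run entered at (row, col); first anchorage may carry
        the branch literal."""
        n = track_len()
        for i in range(n):
            b.add(row, col + 2 * i, VertexType.NORM, label if i == 0 else "eps")
        col_end = col + 2 * n
        if d == depth:
            b.add(row, col_end, VertexType.FINAL, out=outputs[leaf_base])
            return
        fork_col = col_end
        b.add(row, fork_col, VertexType.FORK)
        half = subtree_height(d + 1)
        # vertical offsets must be even: the 2-pitch descent from the
        # branch head can only reach rows of matching parity
        off = 2 * ((half // 2 + 1) // 2)
        row_hi = row - off
        row_lo = row + off
        var = variables[d]
        for sign, child_row, child_label, base in (
            (-1, row_hi, var, leaf_base),
            (+1, row_lo, f"!{var}", leaf_base + (1 << (depth - 1 - d))),
        ):
            head_row = row + 2 * sign
            if (child_row - head_row) % 2:
                raise ValueError("branch row offset must have even parity")
            b.add(head_row, fork_col + 2, VertexType.NORM, child_label)
            r = head_row
            while r != child_row:
                r += 2 * sign
                b.add(r, fork_col + 2, VertexType.NORM)
            grow(d + 1, base, child_row, fork_col + 4, "eps")

    # INIT track feeds the root junction directly
    root_len = track_len()
    b.add(0, 0, VertexType.INIT)
    for i in range(1, root_len + 1):
        b.add(0, 2 * i, VertexType.NORM)
    grow(0, 0, 0, 2 * (root_len + 1), "eps")
    return b.build(variables, function)


def _or_chain_circuit(p: GeneratorParams, rng: np.random.Generator) -> Circuit:
    """OR circuit over n inputs: a vertical fork spine whose true branches
    run right into a vertical join spine.

    Junction fan-outs use a 3-unit pitch (the largest short step) so that
    every junction has exactly three short neighbours; track anchorages
    use a 2-unit pitch.
    """
    variables = [f"x{i + 1}" for i in range(p.n_inputs)]
    n = p.n_inputs
    if n < 2:
        raise ValueError("the join-chain generator needs at least two inputs")
    b = _Builder()

    def track_len() -> int:
        lo, hi = p.track_length
        return int(rng.integers(lo, hi + 1))

    col_f = 0
    # entry track, horizontal into fork 1 at row 0
    lead = track_len()
    b.add(0, col_f - 2 - 2 * lead, VertexType.INIT)
    for i in range(lead):
        b.add(0, col_f - 2 - 2 * (lead - 1 - i), VertexType.NORM)

    # fork spine; spacing is even: 3-pitch out of the fork, 2-pitch run,
    # 3-pitch into the next fork
    false_norms = [max(1, (p.branch_separation - 4) // 2) for _ in range(n - 1)]
    fork_rows = [0]
    for m in false_norms:
        fork_rows.append(fork_rows[-1] + 6 + 2 * (m - 1))
    for i, fr in enumerate(fork_rows):
        b.add(fr, col_f, VertexType.FORK)
        if i < n - 1:
            for k in range(false_norms[i]):
                b.add(fr + 3 + 2 * k, col_f, VertexType.NORM,
                      f"!{variables[i]}" if k == 0 else "eps")
        else:
            tail = track_len()
            for k in range(tail):
                b.add(fr + 3 + 2 * k, col_f, VertexType.NORM,
                      f"!{variables[i]}" if k == 0 else "eps")
            b.add(fr + 3 + 2 * tail, col_f, VertexType.FINAL, out=False)

    # join spine column; parity chosen so 2-pitch runs meet the 3-pitch
    # join approaches exactly
    col_j = col_f + 9 + 2 * track_len()

    for i, fr in enumerate(fork_rows):
        if i == 0:
            # first true branch corners down the join column
            for c in range(col_f + 3, col_j + 1, 2):
                b.add(fr, c, VertexType.NORM,
                      variables[i] if c == col_f + 3 else "eps")
            for r in range(fr + 2, fork_rows[1] - 1, 2):
                b.add(r, col_j, VertexType.NORM)
        else:
            for c in range(col_f + 3, col_j - 5, 2):
                b.add(fr, c, VertexType.NORM,
                      variables[i] if c == col_f + 3 else "eps")
            b.add(fr, col_j - 3, VertexType.NORM)

    for i in range(1, n):
        jr = fork_rows[i]
        b.add(jr, col_j, VertexType.JOIN)
        if i < n - 1:
            for r in range(jr + 2, fork_rows[i + 1] - 1, 2):
                b.add(r, col_j, VertexType.NORM)
    # output track of the last join down to the TRUE final
    tail = track_len()
    r0 = fork_rows[-1] + 2
    for k in range(tail):
        b.add(r0 + 2 * k, col_j, VertexType.NORM)
    b.add(r0 + 2 * tail, col_j, VertexType.FINAL, out=True)

    return b.build(variables, " | ".join(variables))


def random_circuit(p: GeneratorParams) -> Circuit:
    """Generate a validated random circuit; identical seeds give
    identical circuits."""
    rng = np.random.default_rng(p.seed)
    if p.allow_joins:
        return _or_chain_circuit(p, rng)
    return _tree_circuit(p, rng)
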