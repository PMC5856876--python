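"""Automatic identification and classification of leakage transitions.

The intended computation of a walker circuit is a binary decision DAG
embedded in the short-distance sub-graph of the layout.  To recover that
DAG we index every anchorage with a positive integer using a breadth
first search from the INIT anchorage, borrowing the classical array
embedding of a binary tree: a fork with index c hands the indices 2c and
2c+1 to its two branches, a join folds branches back onto a single
index, and vertices along one track share their track's index.

While indexing, the search records the set M of *known transition types*
as triples (pre-index, post-index, TRACK|FORK|JOIN|LEAK).  Every
stepping transition of the unfolded net is then classified by looking up
its (source index, target index) pair in M — in either orientation — and
everything not found in M is a leak.  Combined with the three distance
bands this yields a twelve-way classification whose short-distance LEAK
cell directly flags layout defects.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import pandas as pd

from .circuit import Circuit, VertexType
from .geometry import DistanceParams, StepCategory, step_category, squared_distance
from .petrinet import GSPN, Role

__all__ = [
    "TransitionType",
    "IndexAssignment",
    "AmbiguityError",
    "ClassificationTable",
    "short_adjacency",
    "successors",
    "index_places",
    "classify_transitions",
    "consistency_report",
]


class TransitionType:
    TRACK = "TRACK"
    FORK = "FORK"
    JOIN = "JOIN"
    LEAK = "LEAK"

    ALL = (TRACK, FORK, JOIN, LEAK)


class AmbiguityError(RuntimeError):
    """The short-distance sub-graph does not match any indexing case.

    Carries the offending vertex id and a description of the
    configuration that could not be resolved.
    """

    def __init__(self, vertex_id: str, reason: str):
        self.vertex_id = vertex_id
        self.reason = reason
        super().__init__(f"indexing ambiguous at vertex {vertex_id!r}: {reason}")


@dataclass
class IndexAssignment:
    """Result of the BFS indexing: vertex id -> positive index (0 while
    unindexed) plus the set of vertices flagged by the three-neighbour
    track cases."""

    index: dict[str, int]
    marked: set[str] = field(default_factory=set)

    def __getitem__(self, vertex_id: str) -> int:
        return self.index[vertex_id]


def short_adjacency(
    circuit: Circuit, params: DistanceParams | None = None
) -> dict[str, list[str]]:
    """Short-band adjacency lists, neighbours in lexicographic (x, y) order."""
    params = params or DistanceParams()
    order = circuit.sorted_vertices()
    r2 = params.dS * params.dS
    adj: dict[str, list[str]] = {v.id: [] for v in order}
    for i, u in enumerate(order):
        for v in order[i + 1:]:
            d2 = squared_distance(u.position, v.position)
            if 0 < d2 <= r2:
                adj[u.id].append(v.id)
                adj[v.id].append(u.id)
    key = {v.id: (v.position.x, v.position.y) for v in order}
    for vid in adj:
        adj[vid].sort(key=key.__getitem__)
    return adj


def successors(
    vertex_id: str,
    idx: IndexAssignment,
    shortgraph: dict[str, list[str]],
) -> list[str]:
    """The successor set x° of the BFS: short neighbours y of x with
    index(y) != index(x) and (y unindexed or index(y) != index(x) div 2).

    The second clause keeps the search from walking back through a fork:
    the children 2c and 2c+1 both map to their parent c under integer
    halving.  Neighbour order (lexicographic by position, inherited from
    the adjacency lists) fixes which fork child receives the even index.
    """
    ix = idx.index[vertex_id]
    out = []
    for y in shortgraph[vertex_id]:
        iy = idx.index[y]
        if iy == ix:
            continue
        if iy != 0 and iy == ix // 2:
            continue
        out.append(y)
    return out


def index_places(
    circuit: Circuit, params: DistanceParams | None = None
) -> tuple[IndexAssignment, set[tuple[int, int, str]]]:
    """BFS indexing of the short-distance sub-graph (the place-indexing
    algorithm), returning the index assignment and the set M of known
    transition types.

    Raises :class:`AmbiguityError` when the sub-graph presents a
    configuration outside the supported cases (e.g. more than three short
    neighbours at a track anchorage, or an in-range junction defect).
    """
    params = params or DistanceParams()
    adj = short_adjacency(circuit, params)
    vtype = {vid: v.vtype for vid, v in circuit.vertices.items()}
    idx = IndexAssignment(index={vid: 0 for vid in circuit.vertices})
    M: set[tuple[int, int, str]] = set()
    m_order: list[tuple[int, int, str]] = []  # insertion order, for lookup ties

    def record(i: int, j: int, ttype: str) -> None:
        triple = (i, j, ttype)
        if triple not in M:
            M.add(triple)
            m_order.append(triple)

    init = circuit.init_vertex.id
    idx.index[init] = 1
    queue: deque[str] = deque([init])

    while queue:
        c = queue.popleft()
        ic = idx.index[c]
        succ = successors(c, idx, adj)
        kind = vtype[c]

        if kind == VertexType.INIT:
            if len(adj[c]) != 1 or len(succ) != 1:
                raise AmbiguityError(
                    c, f"INIT must have exactly one short neighbour, has {len(adj[c])}"
                )
            s = succ[0]
            idx.index[s] = ic
            record(ic, ic, TransitionType.TRACK)
            queue.append(s)

        elif kind == VertexType.FORK:
            if len(adj[c]) != 3:
                raise AmbiguityError(
                    c, f"FORK must have exactly 3 short neighbours, has {len(adj[c])}"
                )
            if len(succ) != 2 or any(idx.index[s] != 0 for s in succ):
                raise AmbiguityError(
                    c, "FORK requires exactly two unindexed successors"
                )
            for offset, s in enumerate(succ):
                idx.index[s] = 2 * ic + offset
                record(ic, 2 * ic + offset, TransitionType.FORK)
                queue.append(s)

        elif kind == VertexType.JOIN:
            if len(adj[c]) != 3:
                raise AmbiguityError(
                    c, f"JOIN must have exactly 3 short neighbours, has {len(adj[c])}"
                )
            # Unindexed members of c° may be the true successor or a not-yet
            # reached predecessor branch; the decision is postponed by
            # treating each as a successor on c's own track.
            for s in succ:
                if idx.index[s] == 0:
                    idx.index[s] = ic
                    record(ic, ic, TransitionType.TRACK)
                    queue.append(s)
                # already-indexed members are incoming branches; their JOIN
                # triples are recorded when those branches reach c.

        elif kind == VertexType.FINAL:
            continue  # branches terminate at finals; nothing to investigate

        elif kind == VertexType.NORM:
            n_short = len(adj[c])
            if n_short > 3:
                raise AmbiguityError(
                    c, f"track anchorage with {n_short} short neighbours"
                )
            three = n_short == 3
            for s in succ:
                is_ = idx.index[s]
                join = vtype[s] == VertexType.JOIN
                if is_ == 0 and join:
                    idx.index[s] = 2 * ic
                    record(ic, 2 * ic, TransitionType.JOIN)
                    queue.append(s)
                    if three:
                        idx.marked.add(s)
                elif is_ == 0:
                    idx.index[s] = ic
                    record(ic, ic, TransitionType.TRACK)
                    queue.append(s)
                    if three:
                        idx.marked.add(s)
                elif not three:
                    # two-neighbour track cases on an indexed successor
                    if join and is_ != ic:
                        record(ic, is_, TransitionType.JOIN)
                    elif not join and is_ < ic:
                        # backtracked onto a previously visited track
                        idx.index[s] = ic
                        record(ic, ic, TransitionType.TRACK)
                        queue.append(s)
                    else:
                        raise AmbiguityError(
                            c,
                            f"track successor {s!r} indexed {is_} (own index {ic}) "
                            "matches no case",
                        )
                else:
                    # three-neighbour (potential leak) cases
                    if s in idx.marked and join:
                        record(ic, is_, TransitionType.JOIN)
                    elif s in idx.marked:
                        if is_ < ic:
                            # corner with shortcut transitions
                            idx.index[s] = ic
                            queue.append(s)
                        record(ic, idx.index[s], TransitionType.TRACK)
                    else:
                        record(ic, is_, TransitionType.LEAK)
        else:  # pragma: no cover - vertex types are validated upstream
            raise AmbiguityError(c, f"unknown vertex type {kind!r}")

    unindexed = sorted(v for v, i in idx.index.items() if i == 0)
    if unindexed:
        raise AmbiguityError(
            unindexed[0],
            f"{len(unindexed)} anchorage(s) unreached by the short-distance "
            f"search: {unindexed[:5]}",
        )
    idx._m_order = m_order  # type: ignore[attr-defined]
    return idx, M


# Lookup precedence when several triples share an index pair: junction
# evidence outranks track evidence, leaks come last.
_TYPE_PRIORITY = {
    TransitionType.FORK: 0,
    TransitionType.JOIN: 1,
    TransitionType.TRACK: 2,
    TransitionType.LEAK: 3,
}


@dataclass
class ClassificationTable:
    """Counts of stepping transitions per (structural type, distance band).

    ``labels`` maps each transition id to its (type, band) pair;
    ``counts`` is a type × band DataFrame including the marginal sums.
    """

    labels: dict[str, tuple[str, str]]

    @property
    def counts(self) -> pd.DataFrame:
        df = pd.DataFrame(
            0,
            index=list(TransitionType.ALL),
            columns=list(StepCategory.BANDS),
            dtype=int,
        )
        for ttype, band in self.labels.values():
            df.loc[ttype, band] += 1
        df["Sigma"] = df.sum(axis=1)
        return df

    @property
    def total(self) -> int:
        return len(self.labels)

    def cell(self, ttype: str, band: str) -> int:
        return int(self.counts.loc[ttype, band])

    def to_text(self) -> str:
        df = self.counts.rename(
            index=str.capitalize, columns={"Sigma": "Σ"}
        ).rename(columns=str.capitalize)
        return df.to_string()

    def diff(self, other: "ClassificationTable") -> pd.DataFrame:
        """Cell-wise difference (self - other) of the two count tables."""
        return self.counts - other.counts


def classify_transitions(
    net: GSPN,
    idx: IndexAssignment,
    M: set[tuple[int, int, str]],
) -> ClassificationTable:
    """Classify every STEP/FINALSTEP transition of ``net`` by looking up
    the index pair of its source and target anchorage in M (either
    orientation); anything not in M is a LEAK.  LOOP, BLOCK and FAIL
    transitions are excluded."""
    lookup: dict[tuple[int, int], str] = {}
    for i, j, ttype in sorted(M, key=lambda t: (_TYPE_PRIORITY[t[2]], t[:2])):
        for key in ((i, j), (j, i)):
            if key not in lookup:
                lookup[key] = ttype
    labels: dict[str, tuple[str, str]] = {}
    for t in net.step_transitions():
        pair = (idx.index[t.source_vertex], idx.index[t.target_vertex])
        ttype = lookup.get(pair, TransitionType.LEAK)
        labels[t.id] = (ttype, t.category)
    return ClassificationTable(labels)


def consistency_report(
    idx: IndexAssignment,
    M: set[tuple[int, int, str]],
    table: ClassificationTable | None = None,
) -> list[str]:
    """Advisory check of the index-arithmetic patterns behind each triple
    type: TRACK pairs share an index, FORK children are 2c / 2c+1, JOIN
    targets are 2c or carry a smaller index.  Violations are reported but
    never override the lookup-based classification."""
    notes = []
    for i, j, ttype in sorted(M):
        ok = True
        if ttype == TransitionType.TRACK:
            ok = i == j
        elif ttype == TransitionType.FORK:
            ok = j in (2 * i, 2 * i + 1)
        elif ttype == TransitionType.JOIN:
            ok = j == 2 * i or j < i
        if not ok:
            notes.append(
                f"triple ({i}, {j}, {ttype}) violates the {ttype} index pattern"
            )
    if table is not None:
        by_type = {t: 0 for t in TransitionType.ALL}
        for ttype, _ in table.labels.values():
            by_type[ttype] += 1
        notes.append(
            "classified transitions: "
            + ", ".join(f"{t}={n}" for t, n in by_type.items())
        )
    return notes
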