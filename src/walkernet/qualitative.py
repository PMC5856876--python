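"""Reachability-graph construction and behavioural property checks.

The reachability graph of a net is the directed graph of all markings
reachable from the initial marking, arcs labelled by the fired
transition.  Two exploration modes are offered: TIMEFREE ignores the
priority of immediate transitions (both interleavings of a concurrent
immediate/stochastic pair are explored), PRIORITY restricts firing to
immediate transitions whenever one is enabled — the sub-graph actually
realised by the stochastic semantics.

From the graph we decide the textbook behavioural properties:
k-boundedness (maximum token count), dead states (terminal markings),
reversibility (strong connectivity) and liveness (membership of every
transition in all terminal strongly connected components).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from .petrinet import GSPN, Marking, Role, TransitionKind, enabled, fire

__all__ = [
    "ReachabilityGraph",
    "QualReport",
    "StateSpaceLimit",
    "Mode",
    "build_reachability_graph",
    "check_bound",
    "dead_states",
    "scc_analysis",
    "analyse",
]

CanonicalMarking = tuple[tuple[str, int], ...]


class Mode:
    TIMEFREE = "TIMEFREE"
    PRIORITY = "PRIORITY"


class StateSpaceLimit(RuntimeError):
    def __init__(self, limit: int):
        self.limit = limit
        super().__init__(f"state-space limit of {limit} markings exceeded")


def canonical(m: Marking) -> CanonicalMarking:
    """Sparse sorted representation used for hashing and ordering."""
    return tuple(sorted((p, n) for p, n in m.items() if n))


@dataclass
class ReachabilityGraph:
    root: CanonicalMarking
    nodes: set[CanonicalMarking]
    arcs: set[tuple[CanonicalMarking, str, CanonicalMarking]]
    mode: str

    def out_degree(self, node: CanonicalMarking) -> int:
        return sum(1 for (m, _, _) in self.arcs if m == node)

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for m, t, m2 in self.arcs:
            g.add_edge(m, m2, transition=t)
        return g

    def to_dot(self) -> str:
        names = {node: f"m{i}" for i, node in enumerate(sorted(self.nodes))}
        lines = ["digraph reachability {"]
        for node, name in names.items():
            label = ",".join(f"{p}:{n}" for p, n in node)
            lines.append(f'  {name} [label="{label}"];')
        for m, t, m2 in sorted(self.arcs):
            lines.append(f'  {names[m]} -> {names[m2]} [label="{t}"];')
        lines.append("}")
        return "\n".join(lines)


@dataclass
class QualReport:
    bound: int
    dead: set[CanonicalMarking]
    reversible: bool
    live: bool
    scc_count: int
    terminal_scc_count: int
    n_states: int
    n_arcs: int

    def to_text(self) -> str:
        return (
            f"states            {self.n_states}\n"
            f"arcs              {self.n_arcs}\n"
            f"bound             {self.bound}\n"
            f"dead states       {len(self.dead)}\n"
            f"reversible        {self.reversible}\n"
            f"live              {self.live}\n"
            f"SCCs (terminal)   {self.scc_count} ({self.terminal_scc_count})\n"
        )


def build_reachability_graph(
    net: GSPN,
    mode: str = Mode.TIMEFREE,
    limit: int = 500_000,
) -> ReachabilityGraph:
    """Breadth-first marking exploration from the net's initial marking.

    Raises :class:`StateSpaceLimit` when more than ``limit`` markings are
    reached.  Exploration order is deterministic (FIFO over markings,
    transitions in net order).
    """
    if mode not in (Mode.TIMEFREE, Mode.PRIORITY):
        raise ValueError(f"unknown exploration mode {mode!r}")
    priority = mode == Mode.PRIORITY
    root = canonical(net.m0)
    nodes = {root}
    arcs: set[tuple[CanonicalMarking, str, CanonicalMarking]] = set()
    queue: deque[Marking] = deque([dict(net.m0)])
    while queue:
        m = queue.popleft()
        cm = canonical(m)
        for t in enabled(net, m, priority=priority):
            m2 = fire(net, m, t)
            cm2 = canonical(m2)
            arcs.add((cm, t.id, cm2))
            if cm2 not in nodes:
                nodes.add(cm2)
                if len(nodes) > limit:
                    raise StateSpaceLimit(limit)
                queue.append(m2)
    return ReachabilityGraph(root, nodes, arcs, mode)


def check_bound(rg: ReachabilityGraph) -> int:
    """Smallest k such that the net is k-bounded on the explored graph."""
    return max((n for node in rg.nodes for _, n in node), default=0)


def dead_states(rg: ReachabilityGraph) -> set[CanonicalMarking]:
    """Markings without outgoing arcs.  Nets carrying self-loops on final
    anchorages never report a reached-final marking as dead."""
    with_out = {m for (m, _, _) in rg.arcs}
    return rg.nodes - with_out


def scc_analysis(rg: ReachabilityGraph) -> tuple[bool, bool, int, int]:
    """(reversible, live, #SCCs, #terminal SCCs).

    Reversibility is strong connectivity of the reachability graph;
    a transition is live iff it labels an arc inside every terminal SCC,
    and the net is live iff all transitions are.
    """
    g = rg.to_networkx()
    sccs = list(nx.strongly_connected_components(g))
    condensation = nx.condensation(g, sccs)
    terminal = [
        sccs[i] for i in condensation.nodes if condensation.out_degree(i) == 0
    ]
    reversible = len(sccs) == 1
    transitions = {t for (_, t, _) in rg.arcs}
    live = bool(transitions)
    for scc in terminal:
        inside = {
            t for (m, t, m2) in rg.arcs if m in scc and m2 in scc
        }
        if transitions - inside:
            live = False
            break
    return reversible, live, len(sccs), len(terminal)


def analyse(
    net: GSPN, mode: str = Mode.TIMEFREE, limit: int = 500_000
) -> QualReport:
    """Convenience wrapper: build the graph and summarise all properties."""
    rg = build_reachability_graph(net, mode=mode, limit=limit)
    reversible, live, n_scc, n_term = scc_analysis(rg)
    return QualReport(
        bound=check_bound(rg),
        dead=dead_states(rg),
        reversible=reversible,
        live=live,
        scc_count=n_scc,
        terminal_scc_count=n_term,
        n_states=len(rg.nodes),
        n_arcs=len(rg.arcs),
    )
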