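"""Generalised stochastic Petri nets and the circuit unfolding.

The unfolded net has one ANCHORAGE place per vertex (1 token = the
anchorage may be visited; a second token = the walker sits there) and,
for every labelled vertex, a BLOCKCTRL place driving an immediate
BLOCK/FAIL conflict pair that realises the programming fault model:
blocking succeeds with probability 0.7 (the availability token is
removed) and fails with 0.3.

Stepping transitions connect every ordered in-range vertex pair whose
source is not FINAL.  Under burnt-bridges semantics the walker's
departure consumes the source's availability token, so an anchorage can
never be revisited; under unguided semantics the availability token is
returned.  A rate-carrying self-loop is attached to every FINAL
anchorage so that wanted terminal markings are not dead states.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from xml.etree import ElementTree as ET

from .circuit import Circuit, VertexType, blocked_vertices
from .geometry import DistanceParams, StepCategory, step_category, step_rate

__all__ = [
    "Place",
    "Transition",
    "Marking",
    "GSPN",
    "Semantics",
    "unfold",
    "apply_assignment",
    "enabled",
    "fire",
    "to_pnml",
    "net_dump",
]

Marking = dict[str, int]


class Semantics:
    BURNT_BRIDGES = "BURNT_BRIDGES"
    UNGUIDED = "UNGUIDED"


class PlaceKind:
    ANCHORAGE = "ANCHORAGE"
    BLOCKCTRL = "BLOCKCTRL"


class TransitionKind:
    STOCHASTIC = "STOCHASTIC"
    IMMEDIATE = "IMMEDIATE"


class Role:
    STEP = "STEP"
    FINALSTEP = "FINALSTEP"
    LOOP = "LOOP"
    BLOCK = "BLOCK"
    FAIL = "FAIL"


@dataclass(frozen=True)
class Place:
    id: str
    kind: str
    vertex_ref: str


@dataclass(frozen=True)
class Transition:
    id: str
    kind: str
    rate: float | None = None     # STOCHASTIC only
    weight: float | None = None   # IMMEDIATE only
    role: str = Role.STEP
    source_vertex: str | None = None  # STEP / FINALSTEP
    target_vertex: str | None = None  # STEP / FINALSTEP
    vertex_ref: str | None = None     # LOOP / BLOCK / FAIL
    category: str | None = None       # StepCategory for STEP / FINALSTEP


@dataclass
class GSPN:
    """Places, transitions, weighted arcs and the initial marking.

    Arcs are stored as per-transition pre/post maps; ``f`` exposes the
    textbook arc-weight function on (place, transition) pairs in either
    orientation.
    """

    places: dict[str, Place]
    transitions: dict[str, Transition]
    pre: dict[str, dict[str, int]]   # transition id -> {place id: weight}
    post: dict[str, dict[str, int]]  # transition id -> {place id: weight}
    m0: Marking
    semantics: str = Semantics.BURNT_BRIDGES

    def __post_init__(self) -> None:
        if not self.places or not self.transitions:
            raise ValueError("P and T must be finite, non-empty sets")
        if set(self.places) & set(self.transitions):
            raise ValueError("P and T must be disjoint")
        for tid in self.transitions:
            if not self.pre.get(tid):
                raise ValueError(f"transition {tid!r} has no pre-arc")

    def f(self, src: str, dst: str) -> int:
        """Arc weight f(src, dst); zero when no arc exists."""
        if src in self.places and dst in self.transitions:
            return self.pre[dst].get(src, 0)
        if src in self.transitions and dst in self.places:
            return self.post[src].get(dst, 0)
        raise KeyError(f"({src!r}, {dst!r}) is not a (place, transition) pair")

    def step_transitions(self) -> list[Transition]:
        return [
            t
            for t in self.transitions.values()
            if t.role in (Role.STEP, Role.FINALSTEP)
        ]


def anchorage_place_id(vertex_id: str) -> str:
    return f"A_{vertex_id}"


def blockctrl_place_id(vertex_id: str) -> str:
    return f"B_{vertex_id}"


def unfold(
    circuit: Circuit,
    params: DistanceParams | None = None,
    semantics: str = Semantics.BURNT_BRIDGES,
    block_weight: float = 0.7,
) -> GSPN:
    """Unfold a validated circuit into a GSPN.

    Every ordered vertex pair (u, v) with u not FINAL and a non-NONE step
    category yields one stepping transition at the band's rate; vertices
    are visited in lexicographic (x, y) order so ids and iteration order
    are stable across runs.
    """
    params = params or DistanceParams()
    if semantics not in (Semantics.BURNT_BRIDGES, Semantics.UNGUIDED):
        raise ValueError(f"unknown semantics {semantics!r}")
    if not 0.0 <= block_weight <= 1.0:
        raise ValueError("block weight must lie in [0, 1]")

    order = circuit.sorted_vertices()
    places: dict[str, Place] = {}
    transitions: dict[str, Transition] = {}
    pre: dict[str, dict[str, int]] = {}
    post: dict[str, dict[str, int]] = {}
    m0: Marking = {}

    for v in order:
        pid = anchorage_place_id(v.id)
        places[pid] = Place(pid, PlaceKind.ANCHORAGE, v.id)
        # All anchorages start available; INIT also hosts the walker.
        m0[pid] = 2 if v.vtype == VertexType.INIT else 1

    for u in order:
        if u.vtype == VertexType.FINAL:
            continue  # the walker can never leave a final anchorage
        for v in order:
            if v.id == u.id:
                continue
            cat = step_category(u.position, v.position, params)
            if cat == StepCategory.NONE:
                continue
            role = Role.FINALSTEP if v.vtype == VertexType.FINAL else Role.STEP
            tid = f"step_{u.id}__{v.id}"
            transitions[tid] = Transition(
                tid,
                TransitionKind.STOCHASTIC,
                rate=step_rate(cat, params),
                role=role,
                source_vertex=u.id,
                target_vertex=v.id,
                category=cat,
            )
            au, av = anchorage_place_id(u.id), anchorage_place_id(v.id)
            if semantics == Semantics.BURNT_BRIDGES:
                pre[tid] = {au: 2, av: 1}
                post[tid] = {av: 2}
            else:  # unguided: the source anchorage stays available
                pre[tid] = {au: 2, av: 1}
                post[tid] = {au: 1, av: 2}

    for v in order:
        if v.vtype != VertexType.FINAL:
            continue
        tid = f"loop_{v.id}"
        av = anchorage_place_id(v.id)
        transitions[tid] = Transition(
            tid,
            TransitionKind.STOCHASTIC,
            rate=params.k_s,
            role=Role.LOOP,
            vertex_ref=v.id,
        )
        pre[tid] = {av: 2}
        post[tid] = {av: 2}

    for v in order:
        if v.vtype == VertexType.FINAL or v.label.is_epsilon:
            continue
        bp = blockctrl_place_id(v.id)
        places[bp] = Place(bp, PlaceKind.BLOCKCTRL, v.id)
        m0[bp] = 0  # set per assignment by apply_assignment
        av = anchorage_place_id(v.id)
        t_block = f"block_{v.id}"
        t_fail = f"fail_{v.id}"
        transitions[t_block] = Transition(
            t_block, TransitionKind.IMMEDIATE, weight=block_weight,
            role=Role.BLOCK, vertex_ref=v.id,
        )
        pre[t_block] = {bp: 1, av: 1}
        post[t_block] = {}
        transitions[t_fail] = Transition(
            t_fail, TransitionKind.IMMEDIATE, weight=1.0 - block_weight,
            role=Role.FAIL, vertex_ref=v.id,
        )
        pre[t_fail] = {bp: 1}
        post[t_fail] = {}

    return GSPN(places, transitions, pre, post, m0, semantics)


def apply_assignment(net: GSPN, circuit: Circuit, assignment) -> GSPN:
    """Copy of ``net`` whose BLOCKCTRL places are marked exactly for the
    vertices blocked under ``assignment``."""
    blocked = blocked_vertices(circuit, assignment)
    m0 = dict(net.m0)
    for pid, place in net.places.items():
        if place.kind == PlaceKind.BLOCKCTRL:
            m0[pid] = 1 if place.vertex_ref in blocked else 0
    return replace(net, m0=m0)


def enabled(net: GSPN, m: Marking, priority: bool = True) -> list[Transition]:
    """Transitions enabled in ``m`` (Definition-3 enabling).

    With ``priority`` (GSPN semantics), immediate transitions pre-empt
    stochastic ones: if any immediate transition is enabled only immediate
    transitions are returned.  The time-free explorer passes
    ``priority=False`` to obtain the unprioritised set.
    """
    result = [
        t
        for tid, t in net.transitions.items()
        if all(m.get(p, 0) >= w for p, w in net.pre[tid].items())
    ]
    if priority:
        immediates = [t for t in result if t.kind == TransitionKind.IMMEDIATE]
        if immediates:
            return immediates
    return result


def fire(net: GSPN, m: Marking, t: Transition | str) -> Marking:
    """Fire ``t`` in ``m``: m'(p) = m(p) - f(p,t) + f(t,p).  Atomic; firing
    a disabled transition is an error."""
    tid = t if isinstance(t, str) else t.id
    if tid not in net.transitions:
        raise KeyError(f"unknown transition {tid!r}")
    for p, w in net.pre[tid].items():
        if m.get(p, 0) < w:
            raise ValueError(f"transition {tid!r} is not enabled")
    m2 = dict(m)
    for p, w in net.pre[tid].items():
        m2[p] = m2.get(p, 0) - w
    for p, w in net.post[tid].items():
        m2[p] = m2.get(p, 0) + w
    return m2


# --------------------------------------------------------------------------
# Interchange formats.


def to_pnml(net: GSPN) -> str:
    """Serialise the net structure to PNML (PT-net flavour with tool-specific
    rate/weight annotations)."""
    root = ET.Element("pnml", xmlns="http://www.pnml.org/version-2009/grammar/pnml")
    netel = ET.SubElement(
        root, "net", id="walkernet",
        type="http://www.pnml.org/version-2009/grammar/ptnet",
    )
    page = ET.SubElement(netel, "page", id="page0")
    for pid, place in net.places.items():
        pel = ET.SubElement(page, "place", id=pid)
        name = ET.SubElement(ET.SubElement(pel, "name"), "text")
        name.text = pid
        tokens = net.m0.get(pid, 0)
        if tokens:
            mel = ET.SubElement(ET.SubElement(pel, "initialMarking"), "text")
            mel.text = str(tokens)
    for tid, t in net.transitions.items():
        tel = ET.SubElement(page, "transition", id=tid)
        name = ET.SubElement(ET.SubElement(tel, "name"), "text")
        name.text = tid
        ann = ET.SubElement(tel, "toolspecific", tool="walkernet", version="1")
        if t.kind == TransitionKind.STOCHASTIC:
            ET.SubElement(ann, "rate").text = repr(t.rate)
        else:
            ET.SubElement(ann, "weight").text = repr(t.weight)
            ET.SubElement(ann, "immediate").text = "true"
    n = 0
    for tid in net.transitions:
        for p, w in net.pre[tid].items():
            arc = ET.SubElement(page, "arc", id=f"a{n}", source=p, target=tid)
            ET.SubElement(ET.SubElement(arc, "inscription"), "text").text = str(w)
            n += 1
        for p, w in net.post[tid].items():
            arc = ET.SubElement(page, "arc", id=f"a{n}", source=tid, target=p)
            ET.SubElement(ET.SubElement(arc, "inscription"), "text").text = str(w)
            n += 1
    buf = io.BytesIO()
    ET.ElementTree(root).write(buf, encoding="utf-8", xml_declaration=True)
    return buf.getvalue().decode()


def net_dump(net: GSPN) -> str:
    """Stable plain-text dump (places, transitions, arcs, m0) for golden
    file comparisons."""
    lines = [f"semantics {net.semantics}", "places"]
    for pid in sorted(net.places):
        p = net.places[pid]
        lines.append(f"  {pid} kind={p.kind} vertex={p.vertex_ref} m0={net.m0.get(pid, 0)}")
    lines.append("transitions")
    for tid in sorted(net.transitions):
        t = net.transitions[tid]
        attrs = [f"kind={t.kind}", f"role={t.role}"]
        if t.rate is not None:
            attrs.append(f"rate={t.rate:g}")
        if t.weight is not None:
            attrs.append(f"weight={t.weight:g}")
        if t.category:
            attrs.append(f"cat={t.category}")
        pre = " ".join(f"{p}:{w}" for p, w in sorted(net.pre[tid].items()))
        post = " ".join(f"{p}:{w}" for p, w in sorted(net.post[tid].items()))
        lines.append(f"  {tid} {' '.join(attrs)} pre[{pre}] post[{post}]")
    return "\n".join(lines) + "\n"
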