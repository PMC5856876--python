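"""Shared circuit fixtures and independent oracles."""

import pytest

from walkernet.circuit import Circuit, circuit_from_dict
from walkernet.geometry import DistanceParams
from walkernet.leakage import TransitionType


def build(doc: dict) -> Circuit:
    return circuit_from_dict(doc)


@pytest.fixture
def params() -> DistanceParams:
    return DistanceParams()


@pytest.fixture
def single_step_circuit() -> Circuit:
    """INIT adjacent only to a FINAL: one short step ends every walk."""
    return build({
        "inputs": ["x"], "function": "x",
        "vertices": [
            {"id": "v0", "x": 1, "y": 1, "type": "INIT"},
            {"id": "f", "x": 1, "y": 3, "type": "FINAL", "out": "T"},
        ],
    })


@pytest.fixture
def line_circuit() -> Circuit:
    """INIT - labelled NORM - FINAL, evenly spaced on one row."""
    return build({
        "inputs": ["x"], "function": "x",
        "vertices": [
            {"id": "v0", "x": 1, "y": 1, "type": "INIT"},
            {"id": "n", "x": 1, "y": 4, "type": "NORM", "label": "x"},
            {"id": "f", "x": 1, "y": 7, "type": "FINAL", "out": "T"},
        ],
    })


@pytest.fixture
def fork_circuit() -> Circuit:
    """One fork with two labelled branches ending in opposite finals."""
    return build({
        "inputs": ["x"], "function": "x",
        "vertices": [
            {"id": "v0", "x": 10, "y": 1, "type": "INIT"},
            {"id": "n1", "x": 10, "y": 3, "type": "NORM"},
            {"id": "g", "x": 10, "y": 5, "type": "FORK"},
            {"id": "p", "x": 8, "y": 7, "type": "NORM", "label": "x"},
            {"id": "q", "x": 12, "y": 7, "type": "NORM", "label": "!x"},
            {"id": "fT", "x": 8, "y": 9, "type": "FINAL", "out": "T"},
            {"id": "fF", "x": 12, "y": 9, "type": "FINAL", "out": "F"},
        ],
    })


@pytest.fixture
def diamond_circuit() -> Circuit:
    """Fork-join diamond: both branches reconverge before the final."""
    return build({
        "inputs": ["x"], "function": "x | !x",
        "vertices": [
            {"id": "v0", "x": 10, "y": 1, "type": "INIT"},
            {"id": "n1", "x": 10, "y": 3, "type": "NORM"},
            {"id": "g", "x": 10, "y": 5, "type": "FORK"},
            {"id": "p1", "x": 8, "y": 7, "type": "NORM", "label": "x"},
            {"id": "p2", "x": 8, "y": 9, "type": "NORM"},
            {"id": "q1", "x": 12, "y": 7, "type": "NORM", "label": "!x"},
            {"id": "q2", "x": 12, "y": 9, "type": "NORM"},
            {"id": "j", "x": 10, "y": 11, "type": "JOIN"},
            {"id": "n2", "x": 10, "y": 13, "type": "NORM"},
            {"id": "f", "x": 10, "y": 15, "type": "FINAL", "out": "T"},
        ],
    })


def brute_force_classification(circuit, idx, M, params=None):
    """Independent classifier: pairwise integer distance banding plus a
    direct lookup of the known-transition-type set, computed without the
    unfolded net.  Returns {(source id, target id): (type, band)}."""
    params = params or DistanceParams()
    prio = {TransitionType.FORK: 0, TransitionType.JOIN: 1,
            TransitionType.TRACK: 2, TransitionType.LEAK: 3}
    table = {}
    for i, j, ttype in sorted(M, key=lambda t: (prio[t[2]], t[:2])):
        table.setdefault((i, j), ttype)
        table.setdefault((j, i), ttype)
    out = {}
    vs = list(circuit.vertices.values())
    for u in vs:
        if u.vtype == "FINAL":
            continue
        for v in vs:
            if v.id == u.id:
                continue
            d2 = (u.position.x - v.position.x) ** 2 + (u.position.y - v.position.y) ** 2
            if d2 <= params.dS ** 2:
                band = "SHORT"
            elif d2 <= params.dMgrid ** 2:
                band = "MEDIUM"
            elif d2 <= params.dL ** 2:
                band = "LONG"
            else:
                continue
            ttype = table.get((idx.index[u.id], idx.index[v.id]), TransitionType.LEAK)
            out[(u.id, v.id)] = (ttype, band)
    return out
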