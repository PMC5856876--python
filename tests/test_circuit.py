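"""Circuit model, validation, Boolean evaluation and file round-trips."""

import pytest
from hypothesis import given, settings, strategies as st

from walkernet.circuit import (
    BooleanExpr,
    CircuitValidationError,
    EPSILON,
    Label,
    blocked_vertices,
    circuit_from_dict,
    evaluate_function,
    evaluate_label,
    load_circuit,
    save_circuit,
)
from walkernet.fixtures import naive_layout


def test_line_fixture_loads(line_circuit):
    assert len(line_circuit.vertices) == 3
    assert line_circuit.inputs == ("x",)
    assert line_circuit.init_vertex.id == "v0"
    assert [v.id for v in line_circuit.final_vertices] == ["f"]


@pytest.mark.parametrize(
    "mutation, match",
    [
        (lambda d: d["vertices"].append(
            {"id": "v9", "x": 5, "y": 5, "type": "INIT"}), "INIT"),
        (lambda d: d["vertices"][2].update(label="x"), "must not carry a label"),
        (lambda d: d["vertices"][2].pop("out"), "output"),
        (lambda d: d["vertices"][1].update(label="q"), "not among inputs"),
        (lambda d: d["vertices"][1].update(x=1, y=1), "share position"),
        (lambda d: d.update(function="x | w"), "outside the input set"),
        (lambda d: [v.update(type="NORM") for v in d["vertices"]
                    if v["type"] == "FINAL"], "FINAL"),
    ],
)
def test_validation_errors(mutation, match):
    doc = {
        "inputs": ["x"], "function": "x",
        "vertices": [
            {"id": "v0", "x": 1, "y": 1, "type": "INIT"},
            {"id": "n", "x": 1, "y": 4, "type": "NORM", "label": "x"},
            {"id": "f", "x": 1, "y": 7, "type": "FINAL", "out": "T"},
        ],
    }
    mutation(doc)
    with pytest.raises(CircuitValidationError, match=match):
        circuit_from_dict(doc)


def test_declared_edge_degrees():
    doc = {
        "inputs": ["x"], "function": "x",
        "vertices": [
            {"id": "v0", "x": 1, "y": 1, "type": "INIT"},
            {"id": "n", "x": 1, "y": 4, "type": "NORM", "label": "x"},
            {"id": "f", "x": 1, "y": 7, "type": "FINAL", "out": "T"},
        ],
        "edges": [["v0", "n"], ["n", "f"]],
    }
    circuit_from_dict(doc)  # valid degrees: 1, 2, 1
    doc["edges"] = [["v0", "n"]]
    with pytest.raises(CircuitValidationError, match="degree"):
        circuit_from_dict(doc)


@pytest.mark.parametrize(
    "label, assignment, expected",
    [
        (Label("x"), {"x": False}, False),
        (Label("x"), {"x": True}, True),
        (EPSILON, {"x": False}, True),
        (Label("x", negated=True), {"x": False}, True),
    ],
)
def test_evaluate_label(label, assignment, expected):
    assert evaluate_label(label, assignment) is expected


def test_evaluate_label_unknown_variable():
    with pytest.raises(KeyError):
        evaluate_label(Label("q"), {"x": True})


def test_blocked_vertices_line(line_circuit):
    assert blocked_vertices(line_circuit, {"x": False}) == {"n"}
    assert blocked_vertices(line_circuit, {"x": True}) == set()


def test_blocked_never_contains_init_or_final(fork_circuit):
    for a in fork_circuit.assignments():
        blocked = blocked_vertices(fork_circuit, a)
        assert "v0" not in blocked
        assert not blocked & {"fT", "fF"}


def test_blocking_polarity_on_or_layout():
    c = naive_layout()
    all_true = {"x": True, "y": True, "z": True}
    blocked = blocked_vertices(c, all_true)
    for vid in blocked:
        lab = c.vertices[vid].label
        assert lab.negated, "with all inputs true only negated literals block"


@given(st.booleans(), st.booleans(), st.booleans())
def test_or_function_truth_table(x, y, z):
    expr = BooleanExpr("x | y | z")
    assert expr.evaluate({"x": x, "y": y, "z": z}) is (x or y or z)


def test_expression_parser_precedence_and_errors():
    e = BooleanExpr("!x & y | z")
    assert e.evaluate({"x": False, "y": True, "z": False}) is True
    assert e.evaluate({"x": True, "y": True, "z": False}) is False
    assert BooleanExpr("!(x | y)").evaluate({"x": False, "y": False}) is True
    for bad in ("", "x |", "(x", "x ? y"):
        with pytest.raises(ValueError):
            BooleanExpr(bad)


def test_function_evaluation_counts(line_circuit):
    c = naive_layout()
    falses = [a for a in c.assignments() if not evaluate_function(c, a)]
    assert len(falses) == 1  # a disjunction is false on exactly one assignment
    assert evaluate_function(line_circuit, {"x": True}) is True


@given(st.integers(0, 7), st.sampled_from(["x", "y", "z"]))
@settings(max_examples=24, deadline=None)
def test_blocking_monotone_in_flipped_variable(bits, var):
    """Flipping one input only changes vertices labelled with it."""
    c = naive_layout()
    a = {v: bool((bits >> i) & 1) for i, v in enumerate(c.inputs)}
    b = dict(a)
    b[var] = not b[var]
    delta = blocked_vertices(c, a) ^ blocked_vertices(c, b)
    assert all(c.vertices[vid].label.variable == var for vid in delta)


@pytest.mark.parametrize("fixture", ["line_circuit", "fork_circuit", "diamond_circuit"])
def test_save_load_round_trip(fixture, request, tmp_path):
    c = request.getfixturevalue(fixture)
    path = tmp_path / "c.yaml"
    save_circuit(c, path)
    again = load_circuit(path)
    assert again.structurally_equal(c)


def test_round_trip_preserves_declared_edges(tmp_path):
    doc = {
        "inputs": ["x"], "function": "x",
        "vertices": [
            {"id": "v0", "x": 1, "y": 1, "type": "INIT"},
            {"id": "n", "x": 1, "y": 4, "type": "NORM", "label": "x"},
            {"id": "f", "x": 1, "y": 7, "type": "FINAL", "out": "T"},
        ],
        "edges": [["v0", "n"], ["n", "f"]],
    }
    c = circuit_from_dict(doc)
    path = tmp_path / "c.yaml"
    save_circuit(c, path)
    assert load_circuit(path).declared_edges == c.declared_edges
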