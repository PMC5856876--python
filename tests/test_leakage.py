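"""BFS place indexing and the twelve-way transition classification."""

import pytest

from conftest import brute_force_classification, build
from walkernet.fixtures import GeneratorParams, naive_layout, optimised_layout, random_circuit
from walkernet.leakage import (
    AmbiguityError,
    TransitionType,
    classify_transitions,
    consistency_report,
    index_places,
    short_adjacency,
    successors,
)
from walkernet.petrinet import unfold


def test_line_indexing(line_circuit):
    idx, M = index_places(line_circuit)
    assert idx.index == {"v0": 1, "n": 1, "f": 1}
    assert M == {(1, 1, TransitionType.TRACK)}


def test_fork_children_get_double_indices(fork_circuit):
    idx, M = index_places(fork_circuit)
    assert idx.index["g"] == 1
    assert {idx.index["p"], idx.index["q"]} == {2, 3}
    assert (1, 2, TransitionType.FORK) in M
    assert (1, 3, TransitionType.FORK) in M
    # children inherit their index down the branch
    assert idx.index["fT"] == idx.index["p"]
    assert idx.index["fF"] == idx.index["q"]


def test_diamond_join_indexing(diamond_circuit):
    """A fork-join diamond: the join is indexed 2c by the first incoming
    branch and the second branch records its JOIN triple on arrival."""
    idx, M = index_places(diamond_circuit)
    j = idx.index["j"]
    p2, q2 = idx.index["p2"], idx.index["q2"]
    assert j in (2 * p2, 2 * q2)
    join_triples = {(i, k) for i, k, t in M if t == TransitionType.JOIN}
    assert {(p2, j), (q2, j)} == join_triples
    assert idx.index["n2"] == j  # join successor shares the join index
    assert idx.index["f"] == j


def test_successor_predicate_excludes_parent(fork_circuit):
    idx, _ = index_places(fork_circuit)
    graph = short_adjacency(fork_circuit)
    # p has index 2; its neighbours are g (index 1 = 2 // 2) and fT (index 2):
    # both excluded, so p has no successors left
    assert successors("p", idx, graph) == []


def test_every_vertex_indexed_on_fixtures():
    for circuit in (naive_layout(), optimised_layout()):
        idx, _ = index_places(circuit)
        assert all(i > 0 for i in idx.index.values())
        assert idx.index[circuit.init_vertex.id] == 1


def test_ambiguity_on_overdense_vertex():
    # a 2x2 cluster gives four short neighbours to each anchorage
    doc = {
        "inputs": ["x"], "function": "x",
        "vertices": [
            {"id": "v0", "x": 5, "y": 1, "type": "INIT"},
            {"id": "a", "x": 5, "y": 3, "type": "NORM"},
            {"id": "b", "x": 5, "y": 5, "type": "NORM"},
            {"id": "c", "x": 7, "y": 3, "type": "NORM"},
            {"id": "d", "x": 7, "y": 5, "type": "NORM"},
            {"id": "f", "x": 5, "y": 8, "type": "FINAL", "out": "T"},
        ],
    }
    with pytest.raises(AmbiguityError) as err:
        index_places(build(doc))
    assert err.value.vertex_id


def test_classification_partition(params):
    circuit = random_circuit(GeneratorParams(seed=11, allow_joins=True))
    net = unfold(circuit, params)
    idx, M = index_places(circuit, params)
    table = classify_transitions(net, idx, M)
    assert table.total == len(net.step_transitions())
    assert set(table.labels) == {t.id for t in net.step_transitions()}
    assert int(table.counts.loc[:, "Sigma"].sum()) == table.total


def test_same_index_pairs_are_track(params):
    circuit = naive_layout()
    net = unfold(circuit, params)
    idx, M = index_places(circuit, params)
    table = classify_transitions(net, idx, M)
    for t in net.step_transitions():
        if idx.index[t.source_vertex] == idx.index[t.target_vertex]:
            assert table.labels[t.id][0] == TransitionType.TRACK


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("joins", [False, True])
def test_classification_matches_brute_force(seed, joins, params):
    """The net-based classifier agrees with an independent pairwise
    banding + lookup classifier on generated circuits."""
    circuit = random_circuit(GeneratorParams(seed=seed, allow_joins=joins))
    net = unfold(circuit, params)
    idx, M = index_places(circuit, params)
    table = classify_transitions(net, idx, M)
    oracle = brute_force_classification(circuit, idx, M, params)
    got = {
        (t.source_vertex, t.target_vertex): table.labels[t.id]
        for t in net.step_transitions()
    }
    assert got == oracle


def test_reflection_leaves_counts_invariant(params):
    """Mirroring the layout swaps which fork child receives the even
    index; the classification counts must not change."""
    for seed in (0, 4, 9):
        circuit = random_circuit(GeneratorParams(seed=seed))
        max_x = max(v.position.x for v in circuit.vertices.values())
        mirrored = build({
            "inputs": list(circuit.inputs),
            "function": circuit.function.text,
            "vertices": [
                {
                    "id": v.id,
                    "x": max_x + 1 - v.position.x,
                    "y": v.position.y,
                    "type": v.vtype,
                    **({"label": str(v.label)} if not v.label.is_epsilon else {}),
                    **({"out": "T" if v.output else "F"}
                       if v.vtype == "FINAL" else {}),
                }
                for v in circuit.vertices.values()
            ],
        })
        t1 = classify_transitions(
            unfold(circuit, params), *index_places(circuit, params))
        t2 = classify_transitions(
            unfold(mirrored, params), *index_places(mirrored, params))
        assert t1.counts.equals(t2.counts)


def test_generated_tree_leaks_confined_to_fork_cones(params):
    """With branch separation beyond the long radius, no SHORT leaks
    exist and every remaining leak connects the two sibling sub-circuits
    of some fork (geometrically unavoidable near the fan-out)."""
    circuit = random_circuit(GeneratorParams(seed=5, branch_separation=20))
    net = unfold(circuit, params)
    idx, M = index_places(circuit, params)
    table = classify_transitions(net, idx, M)
    assert table.cell(TransitionType.LEAK, "SHORT") == 0
    for t in net.step_transitions():
        if table.labels[t.id][0] == TransitionType.LEAK:
            i, j = sorted((idx.index[t.source_vertex], idx.index[t.target_vertex]))
            # sibling branches of one fork carry indices 2c and 2c+1
            assert j == i + 1 and i % 2 == 0


def test_consistency_report(params):
    idx, M = index_places(naive_layout(), params)
    notes = consistency_report(idx, M)
    # the naive layout's tight join produces a JOIN triple with a larger
    # target index, flagged (advisory) by the arithmetic pattern check
    assert isinstance(notes, list)
    assert not any("TRACK" in n and "violates" in n for n in notes)


def test_table_text_and_diff(params):
    na, op = naive_layout(), optimised_layout()
    ta = classify_transitions(unfold(na, params), *index_places(na, params))
    to = classify_transitions(unfold(op, params), *index_places(op, params))
    text = ta.to_text()
    assert "Track" in text and "Σ" in text
    diff = ta.diff(to)
    assert int(diff.loc["LEAK", "SHORT"]) == 8 - 2
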