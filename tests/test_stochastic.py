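"""Simulation estimators and the uniformisation oracle."""

import math

import numpy as np
import pytest

from walkernet.circuit import evaluate_function
from walkernet.fixtures import GeneratorParams, random_circuit
from walkernet.leakage import classify_transitions, index_places
from walkernet.petrinet import apply_assignment, unfold
from walkernet.stochastic import (
    SimConfig,
    Status,
    estimate,
    exact_transient,
    simulate_run,
)

TAU = 12_000.0
KS = 0.009


def _pipeline(circuit):
    net = unfold(circuit)
    idx, M = index_places(circuit)
    labels = classify_transitions(net, idx, M).labels
    return net, labels


def _exact_average(circuit, net, labels, tau=TAU):
    fin = cor = dead = rew = 0.0
    assignments = circuit.assignments()
    for a in assignments:
        correct = {
            v.id for v in circuit.final_vertices
            if v.output == evaluate_function(circuit, a)
        }
        ex = exact_transient(
            apply_assignment(net, circuit, a), tau,
            correct_finals=correct, labels=labels,
        )
        fin += ex.final
        cor += ex.correct
        dead += ex.dead
        rew += ex.total_reward
    n = len(assignments)
    return fin / n, cor / n, dead / n, rew / n


def test_single_step_closed_form(single_step_circuit):
    net, labels = _pipeline(single_step_circuit)
    table = estimate(single_step_circuit, net, labels,
                     SimConfig(runs_per_assignment=3000, seed=9))
    expected = 1 - math.exp(-KS * TAU)  # numerically 1
    assert table.averaged["FINAL"] == pytest.approx(expected, abs=1e-3)
    assert table.expected_steps == pytest.approx(1.0, abs=1e-9)
    assert table.pmf[1] == pytest.approx(table.averaged["FINAL"])
    assert (table.pmf[2:] == 0).all()


def test_single_run_outcome(single_step_circuit):
    net, labels = _pipeline(single_step_circuit)
    rng = np.random.default_rng(4)
    out = simulate_run(apply_assignment(net, single_step_circuit, {"x": True}),
                       rng, labels)
    assert out.status == Status.FINAL
    assert out.final_vertex == "f"
    assert out.steps_total == 1
    assert out.arrival_time is not None and out.arrival_time <= TAU
    assert sum(out.steps_by_class.values()) == out.steps_total


def test_mean_arrival_time_is_exponential(single_step_circuit):
    net, labels = _pipeline(single_step_circuit)
    anet = apply_assignment(net, single_step_circuit, {"x": True})
    times = []
    for i in range(4000):
        out = simulate_run(anet, np.random.default_rng(i), labels)
        times.append(out.arrival_time)
    assert np.mean(times) == pytest.approx(1 / KS, rel=0.1)


def test_line_blocked_long_route_closed_form(line_circuit):
    """Blocking forced to succeed leaves only the long direct step:
    P[FINAL] = 1 - exp(-k_s/100 * tau) = 1 - exp(-1.08)."""
    net = unfold(line_circuit, block_weight=1.0)
    idx, M = index_places(line_circuit)
    labels = classify_transitions(net, idx, M).labels
    ex = exact_transient(apply_assignment(net, line_circuit, {"x": False}), TAU,
                         correct_finals=set(), labels=labels)
    assert ex.final == pytest.approx(1 - math.exp(-1.08), abs=1e-9)
    assert ex.dead == 0.0


def test_line_default_blocking_is_a_mixture(line_circuit):
    """0.7/0.3 blocking mixes the long-only chain with the two-step
    route; cross-checked against a dense matrix exponential."""
    from scipy.linalg import expm
    net, labels = _pipeline(line_circuit)
    ex = exact_transient(apply_assignment(net, line_circuit, {"x": False}), TAU,
                         correct_finals=set(), labels=labels)
    p_long = 1 - math.exp(-KS / 100 * TAU)
    q = np.array([
        [-(KS + KS / 100), KS, KS / 100],
        [0.0, -KS, KS],
        [0.0, 0.0, 0.0],
    ])
    p_two = expm(q * TAU)[0, 2]
    assert ex.final == pytest.approx(0.7 * p_long + 0.3 * p_two, abs=1e-8)


def test_estimator_invariants(fork_circuit):
    net, labels = _pipeline(fork_circuit)
    table = estimate(fork_circuit, net, labels,
                     SimConfig(runs_per_assignment=1500, seed=2))
    avg = table.averaged
    assert avg["FINAL"] + avg["DEADLOCK"] + avg["IN_TRANSIT"] == pytest.approx(1.0)
    assert avg["CORRECT"] <= avg["FINAL"]
    assert avg["CONDITION"] * avg["FINAL"] == pytest.approx(avg["CORRECT"])
    # class rewards add up to the total reward (shared trajectories)
    class_sum = table.rewards.drop(index=[("TOTAL", "ALL")])["mean"].sum()
    assert class_sum == pytest.approx(table.expected_steps)
    # the PMF accounts for exactly the final-reaching runs
    assert table.pmf.sum() + table.pmf_overflow == pytest.approx(avg["FINAL"])
    cdf = table.cdf
    assert (np.diff(cdf) >= -1e-12).all()
    assert cdf[-1] <= avg["FINAL"] + 1e-12


def test_reproducibility(fork_circuit):
    net, labels = _pipeline(fork_circuit)
    cfg = SimConfig(runs_per_assignment=400, seed=123)
    t1 = estimate(fork_circuit, net, labels, cfg)
    t2 = estimate(fork_circuit, net, labels, cfg)
    assert t1.averaged.equals(t2.averaged)
    assert t1.rewards.equals(t2.rewards)
    assert (t1.pmf == t2.pmf).all()


def test_tau_zero_limit(fork_circuit):
    net, labels = _pipeline(fork_circuit)
    table = estimate(fork_circuit, net, labels,
                     SimConfig(tau=1e-9, runs_per_assignment=500, seed=1))
    assert table.averaged["FINAL"] == 0.0
    assert table.averaged["DEADLOCK"] == 0.0  # every route is initially open


def test_ssa_matches_oracle_small_circuit():
    p = GeneratorParams(n_inputs=1, max_depth=1, track_length=(1, 1),
                        branch_separation=4, seed=0)
    circuit = random_circuit(p)
    net, labels = _pipeline(circuit)
    table = estimate(circuit, net, labels,
                     SimConfig(runs_per_assignment=4000, seed=77))
    fin, cor, dead, rew = _exact_average(circuit, net, labels)
    for key, exact in (("FINAL", fin), ("CORRECT", cor), ("DEADLOCK", dead)):
        se = max(table.averaged[f"se_{key}"], 1e-6)
        assert abs(table.averaged[key] - exact) < 4 * se
    se_total = max(float(table.rewards.loc[("TOTAL", "ALL"), "se"]), 1e-6)
    assert abs(table.expected_steps - rew) < 4 * se_total
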