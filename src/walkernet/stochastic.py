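"""Stochastic simulation and exact transient analysis of walker nets.

The unfolded GSPN has a very particular structure: after the immediate
blocking conflicts are resolved at time zero, the remaining process is a
continuous-time jump process of a single walker over the anchorages,
with the set of available anchorages shrinking (burnt-bridges) or
constant (unguided).  The simulator exploits this: blocking outcomes are
independent Bernoulli draws per blocked anchorage, and each run is a
race of exponential clocks over the walker's in-range available
neighbours.  Runs absorb at the first final-anchorage visit (the final
self-loops carry no reward and finals cannot be left, so never
simulating them is observationally equivalent for all shipped queries),
at a dead marking, or at the time horizon.

Estimated quantities:

* transient probabilities — FINAL, CORRECT, DEADLOCK and the conditional
  CORRECT/FINAL ratio at the horizon, averaged over input assignments;
* expected impulse rewards — mean accumulated step counts, in total and
  per (structural type, distance band) class;
* performability — PMF/CDF of the number of steps taken by walkers that
  reach a final anchorage.

For small nets :func:`exact_transient` provides an independent oracle:
it branches analytically over the blocking outcomes and computes the
transient distribution and accumulated impulse rewards of each branch's
CTMC by uniformisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import poisson

from .circuit import Circuit, VertexType, blocked_vertices, evaluate_function
from .geometry import StepCategory
from .leakage import TransitionType
from .petrinet import (
    GSPN,
    PlaceKind,
    Role,
    Semantics,
    TransitionKind,
)

__all__ = [
    "SimConfig",
    "RunOutcome",
    "EstimateTable",
    "ExactResult",
    "CompiledNet",
    "simulate_run",
    "estimate",
    "transient_estimates",
    "expected_rewards",
    "step_distribution",
    "exact_transient",
]

CLASSES = [
    (t, b) for t in TransitionType.ALL for b in StepCategory.BANDS
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation configuration.

    tau: time horizon in seconds (200 min by default);
    runs_per_assignment: trajectories per input assignment;
    seed: root seed, spawning one independent substream per
    (assignment, run) pair; assignments: "ALL" or an explicit list;
    n_max: largest step count tracked individually by the PMF/CDF.
    """

    tau: float = 12_000.0
    runs_per_assignment: int = 20_000
    seed: int = 0
    assignments: str | list[dict[str, bool]] = "ALL"
    n_max: int = 60

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.runs_per_assignment < 1:
            raise ValueError("need at least one run per assignment")
        if self.n_max < 0:
            raise ValueError("n_max must be non-negative")


@dataclass
class RunOutcome:
    status: str  # FINAL | DEAD | IN_TRANSIT
    final_vertex: str | None
    arrival_time: float | None
    steps_total: int
    steps_by_class: dict[tuple[str, str], int]


class Status:
    FINAL = "FINAL"
    DEAD = "DEAD"
    IN_TRANSIT = "IN_TRANSIT"


# --------------------------------------------------------------------------
# Compilation of an unfolded net into the walker-level view.


@dataclass
class CompiledNet:
    """Array view of an unfolded walker net for fast trajectory sampling."""

    vertex_ids: list[str]                 # index -> vertex id
    start: int                            # walker's initial anchorage
    finals: np.ndarray                    # bool per vertex
    out_targets: list[np.ndarray]         # per vertex: target indices
    out_rates: list[np.ndarray]           # per vertex: rates
    out_class: list[np.ndarray]           # per vertex: class index into CLASSES
    block_vertices: list[int]             # vertices with a BLOCK/FAIL pair
    block_weight: dict[int, float]        # success probability per vertex
    burnt_bridges: bool

    @classmethod
    def from_net(
        cls,
        net: GSPN,
        labels: dict[str, tuple[str, str]] | None = None,
    ) -> "CompiledNet":
        anchor = [p for p in net.places.values() if p.kind == PlaceKind.ANCHORAGE]
        vertex_ids = [p.vertex_ref for p in anchor]
        vindex = {vid: i for i, vid in enumerate(vertex_ids)}
        start = None
        for p in anchor:
            if net.m0[p.id] == 2:
                start = vindex[p.vertex_ref]
        if start is None:
            raise ValueError("net has no walker token (no anchorage with m0 = 2)")
        finals = np.zeros(len(vertex_ids), dtype=bool)
        outs: list[list[tuple[int, float, int]]] = [[] for _ in vertex_ids]
        class_index = {c: k for k, c in enumerate(CLASSES)}
        for t in net.transitions.values():
            if t.role == Role.LOOP:
                finals[vindex[t.vertex_ref]] = True
            elif t.role in (Role.STEP, Role.FINALSTEP):
                u, v = vindex[t.source_vertex], vindex[t.target_vertex]
                if labels is not None and t.id in labels:
                    cls_key = labels[t.id]
                else:
                    cls_key = (TransitionType.TRACK, t.category)
                outs[u].append((v, t.rate, class_index[cls_key]))
        block_vertices: list[int] = []
        block_weight: dict[int, float] = {}
        for t in net.transitions.values():
            if t.role == Role.BLOCK:
                i = vindex[t.vertex_ref]
                block_vertices.append(i)
                block_weight[i] = t.weight
        block_vertices.sort()
        return cls(
            vertex_ids=vertex_ids,
            start=start,
            finals=finals,
            out_targets=[np.array([o[0] for o in lst], dtype=np.intp) for lst in outs],
            out_rates=[np.array([o[1] for o in lst]) for lst in outs],
            out_class=[np.array([o[2] for o in lst], dtype=np.intp) for lst in outs],
            block_vertices=block_vertices,
            block_weight=block_weight,
            burnt_bridges=net.semantics == Semantics.BURNT_BRIDGES,
        )

    def blocked_from_marking(self, net: GSPN) -> list[int]:
        """Vertices whose BLOCKCTRL place is marked in the net's m0."""
        vindex = {vid: i for i, vid in enumerate(self.vertex_ids)}
        out = []
        for p in net.places.values():
            if p.kind == PlaceKind.BLOCKCTRL and net.m0.get(p.id, 0) > 0:
                out.append(vindex[p.vertex_ref])
        return sorted(out)


def _run(
    compiled: CompiledNet,
    to_block: list[int],
    rng: np.random.Generator,
    tau: float,
) -> tuple[str, int, float | None, np.ndarray]:
    """One trajectory.  Returns (status, final vertex index or -1,
    arrival time, per-class step counts)."""
    n = len(compiled.vertex_ids)
    avail = np.ones(n, dtype=bool)
    for v in to_block:
        if rng.random() < compiled.block_weight[v]:
            avail[v] = False
    pos = compiled.start
    t = 0.0
    counts = np.zeros(len(CLASSES), dtype=np.int64)
    burnt = compiled.burnt_bridges
    while True:
        targets = compiled.out_targets[pos]
        rates = compiled.out_rates[pos]
        mask = avail[targets]
        total = rates[mask].sum()
        if total <= 0.0:
            return Status.DEAD, -1, None, counts
        t += rng.exponential(1.0 / total)
        if t > tau:
            return Status.IN_TRANSIT, -1, None, counts
        live_rates = rates[mask]
        choice = np.searchsorted(
            np.cumsum(live_rates), rng.random() * total, side="right"
        )
        choice = min(choice, len(live_rates) - 1)
        live_targets = targets[mask]
        live_class = compiled.out_class[pos][mask]
        nxt = live_targets[choice]
        counts[live_class[choice]] += 1
        if burnt:
            avail[pos] = False
        pos = nxt
        if compiled.finals[pos]:
            return Status.FINAL, pos, t, counts


def simulate_run(
    net: GSPN,
    rng: np.random.Generator,
    labels: dict[str, tuple[str, str]] | None = None,
) -> RunOutcome:
    """Simulate one trajectory of an assignment-applied net.

    Immediate blocking conflicts are resolved at time zero as independent
    Bernoulli draws with the BLOCK weight; the walker then performs its
    exponential-clock jump process until absorption or the default
    horizon of a :class:`SimConfig`.
    """
    compiled = CompiledNet.from_net(net, labels)
    to_block = compiled.blocked_from_marking(net)
    status, fin, arrival, counts = _run(
        compiled, to_block, rng, SimConfig().tau
    )
    return RunOutcome(
        status=status,
        final_vertex=compiled.vertex_ids[fin] if fin >= 0 else None,
        arrival_time=arrival,
        steps_total=int(counts.sum()),
        steps_by_class={
            CLASSES[k]: int(c) for k, c in enumerate(counts) if c
        },
    )


# --------------------------------------------------------------------------
# Ensemble estimation.


@dataclass
class EstimateTable:
    """Simulation estimates with normal-approximation standard errors.

    ``per_assignment`` carries one row per input assignment;
    ``averaged`` the uniform average over assignments.  ``rewards`` holds
    the expected accumulated impulse rewards per transition class plus
    the total; ``pmf``/``cdf`` the step-count distribution of runs that
    reached a final anchorage (index = number of steps; mass above
    ``n_max`` is reported in ``pmf_overflow``).
    """

    per_assignment: pd.DataFrame
    averaged: pd.Series
    rewards: pd.DataFrame
    rewards_by_assignment: dict[str, pd.DataFrame]
    pmf: np.ndarray
    cdf: np.ndarray
    pmf_overflow: float
    class_pmf: dict[tuple[str, str], np.ndarray]
    runs_per_assignment: int
    tau: float
    seed: int

    @property
    def expected_steps(self) -> float:
        return float(self.rewards.loc[("TOTAL", "ALL"), "mean"])


def _assignment_key(a: dict[str, bool]) -> str:
    return ",".join(f"{k}={'T' if v else 'F'}" for k, v in sorted(a.items()))


def estimate(
    circuit: Circuit,
    net: GSPN,
    labels: dict[str, tuple[str, str]],
    cfg: SimConfig,
) -> EstimateTable:
    """Run the full ensemble and derive all shipped estimators from the
    shared trajectories (so the class rewards sum exactly to the total
    reward, and the PMF sums exactly to the FINAL estimate)."""
    compiled = CompiledNet.from_net(net, labels)
    vindex = {vid: i for i, vid in enumerate(compiled.vertex_ids)}
    outputs = {
        vindex[v.id]: bool(v.output) for v in circuit.final_vertices
    }
    if cfg.assignments == "ALL":
        assignments = circuit.assignments()
    else:
        assignments = list(cfg.assignments)
    R = cfg.runs_per_assignment
    rows = []
    reward_rows: dict[str, pd.DataFrame] = {}
    sum_counts = np.zeros(len(CLASSES))
    sumsq_counts = np.zeros(len(CLASSES))
    sum_total = 0.0
    sumsq_total = 0.0
    hist = np.zeros(cfg.n_max + 1, dtype=np.int64)
    hist_overflow = 0
    class_hist = np.zeros((len(CLASSES), cfg.n_max + 1), dtype=np.int64)

    for a_idx, a in enumerate(assignments):
        expected = evaluate_function(circuit, a)
        to_block = sorted(
            vindex[vid] for vid in blocked_vertices(circuit, a)
        )
        n_final = n_correct = n_dead = 0
        a_sum = np.zeros(len(CLASSES))
        a_sumsq = np.zeros(len(CLASSES))
        for r_idx in range(R):
            ss = np.random.SeedSequence(
                entropy=cfg.seed, spawn_key=(a_idx, r_idx)
            )
            rng = np.random.Generator(np.random.PCG64(ss))
            status, fin, _, counts = _run(compiled, to_block, rng, cfg.tau)
            total = int(counts.sum())
            a_sum += counts
            a_sumsq += counts.astype(float) ** 2
            sum_total += total
            sumsq_total += float(total) ** 2
            if status == Status.FINAL:
                n_final += 1
                if outputs[fin] == expected:
                    n_correct += 1
                if total <= cfg.n_max:
                    hist[total] += 1
                else:
                    hist_overflow += 1
                for k in range(len(CLASSES)):
                    c = counts[k]
                    if c <= cfg.n_max:
                        class_hist[k, c] += 1
            elif status == Status.DEAD:
                n_dead += 1
        sum_counts += a_sum
        sumsq_counts += a_sumsq
        p_final = n_final / R
        p_correct = n_correct / R
        p_dead = n_dead / R
        rows.append(
            {
                "assignment": _assignment_key(a),
                "FINAL": p_final,
                "CORRECT": p_correct,
                "DEADLOCK": p_dead,
                "IN_TRANSIT": 1.0 - p_final - p_dead,
                "CONDITION": (p_correct / p_final) if p_final > 0 else np.nan,
                "se_FINAL": math.sqrt(p_final * (1 - p_final) / R),
                "se_CORRECT": math.sqrt(p_correct * (1 - p_correct) / R),
                "se_DEADLOCK": math.sqrt(p_dead * (1 - p_dead) / R),
            }
        )
        mean_a = a_sum / R
        se_a = np.sqrt(
            np.maximum(a_sumsq / R - mean_a**2, 0.0) / max(R - 1, 1)
        )
        df_a = pd.DataFrame(
            {"mean": mean_a, "se": se_a},
            index=pd.MultiIndex.from_tuples(CLASSES),
        )
        reward_rows[_assignment_key(a)] = df_a

    per_assignment = pd.DataFrame(rows).set_index("assignment")
    A = len(assignments)
    N = A * R
    avg = {}
    for col in ("FINAL", "CORRECT", "DEADLOCK", "IN_TRANSIT"):
        avg[col] = float(per_assignment[col].mean())
    for col in ("FINAL", "CORRECT", "DEADLOCK"):
        avg[f"se_{col}"] = (
            float(np.sqrt((per_assignment[f"se_{col}"] ** 2).sum()) / A)
        )
    if avg["FINAL"] > 0 and avg["CORRECT"] > 0:
        avg["CONDITION"] = avg["CORRECT"] / avg["FINAL"]
        # delta method; CORRECT ⊆ FINAL makes the covariance p_c(1 - p_f)
        var_c = avg["se_CORRECT"] ** 2
        var_f = avg["se_FINAL"] ** 2
        cov = avg["CORRECT"] * (1 - avg["FINAL"]) / N
        ratio = avg["CONDITION"]
        avg["se_CONDITION"] = ratio * math.sqrt(
            max(
                var_c / avg["CORRECT"] ** 2
                + var_f / avg["FINAL"] ** 2
                - 2 * cov / (avg["CORRECT"] * avg["FINAL"]),
                0.0,
            )
        )
    elif avg["FINAL"] > 0:
        avg["CONDITION"] = 0.0
        avg["se_CONDITION"] = 0.0
    else:
        avg["CONDITION"] = np.nan
        avg["se_CONDITION"] = np.nan
    averaged = pd.Series(avg)

    mean_counts = sum_counts / N
    se_counts = np.sqrt(
        np.maximum(sumsq_counts / N - mean_counts**2, 0.0) / max(N - 1, 1)
    )
    mean_total = sum_total / N
    se_total = math.sqrt(
        max(sumsq_total / N - mean_total**2, 0.0) / max(N - 1, 1)
    )
    rewards = pd.DataFrame(
        {"mean": mean_counts, "se": se_counts},
        index=pd.MultiIndex.from_tuples(CLASSES),
    )
    rewards.loc[("TOTAL", "ALL"), :] = [mean_total, se_total]

    pmf = hist / N
    cdf = np.cumsum(pmf)
    class_pmf = {
        CLASSES[k]: class_hist[k] / N for k in range(len(CLASSES))
    }
    return EstimateTable(
        per_assignment=per_assignment,
        averaged=averaged,
        rewards=rewards,
        rewards_by_assignment=reward_rows,
        pmf=pmf,
        cdf=cdf,
        pmf_overflow=hist_overflow / N,
        class_pmf=class_pmf,
        runs_per_assignment=R,
        tau=cfg.tau,
        seed=cfg.seed,
    )


def transient_estimates(
    circuit: Circuit, net: GSPN, labels, cfg: SimConfig
) -> EstimateTable:
    """Transient FINAL/CORRECT/DEADLOCK/CONDITION probabilities at the
    horizon (finals are absorbing, so "at tau" coincides with "by tau")."""
    return estimate(circuit, net, labels, cfg)


def expected_rewards(
    circuit: Circuit, net: GSPN, labels, cfg: SimConfig
) -> EstimateTable:
    """Expected accumulated impulse rewards (step counts) per class."""
    return estimate(circuit, net, labels, cfg)


def step_distribution(
    circuit: Circuit, net: GSPN, labels, cfg: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """PMF and CDF of the number of steps of final-reaching runs."""
    table = estimate(circuit, net, labels, cfg)
    return table.pmf, table.cdf


# --------------------------------------------------------------------------
# Exact oracle via uniformisation.


@dataclass
class ExactResult:
    final: float
    correct: float
    dead: float
    rewards: dict[tuple[str, str], float]
    total_reward: float
    max_states: int


def _uniformise(
    Q: sparse.csr_matrix, pi0: np.ndarray, tau: float, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Transient distribution pi(tau) and accumulated occupancy
    L(tau) = ∫_0^tau pi(t) dt by the uniformisation series."""
    n = Q.shape[0]
    exit_rates = -Q.diagonal()
    lam = float(exit_rates.max()) * 1.02 + 1e-12
    P = sparse.eye(n, format="csr") + Q / lam
    lt = lam * tau
    K = int(poisson.isf(tol, lt)) + 1 if lt > 0 else 1
    pmf = poisson.pmf(np.arange(K + 1), lt)
    sf = poisson.sf(np.arange(K + 1), lt)
    v = pi0.copy()
    pi_tau = pmf[0] * v
    occupancy = (sf[0] / lam) * v
    for k in range(1, K + 1):
        v = v @ P
        pi_tau += pmf[k] * v
        occupancy += (sf[k] / lam) * v
    return pi_tau, occupancy


def exact_transient(
    net: GSPN,
    tau: float,
    correct_finals: set[str] | None = None,
    labels: dict[str, tuple[str, str]] | None = None,
    limit: int = 10_000,
) -> ExactResult:
    """Exact FINAL/CORRECT/DEADLOCK probabilities and expected class
    rewards at ``tau`` for an assignment-applied net.

    Branches analytically over the independent Bernoulli blocking
    outcomes, builds each branch's CTMC over (position, burnt-set)
    states, and applies uniformisation.  Intended as a testing oracle for
    small nets; raises when the state space exceeds ``limit`` or more
    than 16 anchorages are to be blocked.
    """
    compiled = CompiledNet.from_net(net, labels)
    to_block = compiled.blocked_from_marking(net)
    if len(to_block) > 16:
        raise ValueError("too many blocked anchorages for exact branching")
    correct_idx = (
        {i for i, vid in enumerate(compiled.vertex_ids) if vid in correct_finals}
        if correct_finals is not None
        else set()
    )
    total_final = total_correct = total_dead = 0.0
    rewards = np.zeros(len(CLASSES))
    max_states = 0
    burnt_bridges = compiled.burnt_bridges
    for mask in range(1 << len(to_block)):
        prob = 1.0
        blocked = set()
        for b, v in enumerate(to_block):
            w = compiled.block_weight[v]
            if (mask >> b) & 1:
                prob *= w
                blocked.add(v)
            else:
                prob *= 1.0 - w
        if prob == 0.0:
            continue
        # Enumerate CTMC states for this blocking outcome.
        start = (compiled.start, frozenset())
        states = {start: 0}
        order = [start]
        edges: list[tuple[int, int, float, int]] = []  # (src, dst, rate, class)
        absorbing_final: set[int] = set()
        absorbing_dead: set[int] = set()
        queue = [start]
        while queue:
            state = queue.pop()
            si = states[state]
            pos, burnt = state
            if compiled.finals[pos]:
                absorbing_final.add(si)
                continue
            moved = False
            nxt_burnt = burnt | {pos} if burnt_bridges else burnt
            for tgt, rate, kls in zip(
                compiled.out_targets[pos],
                compiled.out_rates[pos],
                compiled.out_class[pos],
            ):
                if tgt in blocked or tgt in burnt:
                    continue
                moved = True
                nxt = (int(tgt), nxt_burnt)
                if nxt not in states:
                    states[nxt] = len(order)
                    order.append(nxt)
                    if len(order) > limit:
                        raise RuntimeError(
                            f"exact oracle state limit {limit} exceeded"
                        )
                    queue.append(nxt)
                edges.append((si, states[nxt], float(rate), int(kls)))
            if not moved:
                absorbing_dead.add(si)
        n = len(order)
        max_states = max(max_states, n)
        rows, cols, vals = [], [], []
        for src, dst, rate, _ in edges:
            rows += [src, src]
            cols += [dst, src]
            vals += [rate, -rate]
        Q = sparse.csr_matrix(
            sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
        )
        pi0 = np.zeros(n)
        pi0[0] = 1.0
        pi_tau, occupancy = _uniformise(Q, pi0, tau)
        fin = sum(pi_tau[i] for i in absorbing_final)
        cor = sum(
            pi_tau[i]
            for i in absorbing_final
            if order[i][0] in correct_idx
        )
        ded = sum(pi_tau[i] for i in absorbing_dead)
        total_final += prob * fin
        total_correct += prob * cor
        total_dead += prob * ded
        # E[# class-c firings] = sum over states of occupancy * class rate
        class_rate = np.zeros((n, len(CLASSES)))
        for src, _, rate, kls in edges:
            class_rate[src, kls] += rate
        rewards += prob * (occupancy @ class_rate)
    return ExactResult(
        final=total_final,
        correct=total_correct,
        dead=total_dead,
        rewards={CLASSES[k]: float(r) for k, r in enumerate(rewards)},
        total_reward=float(rewards.sum()),
        max_states=max_states,
    )
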