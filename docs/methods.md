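# Methods

## Model

A walker circuit is a grid-embedded DSD graph: anchorages (INIT, NORM,
FORK, JOIN, FINAL) at 1-based integer positions (x = row, y = column),
non-final anchorages labelled with a literal over the input variables or
with ε, finals carrying a truth value. Exactly one INIT exists and is
ε-labelled. The intended edge set may be declared explicitly (it is then
checked against the degree rules: INIT and FINAL degree 1, NORM 2,
junctions 3); by default the intended adjacency is taken to be the
short-distance neighbourhood of the embedding, because every analysis
here derives steps purely from distance.

### Stepping rates

A walker at anchorage u may step to any anchorage v at lattice-Euclidean
distance d(u, v) ≤ dL, at rate

    k(u→v) = k_s        if d ≤ dS      ("short")
           = k_s / 50   if dS < d ≤ dM ("medium")
           = k_s / 100  if dM < d ≤ dL ("long")

with defaults dS, dM, dL = 3, 5, 8 grid units and k_s = 0.009 s⁻¹. With
a grid pitch of half the mean anchorage spacing (3.1 nm), dS and dM
reproduce the physical cutoffs 1.5·d_a and 2.5·d_a exactly and dL = 8
corresponds to 24.8 nm, matching the 24 nm maximum interaction distance
to within one lattice site. Band membership is decided in exact integer
arithmetic on squared distances (d ≤ r ⇔ d² ≤ r²); no floating point
enters classification. For dS = 3 the short neighbourhood equals the
union of the L1 ≤ 3 diamond and the L∞ ≤ 2 square, the classical
discrete realisation of the Euclidean disc; we use lattice-Euclidean
membership for all three radii, since that union is exactly the lattice
disc and no analogous published construction exists for radii 5 and 8.

### GSPN encoding

One place per anchorage; 1 token means "may be visited", a second token
is the walker (initially on INIT). A step u→v consumes two tokens from u
and one from v and returns two to v; under burnt-bridges semantics u's
availability token is not returned, so no anchorage is visited twice.
Unguided semantics (supported but not the default) returns it. Finals
have no outgoing steps and carry a rate-k_s self-loop so that a finished
walk is not a dead state. Every labelled anchorage w gets a control
place B_w and an immediate conflict pair: BLOCK (weight 0.7) consumes
B_w's token and w's availability token; FAIL (weight 0.3) consumes only
B_w's. An input assignment marks B_w exactly for the anchorages whose
literal is false. Because each conflict is local, the blocking outcome
is an independent Bernoulli(0.7) draw per blocked anchorage, which the
simulator exploits.

Nets are 2-bounded by construction. One modelling artifact is worth
stating: in the *time-free* reachability graph the interleaving in which
the walker steps onto an anchorage before that anchorage's BLOCK fires
lets the block consume one token of the walker's two-token stack, so
walker conservation ("exactly one doubly marked anchorage after all
immediates fired") holds on the priority (GSPN) reachability graph but
not on the unprioritised one. This is inherent to the fault-model
encoding (block removes one availability token) and has no stochastic
consequence, since immediates always pre-empt timed transitions.

### Leakage identification

The intended computation is recovered from the short-distance sub-graph
by a FIFO breadth-first indexing that starts at INIT with index 1 and
borrows the array embedding of binary trees: a fork with index c assigns
2c and 2c+1 to its two successors (first successor in lexicographic
(x, y) position order receives 2c); track successors inherit their
predecessor's index; a join is assigned twice its discoverer's index and
later incoming tracks record join triples; track anchorages with three
short neighbours handle corner shortcuts and emit LEAK triples for
indexed-but-unmarked neighbours. The successor predicate excludes
neighbours with the same index and the integer-halved parent index, so
the search never walks backwards. Configurations outside the supported
cases (e.g. four short neighbours, junction degree defects) raise an
AmbiguityError naming the offending anchorage; the CLI maps it to a
distinct exit code.

Two deliberate generalisations close gaps in the published case list,
both exercised by the packaged layouts and by unit tests:

* a track anchorage whose successor is an already-indexed JOIN records
  the join triple whatever the relative index order (the literal rule
  only covers "successor index smaller", which a fork–join diamond
  violates);
* a join reached before one of its incoming tracks adopts the
  still-unindexed neighbour as a provisional successor (the published
  "postponed decision"); when the true track arrives with a larger
  index, the override-and-re-queue case repairs the provisional index.
  The provisional TRACK triple left in M is harmless because its index
  pair also occurs legitimately on the join's own track.

Classification looks up each stepping transition's (source index, target
index) pair in M, in either orientation; misses are leaks. When several
triples share a pair, junction evidence outranks track evidence
(FORK > JOIN > TRACK > LEAK) — deterministic, and consistent with the
arithmetic patterns the types obey. An advisory consistency report
flags triples violating those patterns without overriding the lookup.

## Analyses

**Qualitative.** Breadth-first marking exploration per input assignment,
in TIMEFREE mode (both interleavings of immediate/timed conflicts) or
PRIORITY mode (immediates first — the stochastic sub-graph), with a
configurable state limit (default 5·10⁵) that raises rather than
truncates. Properties: bound = maximum token count; dead states =
terminal markings; reversibility = strong connectivity; liveness =
membership of every transition in all terminal SCCs (via networkx).
Burnt-bridges circuits are 2-bounded, not reversible, not live, and
acyclic up to final self-loops.

**Stochastic.** Trajectories resolve blocking at t = 0 by Bernoulli
draws, then race exponential clocks over the walker's in-range available
neighbours; runs absorb at the first final (finals cannot be left and
their self-loops carry no reward, so stopping there is observationally
equivalent for every shipped query), at a dead marking, or at the
horizon τ (default 12 000 s). Estimators, all computed from one shared
ensemble so their internal identities hold exactly: FINAL, CORRECT
(final whose output equals f(a)), DEADLOCK, the ratio CONDITION =
CORRECT/FINAL; expected accumulated impulse rewards per transition class
(one reward unit per fired stepping transition; LOOP/BLOCK/FAIL carry
none) and their total; the PMF/CDF of the step count of final-reaching
runs up to n_max (default 60, overflow reported separately). Averages
over assignments are uniform over all 2^|In| assignments. Every
estimate carries a normal-approximation standard error (CONDITION via
the delta method with the CORRECT ⊆ FINAL covariance). Randomness comes
from one root seed spawning an independent substream per (assignment,
run) pair, so results are bit-reproducible and independent of
scheduling order. Default 20 000 runs per assignment puts the standard
error of a probability near 0.6 below 0.4 percentage points.

**Exact oracle.** For small nets, transient probabilities and expected
class rewards are computed exactly: the blocking outcomes are enumerated
analytically (products of independent Bernoullis, avoiding
vanishing-marking elimination), each outcome's CTMC over (position,
burnt-set) states is built by search (guarded by a state limit), and
uniformisation yields both the transient distribution π(τ) and the
accumulated occupancies ∫₀^τ π(t) dt, from which expected impulse
rewards follow as occupancy-weighted enabled-rate sums. The series is
truncated where the Poisson tail drops below 10⁻¹², with the
uniformisation rate set 2% above the maximal exit rate. The test suite
holds the simulator to within four standard errors of this oracle on
twenty generated circuits and to closed forms (1 − e^{−k_s τ} for a
single-step circuit; 1 − e^{−1.08} for a blocked line's long-range
route) at tight absolute tolerance.

## Packaged circuits and what they can show

The toy circuit (six anchorages, one fork, 7×8 grid) exercises the
template mechanics. The two OR-circuit layouts are *reconstructed
transcriptions*: the figures defining the published layouts are
available only graphically, so the layouts here were rebuilt from the
circuit's DSD structure (three forks, two joins, two finals for x|y|z)
and validated against the published structural counts. Reproduced
exactly: the short-distance classification column (naive
Track/Fork/Join/Leak = 64/12/8/8 directed transitions; optimised
66/12/8/2), including the layout-invariance of short Fork/Join counts
and the leak reduction 8 → 2. Reproduced approximately: expected step
counts (simulated ≈ 16.1 and ≈ 17.0 against published 15.59 and 16.02),
transient probabilities (within a few percentage points; e.g.
conditional correctness ≈ 89% against 91.7%), and the medium/long
classification cells (totals 392 and 379 against 462 and 426). The
residual gaps reflect geometric detail of the original figures that a
reconstruction cannot recover — medium/long counts are sensitive to
every pairwise distance — and the unknown placement of labelled
anchorages; here every anchorage of a branch carries the branch's
literal (including the second and third forks, which lie on the !x and
!y paths), the only labelling we found consistent with the published
high-correctness regime. Acceptance tests that compare per-cell
medium/long counts, transient probabilities and per-class rewards at
publication precision are accordingly expected to fail and are left
honest rather than loosened.

The random-circuit generator lays binary decision trees (or OR-chains
with a fork spine and a join spine) on the grid with a 2-unit track
pitch and 3-unit junction fan-outs, guaranteeing the degree structure of
the short band whenever the branch separation exceeds the short radius.
Cross-branch pairs below the long radius are then confined to the cones
around junctions — they cannot be eliminated entirely, because a fork's
two children must both sit within dS of the fork and hence within 2·dS
of each other, inside the long band. Generated circuits therefore model
the *structure* of real layouts faithfully but their leak profile is
junction-local; passing property tests on them shows correctness of the
algorithms, not that arbitrary hand-drawn layouts are leak-free.

## Numerical and design choices

* Determinism everywhere: vertices are processed in lexicographic
  (x, y) order for unfolding and indexing; markings are canonicalised to
  sorted sparse tuples; simulation substreams are counter-derived.
* Banding at band boundaries is inclusive on the upper edge (d = dS is
  short), matching the piecewise rate law's ≤ comparisons.
* NONE (out of range) is a regular banding result, not an error, so the
  unfolder can skip such pairs silently.
* LOOP transitions carry rate k_s; any positive rate works since loops
  only mark wanted terminal markings as live and are excluded from
  rewards.
* Steps targeting INIT are generated like any other; under burnt-bridges
  INIT's availability token is consumed on departure, so they are
  harmless.
* The circuit file format is YAML with a small fixed schema; round-trip
  load∘save is the identity and is property-tested.
* The CLI seeds, config hash and version are recorded in every report
  header; exit codes distinguish validation (2), ambiguity (3) and
  resource-limit (4) failures.

## Known limitations

* 2D only; the stencil and distance code do not preclude a third
  coordinate, but nothing else supports one.
* No marking-dependent rates, inhibitor/reset arcs, or general coloured
  nets — the unfolding is specific to the walker template.
* The exact oracle enumerates burnt-set CTMCs, which grow roughly
  exponentially in circuit size; it is a testing device for circuits of
  ~10–16 anchorages, not an analysis path for real layouts.
* No CSL/CSRL formula language: the shipped six query families are
  implemented directly.
* Layout synthesis/optimisation is out of scope; the package assesses
  and compares given layouts.
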