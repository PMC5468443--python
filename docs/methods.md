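# Methods

## Scope

`brnkit` implements the qualitative (kinetic-logic) and hybrid-delay
analysis of multivalued biological regulatory networks (BRNs): logical
parameter inference by CTL model checking, asynchronous state-graph and
attractor analysis, betweenness-centrality-based cycle selection, and exact
projection of a cycle's timing system onto delay-only invariance-kernel
constraints with a pairwise delay relation matrix.  The packaged case study
is the six-entity mTOR network (PI3K, PTEN, mTORC2, Akt, mTORC1, FOXO), for
which all inputs ship with the package (`data/mtor.yaml`, `data/mtor.ctl`).

## Logical model

A BRN is a digraph of entities with signed, thresholded interactions.  In a
qualitative state `s` (a vector of integer levels), a regulator `u` of `x`
is a *resource* iff it currently pushes `x` up: an activator with
`s_u >= threshold`, or an inhibitor with `s_u < threshold` (absence of an
inhibitor helps).  The dynamics are parameterized by logical parameters
`K_x(omega)`: the focal level toward which `x` drifts when its resource set
is `omega`.  A parameterization is complete when it covers every subset of
every entity's regulators (26 entries for the mTOR model).  The *Snoussi
condition* is monotonicity of `K` over resource-set inclusion: gaining a
resource never lowers the focal level.

In the packaged mTOR model PTEN is encoded as an inhibitor of PI3K with
absence-as-resource.  This is the unique sign assignment (together with
mTORC1 ⊣ PI3K, PI3K ⊣ PTEN, PI3K/FOXO → mTORC2 ⊣ mTORC1, PI3K/mTORC2 →
Akt, Akt → mTORC1 ⊣ FOXO, Akt/mTORC1 ⊣ FOXO) consistent with the model's
resource table, its stable state and its homeostatic cycle.  The
mTORC1 → FOXO edge is packaged as inhibition; it is non-functional under
the retained parameters (both signs give identical dynamics).

## Asynchronous dynamics

Unit-step asynchronous semantics: every entity whose focal level differs
from its current level yields one successor in which it moves one level
toward the focal value.  A state with no successors is stable.  The full
state graph enumerates all `prod_i (max_i + 1)` states (capped at 1e6 by
default); attractors are the terminal SCCs of this digraph, computed via
SCC condensation, classified stable (singleton without self-loop) or
cyclic.  For the mTOR model this yields 64 states, 192 transitions and the
single stable attractor (1,0,1,1,1,0) — the proliferative deadlock with
both tumor suppressors off.

## CTL engine and parameter inference

Formulas (atoms `entity = level`, boolean connectives, EX/EF/EG/AX/AF/AG
and both until forms) are evaluated by standard backward fixpoint labeling.
Paths are maximal with a totalized transition relation: a deadlock state
loops on itself, so `AG phi` can hold at a stable `phi`-state.  This is
required for fixpoint-style observations such as `EF(AG(...))` and matches
the convention of symbolic model checkers.  Model-level satisfaction is
universal over all initial states; an existential mode exists behind a
flag.

Inference enumerates the Cartesian product of the declared parameter
ranges (128 candidates for the mTOR ranges) and retains candidates whose
state graph satisfies every formula.  For the packaged mTOR run the
candidate space is additionally restricted to Snoussi-monotone
parameterizations (50 of the 128): with that restriction CTL filtering
retains exactly 8 models, including the packaged selection.  Without it,
32 models pass the three formulas (16 with the deadlock as unique stable
state); the library-level default of `infer` therefore stays
`snoussi=False` while the packaged pipeline configuration sets
`snoussi=True`, the regime under which the 8-model result is reproducible.

The partition of retained models by "has the deadlock as a stable state"
versus "as the unique stable state" is reported under both readings, since
the two differ (8 vs a subset) and neither is privileged.

## Cycle selection

Betweenness is directed, unnormalized shortest-path betweenness with
endpoints excluded (Brandes, via networkx), computed on the state graph.
Elementary circuits are enumerated Johnson-style up to a length cap
(default 20) and count cap (default 1e5); the mTOR graph has exactly 8.
Circuits are ranked by the *sum* of member-state betweenness (default),
with mean as an option; ties break toward the longer cycle, then the
lexicographically smallest canonical rotation.  Summed centrality measures
the total shortest-path traffic the loop carries; under it the 10-state
homeostatic cycle (PTEN constant at 1, all other entities oscillating) is
top-ranked with a clear margin, whereas under mean an 8-state circuit edges
it out — the ranking report emitted alongside the selection makes the
choice auditable.

## Delay kernel

A selected cycle is refined into a linear timing system.  The system dwells
`d_i >= 0` time units in each cycle location; each entity's production
delay `δ+` (one-level rise) or degradation delay `|δ−|` (fall) equals the
total dwell time between its consecutive level-change events — each
entity's clock runs continuously and resets only at that entity's own
events (inter-event convention).  Entities constant along the cycle (PTEN)
carry no delay symbols.  Dwell times are non-strict (zero-duration
locations admitted); delays are strictly positive.  Because every entity's
rise and fall windows tile the whole cycle, the period
`π(x) = δx+ + |δx−|` equals the cycle period `T` for every oscillating
entity — the equal-period property, which the projected kernel entails as
explicit equalities.

The invariance kernel — the delay valuations under which the hybrid
trajectory can follow the cycle forever — is obtained by exact existential
elimination of all `d_i` (Fourier–Motzkin with equality back-substitution,
rational arithmetic throughout), followed by redundancy pruning via
entailment checks against the positivity domain.  Feasibility and
entailment are exact decisions with rational witnesses; no floating point
is used anywhere in this stage.  The relation matrix marks, for each pair
of delay symbols, whether the kernel forces an ordering (checked as
infeasibility of the strict reverse).  For the mTOR cycle four orderings
are forced: `|δAkt−| <= |δmTORC2−|` (with a strict-inequality witness, and
the reverse strict order infeasible) together with its period-mirrored
companion `δmTORC2+ <= δAkt+`, and the analogous PI3K pair — the
biologically headline relation being that Akt must degrade no slower than
mTORC2 for homeostasis to persist.

An independent numeric oracle (`simulate_cycle`) solves the timing
equations for the dwell times at a concrete delay valuation by exact
Gaussian elimination (falling back to Fourier–Motzkin only for
underdetermined systems) and checks nonnegativity; membership in the
projected kernel coincides with schedulability for every tested valuation.

`data/mtor_delay_constraints.txt` transcribes a previously reported
nine-inequality rendering of this cycle's kernel, as an example input for
the constraint-file mode of the relation-matrix tool.  The computed kernel
entails six of those nine inequalities exactly; the remaining three are
not consequences of the timing semantics above — in duration space they
reduce to conditions such as `d_4 + d_5 <= d_1 + d_9 + d_10`, which
nonnegative dwell times do not force, and concrete positive delay
valuations satisfying every timing equation but violating them exist (for
instance a long dwell in the location preceding Akt's fall).  Alternative
clock conventions (per-location clock resets; clocks frozen while an
entity is not called) were examined and entail strictly fewer of the nine,
so the inter-event convention is kept.  The relation-matrix mode accepts
such a transcribed file as input precisely so the two renderings can be
compared.

## Synthetic fixtures

The generator module makes every stage testable without the packaged
model:

- `toy_circuits()` — canonical feedback circuits with classical dynamics:
  mutual activation (positive circuit, exactly two stable states), a
  two-gene negative loop (no stable state, one 4-state cyclic attractor),
  and a self-degrading entity.  These are the smallest instances of the
  multistationarity/homeostasis dichotomy of feedback circuits.
- `random_brn(n, density, max_level, seed)` — seeded random signed
  networks (default density 0.4, Boolean levels) with complete parameter
  specs and optionally Snoussi-monotone parameters, capped at 8 entities
  so brute-force state enumeration stays instantaneous.
- `random_digraph(n, p, seed)` — Erdős–Rényi digraphs for CTL and
  centrality oracles.
- `random_cycle_instance(n, seed)` — random Boolean single-step cycles
  (one rise and one fall per entity, rejection-sampled for distinct
  states) to stress the delay projection; every instance satisfies the
  equal-period property after projection.

These fixtures emulate the combinatorial structure of regulatory dynamics
(signed thresholded interactions, asynchronous unit steps), not
biological realism: no scale-free topology, no multi-edge regulation, no
noise.  Passing tests on them establishes algorithmic correctness (oracle
equivalence of the graph builder, CTL checker, betweenness and the
projection), not predictive validity on real networks.

## Numerical and determinism choices

- All state/edge iteration orders are fixed (lexicographic states, entity
  order within a state), so counts, exports and reports are bit-stable;
  the pipeline's JSON report is byte-identical across runs.
- Constraint canonicalization scales to coprime integer coefficients
  (positive leading coefficient for equalities) and is idempotent.
- Test problem sizes: oracle-equivalence suites use 200 random graphs of
  up to 12 nodes for CTL, 50–100 random digraphs/networks for betweenness
  and the state-graph builder, and 200 random delay valuations for the
  projection/schedule equivalence — sizes at which the brute-force oracles
  are exhaustive yet run in milliseconds.

## Known limitations

- Explicit-state CTL checking only (adequate to ~1e6 states); no BDDs,
  fairness, or LTL/CTL*.
- Single deterministic cycles in the delay stage; no general hybrid
  reachability, stochastic delays, or synthesis for off-cycle paths.
- One interaction per ordered entity pair; no context-dependent signs; no
  SBML-qual import (model schema is the packaged YAML dialect).
- Synchronous or priority-class update schemes are out of scope.
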