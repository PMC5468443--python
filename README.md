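# brnkit

Kinetic-logic modelling and hybrid delay analysis of biological regulatory
networks (BRNs), for systems biologists studying the qualitative dynamics
of small signalling/regulatory circuits.  The packaged case study is the
six-entity mTOR network (PI3K, PTEN, mTORC2, Akt, mTORC1, FOXO), whose
dynamics separate a homeostatic oscillation from a proliferative
(carcinogenic) deadlock.

## What it computes

A BRN is a digraph of entities with signed, thresholded regulations.  In
state `s`, regulator `u` is a **resource** of target `x` iff it pushes `x`
up (activator with `s_u ≥ threshold`, or inhibitor with `s_u < threshold`),
and `x` drifts toward the focal level `K_x(ω)` given its resource set `ω`.
The pipeline covers:

1. **Parameter inference** — enumerate all parameterizations within the
   declared ranges of `K_x(ω)` (optionally restricted to Snoussi-monotone
   ones: `ω ⊆ ω′ ⇒ K(ω) ≤ K(ω′)`) and retain those whose asynchronous
   state graph satisfies a set of CTL observations in every state
   (fixpoint-labelling model checker, deadlocks totalized by self-loops).
2. **Qualitative dynamics** — the full asynchronous unit-step state graph,
   its stable states (no outgoing transition) and attractors (terminal
   SCCs).
3. **Cycle selection** — directed unnormalized betweenness centrality over
   the state graph, Johnson-style elementary-circuit enumeration, and
   ranking of circuits by total member-state betweenness.
4. **Delay kernel** — the selected cycle's linear timing system over
   location dwell times `d_i ≥ 0` and per-entity production/degradation
   delays `δx±` (a delay spans the dwell times between the entity's
   consecutive level changes, so the period `π(x) = δx+ + |δx−|` is shared
   by all oscillating entities); exact Fourier–Motzkin projection onto the
   delays yields the invariance-kernel constraints, from which a pairwise
   **relation matrix** of forced delay orderings is decided by exact
   rational feasibility checks.

## Worked example

```
brnkit run --out report/
cat report/report.txt
```

prints (abridged):

```
candidate parameterizations : 128
retained by CTL inference   : 8
packaged selection retained : True

state graph                 : 64 states, 192 transitions
stable states               : 101110
attractors                  : 1

elementary circuits (<= len 20) : 8
selected cycle (sum betweenness): 010001 -> 011001 -> 111001 -> 111101 ->
  111100 -> 111110 -> 011110 -> 011010 -> 010010 -> 010011

forced delay orderings:
  dAkt- vs dmTORC2-: <=
  dPI3K- vs dmTORC2-: <=
  dmTORC2+ vs dAkt+: <=
  dmTORC2+ vs dPI3K+: <=
```

Reading the numbers: of the 128 candidate parameterizations of the mTOR
model, 8 satisfy all three CTL observations under the Snoussi condition,
including the packaged selection.  Its 64-state graph has a single
attractor — the stable state `101110`, i.e. PI3K/mTORC2/Akt/mTORC1 on with
both tumor suppressors (PTEN, FOXO) off, the proliferative deadlock.  The
top-ranked of the 8 elementary circuits is the 10-state homeostatic cycle
in which PTEN stays at level 1 while every other entity oscillates (state
strings follow the order PI3K, PTEN, mTORC2, Akt, mTORC1, FOXO).  Its
invariance kernel forces `|δAkt−| ≤ |δmTORC2−|`: homeostasis requires Akt
to degrade at least as fast as mTORC2 — the model's therapeutic headline —
along with the period-mirrored production ordering and the analogous PI3K
pair.

Individual stages are available as subcommands (`brnkit infer`, `graph`,
`centrality`, `cycles`, `kernel`, `relations`, `synth`) and as plain
library calls (`brnkit.builtin_model()`, `brnkit.build_state_graph`, ...).
See `docs/methods.md` for the model conventions, parameter defaults and
known limitations.

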