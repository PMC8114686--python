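# sbgnq

Qualitative dynamics toolkit for SBGN Process Description (PD) maps:
manipulate and merge reaction-network maps, translate them into
asynchronous automata networks under a permissive Boolean semantics, and
interrogate the resulting model — reachability of phase markers, minimal
precursor states, phase-progression validation, and loss/gain-of-function
mutation screens that control checkpoints.

## Who this is for

Curators and modellers who maintain large molecular interaction maps
(circadian clock, cell cycle, signalling pathways) in SBGN PD or
CellDesigner format and want to *validate* a map dynamically without
committing to kinetic parameters: does the network structure alone support
the known succession of phases?  Which entities of one coupled oscillator
control the checkpoints of the other?

## The model

A PD map contains entity pools (proteins, chemicals, complexes — possibly
decorated with state variables such as a phosphorylation `P@Thr172`),
processes consuming and producing them, and modulation arcs (stimulation,
inhibition, catalysis, necessary stimulation) whose source may be a logical
AND/OR/NOT function over pools.

The qualitative interpretation assigns every entity a state in
{absent, present} and every process a state in {off, on}, one binary
automaton each.  Local transitions are guarded:

- a process may switch **on** iff all its reactants are present, all
  necessary stimulations are active, all absolute inhibitions are inactive,
  and — if it carries any plain stimulation/catalysis or inhibition arc —
  at least one stimulation is active or one inhibition inactive;
- a process may switch **off** iff all its products are present;
- an entity may become **present** iff some process producing it is on,
  and **absent** iff some process consuming it is on with all of its
  products present.

Updates are asynchronous (one automaton per step), so the dynamics are a
non-deterministic transition system, equivalent to a 1-safe Petri net.  A
goal (e.g. "phase marker present, all other phases' markers absent") is
*reachable* from an initial state when some trajectory attains it; the
engine is an exact breadth-first search with explicit budgets, so negative
answers mean the full reachable set was exhausted and positive answers come
with minimal-length witness trajectories.

A **precursor state** is a smallest entity set whose initial presence makes
every entity of the map producible when modulator effects are ignored
(a least fixpoint over the reaction graph), optionally refined by
lexicographic objectives (fewest set state variables, fewest complexes).
Mutation screens enumerate all subset-minimal LoF/GoF sets, within declared
bounds, that make a checkpoint marker unreachable.

## Worked example

The packaged NAD salvage motif shows a circular necessary condition: the
marker `M` needs `NAD`, `NAD` is made from `NMN` by the `NMNAT` enzyme,
but `NMN` can only be made from `NAM` by an enzyme whose own production
needs `M`.

```python
>>> import sbgnq as q
>>> from sbgnq import synthetic_data as syn
>>> nad = syn.make_nad_motif()
>>> an = q.translate(nad)
>>> len(an.automata), len(an.rules)
(11, 17)
>>> goal = q.GoalSpec(frozenset(["M"]))
>>> q.reachable(an, q.initial_state(an, ["NAM", "NMNAT"]), goal, 10**6).status
'unreachable'
>>> v = q.reachable(an, q.initial_state(an, ["NMN", "NMNAT"]), goal, 10**6)
>>> v.status, len(v.witness)
('reachable', 5)
>>> [s.texts for s in q.compute_precursors(nad)]
[('NAM', 'NMNAT'), ('NMN', 'NMNAT')]
```

The 11 automata are the 6 entity pools plus 5 processes; 17 guarded rules
encode their transitions.  Seeds holding only `NAM` can never produce the
marker (the circular dependency), while `NMN`-containing seeds reach it in
a 5-state minimal trajectory (switch the NAD-producing process on, produce
NAD, enable the marker's source process, produce M).  Exactly two minimal
precursor states exist, and the pure catalyst `NMNAT` — invisible to the
producibility closure — sits in both.

The same analyses run from the shell:

```
sbgnq fixtures maps/
sbgnq reach maps/nad_motif.sbgn --init NMN --init NMNAT --present M
sbgnq precursor maps/nad_motif.sbgn
sbgnq mutations maps/toy_coupled.sbgn --target X3 \
      --candidates A --candidates B --candidates W --max-size 1
sbgnq validate maps/toy_clock.sbgn --cycle my_cycle.yaml
```

Marker tables for the mammalian cell cycle (early G1 … M) and the
circadian clock (RORG, SIRT1, ARNTL-CLOCK, PER-CRY) ship as data assets
(`sbgnq.phases.load_cycle_spec("cell_cycle")`), using the textual entity
grammar `label(value@site|...)` with `:`-separated complex subunits.

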