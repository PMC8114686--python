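# Methods

## Scope and data model

The toolkit models the *conceptual* content of an SBGN Process Description
map: compartments, entity pools, processes, modulation arcs and logical
functions.  Layout is discarded on read and auto-generated (placeholder
boxes) on write.  Entity pools are immutable value objects; structural
equality compares class, label, compartment, state variables and subunits,
with subunit order and state-variable order ignored (a complex is a bag of
subunits) but *preserved in storage*, so the textual renderer is the exact
inverse of the marker-grammar parser.  Duplicate state variables with no
site (e.g. `pRB(P|P)`) are told apart by an ordinal assigned in declaration
order.

Process identifiers are unique per map and survive SBGN-ML round trips
(they become glyph ids), but are excluded from structural identity: merging
two maps unions concepts under structural equality, re-identifying genuine
identifier collisions and retargeting modulations.  Harmonization edits
(rename, re-compartmentalize, add state variables, add/delete concepts)
are pure transformations driven by replayable YAML scripts, with per-edit
match counts reported and zero-match edits flagged as no-ops.

Readers: SBGN-ML 0.2/0.3 (language must be process description; unknown
glyph/arc classes are skipped with a warning recorded in a parse report
whose counts account for every supported element) and CellDesigner extended
SBML (species classes mapped to the nearest PD class, modification residues
to state variables, complexes rebuilt from included species, modifier types
to modulation classes, MIRIAM annotations kept as (database, identifier)
pairs).  Both readers are implemented directly on `lxml`; writing targets
SBGN-ML 0.3 with deterministic element ordering, so identical maps produce
byte-identical files.

## The qualitative semantics

Every entity pool (except empty-set source/sink participants) and every
process becomes one binary automaton.  Guards implement the permissive
firing discipline:

- process off→on: all reactants present ∧ all necessary stimulations
  active ∧ all absolute inhibitions inactive ∧ (if any plain
  stimulation/catalysis/modulation or inhibition arc exists: some
  stimulation active ∨ some inhibition inactive);
- process on→off: all products present;
- entity absent→present: some producing process on;
- entity present→absent: some consuming process on with all its products
  present (production strictly precedes consumption).

Design choices in the translation:

- **Vacuous disjunct.**  A process with no plain stimulation or inhibition
  arcs satisfies the stimulation/inhibition clause vacuously; otherwise
  unmodulated processes could never fire.
- **Catalysis and generic modulation are treated as stimulations** (SBGN
  subtyping); the choice is logged per process at translation time.
- **Absolute inhibition** is never inferred from SBGN-ML — no PD arc class
  encodes it — and exists only as an explicitly set modulation class.
- **Stoichiometry is ignored**: multiset participants collapse to sets in
  guards (Boolean abstraction).
- **Self-reference elimination**: when a process has the same pool as
  reactant and product (a template, e.g. a transcribed gene), the pool's
  present→absent guard drops the self-conjunct — it holds by the rule's
  own direction — keeping the invariant that no guard mentions its own
  automaton.
- Guards are Boolean expression trees with constant folding only; no DNF
  expansion, so translation is linear in map size.  Automaton ids are
  rendered entity texts, suffixed with `@compartment` only when the same
  text occurs in several compartments.

A consequence of the permissive disjunct worth noting: an *inactive
inhibition* is itself an enabling witness for its process.  Removing an
inhibition arc from a process that retains other plain arcs can therefore
remove behaviors, and adding a stimulation to a previously unmodulated
process can as well (the vacuous clause becomes a real one).  Monotone
permissiveness holds only in the complementary cases (removing a process's
sole plain arc; adding a stimulation to an already-modulated process), and
the property tests are scoped accordingly.

## Reachability

Exact explicit-state breadth-first search over packed bit-vector states in
a canonical automaton order.  BFS (rather than depth-first or directed
search) guarantees minimal-length witnesses.  The exploration budget
(default 5×10⁶ states) is honest: exhausting it yields a distinct
`budget-exceeded` verdict, never `unreachable`.  Sequence reachability
(phase successions, with repeats) is a layered multi-source BFS: each layer
collects every state satisfying the next goal reachable from the previous
layer's satisfying states; a state may satisfy consecutive goals at once
(the packaged cycles have disjoint marker sets, making the distinction
immaterial there).  Witnesses are stitched across layers.

Mutations rewrite the network: LoF removes an entity's rise rules and
clamps it absent in initial states (declaring a LoF entity present is an
error); GoF removes its fall rules and clamps it present.  Guards that
*reference* the mutated entity are untouched.  Disabling a marker set is
LoF applied to each marker.  Initial states always start with every
process off.

The structural over-approximation ignores modulations entirely: a least
fixpoint in which seeded entities, products of source processes, and
products of processes with producible reactants are producible.  Anything
outside the fixpoint is certifiably unreachable under the full semantics;
membership proves nothing (the approximation is one-sided).

## Precursor states

A precursor state must make the whole map producible under the closure and
must contain the configured `required` entities — the generalization of
a priori constraints such as forcing the cell-cycle driver complex
`pRB:E2F1:DP1` into every seed; only inclusion is enforced, free forms are
not excluded.  Entities with no producing process —
notably pure catalysts, which the closure cannot see — are forced into
every solution, which prunes the search sharply; entities already derivable
from that base can never help and are dropped from the candidate pool.
The solver then scans candidate subsets in increasing cardinality
(branch-and-bound over the subset lattice with the closure as feasibility
check) and enumerates *all* optima under the lexicographic objectives, in
configurable order (default: cardinality, then the count of state
variables with a set value — counted recursively through complex subunits,
since a modified subunit is a modified entity — then the count of
complexes).  For objective orders omitting cardinality the optimum is only
defined up to supersets with zero-cost entities, so optima are reported
among subset-minimal feasible sets.  An equivalent answer-set-programming
encoding ships as a text asset (`data/precursor.lp`) for use with an
external ASP solver; the native solver is authoritative.

## Phases and the A/B/C protocol

A cycle is an ordered list of phases with pairwise-disjoint marker sets
(the packaged tables: six cell-cycle phases with 17 markers, four clock
phases with 4 markers).  Being "in" a phase means: at least one of its
markers present and *all markers of all other phases of the same cycle*
absent — scoped per cycle; a second cycle's markers are deliberately
unconstrained, coupling entering only through shared dynamics.  Early/late
sub-phases are ordinary phases in the cyclic order.

`validate_progression` runs, per precursor state: (A) plain reachability
of each marker; (B) each phase goal, a phase being reachable when at least
one of its markers' goals is; (C) part B re-evaluated with the preceding
phase's markers disabled — a phase that flips to unreachable shows every
route passes through its predecessor; plus the cyclic sequence of phase
goals repeated (default four times).  Budget-exhausted verdicts surface as
`unknown`, never as `unreachable`; an optional seeded random-walk fallback
can upgrade an `unknown` to `reachable (simulation)` — explicitly labelled
non-exhaustive — but never downgrade.

## Mutation screens and reliance

The checkpoint screen enumerates all mutation sets over
candidates × {LoF, GoF} up to the requested size, in increasing size so
that every reported set is subset-minimal (supersets of found blockers are
skipped), and re-verifies each before reporting.  Within its declared
bounds the screen is exhaustive — a deliberate strengthening over
deduction-based screening, which scales further but may miss controls.
Budget-exhausted checks count as non-blocking, so only certain blocks are
reported.  The control summary groups blocking entities per target marker
with their mutation kind and source-map tag from a provenance partition
(the packaged default candidate choice mirrors cross-map screens: entities
of the *other* map).

Trajectory reliance is an existential surrogate: the entity is "relied on"
if some trajectory reaches a state with the entity present and the goal
after that, decided by the layered search.  This does not establish that
*every* trajectory needs the entity (a universal, cut-set-style notion);
the gap is intentional and documented here.

## Synthetic data

The fixtures encode the study conditions in miniature and are
hand-specified so expected verdicts are derivable by hand and by brute
force: a two-entity negative-feedback oscillator (phases P1/P2), the
NAD+/NMN/NAM circular-dependency motif with its marker dichotomy, the
oscillator coupled to a three-stage cycle through a necessary stimulation
(candidate screens find LoF of the activator, LoF of the gating enzyme,
and GoF of the repressor), and an alternatives motif whose two
translocation cycles and one three-metabolite cycle factor the minimal
precursor states into 2×2×3 = 12 interchangeable optima.  All fixtures
live in a single compartment ("cell") so marker resolution is unambiguous.

The random generator emulates small connected PD maps — exact entity and
process counts, one guaranteed source process, occasional sinks, modulation
arcs drawn at a mean density with configurable necessary-stimulation and
inhibition fractions — and is deterministic per seed (same parameters →
byte-identical SBGN-ML).  It exists for property testing: it does not
emulate hub structure, compartmentalization, complexes or annotations of
curated maps, so passing property suites demonstrates engine correctness
on the mechanics, not biological realism.

## Verification strategy and problem sizes

Every engine is cross-checked against an independent brute-force oracle
that re-derives the firing rules from the map on each call: the step
relation exhaustively on all states of every corpus network (fixtures and
100 seeded random maps, all ≤ 12 automata), BFS verdicts and witness
minimality against full oracle state graphs, closure soundness against the
oracle's reachable entity sets, precursor enumeration against exhaustive
subset search (maps ≤ 15 entities), and every blocking set against
independent re-verification.  These corpus sizes keep the exhaustive
cross-validation exact while the whole suite runs in seconds; they are the
package's chosen desk-scale study conditions.

## Known limitations

- Full-scale merged-map model checking (hundreds of automata) is out of
  scope for the exact engine; the honest-budget design anticipates it.
- Attractor computation, timed/stochastic semantics, and synchronous or
  most-permissive update schemes are not implemented.
- The CellDesigner reader covers the conceptual subset above, not full
  format fidelity (layout, fonts, notes markup are discarded with logged
  warnings).
- The published circadian-clock CellDesigner map is external supplementary
  data and is not bundled; the parsing-count acceptance check requires
  dropping it in as `src/sbgnq/data/CircadianClock.xml`.
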