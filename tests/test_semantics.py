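"""General-semantics translation and the asynchronous step relation."""

from itertools import product

import pytest

import sbgnq as q
from sbgnq.pd_core import LogicalFunction, Modulation, PDMap, Process
from sbgnq.semantics import step, translate
from sbgnq import synthetic_data as syn

from conftest import small_random_maps
from oracle import all_states, automaton_names, oracle_successors


# ---------------------------------------------------------------------------
# eval_modulation
# ---------------------------------------------------------------------------

def test_eval_modulation_entity_and_negation():
    b = q.parse_entity_text("B")
    assert q.eval_modulation(b, {"B": 0}) is False
    assert q.eval_modulation(b, {"B": 1}) is True
    assert q.eval_modulation(LogicalFunction("NOT", (b,)), {"B": 0}) is True


def test_eval_modulation_truth_table():
    a, b = q.parse_entity_text("A"), q.parse_entity_text("B")
    gate = LogicalFunction("AND", (a, LogicalFunction("NOT", (b,))))
    for va, vb in product((0, 1), repeat=2):
        assert q.eval_modulation(gate, {"A": va, "B": vb}) == (
            va == 1 and vb == 0
        )


def test_eval_modulation_missing_automaton():
    with pytest.raises(q.MissingAutomatonError):
        q.eval_modulation(q.parse_entity_text("Z"), {"A": 1})


# ---------------------------------------------------------------------------
# can_switch_on
# ---------------------------------------------------------------------------

def _state(pdmap, **overrides):
    ids, pids = automaton_names(pdmap)
    s = {aid: 0 for aid in list(ids.values()) + pids}
    s.update(overrides)
    return s


def test_unmodulated_process_fires_on_reactants(nad_motif):
    p5 = nad_motif.processes["p5"]  # NMN -> NAM, no modulators
    assert q.can_switch_on(nad_motif, p5, _state(nad_motif, NMN=1))
    assert not q.can_switch_on(nad_motif, p5, _state(nad_motif))


def test_necessary_stimulation_gates_source_process(nad_motif):
    p3 = nad_motif.processes["p3"]  # source -> M, necessary stim NAD
    assert not q.can_switch_on(nad_motif, p3, _state(nad_motif, NAD=0))
    assert q.can_switch_on(nad_motif, p3, _state(nad_motif, NAD=1))


def test_single_inhibitor_blocks_when_active(toy_clock):
    tA = toy_clock.processes["tA"]
    assert not q.can_switch_on(toy_clock, tA, _state(toy_clock, B=1))
    assert q.can_switch_on(toy_clock, tA, _state(toy_clock, B=0))


# ---------------------------------------------------------------------------
# translate
# ---------------------------------------------------------------------------

def test_empty_map_translates_to_empty_network():
    an = translate(PDMap())
    assert len(an.automata) == 0 and len(an.rules) == 0


def test_toy_clock_network_shape(toy_clock_an):
    assert len(toy_clock_an.automata) == 6
    assert len(toy_clock_an.rules) == 12
    assert sorted(toy_clock_an.entity_ids) == ["A", "B"]
    assert sorted(toy_clock_an.process_ids) == ["dA", "dB", "tA", "tB"]


def test_entity_production_guard_references_only_producers(nad_an):
    (rule,) = nad_an.rules_for("NAM", frm=0)
    assert rule.guard.variables() == {"p5"}


def test_automata_counts_match_map(toy_coupled, coupled_an):
    assert len(coupled_an.entity_ids) == len(toy_coupled.entity_pools)
    assert len(coupled_an.process_ids) == len(toy_coupled.processes)


def test_unproducible_entity_lacks_rise_rule():
    m = PDMap()
    x = q.parse_entity_text("X")
    m.add_process(Process("generic", (x,), (), "sink"))
    an = translate(m)
    assert an.rules_for("X", frm=0) == []
    assert len(an.rules_for("X", frm=1)) == 1


def test_translation_is_deterministic(toy_coupled):
    a, b = translate(toy_coupled), translate(syn.make_toy_coupled())
    assert a.order == b.order
    assert a.to_text() == b.to_text()


def test_exchange_text_and_provenance(toy_clock_an):
    text = toy_clock_an.to_text()
    assert 'automaton "A" entity' in text
    assert '"A" 0 -> 1 when "tA"=1' in text
    import json

    prov = json.loads(toy_clock_an.provenance_json())
    assert prov["A"]["kind"] == "entity"
    assert prov["tA"]["kind"] == "process"


# ---------------------------------------------------------------------------
# step
# ---------------------------------------------------------------------------

def test_step_from_all_zero_has_single_successor(toy_clock_an):
    s0 = q.initial_state(toy_clock_an)
    succ = step(toy_clock_an, s0)
    assert len(succ) == 1
    assert succ[0][1].label() == "tA:0->1"


def test_deadlock_has_no_successors():
    m = PDMap()
    x = q.parse_entity_text("X")
    m.add_process(Process("generic", (x,), (), "sink"))
    an = translate(m)
    assert step(an, {"X": 0, "sink": 0}) == []


def test_successors_differ_in_exactly_one_coordinate(coupled_an):
    import random

    rng = random.Random(7)
    for _ in range(50):
        state = {aid: rng.randint(0, 1) for aid in coupled_an.order}
        for nxt, _rule in step(coupled_an, state):
            assert sum(state[a] != nxt[a] for a in coupled_an.order) == 1


# ---------------------------------------------------------------------------
# engine vs brute-force interpreter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "factory", [syn.make_toy_clock, syn.make_nad_motif]
)
def test_step_matches_oracle_exhaustively_on_fixtures(factory):
    pdmap = factory()
    an = translate(pdmap)
    assert len(an.automata) <= 12
    for state in all_states(pdmap):
        engine = {
            frozenset(s.items()) for s, _ in step(an, state)
        }
        assert engine == oracle_successors(pdmap, state), state


def test_step_matches_oracle_on_seeded_random_maps():
    for pdmap in small_random_maps(25, base_seed=100):
        an = translate(pdmap)
        assert len(an.automata) <= 12
        for state in all_states(pdmap):
            engine = {frozenset(s.items()) for s, _ in step(an, state)}
            assert engine == oracle_successors(pdmap, state)


def test_removing_sole_inhibition_never_removes_successors():
    # under the permissive disjunct, an inactive inhibition is itself an
    # enabling witness, so removal is only guaranteed monotone when the
    # process carries no other plain stimulation/inhibition arc (the clause
    # then becomes vacuous)
    checked = 0
    for pdmap in small_random_maps(20, base_seed=300):
        plain = {}
        for m in pdmap.modulations:
            if m.mod_class in ("stimulation", "catalysis", "modulation",
                               "inhibition"):
                plain.setdefault(m.target, []).append(m)
        sole = [
            ms[0] for ms in plain.values()
            if len(ms) == 1 and ms[0].mod_class == "inhibition"
        ]
        if not sole:
            continue
        relaxed = pdmap.copy()
        relaxed.modulations = pdmap.modulations - {sole[0]}
        an, an_relaxed = translate(pdmap), translate(relaxed)
        for state in all_states(pdmap):
            before = {frozenset(s.items()) for s, _ in step(an, state)}
            after = {frozenset(s.items()) for s, _ in step(an_relaxed, state)}
            assert before <= after
        checked += 1
    assert checked > 0


def test_adding_stimulation_to_modulated_process_never_removes_successors(
    toy_clock,
):
    # tA already has an inhibition arc, so one more stimulation only adds a
    # disjunct to its firing clause
    extended = toy_clock.copy()
    a = q.find_entity(extended, "A")
    extended.modulations = set(extended.modulations)
    extended.add_modulation(Modulation("stimulation", a, "tA"))
    an, an_ext = translate(toy_clock), translate(extended)
    for state in all_states(toy_clock):
        before = {frozenset(s.items()) for s, _ in step(an, state)}
        after = {frozenset(s.items()) for s, _ in step(an_ext, state)}
        assert before <= after
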