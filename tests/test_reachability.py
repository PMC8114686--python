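"""BFS reachability vs brute-force state graphs; mutations; closure."""

import pytest

import sbgnq as q
from sbgnq.reachability import (
    BUDGET_EXCEEDED,
    REACHABLE,
    UNREACHABLE,
    GoalSpec,
    Mutation,
)
from sbgnq.semantics import translate
from sbgnq import synthetic_data as syn

from conftest import small_random_maps
from oracle import (
    automaton_names,
    oracle_closure,
    oracle_reachable,
    oracle_reachable_entities,
)


# ---------------------------------------------------------------------------
# initial_state
# ---------------------------------------------------------------------------

def test_initial_state_empty_is_all_zero(toy_clock_an):
    assert all(v == 0 for v in q.initial_state(toy_clock_an).values())


def test_initial_state_sets_exactly_listed_entities(nad_an):
    s = q.initial_state(nad_an, ["NMN", "NMNAT"])
    assert {a for a, v in s.items() if v} == {"NMN", "NMNAT"}


def test_initial_state_processes_always_off(coupled_an):
    s = q.initial_state(coupled_an, ["A", "X1", "W"])
    assert all(s[p] == 0 for p in coupled_an.process_ids)


def test_initial_state_unknown_entity(toy_clock_an):
    with pytest.raises(KeyError):
        q.initial_state(toy_clock_an, ["nonexistent"])


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

def test_lof_removes_rise_rules(toy_clock_an):
    mutated = q.apply_mutations(toy_clock_an, [Mutation("A", "LoF")])
    assert mutated.rules_for("A", frm=0) == []
    assert toy_clock_an.rules_for("A", frm=0) != []  # original untouched


def test_gof_freezes_entity_present(toy_clock_an):
    mutated = q.apply_mutations(toy_clock_an, [Mutation("B", "GoF")])
    assert mutated.rules_for("B", frm=1) == []
    init = q.initial_state(mutated)
    assert init["B"] == 1
    # tA is inhibited by B, which can never leave state 1
    v = q.reachable(mutated, init, GoalSpec(frozenset(["A"])), 10_000)
    assert v.status == UNREACHABLE


def test_empty_mutation_set_is_identity(toy_clock_an):
    mutated = q.apply_mutations(toy_clock_an, [])
    assert mutated.to_text() == toy_clock_an.to_text()


def test_conflicting_mutations_rejected(toy_clock_an):
    with pytest.raises(q.ConflictError):
        q.apply_mutations(
            toy_clock_an, [Mutation("A", "LoF"), Mutation("A", "GoF")]
        )


def test_lof_entity_cannot_be_declared_present(toy_clock_an):
    mutated = q.apply_mutations(toy_clock_an, [Mutation("A", "LoF")])
    with pytest.raises(q.InconsistentInitError):
        q.initial_state(mutated, ["A"])


def test_disable_markers_makes_marker_unreachable(toy_clock_an):
    disabled = q.disable_markers(toy_clock_an, ["B"])
    v = q.reachable(
        disabled, q.initial_state(disabled), GoalSpec(frozenset(["B"])), 10_000
    )
    assert v.status == UNREACHABLE
    # disabling nothing changes nothing
    assert q.disable_markers(toy_clock_an, []).to_text() == toy_clock_an.to_text()


def test_mutation_monotonicity(coupled_an):
    # a larger mutation set never enlarges the reachable set on unmutated
    # coordinates
    small = q.apply_mutations(coupled_an, [Mutation("W", "LoF")])
    large = q.apply_mutations(
        coupled_an, [Mutation("W", "LoF"), Mutation("B", "LoF")]
    )
    goal_vars = [a for a in coupled_an.entity_ids if a not in ("W", "B")]
    for aid in goal_vars:
        goal = GoalSpec(frozenset([aid]))
        v_small = q.reachable(small, q.initial_state(small), goal, 100_000)
        v_large = q.reachable(large, q.initial_state(large), goal, 100_000)
        if v_large.status == REACHABLE:
            assert v_small.status == REACHABLE


# ---------------------------------------------------------------------------
# reachable
# ---------------------------------------------------------------------------

def test_goal_satisfied_at_init_gives_length_one_witness(nad_an):
    init = q.initial_state(nad_an, ["NAM"])
    v = q.reachable(nad_an, init, GoalSpec(frozenset(["NAM"])), 100)
    assert v.status == REACHABLE and len(v.witness) == 1


def test_toy_clock_b_reachable(toy_clock_an):
    v = q.reachable(
        toy_clock_an, q.initial_state(toy_clock_an),
        GoalSpec(frozenset(["B"])), 10_000,
    )
    assert v.status == REACHABLE


def test_nad_dichotomy(nad_an):
    goal = GoalSpec(frozenset(["M"]))
    bad = q.reachable(nad_an, q.initial_state(nad_an, ["NAM", "NMNAT"]), goal, 100_000)
    good = q.reachable(nad_an, q.initial_state(nad_an, ["NMN", "NMNAT"]), goal, 100_000)
    assert bad.status == UNREACHABLE
    assert good.status == REACHABLE


def test_budget_exhaustion_is_distinct_verdict(coupled_an):
    never = GoalSpec(frozenset(), frozenset())  # trivially satisfied
    v = q.reachable(coupled_an, q.initial_state(coupled_an), never, 1)
    assert v.status == REACHABLE  # init satisfies it
    impossible = GoalSpec(frozenset(["A", "B", "X1", "X2", "X3", "W"]))
    v2 = q.reachable(coupled_an, q.initial_state(coupled_an), impossible, 5)
    assert v2.status == BUDGET_EXCEEDED


def test_witness_is_valid_trajectory(nad_an):
    init = q.initial_state(nad_an, ["NMN", "NMNAT"])
    v = q.reachable(nad_an, init, GoalSpec(frozenset(["M"])), 100_000)
    traj = v.witness
    assert traj.states[0] == init
    assert len(traj.fired) == len(traj.states) - 1
    from sbgnq.semantics import step

    for a, b in zip(traj.states, traj.states[1:]):
        succ = {frozenset(s.items()) for s, _ in step(nad_an, a)}
        assert frozenset(b.items()) in succ


@pytest.mark.parametrize(
    "factory, inits",
    [
        (syn.make_toy_clock, [[], ["A"], ["B"]]),
        (syn.make_nad_motif, [[], ["NAM", "NMNAT"], ["NMN", "NMNAT"]]),
    ],
)
def test_bfs_matches_oracle_graph_on_fixtures(factory, inits):
    pdmap = factory()
    an = translate(pdmap)
    for present in inits:
        init = q.initial_state(an, present)
        for target in an.entity_ids:
            goal = GoalSpec(frozenset([target]))
            verdict = q.reachable(an, init, goal, 1_000_000)
            expect, dist = oracle_reachable(
                pdmap, init, lambda s: s[target] == 1
            )
            assert (verdict.status == REACHABLE) == expect
            if expect:
                # BFS witnesses are minimal-length
                assert len(verdict.witness) - 1 == dist


def test_bfs_matches_oracle_graph_on_random_maps():
    for pdmap in small_random_maps(20, base_seed=500):
        an = translate(pdmap)
        init = q.initial_state(an)
        for target in an.entity_ids:
            goal = GoalSpec(frozenset([target]))
            verdict = q.reachable(an, init, goal, 1_000_000)
            expect, dist = oracle_reachable(
                pdmap, init, lambda s: s[target] == 1
            )
            assert (verdict.status == REACHABLE) == expect
            if expect:
                assert len(verdict.witness) - 1 == dist


# ---------------------------------------------------------------------------
# sequence_reachable
# ---------------------------------------------------------------------------

def test_empty_goal_list_vacuously_reachable(toy_clock_an):
    v = q.sequence_reachable(toy_clock_an, q.initial_state(toy_clock_an), [])
    assert v.status == REACHABLE


def test_toy_clock_phase_sequence_four_repeats(toy_clock_an):
    p1 = GoalSpec(frozenset(["A"]), frozenset(["B"]))
    p2 = GoalSpec(frozenset(["B"]), frozenset(["A"]))
    goals = [p1, p2] * 4
    v = q.sequence_reachable(
        toy_clock_an, q.initial_state(toy_clock_an), goals, 1_000_000
    )
    assert v.status == REACHABLE
    # the witness really visits the goals in order
    traj = v.witness
    idx = 0
    for s in traj.states:
        if idx < len(goals) and goals[idx].satisfied(s):
            idx += 1
    assert idx == len(goals)


def test_sequence_fails_under_lof(toy_clock_an):
    mutated = q.apply_mutations(toy_clock_an, [Mutation("A", "LoF")])
    p1 = GoalSpec(frozenset(["A"]), frozenset(["B"]))
    v = q.sequence_reachable(mutated, q.initial_state(mutated), [p1], 100_000)
    assert v.status == UNREACHABLE


# ---------------------------------------------------------------------------
# structural over-approximation
# ---------------------------------------------------------------------------

def test_closure_fixpoints_on_nad(nad_motif):
    assert q.unreachability_overapprox(nad_motif, []) == {"M", "NAMPT"}
    assert q.unreachability_overapprox(nad_motif, ["NAM", "NMNAT"]) == {
        "M", "NAD", "NAM", "NAMPT", "NMN", "NMNAT",
    }


def test_closure_is_sound_overapprox_on_fixtures(nad_motif):
    an = translate(nad_motif)
    for present in ([], ["NAM", "NMNAT"], ["NMN", "NMNAT"]):
        init = q.initial_state(an, present)
        truly = oracle_reachable_entities(nad_motif, init)
        assert truly <= q.unreachability_overapprox(nad_motif, present)


def test_closure_is_sound_overapprox_on_random_maps():
    for pdmap in small_random_maps(20, base_seed=700):
        an = translate(pdmap)
        init = q.initial_state(an)
        truly = oracle_reachable_entities(pdmap, init)
        assert truly <= q.unreachability_overapprox(pdmap, [])


def test_closure_matches_independent_fixpoint():
    for pdmap in small_random_maps(10, base_seed=900):
        ids, _ = automaton_names(pdmap)
        got = q.unreachability_overapprox(pdmap, [])
        want = {ids[e] for e in oracle_closure(pdmap, set())}
        assert got == want


# ---------------------------------------------------------------------------
# random walk
# ---------------------------------------------------------------------------

def test_random_walk_stays_within_reachable_set(nad_motif, nad_an):
    init = q.initial_state(nad_an, ["NMN", "NMNAT"])
    reachable_states, _ = __import__("oracle").oracle_state_graph(nad_motif, init)
    traj = q.random_walk(nad_an, init, steps=200, seed=11)
    for s in traj.states:
        assert frozenset(s.items()) in reachable_states


def test_random_walk_is_seed_deterministic(coupled_an):
    init = q.initial_state(coupled_an)
    a = q.random_walk(coupled_an, init, 50, seed=3)
    b = q.random_walk(coupled_an, init, 50, seed=3)
    assert a.fired == b.fired
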