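"""Independent brute-force oracles.

Everything here re-derives the qualitative semantics directly from the map
on every call — no guard trees, no precompiled rules — so it can confirm
the rule-based engine without sharing its code path.  Only the automaton
*naming* convention is shared (entity text / process identifier), since
names are cosmetic.
"""

from itertools import combinations, product

from sbgnq.pd_core import LogicalFunction, PDMap
from sbgnq.semantics import AutomataNetwork, _entity_ids_for_map


def automaton_names(pdmap: PDMap):
    """(entity ids dict, process ids list) under the shared naming scheme."""
    return _entity_ids_for_map(pdmap), sorted(pdmap.processes)


def oracle_successors(pdmap: PDMap, state: dict) -> set:
    """All asynchronous successors of *state*, re-derived from the map.

    Returns a set of frozenset(state.items()) for set comparison.
    """
    ids, _ = automaton_names(pdmap)

    def satisfied(source) -> bool:
        if isinstance(source, LogicalFunction):
            vals = [satisfied(c) for c in source.children]
            if source.operator == "AND":
                return all(vals)
            if source.operator == "OR":
                return any(vals)
            return not vals[0]
        return state[ids[source]] == 1

    succ = set()

    def flip(aid, value):
        nxt = dict(state)
        nxt[aid] = value
        succ.add(frozenset(nxt.items()))

    for pid, proc in pdmap.processes.items():
        mods = [m for m in pdmap.modulations if m.target == pid]
        if state[pid] == 0:
            # a process may switch on: all reactants present, all necessary
            # stimulations active, all absolute inhibitions inactive, and at
            # least one stimulation active or one inhibition inactive (when
            # any such arc exists)
            if not all(state[ids[r]] for r in proc.reactants):
                pass
            elif not all(
                satisfied(m.source)
                for m in mods if m.mod_class == "necessary-stimulation"
            ):
                pass
            elif any(
                satisfied(m.source)
                for m in mods if m.mod_class == "absolute-inhibition"
            ):
                pass
            else:
                plain_stim = [
                    satisfied(m.source) for m in mods
                    if m.mod_class in ("stimulation", "catalysis", "modulation")
                ]
                plain_inh = [
                    satisfied(m.source) for m in mods
                    if m.mod_class == "inhibition"
                ]
                if (
                    (not plain_stim and not plain_inh)
                    or any(plain_stim)
                    or any(not v for v in plain_inh)
                ):
                    flip(pid, 1)
        else:
            # a process may switch off: all products present
            if all(state[ids[p]] for p in proc.products):
                flip(pid, 0)

    for entity, aid in ids.items():
        if state[aid] == 0:
            # may become present: product of a process that is on
            if any(
                state[pid] == 1
                for pid, proc in pdmap.processes.items()
                if entity in proc.products
            ):
                flip(aid, 1)
        else:
            # may become absent: reactant of an on process with all
            # products present
            if any(
                state[pid] == 1
                and all(state[ids[q]] for q in proc.products)
                for pid, proc in pdmap.processes.items()
                if entity in proc.reactants
            ):
                flip(aid, 0)
    return succ


def all_states(pdmap: PDMap):
    """Every global state of the map's network (entities + processes)."""
    ids, pids = automaton_names(pdmap)
    names = sorted(ids.values()) + pids
    for bits in product((0, 1), repeat=len(names)):
        yield dict(zip(names, bits))


def oracle_state_graph(pdmap: PDMap, init: dict):
    """Reachable state set from *init*, via the brute-force interpreter."""
    start = frozenset(init.items())
    seen = {start}
    frontier = [start]
    dist = {start: 0}
    while frontier:
        nxt = []
        for s in frontier:
            for t in oracle_successors(pdmap, dict(s)):
                if t not in seen:
                    seen.add(t)
                    dist[t] = dist[s] + 1
                    nxt.append(t)
        frontier = nxt
    return seen, dist


def oracle_reachable(pdmap: PDMap, init: dict, pred):
    """(reachable?, minimal distance) for goal predicate *pred*."""
    seen, dist = oracle_state_graph(pdmap, init)
    hits = [dist[s] for s in seen if pred(dict(s))]
    return (True, min(hits)) if hits else (False, None)


def oracle_reachable_entities(pdmap: PDMap, init: dict) -> set:
    """Entity ids present in at least one reachable state."""
    ids, _ = automaton_names(pdmap)
    seen, _ = oracle_state_graph(pdmap, init)
    out = set()
    for s in seen:
        d = dict(s)
        out.update(aid for aid in ids.values() if d[aid] == 1)
    return out


def oracle_closure(pdmap: PDMap, seed_entities) -> set:
    """Producibility fixpoint, modulations ignored (independent rewrite)."""
    reached = set(seed_entities)
    while True:
        added = False
        for proc in pdmap.processes.values():
            if set(proc.reactants) <= reached:
                for q in proc.products:
                    if q not in reached:
                        reached.add(q)
                        added = True
        if not added:
            return reached


def oracle_precursors(pdmap: PDMap, required=frozenset()):
    """All minimum-cardinality seeds covering the map, then filtered by the
    secondary objectives (set state variables, complexes), by exhaustive
    subset enumeration in increasing cardinality."""
    from sbgnq.precursor import count_set_state_variables

    entities = sorted(pdmap.entity_pools, key=lambda e: e.text)
    required = frozenset(required)
    free = [e for e in entities if e not in required]
    for k in range(len(free) + 1):
        sols = []
        for combo in combinations(free, k):
            seed = required | frozenset(combo)
            if oracle_closure(pdmap, seed) == set(entities):
                sols.append(seed)
        if sols:
            def vec(s):
                return (
                    sum(count_set_state_variables(e) for e in s),
                    sum(1 for e in s if e.epn_class == "complex"),
                )
            best = min(vec(s) for s in sols)
            return sorted(
                (s for s in sols if vec(s) == best),
                key=lambda s: sorted(e.text for e in s),
            )
    return []


def network_size(an: AutomataNetwork) -> int:
    return len(an.automata)
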