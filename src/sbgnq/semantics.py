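"""Qualitative general semantics: PD map -> asynchronous automata network.

Under the general semantics every entity pool is "present"/"absent" and
every process "switched on"/"switched off"; each is encoded by one binary
automaton.  State changes are asynchronous (one automaton per step) and
maximally permissive:

- a process may switch ON when all its reactants are present, all necessary
  stimulations targeting it are active, all absolute inhibitions are
  inactive, and — if it has any plain stimulation/catalysis/modulation or
  inhibition arcs — at least one stimulation is active or one inhibition
  inactive (a process with no such arcs satisfies this clause vacuously,
  otherwise unmodulated processes could never fire);
- a process may switch OFF when all its products are present;
- an entity may become present when some process producing it is on;
- an entity may become absent when some process consuming it is on and all
  of that process's products are present (production before consumption).

A modulation is active iff its source is satisfied: a present entity, or a
satisfied AND/OR/NOT function over entities.  Catalysis and generic
modulation are treated as stimulation (SBGN subtyping); the choice is
logged per process at translation time.  Stoichiometry is ignored and
source/sink pools get no automaton.  The network is equivalent to a 1-safe
Petri net.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .pd_core import (
    EntityPool,
    LogicalFunction,
    PDMap,
    Process,
    render_entity_text,
    _entity_sort_key,
)

logger = logging.getLogger("sbgnq")

__all__ = [
    "Expr",
    "TRUE",
    "FALSE",
    "Var",
    "Not",
    "And",
    "Or",
    "Automaton",
    "TransitionRule",
    "AutomataNetwork",
    "MissingAutomatonError",
    "eval_modulation",
    "can_switch_on",
    "translate",
    "step",
]


class MissingAutomatonError(KeyError):
    """A guard or modulation references an automaton absent from the state."""


# ---------------------------------------------------------------------------
# Boolean expression trees (guards)
# ---------------------------------------------------------------------------

class Expr:
    """Side-effect-free Boolean condition over automata local states."""

    def eval(self, state) -> bool:
        raise NotImplementedError

    def variables(self) -> frozenset:
        raise NotImplementedError


class _Const(Expr):
    def __init__(self, value: bool):
        self.value = value

    def eval(self, state) -> bool:
        return self.value

    def variables(self):
        return frozenset()

    def __repr__(self):
        return "true" if self.value else "false"


TRUE = _Const(True)
FALSE = _Const(False)


class Var(Expr):
    """Atom: automaton *aid* is in local state 1."""

    __slots__ = ("aid",)

    def __init__(self, aid: str):
        self.aid = aid

    def eval(self, state) -> bool:
        try:
            return bool(state[self.aid])
        except KeyError:
            raise MissingAutomatonError(self.aid) from None

    def variables(self):
        return frozenset((self.aid,))

    def __repr__(self):
        return f'"{self.aid}"=1'


class Not(Expr):
    __slots__ = ("child",)

    def __init__(self, child: Expr):
        self.child = child

    def eval(self, state) -> bool:
        return not self.child.eval(state)

    def variables(self):
        return self.child.variables()

    def __repr__(self):
        if isinstance(self.child, Var):
            return f'"{self.child.aid}"=0'
        return f"not ({self.child!r})"


class And(Expr):
    __slots__ = ("children",)

    def __init__(self, children: Iterable[Expr]):
        self.children = tuple(children)

    def eval(self, state) -> bool:
        return all(c.eval(state) for c in self.children)

    def variables(self):
        return frozenset().union(*(c.variables() for c in self.children))

    def __repr__(self):
        return " and ".join(f"({c!r})" for c in self.children) or "true"


class Or(Expr):
    __slots__ = ("children",)

    def __init__(self, children: Iterable[Expr]):
        self.children = tuple(children)

    def eval(self, state) -> bool:
        return any(c.eval(state) for c in self.children)

    def variables(self):
        return frozenset().union(*(c.variables() for c in self.children))

    def __repr__(self):
        return " or ".join(f"({c!r})" for c in self.children) or "false"


def _and(exprs) -> Expr:
    exprs = [e for e in exprs if e is not TRUE]
    if any(e is FALSE for e in exprs):
        return FALSE
    if not exprs:
        return TRUE
    if len(exprs) == 1:
        return exprs[0]
    return And(exprs)


def _or(exprs) -> Expr:
    exprs = [e for e in exprs if e is not FALSE]
    if any(e is TRUE for e in exprs):
        return TRUE
    if not exprs:
        return FALSE
    if len(exprs) == 1:
        return exprs[0]
    return Or(exprs)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Automaton:
    """One binary automaton (local states fixed to {0, 1})."""

    id: str
    kind: str  # "entity" | "process"


@dataclass(frozen=True)
class TransitionRule:
    """Guarded local transition ``automaton: frm -> 1-frm when guard``."""

    automaton: str
    frm: int  # 0 or 1; direction is frm -> 1-frm
    guard: Expr = TRUE

    @property
    def to(self) -> int:
        return 1 - self.frm

    def label(self) -> str:
        return f"{self.automaton}:{self.frm}->{self.to}"


@dataclass
class AutomataNetwork:
    """Asynchronous automata network with provenance back to the source map.

    ``order`` fixes a canonical automaton ordering (entities in canonical
    entity order, then processes by identifier) used for state packing and
    deterministic iteration.  ``forced`` holds values clamped by mutations
    (see :mod:`sbgnq.reachability`).
    """

    automata: dict = field(default_factory=dict)  # id -> Automaton
    rules: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)  # id -> source concept
    order: list = field(default_factory=list)
    forced: dict = field(default_factory=dict)  # id -> clamped value

    def __post_init__(self):
        if not self.order:
            self.order = sorted(self.automata)
        self._index()

    def _index(self):
        self._rules_by_automaton: dict = {}
        for r in self.rules:
            unknown = r.guard.variables() - set(self.automata)
            if unknown:
                raise MissingAutomatonError(sorted(unknown)[0])
            if r.automaton in r.guard.variables():
                raise ValueError(
                    f"guard of {r.label()} references its own automaton"
                )
            self._rules_by_automaton.setdefault(r.automaton, []).append(r)

    def rules_for(self, aid: str, frm: Optional[int] = None):
        rules = self._rules_by_automaton.get(aid, [])
        if frm is None:
            return list(rules)
        return [r for r in rules if r.frm == frm]

    @property
    def entity_ids(self):
        return [a for a in self.order if self.automata[a].kind == "entity"]

    @property
    def process_ids(self):
        return [a for a in self.order if self.automata[a].kind == "process"]

    def entity_id(self, query) -> str:
        """Resolve an entity pool, marker text, or automaton id to an id."""
        if isinstance(query, str):
            if query in self.automata:
                return query
            hits = [
                aid for aid, concept in self.provenance.items()
                if isinstance(concept, EntityPool)
                and render_entity_text(concept) == query
            ]
            if len(hits) == 1:
                return hits[0]
            if len(hits) > 1:
                raise KeyError(f"ambiguous entity {query!r}: {sorted(hits)}")
            raise KeyError(f"no automaton for entity {query!r}")
        for aid, concept in self.provenance.items():
            if concept == query:
                return aid
        raise KeyError(f"no automaton for entity {render_entity_text(query)!r}")

    def replaced(self, rules=None, forced=None) -> "AutomataNetwork":
        return AutomataNetwork(
            automata=dict(self.automata),
            rules=list(self.rules if rules is None else rules),
            provenance=dict(self.provenance),
            order=list(self.order),
            forced=dict(self.forced if forced is None else forced),
        )

    # -- state packing ------------------------------------------------------

    def pack(self, state: dict) -> int:
        bits = 0
        for i, aid in enumerate(self.order):
            if state[aid]:
                bits |= 1 << i
        return bits

    def unpack(self, bits: int) -> dict:
        return {aid: (bits >> i) & 1 for i, aid in enumerate(self.order)}

    # -- exchange formats ---------------------------------------------------

    def to_text(self) -> str:
        """Plain-text exchange format: one automaton declaration per line,
        then one guarded transition per line."""
        lines = [
            f'automaton "{aid}" {self.automata[aid].kind}' for aid in self.order
        ]
        for aid in self.order:
            for r in sorted(self.rules_for(aid), key=lambda r: r.frm):
                lines.append(f'"{aid}" {r.frm} -> {r.to} when {r.guard!r}')
        return "\n".join(lines) + "\n"

    def provenance_json(self) -> str:
        payload = {}
        for aid in self.order:
            concept = self.provenance.get(aid)
            if isinstance(concept, EntityPool):
                payload[aid] = {
                    "kind": "entity",
                    "text": render_entity_text(concept),
                    "compartment": concept.compartment.label
                    if concept.compartment else None,
                }
            elif isinstance(concept, Process):
                payload[aid] = {
                    "kind": "process",
                    "class": concept.process_class,
                    "identifier": concept.identifier,
                }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Rule evaluation on the map (reference semantics for single states)
# ---------------------------------------------------------------------------

def _entity_ids_for_map(pdmap: PDMap) -> dict:
    """Canonical automaton id per entity pool.

    The rendered entity text when unique in the map; disambiguated with an
    ``@compartment`` suffix otherwise.  Deterministic for a given map.
    """
    pools = sorted(pdmap.entity_pools, key=_entity_sort_key)
    by_text: dict = {}
    for e in pools:
        by_text.setdefault(render_entity_text(e), []).append(e)
    ids = {}
    for text, group in by_text.items():
        if len(group) == 1:
            ids[group[0]] = text
        else:
            for e in group:
                comp = e.compartment.label if e.compartment else ""
                ids[e] = f"{text}@{comp}"
    if len(set(ids.values())) != len(ids):
        # same text and compartment but different class: fall back to class tag
        ids = {
            e: f"{render_entity_text(e)}@{e.compartment.label if e.compartment else ''}"
               f"#{e.epn_class}"
            for e in pools
        }
    return ids


def eval_modulation(source, state: dict, ids: Optional[dict] = None) -> bool:
    """Truth value of a modulation source in a global state.

    An entity source is satisfied iff its automaton is at 1; a logical
    function is evaluated with present = true.  *ids* maps entity pools to
    automaton ids (defaults to rendered entity text)."""
    if isinstance(source, LogicalFunction):
        values = (eval_modulation(c, state, ids) for c in source.children)
        if source.operator == "AND":
            return all(values)
        if source.operator == "OR":
            return any(values)
        return not next(values)
    aid = ids[source] if ids is not None else render_entity_text(source)
    try:
        return bool(state[aid])
    except KeyError:
        raise MissingAutomatonError(aid) from None


def can_switch_on(
    pdmap: PDMap, process: Process, state: dict, ids: Optional[dict] = None
) -> bool:
    """May *process* switch on in *state*?

    All reactants present, all necessary stimulations active, all absolute
    inhibitions inactive, and — only if plain stimulation/catalysis/
    modulation or inhibition arcs exist — at least one stimulation active or
    one inhibition inactive."""
    if ids is None:
        ids = _entity_ids_for_map(pdmap)
    for r in process.reactants:
        if not state[ids[r]]:
            return False
    stims, inhibs = [], []
    for m in pdmap.modulations_of(process.identifier):
        active = eval_modulation(m.source, state, ids)
        if m.mod_class == "necessary-stimulation":
            if not active:
                return False
        elif m.mod_class == "absolute-inhibition":
            if active:
                return False
        elif m.mod_class == "inhibition":
            inhibs.append(active)
        else:  # stimulation, catalysis, generic modulation
            stims.append(active)
    if not stims and not inhibs:
        return True  # vacuous disjunct: unmodulated process
    return any(stims) or any(not a for a in inhibs)


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def _source_expr(source, ids: dict) -> Expr:
    if isinstance(source, LogicalFunction):
        children = [_source_expr(c, ids) for c in source.children]
        if source.operator == "AND":
            return _and(children)
        if source.operator == "OR":
            return _or(children)
        return Not(children[0])
    return Var(ids[source])


def translate(pdmap: PDMap) -> AutomataNetwork:
    """Encode *pdmap* as an asynchronous automata network.

    One automaton per entity pool and per process; guards built from the
    general-semantics rules.  An automaton whose direction has an
    unsatisfiable or empty guard simply lacks that rule.  Deterministic:
    the same map always yields an identical network."""
    ids = _entity_ids_for_map(pdmap)
    automata: dict = {}
    provenance: dict = {}
    order: list = []

    for e in sorted(pdmap.entity_pools, key=_entity_sort_key):
        aid = ids[e]
        automata[aid] = Automaton(aid, "entity")
        provenance[aid] = e
        order.append(aid)

    proc_ids: dict = {}
    for pid in sorted(pdmap.processes):
        aid = pid if pid not in automata else f"process:{pid}"
        automata[aid] = Automaton(aid, "process")
        provenance[aid] = pdmap.processes[pid]
        proc_ids[pid] = aid
        order.append(aid)

    rules: list = []
    for pid in sorted(pdmap.processes):
        proc = pdmap.processes[pid]
        aid = proc_ids[pid]
        conjuncts = [Var(ids[r]) for r in set(proc.reactants)]
        stims, inhibs = [], []
        for m in sorted(
            pdmap.modulations_of(pid), key=lambda m: (m.mod_class, repr(m.source))
        ):
            expr = _source_expr(m.source, ids)
            if m.mod_class == "necessary-stimulation":
                conjuncts.append(expr)
            elif m.mod_class == "absolute-inhibition":
                conjuncts.append(Not(expr))
            elif m.mod_class == "inhibition":
                inhibs.append(expr)
            else:
                if m.mod_class in ("catalysis", "modulation"):
                    logger.debug(
                        "process %s: treating %s arc as stimulation",
                        pid, m.mod_class,
                    )
                stims.append(expr)
        if stims or inhibs:
            conjuncts.append(_or(stims + [Not(i) for i in inhibs]))
        on_guard = _and(conjuncts)
        if on_guard is not FALSE:
            rules.append(TransitionRule(aid, 0, on_guard))
        off_guard = _and([Var(ids[p]) for p in set(proc.products)])
        if off_guard is not FALSE:
            rules.append(TransitionRule(aid, 1, off_guard))

    for e in sorted(pdmap.entity_pools, key=_entity_sort_key):
        aid = ids[e]
        producers = [
            Var(proc_ids[p.identifier]) for p in pdmap.producers_of(e)
        ]
        if producers:
            rules.append(TransitionRule(aid, 0, _or(producers)))
        consumers = []
        for p in pdmap.consumers_of(e):
            # the entity itself may be among the products (e.g. a template
            # that is both reactant and product): from local state 1 that
            # conjunct holds vacuously and must not self-reference
            consumers.append(
                _and(
                    [Var(proc_ids[p.identifier])]
                    + [Var(ids[q]) for q in set(p.products) if q != e]
                )
            )
        if consumers:
            rules.append(TransitionRule(aid, 1, _or(consumers)))

    return AutomataNetwork(
        automata=automata, rules=rules, provenance=provenance, order=order
    )


def step(an: AutomataNetwork, state: dict) -> list:
    """Asynchronous successors of *state*: one per enabled rule.

    Each successor differs from *state* in exactly one automaton.
    Deterministic order (canonical automaton order, 0->1 before 1->0).
    Returns a list of ``(successor state, fired rule)`` pairs accessible
    positionally; plain successor states via ``[s for s, _ in step(...)]``.
    """
    out = []
    for aid in an.order:
        for rule in sorted(an.rules_for(aid, frm=state[aid]), key=lambda r: r.frm):
            if rule.guard.eval(state):
                nxt = dict(state)
                nxt[aid] = rule.to
                out.append((nxt, rule))
    return out
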