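"""Minimal precursor states.

A precursor state is a smallest set of entities whose initial presence lets
every entity of the map be produced when modulator effects are ignored:
seeding the producibility closure (a least fixpoint over the reaction graph
with all modulations removed) with the precursor covers the whole map.
Catalysts are modulations and hence invisible to the closure, so an enzyme
with no producing process must sit in every precursor state.

Optima are enumerated exhaustively under lexicographic objectives
(default order): (1) fewest entities, (2) fewest state variables set to a
value among the chosen entities (counted recursively through complex
subunits), (3) fewest complexes.  The solver is a branch-and-bound over the
subset lattice with the closure as feasibility check; an equivalent
answer-set-programming encoding is shipped as a text asset
(``data/precursor.lp``) for use with an external ASP solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

from .pd_core import EntityPool, PDMap, render_entity_text, _entity_sort_key
from .reachability import unreachability_overapprox
from .semantics import _entity_ids_for_map

__all__ = [
    "PrecursorState",
    "ObjectiveConfig",
    "InfeasibleMapError",
    "OBJECTIVES",
    "closure",
    "compute_precursors",
    "count_set_state_variables",
]

OBJECTIVES = ("min-cardinality", "min-state-variables", "min-complexes")


class InfeasibleMapError(ValueError):
    """No seed can make every entity producible; names the unreachable ones."""

    def __init__(self, unreachable: Iterable[str]):
        self.unreachable = sorted(unreachable)
        super().__init__(
            "no precursor state exists; unproducible even from the full seed: "
            + ", ".join(self.unreachable)
        )


@dataclass(frozen=True)
class PrecursorState:
    """A minimal set of initially-present entities covering the map."""

    entities: frozenset  # of EntityPool

    def __post_init__(self):
        object.__setattr__(self, "entities", frozenset(self.entities))

    @property
    def texts(self) -> tuple:
        return tuple(
            sorted(render_entity_text(e) for e in self.entities)
        )


@dataclass(frozen=True)
class ObjectiveConfig:
    """Required entities plus the lexicographic objective order."""

    required: frozenset = frozenset()
    order: tuple = OBJECTIVES

    def __post_init__(self):
        object.__setattr__(self, "required", frozenset(self.required))
        object.__setattr__(self, "order", tuple(self.order))
        if not self.order:
            raise ValueError("objective order must be non-empty")
        if len(set(self.order)) != len(self.order):
            raise ValueError("duplicate objectives")
        unknown = set(self.order) - set(OBJECTIVES)
        if unknown:
            raise ValueError(f"unknown objectives: {sorted(unknown)}")


def closure(pdmap: PDMap, seed: Iterable) -> frozenset:
    """Entities producible from *seed* when modulations are ignored.

    Same least fixpoint as
    :func:`sbgnq.reachability.unreachability_overapprox`, exposed here as
    the feasibility predicate of the precursor search; returns entity pools
    rather than automaton ids."""
    ids = _entity_ids_for_map(pdmap)
    reached = unreachability_overapprox(pdmap, seed)
    return frozenset(e for e, aid in ids.items() if aid in reached)


def count_set_state_variables(entity: EntityPool) -> int:
    """State variables with a set value, recursively through subunits."""
    n = sum(1 for sv in entity.state_variables if sv.is_set)
    return n + sum(count_set_state_variables(s) for s in entity.subunits)


def _objective_vector(entities: frozenset, order: tuple) -> tuple:
    values = {
        "min-cardinality": len(entities),
        "min-state-variables": sum(count_set_state_variables(e) for e in entities),
        "min-complexes": sum(1 for e in entities if e.epn_class == "complex"),
    }
    return tuple(values[o] for o in order)


def compute_precursors(
    pdmap: PDMap, config: ObjectiveConfig = ObjectiveConfig()
) -> list:
    """Enumerate ALL lexicographically optimal precursor states.

    Every solution contains ``config.required`` and passes the closure
    constraint (all entities producible).  Entities with no producing
    process are forced into every solution, which prunes the search; the
    remaining candidates are scanned by increasing added cardinality and
    all subset-minimal feasible seeds are collected before the objective
    filter.  Raises :class:`InfeasibleMapError` when even the full entity
    set cannot cover the map (a self-consuming production loop)."""
    entities = frozenset(pdmap.entity_pools)
    missing = config.required - entities
    if missing:
        raise KeyError(
            "required entities not in map: "
            + ", ".join(sorted(render_entity_text(e) for e in missing))
        )
    full = closure(pdmap, entities)
    if full != entities:
        raise InfeasibleMapError(
            render_entity_text(e) for e in entities - full
        )

    producible_at_all = {
        e for e in entities if any(pdmap.producers_of(e))
    }
    mandatory = entities - producible_at_all
    base = frozenset(config.required | mandatory)
    derivable = closure(pdmap, base)
    candidates = sorted(entities - base - derivable, key=_entity_sort_key)

    def feasible(extra) -> bool:
        return closure(pdmap, base | frozenset(extra)) == entities

    cardinality_only = config.order[0] == "min-cardinality"
    minimal_extras: list = []
    found_size = None
    for k in range(len(candidates) + 1):
        if found_size is not None and cardinality_only:
            break
        layer = []
        for combo in combinations(candidates, k):
            s = frozenset(combo)
            if any(m <= s for m in minimal_extras):
                continue  # contains a smaller feasible seed: not subset-minimal
            if feasible(s):
                layer.append(s)
        if layer and found_size is None:
            found_size = k
        minimal_extras.extend(layer)

    solutions = [base | s for s in minimal_extras]
    if not solutions:
        # base itself must be feasible then (candidates empty)
        raise InfeasibleMapError(
            render_entity_text(e) for e in entities - closure(pdmap, base)
        )
    best = min(_objective_vector(s, config.order) for s in solutions)
    optima = [
        PrecursorState(s)
        for s in solutions
        if _objective_vector(s, config.order) == best
    ]
    return sorted(optima, key=lambda p: p.texts)
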