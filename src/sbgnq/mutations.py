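"""Mutation screens controlling checkpoint markers.

A checkpoint is controlled by a set of simultaneous mutations — each
loss-of-function (the entity can never be present) or gain-of-function
(never absent) — that makes a phase marker unreachable from the precursor
state.  The screen here is exhaustive within its declared bounds
(candidate entities x {LoF, GoF}, up to a maximum set size) and every
reported set is subset-minimal and independently re-verified by the exact
reachability engine.  This trades the scale of static-analysis deduction
for completeness on desk-scale networks.

Also provides an existential trajectory-reliance check: whether some
trajectory to a goal passes through a state where a given entity is
present, decided by staged (layered) reachability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Optional

import pandas as pd

from .reachability import (
    BUDGET_EXCEEDED,
    DEFAULT_BUDGET,
    REACHABLE,
    UNREACHABLE,
    ConflictError,
    GoalSpec,
    Mutation,
    apply_mutations,
    initial_state,
    reachable,
    sequence_reachable,
)

__all__ = [
    "MutationSet",
    "ControlReport",
    "blocking_mutations",
    "control_summary",
    "trajectory_reliance",
]


@dataclass(frozen=True)
class MutationSet:
    """An internally consistent set of mutations (one per entity)."""

    mutations: frozenset

    def __post_init__(self):
        object.__setattr__(self, "mutations", frozenset(self.mutations))
        entities = [m.entity for m in self.mutations]
        if len(set(entities)) != len(entities):
            raise ConflictError("conflicting mutations on one entity")

    @property
    def entities(self) -> frozenset:
        return frozenset(m.entity for m in self.mutations)

    def as_tuples(self) -> tuple:
        return tuple(sorted((m.entity, m.kind) for m in self.mutations))

    def __len__(self):
        return len(self.mutations)

    def __le__(self, other) -> bool:
        return self.mutations <= other.mutations


def blocking_mutations(
    an,
    init_entities: Iterable,
    marker_goal,
    max_size: int,
    candidates: Iterable,
    budget: int = DEFAULT_BUDGET,
) -> list:
    """All subset-minimal mutation sets (size <= *max_size*, over
    *candidates* x {LoF, GoF}) that make *marker_goal* unreachable.

    *init_entities* are the entities present in the unmutated initial
    state.  The goal must be reachable in the unmutated network (otherwise
    every set trivially blocks).  For each candidate set, the initial state
    is re-derived with the mutations' clamped values (GoF entities start
    present); a LoF candidate that the caller declares initially present is
    a :class:`~sbgnq.reachability.ConflictError`.  Each returned set is
    re-verified before being reported.  Budget-exhausted checks are treated
    as non-blocking (conservative: only certain blocks are reported).
    """
    init_entities = list(init_entities)
    cand_ids = sorted(an.entity_id(c) for c in candidates)
    unknown = set(cand_ids) - set(an.entity_ids)
    if unknown:
        raise KeyError(f"candidates are not entity automata: {sorted(unknown)}")
    init_ids = {an.entity_id(e) for e in init_entities}
    base = reachable(an, initial_state(an, init_entities), marker_goal, budget)
    if base.status == UNREACHABLE:
        raise ValueError(
            "marker goal is unreachable without mutations; "
            "every mutation set would trivially block"
        )
    if base.status == BUDGET_EXCEEDED:
        raise ValueError("budget exhausted on the unmutated network")
    for c in cand_ids:
        if c in init_ids:
            raise ConflictError(
                f"candidate {c!r} is present in the initial state; "
                "a LoF clamp would contradict it"
            )

    def blocks(mut_set: MutationSet) -> bool:
        mutated = apply_mutations(an, mut_set.mutations)
        mut_init = initial_state(mutated, init_entities)
        return reachable(mutated, mut_init, marker_goal, budget).status == UNREACHABLE

    found: list = []
    for size in range(1, max_size + 1):
        for entity_combo in combinations(cand_ids, size):
            for kinds in product(("LoF", "GoF"), repeat=size):
                ms = MutationSet(
                    frozenset(
                        Mutation(e, k) for e, k in zip(entity_combo, kinds)
                    )
                )
                if any(smaller <= ms for smaller in found):
                    continue  # a subset already blocks: not minimal
                if blocks(ms):
                    found.append(ms)
    # re-verification pass: every reported set must block when re-applied
    verified = [ms for ms in found if blocks(ms)]
    assert verified == found, "screen and verification disagree"
    return sorted(verified, key=lambda m: (len(m), m.as_tuples()))


@dataclass
class ControlReport:
    """Blocking sets per target marker, with a per-entity summary.

    ``per_marker[marker] = list of MutationSet``;
    ``entity_summary[marker] = [(entity, kind, source tag), ...]`` listing
    each entity appearing in at least one blocking set, once per mutation
    kind, annotated with its source-map tag from the provenance partition.
    """

    per_marker: dict = field(default_factory=dict)
    entity_summary: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"marker": marker, "entity": e, "mutation": kind, "source_map": tag}
            for marker, entries in self.entity_summary.items()
            for e, kind, tag in entries
        ]
        return pd.DataFrame(rows, columns=["marker", "entity", "mutation", "source_map"])

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)


def control_summary(results: Iterable, partition: Optional[dict] = None) -> ControlReport:
    """Summarize screen results: *results* is (marker label, mutation sets)
    pairs; *partition* maps entity id -> source-map tag.  Entities in
    several blocking sets are listed once per mutation kind; ordering is
    deterministic."""
    partition = partition or {}
    report = ControlReport()
    for marker, sets in results:
        sets = sorted(sets, key=lambda m: (len(m), m.as_tuples()))
        report.per_marker[marker] = sets
        entries = sorted(
            {
                (m.entity, m.kind, partition.get(m.entity, ""))
                for ms in sets
                for m in ms.mutations
            }
        )
        report.entity_summary[marker] = entries
    return report


def trajectory_reliance(
    an,
    init: dict,
    goal,
    entity,
    budget: int = DEFAULT_BUDGET,
) -> str:
    """Does some trajectory to *goal* pass through *entity* present?

    Existential check by staged reachability: first reach a state with the
    entity present, then the goal from there.  Returns ``"relies"``,
    ``"does-not-rely"``, or ``"unknown"`` on budget exhaustion.  The goal
    must be reachable at all (precondition)."""
    aid = an.entity_id(entity)
    base = reachable(an, init, goal, budget)
    if base.status == UNREACHABLE:
        raise ValueError("goal is not reachable; reliance is undefined")
    if base.status == BUDGET_EXCEEDED:
        return "unknown"
    if init[aid]:
        return "relies"
    staged = sequence_reachable(
        an, init, [GoalSpec(frozenset((aid,))), goal], budget
    )
    if staged.status == BUDGET_EXCEEDED:
        return "unknown"
    return "relies" if staged.status == REACHABLE else "does-not-rely"
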