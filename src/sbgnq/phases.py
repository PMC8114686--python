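"""Phase-marker bookkeeping and progression validation.

A cycle (cell cycle, circadian clock) is an ordered list of phases, each
characterized by marker entities: the model is "in" a phase when at least
one marker of that phase is present and all markers of all *other* phases
of the same cycle are absent.  Marker tables for the mammalian cell cycle
(early G1, late G1, early S, late S, G2, M) and the circadian clock (RORG,
SIRT1, ARNTL-CLOCK, PER-CRY) are packaged as data assets.

``validate_progression`` runs, per precursor state, the three-part
protocol: (A) plain reachability of every individual marker; (B)
reachability of every phase goal; (C) phase reachability re-checked with
the preceding phase's markers disabled (LoF) — a phase that stays reachable
indicates trajectories bypassing its predecessor; plus reachability of the
full cyclic phase sequence repeated a configurable number of times
(default 4).  Budget-exhausted verdicts propagate as "unknown", never as
false; a seeded random-walk fallback with explicit non-exhaustiveness
labelling can then be consulted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import pandas as pd
import yaml

from .pd_core import EntityPool, parse_entity_text, render_entity_text
from .reachability import (
    BUDGET_EXCEEDED,
    DEFAULT_BUDGET,
    REACHABLE,
    AnyGoal,
    GoalSpec,
    disable_markers,
    initial_state,
    random_walk,
    reachable,
    sequence_reachable,
)

__all__ = [
    "Marker",
    "Phase",
    "CycleSpec",
    "ProgressionReport",
    "MarkerResolutionError",
    "load_cycle_spec",
    "phase_goal",
    "validate_progression",
]


class MarkerResolutionError(ValueError):
    """A marker that does not resolve to an automaton of the network."""


@dataclass(frozen=True)
class Marker:
    """A phase marker: an entity (marker-grammar text) and its compartment."""

    entity: EntityPool
    compartment: str = ""

    @classmethod
    def from_text(cls, text: str, compartment: str = "") -> "Marker":
        return cls(parse_entity_text(text), compartment)

    @property
    def text(self) -> str:
        return render_entity_text(self.entity)


@dataclass(frozen=True)
class Phase:
    name: str
    markers: tuple

    def __post_init__(self):
        object.__setattr__(self, "markers", tuple(self.markers))
        if not self.markers:
            raise ValueError(f"phase {self.name!r} has no markers")


@dataclass(frozen=True)
class CycleSpec:
    """Named phases in cyclic order; marker sets must be pairwise disjoint."""

    name: str
    phases: tuple

    def __post_init__(self):
        object.__setattr__(self, "phases", tuple(self.phases))
        if len(self.phases) < 2:
            raise ValueError("a cycle needs at least two phases")
        seen: dict = {}
        for ph in self.phases:
            for m in ph.markers:
                if m in seen and seen[m] != ph.name:
                    raise ValueError(
                        f"marker {m.text!r} shared by phases "
                        f"{seen[m]!r} and {ph.name!r}"
                    )
                seen[m] = ph.name

    def phase(self, name: str) -> Phase:
        for ph in self.phases:
            if ph.name == name:
                return ph
        raise KeyError(name)

    def preceding(self, phase: Phase) -> Phase:
        i = self.phases.index(phase)
        return self.phases[i - 1]


def load_cycle_spec(name_or_path) -> CycleSpec:
    """Load a cycle spec from YAML; ``"cell_cycle"`` and
    ``"circadian_clock"`` name the packaged marker tables."""
    name = str(name_or_path)
    if name in ("cell_cycle", "circadian_clock"):
        text = (
            resources.files("sbgnq").joinpath(f"data/{name}.yaml").read_text()
        )
    else:
        with open(name_or_path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "phases" not in raw:
        raise ValueError(
            f"cycle spec {name!r} must be a YAML mapping with 'name' and 'phases'"
        )
    phases = tuple(
        Phase(
            p["name"],
            tuple(
                Marker.from_text(m["entity"], m.get("compartment", ""))
                for m in p["markers"]
            ),
        )
        for p in raw["phases"]
    )
    return CycleSpec(raw["name"], phases)


# ---------------------------------------------------------------------------
# Goals
# ---------------------------------------------------------------------------

def _marker_id(an, marker: Marker) -> str:
    """Resolve a marker to an automaton id, trying the compartment suffix."""
    for query in (
        marker.entity,
        marker.text,
        f"{marker.text}@{marker.compartment}" if marker.compartment else None,
    ):
        if query is None:
            continue
        try:
            return an.entity_id(query)
        except KeyError:
            continue
    raise MarkerResolutionError(
        f"marker {marker.text!r} (compartment {marker.compartment!r}) "
        "does not resolve in the network"
    )


def phase_goal(
    cycle: CycleSpec, phase: Phase, marker: Marker, an=None
) -> GoalSpec:
    """Goal for being in *phase* via *marker*: the marker present and every
    marker of every other phase of the same cycle absent.  Scoped to the one
    cycle; a second cycle's markers are unconstrained.  With *an* given,
    ids are resolved against the network; otherwise marker texts are used."""
    if marker not in phase.markers:
        raise ValueError(f"marker {marker.text!r} not in phase {phase.name!r}")

    def mid(m):
        return _marker_id(an, m) if an is not None else m.text

    absent = frozenset(
        mid(m)
        for ph in cycle.phases
        if ph != phase
        for m in ph.markers
    )
    return GoalSpec(frozenset((mid(marker),)), absent)


# ---------------------------------------------------------------------------
# Progression protocol
# ---------------------------------------------------------------------------

_VERDICT_LABEL = {True: "reachable", False: "unreachable"}


def _label(verdict) -> str:
    if verdict.status == BUDGET_EXCEEDED:
        return "unknown"
    return _VERDICT_LABEL[verdict.status == REACHABLE]


@dataclass
class ProgressionReport:
    """A/B/C results per precursor state and phase.

    ``marker_reachability[precursor][phase] = (reachable count, total)``;
    ``phase_reachability`` and ``phase_without_predecessor`` map to
    "reachable"/"unreachable"/"unknown"; ``sequence`` is the cyclic-order
    verdict per precursor.  ``budget_exceeded`` flags any "unknown".
    """

    cycle: str = ""
    repeats: int = 4
    precursors: list = field(default_factory=list)  # labels
    marker_reachability: dict = field(default_factory=dict)
    marker_detail: dict = field(default_factory=dict)
    phase_reachability: dict = field(default_factory=dict)
    phase_without_predecessor: dict = field(default_factory=dict)
    sequence: dict = field(default_factory=dict)
    budget_exceeded: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pre in self.precursors:
            for phase, (n, total) in self.marker_reachability[pre].items():
                rows.append(
                    {
                        "precursor": pre,
                        "phase": phase,
                        "markers_reachable": f"{n}/{total}",
                        "phase_reachable": self.phase_reachability[pre][phase],
                        "without_predecessor":
                            self.phase_without_predecessor[pre][phase],
                        "sequence": self.sequence[pre],
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)

    def to_dict(self) -> dict:
        return {
            "cycle": self.cycle,
            "repeats": self.repeats,
            "precursors": list(self.precursors),
            "marker_reachability": {
                pre: {ph: list(v) for ph, v in d.items()}
                for pre, d in self.marker_reachability.items()
            },
            "marker_detail": self.marker_detail,
            "phase_reachability": self.phase_reachability,
            "phase_without_predecessor": self.phase_without_predecessor,
            "sequence": self.sequence,
            "budget_exceeded": self.budget_exceeded,
        }


def validate_progression(
    an,
    precursors: Iterable,
    cycle: CycleSpec,
    repeats: int = 4,
    budget: int = DEFAULT_BUDGET,
    fallback_walks: int = 0,
    fallback_steps: int = 0,
    seed: int = 0,
) -> ProgressionReport:
    """Run the A/B/C protocol for every precursor state.

    *precursors* is an iterable of entity collections (e.g.
    :class:`~sbgnq.precursor.PrecursorState` instances or id sets).  All
    markers are resolved against the network before any model checking.
    When *fallback_walks* is positive, phases left "unknown" by budget
    exhaustion are probed by seeded random walks (a positive hit upgrades
    to "reachable"; the walk is non-exhaustive so a miss never downgrades).
    """
    marker_ids = {
        (ph.name, m): _marker_id(an, m)
        for ph in cycle.phases
        for m in ph.markers
    }

    report = ProgressionReport(cycle=cycle.name, repeats=repeats)

    for pre in precursors:
        entities = getattr(pre, "entities", pre)
        init = initial_state(an, entities)
        label = ",".join(sorted(an.entity_id(e) for e in entities)) or "(empty)"
        report.precursors.append(label)
        report.marker_reachability[label] = {}
        report.marker_detail[label] = {}
        report.phase_reachability[label] = {}
        report.phase_without_predecessor[label] = {}

        phase_any_goal = {}
        for ph in cycle.phases:
            # (A) plain marker reachability
            detail = {}
            for m in ph.markers:
                v = reachable(
                    an, init, GoalSpec(frozenset((marker_ids[(ph.name, m)],))),
                    budget,
                )
                report.budget_exceeded |= v.status == BUDGET_EXCEEDED
                detail[m.text] = _label(v)
            report.marker_detail[label][ph.name] = detail
            report.marker_reachability[label][ph.name] = (
                sum(1 for s in detail.values() if s == "reachable"),
                len(ph.markers),
            )

            # (B) phase goal: any marker goal reachable
            goals = [phase_goal(cycle, ph, m, an) for m in ph.markers]
            phase_any_goal[ph.name] = AnyGoal(tuple(goals))
            statuses = []
            for g in goals:
                v = reachable(an, init, g, budget)
                report.budget_exceeded |= v.status == BUDGET_EXCEEDED
                statuses.append(_label(v))
            if "reachable" in statuses:
                status = "reachable"
            elif "unknown" in statuses:
                status = "unknown"
            else:
                status = "unreachable"
            report.phase_reachability[label][ph.name] = status

        # (C) phase reachability with the preceding phase disabled
        for ph in cycle.phases:
            prev = cycle.preceding(ph)
            if report.phase_reachability[label][ph.name] == "unreachable":
                report.phase_without_predecessor[label][ph.name] = "unreachable"
                continue
            disabled = disable_markers(
                an, [marker_ids[(prev.name, m)] for m in prev.markers]
            )
            init_c = initial_state(disabled, entities)
            statuses = []
            for m in ph.markers:
                g = phase_goal(cycle, ph, m, an)
                v = reachable(disabled, init_c, g, budget)
                report.budget_exceeded |= v.status == BUDGET_EXCEEDED
                statuses.append(_label(v))
            if "reachable" in statuses:
                status = "reachable"
            elif "unknown" in statuses:
                status = "unknown"
            else:
                status = "unreachable"
            if status == "unknown" and fallback_walks:
                status = _walk_probe(
                    disabled, init_c, phase_any_goal[ph.name],
                    fallback_walks, fallback_steps, seed,
                )
            report.phase_without_predecessor[label][ph.name] = status

        # cyclic sequence, repeated
        seq_goals = [
            phase_any_goal[ph.name] for _ in range(repeats) for ph in cycle.phases
        ]
        v = sequence_reachable(an, init, seq_goals, budget)
        report.budget_exceeded |= v.status == BUDGET_EXCEEDED
        report.sequence[label] = _label(v)

    return report


def _walk_probe(an, init, goal, walks: int, steps: int, seed: int) -> str:
    """Non-exhaustive random-walk probe; can only confirm reachability."""
    for w in range(walks):
        traj = random_walk(an, init, steps, seed=seed + w)
        if any(goal.satisfied(s) for s in traj.states):
            return "reachable (simulation)"
    return "unknown"
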