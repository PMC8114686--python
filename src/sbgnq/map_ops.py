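"""Programmatic harmonization and merging of PD maps.

Merging two independently curated maps only makes sense after their shared
concepts have been made structurally identical (same labels, same
phosphosite granularity, same compartments).  This module provides replayable
edit scripts for that harmonization step, and a total ``merge`` that unions
two harmonized maps, collapsing structurally-equal concepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import yaml

from .pd_core import (
    Compartment,
    EntityPool,
    LogicalFunction,
    MapIntegrityError,
    Modulation,
    PDMap,
    Process,
    StateVariable,
    parse_entity_text,
)

__all__ = [
    "Edit",
    "EditScript",
    "HarmonizationReport",
    "harmonize",
    "merge",
]

_EDIT_KINDS = (
    "rename-label",
    "set-compartment",
    "add-state-variable",
    "delete-entity",
    "delete-process",
    "add-process",
    "add-modulation",
)


@dataclass(frozen=True)
class Edit:
    """One harmonization edit.

    ``kind`` selects the operation; ``args`` its parameters:

    - ``rename-label``: {old, new} — relabel every pool (and subunit) with
      label *old*;
    - ``set-compartment``: {entity, compartment} — move matching top-level
      pools;
    - ``add-state-variable``: {entity, value, site} — decorate matching
      pools, including occurrences as complex subunits;
    - ``delete-entity``: {entity} — remove matching pools and everything
      referencing them;
    - ``delete-process``: {id};
    - ``add-process`` / ``add-modulation``: concept payloads (entity texts).
    """

    kind: str
    args: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _EDIT_KINDS:
            raise ValueError(f"unknown edit kind {self.kind!r}")
        object.__setattr__(self, "args", dict(self.args))

    def __hash__(self):
        return hash((self.kind, tuple(sorted(self.args.items()))))


@dataclass
class EditScript:
    """Ordered, serializable, replayable list of edits."""

    edits: list = field(default_factory=list)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            [{"kind": e.kind, **e.args} for e in self.edits], sort_keys=False
        )

    @classmethod
    def from_yaml(cls, text: str) -> "EditScript":
        raw = yaml.safe_load(text) or []
        edits = []
        for item in raw:
            kind = item.pop("kind")
            edits.append(Edit(kind, item))
        return cls(edits)

    @classmethod
    def load(cls, path) -> "EditScript":
        with open(path) as fh:
            return cls.from_yaml(fh.read())

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())


@dataclass
class HarmonizationReport:
    """Per-edit match counts; an edit matching nothing is a logged no-op."""

    counts: list = field(default_factory=list)  # (Edit, matches)

    @property
    def noops(self):
        return [e for e, n in self.counts if n == 0]


def _rewrite_entity(entity: EntityPool, fn) -> EntityPool:
    """Apply *fn* bottom-up through subunits; fn maps EntityPool->EntityPool."""
    if entity.subunits:
        entity = replace(
            entity,
            subunits=tuple(_rewrite_entity(s, fn) for s in entity.subunits),
        )
    return fn(entity)


def _rewrite_source(source, fn):
    if isinstance(source, LogicalFunction):
        return LogicalFunction(
            source.operator, tuple(_rewrite_source(c, fn) for c in source.children)
        )
    return _rewrite_entity(source, fn)


def _rewrite_map(pdmap: PDMap, fn) -> PDMap:
    """Rebuild the map with every entity occurrence rewritten by *fn*."""
    out = PDMap()
    out.compartments = set(pdmap.compartments)
    mapping = {}
    for e in pdmap.entity_pools:
        mapping[e] = _rewrite_entity(e, fn)
        out.add_entity(mapping[e])
    for p in pdmap.processes.values():
        out.add_process(
            replace(
                p,
                reactants=tuple(mapping[r] for r in p.reactants),
                products=tuple(mapping[r] for r in p.products),
            )
        )
    for m in pdmap.modulations:
        out.add_modulation(
            Modulation(m.mod_class, _rewrite_source(m.source, fn), m.target)
        )
    for concept, refs in pdmap.annotations.items():
        out.annotate(mapping.get(concept, concept), refs)
    return out


def _matches_query(entity: EntityPool, query: EntityPool) -> bool:
    """Structural match, ignoring compartment when the query has none."""
    if query.compartment is None:
        entity = replace(entity, compartment=None)
    return entity == query


def _count_matches(pdmap: PDMap, pred) -> int:
    n = 0
    for e in pdmap.entity_pools:
        stack = [e]
        while stack:
            cur = stack.pop()
            if pred(cur):
                n += 1
            stack.extend(cur.subunits)
    return n


def _apply_edit(pdmap: PDMap, edit: Edit):
    """Returns (new map, match count)."""
    args = edit.args
    if edit.kind == "rename-label":
        old, new = args["old"], args["new"]
        n = _count_matches(pdmap, lambda e: e.label == old)

        def fn(e):
            return replace(e, label=new) if e.label == old else e

        return _rewrite_map(pdmap, fn), n

    if edit.kind == "set-compartment":
        query = parse_entity_text(args["entity"])
        comp = Compartment(args["compartment"])
        hits = [e for e in pdmap.entity_pools if _matches_query(e, query)]

        def fn(e):
            return replace(e, compartment=comp) if e in hits else e

        out = _rewrite_map(pdmap, fn)
        out.compartments.add(comp)
        return out, len(hits)

    if edit.kind == "add-state-variable":
        query = parse_entity_text(args["entity"])
        sv = StateVariable(args.get("value", ""), args.get("site", ""))
        n = _count_matches(pdmap, lambda e: _matches_query(e, query))

        def fn(e):
            if _matches_query(e, query):
                ordinal = sum(
                    1 for s in e.state_variables
                    if (s.value, s.site) == (sv.value, sv.site)
                )
                return replace(
                    e,
                    state_variables=e.state_variables
                    + (StateVariable(sv.value, sv.site, ordinal),),
                )
            return e

        return _rewrite_map(pdmap, fn), n

    if edit.kind == "delete-entity":
        query = parse_entity_text(args["entity"])
        hits = {e for e in pdmap.entity_pools if _matches_query(e, query)}
        out = PDMap()
        out.compartments = set(pdmap.compartments)
        for e in pdmap.entity_pools - hits:
            out.add_entity(e)
        for p in pdmap.processes.values():
            if any(r in hits for r in (*p.reactants, *p.products)):
                continue
            out.add_process(p)
        for m in pdmap.modulations:
            if m.target not in out.processes:
                continue
            if any(e in hits for e in m.source_entities()):
                raise MapIntegrityError(
                    f"edit {edit.kind} on {args['entity']!r} would leave a "
                    "dangling modulation source"
                )
            out.add_modulation(m)
        for concept, refs in pdmap.annotations.items():
            if concept in hits:
                continue
            if isinstance(concept, str) and concept not in out.processes:
                continue
            out.annotate(concept, refs)
        return out, len(hits)

    if edit.kind == "delete-process":
        pid = args["id"]
        if pid not in pdmap.processes:
            return pdmap.copy(), 0
        out = pdmap.copy()
        del out.processes[pid]
        out.modulations = {m for m in out.modulations if m.target != pid}
        out.annotations.pop(pid, None)
        return out, 1

    if edit.kind == "add-process":
        out = pdmap.copy()
        proc = Process(
            args.get("class", "generic"),
            tuple(parse_entity_text(t) for t in args.get("reactants", ())),
            tuple(parse_entity_text(t) for t in args.get("products", ())),
            identifier=args.get("id", ""),
        )
        out.add_process(proc)
        return out, 1

    if edit.kind == "add-modulation":
        out = pdmap.copy()
        mod = Modulation(
            args.get("class", "modulation"),
            parse_entity_text(args["source"]),
            args["target"],
        )
        out.add_modulation(mod)
        return out, 1

    raise AssertionError(edit.kind)


def harmonize(pdmap: PDMap, script: EditScript):
    """Apply *script* to a copy of *pdmap*, in order.

    Pure transformation: the input map is untouched.  Returns
    ``(new map, HarmonizationReport)``; edits that resolve to no concept are
    counted as no-ops in the report.  A structurally invalid result raises
    :class:`~sbgnq.pd_core.MapIntegrityError` naming the edit.
    """
    current = pdmap.copy()
    report = HarmonizationReport()
    for edit in script.edits:
        try:
            current, n = _apply_edit(current, edit)
            current.validate()
        except MapIntegrityError as exc:
            raise MapIntegrityError(f"edit {edit.kind} {edit.args}: {exc}") from None
        report.counts.append((edit, n))
    return current, report


def merge(a: PDMap, b: PDMap) -> PDMap:
    """Union of two harmonized maps under structural equality.

    Compartments, entity pools, processes and modulations are unioned;
    structurally equal concepts appear once.  Processes are identified by
    their structural key (class, reactants, products): when maps disagree on
    the identifier of a structurally equal process, the first map's
    identifier wins and the second's modulations are retargeted; genuine
    identifier collisions between structurally different processes are
    resolved by re-identification.  Annotations are unioned per concept,
    keyed by (database, identifier).  Total: never raises on valid inputs.
    """
    out = PDMap()
    out.compartments = a.compartments | b.compartments
    for e in (*a.entity_pools, *b.entity_pools):
        out.add_entity(e)

    by_structure: dict = {}
    remap_b: dict = {}
    for p in a.processes.values():
        out.add_process(p)
        by_structure[p.structural_key()] = p.identifier
    for p in b.processes.values():
        key = p.structural_key()
        if key in by_structure:
            remap_b[p.identifier] = by_structure[key]
            continue
        pid = p.identifier
        if pid in out.processes:
            new_pid = pid
            k = 1
            while new_pid in out.processes:
                new_pid = f"{pid}.{k}"
                k += 1
            p = Process(p.process_class, p.reactants, p.products, new_pid)
            remap_b[pid] = new_pid
        out.add_process(p)
        by_structure[key] = p.identifier

    for m in a.modulations:
        out.add_modulation(m)
    for m in b.modulations:
        out.add_modulation(
            Modulation(m.mod_class, m.source, remap_b.get(m.target, m.target))
        )

    for concept, refs in a.annotations.items():
        out.annotate(concept, refs)
    for concept, refs in b.annotations.items():
        if isinstance(concept, str):
            concept = remap_b.get(concept, concept)
            if concept not in out.processes:
                continue
        out.annotate(concept, refs)
    return out
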