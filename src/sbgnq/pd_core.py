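"""Conceptual data model for SBGN Process Description (PD) maps.

An SBGN PD map describes a reaction network: pools of identical molecules
(entity pool nodes) located in compartments, processes that consume and
produce them, and modulation arcs (stimulation, inhibition, catalysis,
necessary stimulation, generic modulation) whose source may be a single
entity pool or a logical function over several.

This module holds the in-memory model (hashable, canonicalized value
objects), the textual entity grammar used by phase-marker tables and
configuration files, and readers/writers for SBGN-ML (read+write) and
CellDesigner extended SBML (read only, conceptual subset).  Layout is
discarded on read and auto-generated on write: only the conceptual content
of a map is modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Union

from lxml import etree

logger = logging.getLogger("sbgnq")

__all__ = [
    "Compartment",
    "StateVariable",
    "EntityPool",
    "LogicalFunction",
    "Process",
    "Modulation",
    "PDMap",
    "ParseReport",
    "GrammarError",
    "UnsupportedLanguageError",
    "UnsupportedDialectError",
    "MapIntegrityError",
    "AmbiguousMatchError",
    "EPN_CLASSES",
    "PROCESS_CLASSES",
    "MODULATION_CLASSES",
    "parse_entity_text",
    "render_entity_text",
    "read_sbgnml",
    "write_sbgnml",
    "read_celldesigner",
    "find_entity",
]

EPN_CLASSES = (
    "macromolecule",
    "simple-chemical",
    "nucleic-acid-feature",
    "complex",
    "unspecified",
    "source-sink",
    "perturbing-agent",
)

PROCESS_CLASSES = (
    "generic",
    "association",
    "dissociation",
    "phenotype",
    "omitted",
    "uncertain",
)

MODULATION_CLASSES = (
    "modulation",
    "stimulation",
    "inhibition",
    "necessary-stimulation",
    "catalysis",
    "absolute-inhibition",
)


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class GrammarError(ValueError):
    """Malformed entity text; carries the 0-based character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class UnsupportedLanguageError(ValueError):
    """SBGN-ML file whose map language is not Process Description."""


class UnsupportedDialectError(ValueError):
    """SBML file without the CellDesigner extension."""


class MapIntegrityError(ValueError):
    """A map whose processes/modulations reference missing concepts."""


class AmbiguousMatchError(LookupError):
    """A fuzzy entity query that matches several pools."""

    def __init__(self, query: str, candidates: list):
        super().__init__(
            f"query {query!r} is ambiguous: matches "
            + ", ".join(render_entity_text(c) for c in candidates)
        )
        self.candidates = candidates


# ---------------------------------------------------------------------------
# Value objects
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Compartment:
    """A compartment in which entity pools are localized."""

    label: str

    def __post_init__(self):
        if not self.label:
            raise ValueError("compartment label must be non-empty")


@dataclass(frozen=True, order=True)
class StateVariable:
    """A state decoration on an entity, e.g. phosphorylation at a residue.

    ``value`` is the modification value ("P", "Ac", "ADPr", ...; empty =
    unset) and ``site`` the residue ("Thr172", ...; empty = unspecified).
    Two otherwise identical state variables on the same entity (e.g.
    ``pRB(P|P)``) are distinguished by ``ordinal``.
    """

    value: str = ""
    site: str = ""
    ordinal: int = 0

    @property
    def is_set(self) -> bool:
        return self.value != ""


def _reassign_ordinals(svs: Iterable[StateVariable]) -> tuple:
    """Keep declaration order; ordinals number duplicates of one (value, site)."""
    out = []
    seen: dict = {}
    for sv in svs:
        k = (sv.value, sv.site)
        out.append(StateVariable(sv.value, sv.site, seen.get(k, 0)))
        seen[k] = seen.get(k, 0) + 1
    return tuple(out)


@dataclass(frozen=True, eq=False)
class EntityPool:
    """A pool of identical molecules (entity pool node).

    Structural equality (``==``/``hash``) compares class, label,
    compartment, the canonically-sorted state variables, and the
    recursively canonicalized subunits — so complexes are equal up to
    subunit permutation.  Declaration order of subunits and state variables
    is preserved for rendering, making the textual renderer the exact
    inverse of the parser.
    """

    epn_class: str
    label: str = ""
    compartment: Optional[Compartment] = None
    state_variables: tuple = ()
    subunits: tuple = ()

    def __post_init__(self):
        if self.epn_class not in EPN_CLASSES:
            raise ValueError(f"unknown EPN class {self.epn_class!r}")
        if self.subunits and self.epn_class != "complex":
            raise ValueError("only complexes may have subunits")
        if self.epn_class == "complex" and not self.subunits:
            raise ValueError("a complex must have at least one subunit")
        object.__setattr__(
            self, "state_variables", _reassign_ordinals(self.state_variables)
        )
        object.__setattr__(self, "subunits", tuple(self.subunits))
        object.__setattr__(self, "_key", _entity_sort_key(self))

    def __eq__(self, other):
        if not isinstance(other, EntityPool):
            return NotImplemented
        return self._key == other._key

    def __hash__(self):
        return hash(self._key)

    @property
    def text(self) -> str:
        return render_entity_text(self)


def _entity_sort_key(e: EntityPool):
    """Canonical, order-insensitive structural key (also the sort key)."""
    cached = getattr(e, "_key", None)
    if cached is not None:
        return cached
    return (
        e.label,
        e.epn_class,
        tuple(sorted((sv.value, sv.site, sv.ordinal) for sv in e.state_variables)),
        tuple(sorted(_entity_sort_key(s) for s in e.subunits)),
        e.compartment.label if e.compartment else "",
    )


@dataclass(frozen=True)
class LogicalFunction:
    """AND/OR/NOT combination of entity pools modulating a process."""

    operator: str
    children: tuple

    def __post_init__(self):
        if self.operator not in ("AND", "OR", "NOT"):
            raise ValueError(f"unknown operator {self.operator!r}")
        if self.operator == "NOT" and len(self.children) != 1:
            raise ValueError("NOT takes exactly one child")
        if self.operator in ("AND", "OR") and len(self.children) < 2:
            raise ValueError(f"{self.operator} takes at least two children")
        object.__setattr__(
            self, "children", tuple(sorted(self.children, key=_source_sort_key))
        )

    def entities(self) -> Iterator[EntityPool]:
        for c in self.children:
            if isinstance(c, LogicalFunction):
                yield from c.entities()
            else:
                yield c


def _source_sort_key(s):
    if isinstance(s, LogicalFunction):
        return (1, s.operator, tuple(_source_sort_key(c) for c in s.children))
    return (0, _entity_sort_key(s))


@dataclass(frozen=True)
class Process:
    """A process transforming reactant pools into product pools.

    A source process has no reactants; a sink process has no products.
    ``identifier`` is unique per map but excluded from the structural key
    used when maps are merged.
    """

    process_class: str
    reactants: tuple = ()
    products: tuple = ()
    identifier: str = ""

    def __post_init__(self):
        if self.process_class not in PROCESS_CLASSES:
            raise ValueError(f"unknown process class {self.process_class!r}")
        object.__setattr__(
            self, "reactants", tuple(sorted(self.reactants, key=_entity_sort_key))
        )
        object.__setattr__(
            self, "products", tuple(sorted(self.products, key=_entity_sort_key))
        )

    def structural_key(self):
        return (self.process_class, self.reactants, self.products)


@dataclass(frozen=True)
class Modulation:
    """A modulation arc from an entity pool or logical function to a process.

    The target is referenced by process identifier.  The
    ``absolute-inhibition`` class is never produced by SBGN-ML parsing; it
    can only be set explicitly (configuration or edit scripts).
    """

    mod_class: str
    source: Union[EntityPool, LogicalFunction]
    target: str

    def __post_init__(self):
        if self.mod_class not in MODULATION_CLASSES:
            raise ValueError(f"unknown modulation class {self.mod_class!r}")

    def source_entities(self) -> Iterator[EntityPool]:
        if isinstance(self.source, LogicalFunction):
            yield from self.source.entities()
        else:
            yield self.source


# ---------------------------------------------------------------------------
# PDMap
# ---------------------------------------------------------------------------

class PDMap:
    """Conceptual content of one SBGN PD map.

    Mutable container; the analysis layers treat maps as values and copy
    before editing.  Structural equality (``==``) ignores process
    identifiers and ordering.
    """

    def __init__(self):
        self.compartments: set = set()
        self.entity_pools: set = set()
        self.processes: dict = {}  # identifier -> Process
        self.modulations: set = set()
        # concept (EntityPool | process identifier) -> tuple of (db, id)
        self.annotations: dict = {}

    # -- construction -------------------------------------------------------

    def add_compartment(self, comp: Compartment) -> Compartment:
        self.compartments.add(comp)
        return comp

    def add_entity(self, entity: EntityPool) -> EntityPool:
        if entity.epn_class == "source-sink":
            return entity  # empty-set participants carry no pool
        if entity.compartment is not None:
            self.compartments.add(entity.compartment)
        self.entity_pools.add(entity)
        return entity

    def add_process(self, process: Process) -> Process:
        if not process.identifier:
            process = replace(process, identifier=f"p{len(self.processes) + 1}")
        if process.identifier in self.processes:
            raise ValueError(f"duplicate process identifier {process.identifier!r}")
        for e in (*process.reactants, *process.products):
            self.add_entity(e)
        self.processes[process.identifier] = process
        return process

    def add_modulation(self, mod: Modulation) -> Modulation:
        if mod.target not in self.processes:
            raise MapIntegrityError(
                f"modulation targets unknown process {mod.target!r}"
            )
        for e in mod.source_entities():
            self.add_entity(e)
        self.modulations.add(mod)
        return mod

    def annotate(self, concept, refs: Iterable) -> None:
        existing = dict.fromkeys(self.annotations.get(concept, ()))
        for ref in refs:
            existing[tuple(ref)] = None
        self.annotations[concept] = tuple(existing)

    def copy(self) -> "PDMap":
        m = PDMap()
        m.compartments = set(self.compartments)
        m.entity_pools = set(self.entity_pools)
        m.processes = dict(self.processes)
        m.modulations = set(self.modulations)
        m.annotations = dict(self.annotations)
        return m

    # -- queries ------------------------------------------------------------

    def modulations_of(self, process_id: str):
        return [m for m in self.modulations if m.target == process_id]

    def producers_of(self, entity: EntityPool):
        return [p for p in self.processes.values() if entity in p.products]

    def consumers_of(self, entity: EntityPool):
        return [p for p in self.processes.values() if entity in p.reactants]

    # -- integrity ----------------------------------------------------------

    def validate(self) -> None:
        for p in self.processes.values():
            for e in (*p.reactants, *p.products):
                if e not in self.entity_pools:
                    raise MapIntegrityError(
                        f"process {p.identifier!r} references entity "
                        f"{render_entity_text(e)!r} not in the map"
                    )
        for m in self.modulations:
            if m.target not in self.processes:
                raise MapIntegrityError(
                    f"modulation targets unknown process {m.target!r}"
                )
            for e in m.source_entities():
                if e not in self.entity_pools:
                    raise MapIntegrityError(
                        f"modulation source {render_entity_text(e)!r} not in the map"
                    )

    # -- structural equality ------------------------------------------------

    def structural_signature(self):
        def proc_key(p):
            return (
                p.process_class,
                tuple(_entity_sort_key(e) for e in p.reactants),
                tuple(_entity_sort_key(e) for e in p.products),
            )

        procs = sorted(proc_key(p) for p in self.processes.values())
        id_to_key = {p.identifier: proc_key(p) for p in self.processes.values()}
        mods = sorted(
            (m.mod_class, _source_sort_key(m.source), id_to_key[m.target])
            for m in self.modulations
        )
        return (
            tuple(sorted(self.compartments)),
            tuple(sorted(self.entity_pools, key=_entity_sort_key)),
            tuple(procs),
            tuple(mods),
        )

    def __eq__(self, other):
        if not isinstance(other, PDMap):
            return NotImplemented
        return self.structural_signature() == other.structural_signature()

    def __repr__(self):
        return (
            f"<PDMap {len(self.entity_pools)} entities, "
            f"{len(self.processes)} processes, "
            f"{len(self.modulations)} modulations>"
        )


# ---------------------------------------------------------------------------
# Entity grammar  (marker strings, e.g. "CCND1:CDK6(P@Thr):CDKN1B")
# ---------------------------------------------------------------------------
#
#   complex = entity { ":" entity }
#   entity  = label [ "(" mod { "|" mod } ")" ]
#   mod     = value [ "@" site ]
#
# Every ":" separates subunits; case-sensitive; offsets in errors are
# 0-based.  Whitespace around tokens is ignored (marker tables line-wrap).

_DELIMS = set(":()|@")


def _scan_token(text: str, pos: int) -> tuple:
    start = pos
    while pos < len(text) and text[pos] not in _DELIMS:
        pos += 1
    return text[start:pos].strip(), pos


def parse_entity_text(
    text: str,
    compartment: Optional[str] = None,
    chemical_labels: Iterable[str] = (),
) -> EntityPool:
    """Parse a marker string into an :class:`EntityPool`.

    Single entities become macromolecules (or simple chemicals when their
    label is listed in *chemical_labels*); ``":"``-joined entities become a
    complex of those subunits.  *compartment* is attached to the top-level
    pool when given.
    """
    chemicals = set(chemical_labels)
    comp = Compartment(compartment) if compartment else None
    units = []
    pos = 0
    n = len(text)
    while True:
        label, pos = _scan_token(text, pos)
        if not label:
            raise GrammarError("empty entity label", pos)
        svs = []
        if pos < n and text[pos] == "(":
            open_at = pos
            pos += 1
            while True:
                value, pos = _scan_token(text, pos)
                site = ""
                if pos < n and text[pos] == "@":
                    pos += 1
                    site, pos = _scan_token(text, pos)
                    if not site:
                        raise GrammarError("empty site after '@'", pos)
                if not value and not site:
                    raise GrammarError("empty state variable", pos)
                svs.append(StateVariable(value, site, ordinal=len(svs)))
                if pos < n and text[pos] == "|":
                    pos += 1
                    continue
                if pos < n and text[pos] == ")":
                    pos += 1
                    break
                raise GrammarError("unbalanced parenthesis", open_at)
        cls = "simple-chemical" if label in chemicals else "macromolecule"
        units.append(EntityPool(cls, label, None, tuple(svs)))
        if pos < n and text[pos] == ":":
            pos += 1
            continue
        break
    if pos != n:
        raise GrammarError(f"unexpected character {text[pos]!r}", pos)
    if len(units) == 1:
        return replace(units[0], compartment=comp)
    return EntityPool("complex", "", comp, (), tuple(units))


def render_entity_text(entity: EntityPool) -> str:
    """Inverse of :func:`parse_entity_text` (compartment not rendered)."""
    if entity.epn_class == "complex":
        return ":".join(render_entity_text(s) for s in entity.subunits)
    out = entity.label
    if entity.state_variables:
        mods = "|".join(
            sv.value + (f"@{sv.site}" if sv.site else "")
            for sv in entity.state_variables
        )
        out += f"({mods})"
    return out


def find_entity(pdmap: PDMap, query, fuzzy: bool = False) -> Optional[EntityPool]:
    """Locate the unique structurally-equal entity pool, or ``None``.

    String queries are parsed with the marker grammar first.  When exact
    structural lookup fails, matching falls back to rendered-text equality
    against the map's inventory (this resolves complexes whose subunit
    labels themselves contain ``":"``, such as SWI:SNF), then — with
    ``fuzzy`` — to substring matching, raising :class:`AmbiguousMatchError`
    on several candidates.
    """
    if isinstance(query, str):
        text = query.strip()
        try:
            parsed = parse_entity_text(text)
        except GrammarError:
            parsed = None
    else:
        parsed = query
        text = render_entity_text(query)

    if parsed is not None and parsed in pdmap.entity_pools:
        return parsed
    # ignore compartment: unique match on compartment-free structure
    if parsed is not None:
        bare = replace(parsed, compartment=None)
        hits = [
            e for e in pdmap.entity_pools
            if replace(e, compartment=None) == bare
        ]
        if len(hits) == 1:
            return hits[0]
    # rendered-text fallback (longest-label complexes like SWI:SNF)
    hits = [e for e in pdmap.entity_pools if render_entity_text(e) == text]
    if len(hits) == 1:
        return hits[0]
    if fuzzy:
        cands = [e for e in pdmap.entity_pools if text in render_entity_text(e)]
        if len(cands) > 1:
            raise AmbiguousMatchError(text, sorted(cands, key=_entity_sort_key))
        if cands:
            return cands[0]
    return None


# ---------------------------------------------------------------------------
# SBGN-ML  (read 0.2 / 0.3, write 0.3)
# ---------------------------------------------------------------------------

_SBGN_NS = {
    "0.2": "http://sbgn.org/libsbgn/0.2",
    "0.3": "http://sbgn.org/libsbgn/0.3",
}

_EPN_TO_SBGN = {
    "macromolecule": "macromolecule",
    "simple-chemical": "simple chemical",
    "nucleic-acid-feature": "nucleic acid feature",
    "complex": "complex",
    "unspecified": "unspecified entity",
    "source-sink": "source and sink",
    "perturbing-agent": "perturbing agent",
}
_SBGN_TO_EPN = {v: k for k, v in _EPN_TO_SBGN.items()}
_SBGN_TO_EPN["empty set"] = "source-sink"  # 0.3 rename

_PROC_TO_SBGN = {
    "generic": "process",
    "association": "association",
    "dissociation": "dissociation",
    "phenotype": "phenotype",
    "omitted": "omitted process",
    "uncertain": "uncertain process",
}
_SBGN_TO_PROC = {v: k for k, v in _PROC_TO_SBGN.items()}

_MOD_TO_SBGN = {
    "modulation": "modulation",
    "stimulation": "stimulation",
    "inhibition": "inhibition",
    "necessary-stimulation": "necessary stimulation",
    "catalysis": "catalysis",
    # written for completeness; never produced by parsing
    "absolute-inhibition": "absolute inhibition",
}
_SBGN_TO_MOD = {
    v: k for k, v in _MOD_TO_SBGN.items() if k != "absolute-inhibition"
}

_LOGIC_CLASSES = {"and": "AND", "or": "OR", "not": "NOT"}


@dataclass
class ParseReport:
    """Structured record of what a reader consumed, skipped, and warned on."""

    glyph_counts: dict = field(default_factory=dict)
    arc_counts: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        logger.warning(message)


def _localname(el) -> str:
    return etree.QName(el).localname


def write_sbgnml(pdmap: PDMap, path) -> None:
    """Serialize *pdmap* to SBGN-ML 0.3 with placeholder layout.

    Output is deterministic (canonical ordering of glyphs and arcs), so the
    same map always yields byte-identical files.
    """
    ns = _SBGN_NS["0.3"]
    root = etree.Element(f"{{{ns}}}sbgn", nsmap={None: ns})
    map_el = etree.SubElement(
        root, f"{{{ns}}}map", attrib={"language": "process description", "id": "map1"}
    )

    counter = {"n": 0}

    def fresh(prefix: str) -> str:
        counter["n"] += 1
        return f"{prefix}{counter['n']}"

    def bbox(el):
        i = counter["n"]
        etree.SubElement(
            el, f"{{{ns}}}bbox",
            attrib={"x": str(10.0 * i), "y": str(10.0 * i), "w": "40.0", "h": "20.0"},
        )

    comp_ids = {}
    for comp in sorted(pdmap.compartments):
        gid = fresh("comp")
        g = etree.SubElement(
            map_el, f"{{{ns}}}glyph", attrib={"class": "compartment", "id": gid}
        )
        etree.SubElement(g, f"{{{ns}}}label", attrib={"text": comp.label})
        bbox(g)
        comp_ids[comp] = gid

    entity_ids = {}

    def emit_entity(parent, entity: EntityPool, top: bool) -> str:
        gid = fresh("g")
        attrib = {"class": _EPN_TO_SBGN[entity.epn_class], "id": gid}
        if top and entity.compartment is not None:
            attrib["compartmentRef"] = comp_ids[entity.compartment]
        g = etree.SubElement(parent, f"{{{ns}}}glyph", attrib=attrib)
        if entity.label:
            etree.SubElement(g, f"{{{ns}}}label", attrib={"text": entity.label})
        bbox(g)
        for sv in entity.state_variables:
            sg = etree.SubElement(
                g, f"{{{ns}}}glyph",
                attrib={"class": "state variable", "id": fresh("sv")},
            )
            attr = {}
            if sv.value:
                attr["value"] = sv.value
            if sv.site:
                attr["variable"] = sv.site
            etree.SubElement(sg, f"{{{ns}}}state", attrib=attr)
            bbox(sg)
        for sub in entity.subunits:
            emit_entity(g, sub, top=False)
        return gid

    for entity in sorted(pdmap.entity_pools, key=_entity_sort_key):
        entity_ids[entity] = emit_entity(map_el, entity, top=True)

    def ncname(identifier: str) -> str:
        safe = "".join(
            c if (c.isalnum() or c in "._-") else "_" for c in identifier
        )
        if not safe or not (safe[0].isalpha() or safe[0] == "_"):
            safe = f"p_{safe}"
        return safe

    proc_ids = {}
    arcs = []  # deferred so glyphs precede arcs
    taken = set(entity_ids.values()) | set(comp_ids.values())
    for pid in sorted(pdmap.processes):
        proc = pdmap.processes[pid]
        gid = ncname(pid)  # keep identifiers stable across round trips
        while gid in taken:
            gid = fresh(f"{gid}_")
        taken.add(gid)
        g = etree.SubElement(
            map_el, f"{{{ns}}}glyph",
            attrib={"class": _PROC_TO_SBGN[proc.process_class], "id": gid},
        )
        bbox(g)
        proc_ids[pid] = gid
        if not proc.reactants:  # explicit empty-set participant
            sid = fresh("src")
            sg = etree.SubElement(
                map_el, f"{{{ns}}}glyph",
                attrib={"class": "source and sink", "id": sid},
            )
            bbox(sg)
            arcs.append(("consumption", sid, gid))
        for r in proc.reactants:
            arcs.append(("consumption", entity_ids[r], gid))
        if not proc.products:
            sid = fresh("snk")
            sg = etree.SubElement(
                map_el, f"{{{ns}}}glyph",
                attrib={"class": "source and sink", "id": sid},
            )
            bbox(sg)
            arcs.append(("production", gid, sid))
        for p in proc.products:
            arcs.append(("production", gid, entity_ids[p]))

    def emit_logic(lf: LogicalFunction) -> str:
        gid = fresh("op")
        g = etree.SubElement(
            map_el, f"{{{ns}}}glyph",
            attrib={"class": lf.operator.lower(), "id": gid},
        )
        bbox(g)
        for child in lf.children:
            if isinstance(child, LogicalFunction):
                cid = emit_logic(child)
            else:
                cid = entity_ids[child]
            arcs.append(("logic arc", cid, gid))
        return gid

    for mod in sorted(
        pdmap.modulations,
        key=lambda m: (m.target, m.mod_class, _source_sort_key(m.source)),
    ):
        if isinstance(mod.source, LogicalFunction):
            sid = emit_logic(mod.source)
        else:
            sid = entity_ids[mod.source]
        arcs.append((_MOD_TO_SBGN[mod.mod_class], sid, proc_ids[mod.target]))

    for cls, src, tgt in arcs:
        a = etree.SubElement(
            map_el, f"{{{ns}}}arc",
            attrib={"class": cls, "id": fresh("a"), "source": src, "target": tgt},
        )
        etree.SubElement(a, f"{{{ns}}}start", attrib={"x": "0", "y": "0"})
        etree.SubElement(a, f"{{{ns}}}end", attrib={"x": "0", "y": "0"})

    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def read_sbgnml(path) -> tuple:
    """Read an SBGN-ML (0.2 or 0.3) PD map.

    Returns ``(PDMap, ParseReport)``.  Glyph layout is discarded;
    structurally-equal duplicate glyphs collapse to one pool; unknown glyph
    or arc classes are skipped with a warning recorded in the report.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise GrammarError(f"malformed XML: {exc}", 0) from None
    root = tree.getroot()
    if _localname(root) != "sbgn":
        raise UnsupportedLanguageError(f"not an SBGN-ML document: <{root.tag}>")
    map_el = next((c for c in root if _localname(c) == "map"), None)
    if map_el is None:
        raise UnsupportedLanguageError("no <map> element")
    language = map_el.get("language")
    if language is not None and language != "process description":
        raise UnsupportedLanguageError(f"unsupported map language {language!r}")

    report = ParseReport()
    if language is None:
        report.warn("map has no language attribute; assuming process description")

    pdmap = PDMap()
    comp_by_id: dict = {}
    entity_by_id: dict = {}    # glyph id -> EntityPool (canonical)
    proc_by_id: dict = {}      # glyph id -> process glyph info
    logic_by_id: dict = {}     # glyph id -> operator
    port_owner: dict = {}      # port id -> glyph id
    source_sink_ids: set = set()

    def register_ports(g, gid):
        for child in g:
            if _localname(child) == "port":
                port_owner[child.get("id")] = gid

    def glyph_label(g) -> str:
        for child in g:
            if _localname(child) == "label":
                return child.get("text") or ""
        return ""

    def build_entity(g, compartment) -> EntityPool:
        cls = _SBGN_TO_EPN[g.get("class")]
        svs, subs = [], []
        for child in g:
            lc = _localname(child)
            if lc == "glyph":
                ccls = child.get("class")
                if ccls == "state variable":
                    state = next(
                        (c for c in child if _localname(c) == "state"), None
                    )
                    value = state.get("value") if state is not None else None
                    site = state.get("variable") if state is not None else None
                    if value or site:
                        svs.append(
                            StateVariable(value or "", site or "", len(svs))
                        )
                elif ccls == "unit of information":
                    pass  # cardinality/type decorations are not modelled
                elif ccls in _SBGN_TO_EPN:
                    subs.append(build_entity(child, None))
                else:
                    report.skipped.append(ccls)
                    report.warn(f"skipping unknown subglyph class {ccls!r}")
        if cls != "complex" and subs:
            report.warn(f"dropping subunits of non-complex glyph {g.get('id')!r}")
            subs = []
        return EntityPool(cls, glyph_label(g), compartment, tuple(svs), tuple(subs))

    glyphs = [c for c in map_el if _localname(c) == "glyph"]
    arcs = [c for c in map_el if _localname(c) == "arc"]

    # compartments first (entity glyphs reference them)
    for g in glyphs:
        if g.get("class") == "compartment":
            comp = Compartment(glyph_label(g) or g.get("id"))
            pdmap.add_compartment(comp)
            comp_by_id[g.get("id")] = comp
            report.glyph_counts["compartment"] = (
                report.glyph_counts.get("compartment", 0) + 1
            )

    for g in glyphs:
        cls = g.get("class")
        gid = g.get("id")
        register_ports(g, gid)
        if cls == "compartment":
            continue
        if cls in _SBGN_TO_EPN:
            if _SBGN_TO_EPN[cls] == "source-sink":
                source_sink_ids.add(gid)
            else:
                comp = comp_by_id.get(g.get("compartmentRef"))
                entity = pdmap.add_entity(build_entity(g, comp))
                entity_by_id[gid] = entity
            report.glyph_counts[cls] = report.glyph_counts.get(cls, 0) + 1
        elif cls in _SBGN_TO_PROC:
            proc_by_id[gid] = {
                "class": _SBGN_TO_PROC[cls], "reactants": [], "products": []
            }
            report.glyph_counts[cls] = report.glyph_counts.get(cls, 0) + 1
        elif cls in _LOGIC_CLASSES:
            logic_by_id[gid] = {"operator": _LOGIC_CLASSES[cls], "children": []}
            report.glyph_counts[cls] = report.glyph_counts.get(cls, 0) + 1
        else:
            report.skipped.append(cls)
            report.warn(f"skipping unknown glyph class {cls!r}")

    def resolve(ref):
        return port_owner.get(ref, ref)

    modulation_arcs = []
    for a in arcs:
        cls = a.get("class")
        src = resolve(a.get("source"))
        tgt = resolve(a.get("target"))
        if cls == "consumption":
            if tgt in proc_by_id and src in entity_by_id:
                proc_by_id[tgt]["reactants"].append(entity_by_id[src])
            elif tgt not in proc_by_id or src not in source_sink_ids:
                report.warn(f"dangling consumption arc {a.get('id')!r}")
        elif cls == "production":
            if src in proc_by_id and tgt in entity_by_id:
                proc_by_id[src]["products"].append(entity_by_id[tgt])
            elif src not in proc_by_id or tgt not in source_sink_ids:
                report.warn(f"dangling production arc {a.get('id')!r}")
        elif cls == "logic arc":
            if tgt in logic_by_id:
                logic_by_id[tgt]["children"].append(src)
            else:
                report.warn(f"dangling logic arc {a.get('id')!r}")
        elif cls in _SBGN_TO_MOD:
            modulation_arcs.append((cls, src, tgt, a.get("id")))
        else:
            report.skipped.append(cls)
            report.warn(f"skipping unknown arc class {cls!r}")
            continue
        report.arc_counts[cls] = report.arc_counts.get(cls, 0) + 1

    for gid, info in proc_by_id.items():
        pdmap.add_process(
            Process(
                info["class"],
                tuple(info["reactants"]),
                tuple(info["products"]),
                identifier=gid,
            )
        )

    def build_source(ref):
        if ref in entity_by_id:
            return entity_by_id[ref]
        if ref in logic_by_id:
            info = logic_by_id[ref]
            children = tuple(build_source(c) for c in info["children"])
            if any(c is None for c in children):
                return None
            return LogicalFunction(info["operator"], children)
        return None

    for cls, src, tgt, aid in modulation_arcs:
        source = build_source(src)
        if source is None or tgt not in proc_by_id:
            report.warn(f"dangling modulation arc {aid!r}")
            continue
        pdmap.add_modulation(Modulation(_SBGN_TO_MOD[cls], source, tgt))

    pdmap.validate()
    return pdmap, report


# ---------------------------------------------------------------------------
# CellDesigner extended SBML  (read only, conceptual subset)
# ---------------------------------------------------------------------------

_CD_CLASS_TO_EPN = {
    "PROTEIN": "macromolecule",
    "RECEPTOR": "macromolecule",
    "TRUNCATED": "macromolecule",
    "GENE": "nucleic-acid-feature",
    "RNA": "nucleic-acid-feature",
    "ANTISENSE_RNA": "nucleic-acid-feature",
    "SIMPLE_MOLECULE": "simple-chemical",
    "ION": "simple-chemical",
    "DRUG": "perturbing-agent",
    "COMPLEX": "complex",
    "DEGRADED": "source-sink",
    "UNKNOWN": "unspecified",
    "PHENOTYPE": "unspecified",
}

_CD_STATE_TO_VALUE = {
    "phosphorylated": "P",
    "acetylated": "Ac",
    "ubiquitinated": "Ub",
    "methylated": "Me",
    "hydroxylated": "OH",
    "glycosylated": "G",
    "myristoylated": "My",
    "palmytoylated": "Pa",
    "prenylated": "Pr",
    "protonated": "H",
    "sulfated": "S",
}

_CD_REACTION_TO_PROC = {
    "STATE_TRANSITION": "generic",
    "TRANSCRIPTION": "generic",
    "TRANSLATION": "generic",
    "TRANSPORT": "generic",
    "DEGRADATION": "generic",
    "HETERODIMER_ASSOCIATION": "association",
    "DISSOCIATION": "dissociation",
    "TRUNCATION": "dissociation",
    "KNOWN_TRANSITION_OMITTED": "omitted",
    "UNKNOWN_TRANSITION": "uncertain",
}

_CD_MODIFIER_TO_MOD = {
    "CATALYSIS": "catalysis",
    "UNKNOWN_CATALYSIS": "catalysis",
    "INHIBITION": "inhibition",
    "UNKNOWN_INHIBITION": "inhibition",
    "PHYSICAL_STIMULATION": "stimulation",
    "TRIGGER": "necessary-stimulation",
    "MODULATION": "modulation",
}


def _iter_local(el, name):
    for child in el.iter():
        if isinstance(child.tag, str) and etree.QName(child).localname == name:
            yield child


def _miriam_refs(species_el) -> list:
    """External links as (database, identifier) pairs from RDF annotations."""
    refs = []
    for li in _iter_local(species_el, "li"):
        resource = li.get(
            "{http://www.w3.org/1999/02/22-rdf-syntax-ns#}resource"
        ) or li.get("resource")
        if not resource:
            continue
        if resource.startswith("urn:miriam:"):
            parts = resource[len("urn:miriam:"):].split(":", 1)
            if len(parts) == 2:
                refs.append((parts[0], parts[1]))
        elif "identifiers.org/" in resource:
            tail = resource.split("identifiers.org/", 1)[1]
            parts = tail.split("/", 1)
            if len(parts) == 2:
                refs.append((parts[0], parts[1]))
    return refs


def read_celldesigner(path) -> tuple:
    """Read a CellDesigner extended-SBML map into a :class:`PDMap`.

    Species become entity pools (CellDesigner species class mapped to the
    closest PD class, modification residues to state variables, complexes
    reconstructed from included species); reactions become processes and
    their modifiers modulations; MIRIAM annotations are kept as
    (database, identifier) pairs.  Layout, fonts and notes markup are
    discarded with a logged warning.  Returns ``(PDMap, ParseReport)``.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise GrammarError(f"malformed XML: {exc}", 0) from None
    root = tree.getroot()
    if _localname(root) != "sbml":
        raise UnsupportedDialectError(f"not an SBML document: <{root.tag}>")
    if not any(
        isinstance(el.tag, str) and "celldesigner" in etree.QName(el).namespace.lower()
        for el in root.iter()
        if isinstance(el.tag, str) and etree.QName(el).namespace
    ):
        raise UnsupportedDialectError("SBML file lacks the CellDesigner extension")

    report = ParseReport()
    pdmap = PDMap()

    comp_by_id = {}
    for c in _iter_local(root, "compartment"):
        label = c.get("name") or c.get("id")
        if label == "default":
            comp_by_id[c.get("id")] = None
            continue
        comp = Compartment(label)
        pdmap.add_compartment(comp)
        comp_by_id[c.get("id")] = comp

    # protein definitions: residue id -> site name, per protein
    residue_site: dict = {}
    protein_name: dict = {}
    for prot in _iter_local(root, "protein"):
        pid = prot.get("id")
        protein_name[pid] = prot.get("name") or pid
        for res in _iter_local(prot, "modificationResidue"):
            residue_site[(pid, res.get("id"))] = res.get("name") or ""

    def species_identity(sp):
        ident = next(_iter_local(sp, "speciesIdentity"), None)
        if ident is None:
            return "PROTEIN", None, []
        cls_el = next(_iter_local(ident, "class"), None)
        cd_class = (cls_el.text or "PROTEIN").strip() if cls_el is not None else "PROTEIN"
        prot_ref_el = next(_iter_local(ident, "proteinReference"), None)
        prot_ref = prot_ref_el.text.strip() if prot_ref_el is not None and prot_ref_el.text else None
        svs = []
        for m in _iter_local(ident, "modification"):
            state = (m.get("state") or "").strip()
            if not state or state.lower() in ("don't care", "free"):
                continue
            value = _CD_STATE_TO_VALUE.get(state.lower(), state)
            site = residue_site.get((prot_ref, m.get("residue")), "")
            svs.append(StateVariable(value, site, len(svs)))
        return cd_class, prot_ref, svs

    def build_pool(sp, comp, as_subunit=False):
        cd_class, _prot, svs = species_identity(sp)
        epn = _CD_CLASS_TO_EPN.get(cd_class)
        if epn is None:
            report.warn(f"unmapped species class {cd_class!r}; using 'unspecified'")
            epn = "unspecified"
        label = sp.get("name") or sp.get("id")
        if epn == "complex":
            # filled in by the included-species pass; label kept in annotations
            return ("complex", label, comp, tuple(svs))
        if epn == "source-sink":
            return EntityPool("source-sink")
        return EntityPool(epn, label, None if as_subunit else comp, tuple(svs))

    # included species grouped by parent complex
    included: dict = {}
    for losi in _iter_local(root, "listOfIncludedSpecies"):
        for sp in _iter_local(losi, "species"):
            parent = None
            ann = next(_iter_local(sp, "complexSpecies"), None)
            if ann is not None and ann.text:
                parent = ann.text.strip()
            if parent is None:
                parent = sp.get("complexSpecies")
            pool = build_pool(sp, None, as_subunit=True)
            if isinstance(pool, tuple):
                report.warn(f"nested complex species {sp.get('id')!r} flattened")
                continue
            included.setdefault(parent, []).append(pool)

    species_pool: dict = {}
    model = next(_iter_local(root, "model"), root)
    list_of_species = next(
        (el for el in model.iter()
         if isinstance(el.tag, str)
         and etree.QName(el).localname == "listOfSpecies"),
        None,
    )
    species_els = list(_iter_local(list_of_species, "species")) if list_of_species is not None else []
    for sp in species_els:
        sid = sp.get("id")
        comp = comp_by_id.get(sp.get("compartment"))
        pool = build_pool(sp, comp)
        if isinstance(pool, tuple):
            _, label, pcomp, svs = pool
            subs = included.get(sid)
            if not subs:
                report.warn(
                    f"complex species {sid!r} has no included species; "
                    "kept as a single unspecified pool"
                )
                pool = EntityPool("unspecified", label, pcomp, svs)
            else:
                pool = EntityPool("complex", "", pcomp, svs, tuple(subs))
                pdmap.annotate(pool, [("celldesigner.name", label)])
        if pool.epn_class == "source-sink":
            species_pool[sid] = pool
            report.glyph_counts["DEGRADED"] = report.glyph_counts.get("DEGRADED", 0) + 1
            continue
        pdmap.add_entity(pool)
        refs = _miriam_refs(sp)
        if refs:
            pdmap.annotate(pool, refs)
        species_pool[sid] = pool
        report.glyph_counts["species"] = report.glyph_counts.get("species", 0) + 1

    for rx in _iter_local(root, "reaction"):
        rid = rx.get("id")
        rtype_el = next(_iter_local(rx, "reactionType"), None)
        rtype = (rtype_el.text or "").strip() if rtype_el is not None else "STATE_TRANSITION"
        pclass = _CD_REACTION_TO_PROC.get(rtype)
        if pclass is None:
            report.warn(f"unmapped reaction type {rtype!r}; using 'generic'")
            pclass = "generic"

        def participants(kind):
            lst = next(
                (el for el in rx.iter()
                 if isinstance(el.tag, str)
                 and etree.QName(el).localname == kind),
                None,
            )
            if lst is None:
                return []
            out = []
            for ref in _iter_local(lst, "speciesReference"):
                pool = species_pool.get(ref.get("species"))
                if pool is None:
                    report.warn(f"reaction {rid!r} references unknown species")
                elif pool.epn_class != "source-sink":
                    out.append(pool)
            return out

        proc = pdmap.add_process(
            Process(
                pclass,
                tuple(participants("listOfReactants")),
                tuple(participants("listOfProducts")),
                identifier=rid,
            )
        )
        refs = _miriam_refs(rx)
        if refs:
            pdmap.annotate(proc.identifier, refs)
        report.glyph_counts["reaction"] = report.glyph_counts.get("reaction", 0) + 1

        mod_lst = next(
            (el for el in rx.iter()
             if isinstance(el.tag, str)
             and etree.QName(el).localname == "listOfModifiers"),
            None,
        )
        if mod_lst is None:
            continue
        # celldesigner modification types, keyed by modifier species
        cd_types = {}
        for m in _iter_local(rx, "modification"):
            if m.get("modifiers") or m.get("type"):
                for mid in (m.get("modifiers") or "").split(","):
                    if mid:
                        cd_types[mid] = m.get("type") or "MODULATION"
        for ref in _iter_local(mod_lst, "modifierSpeciesReference"):
            sid = ref.get("species")
            pool = species_pool.get(sid)
            if pool is None or pool.epn_class == "source-sink":
                report.warn(f"reaction {rid!r} has unresolvable modifier {sid!r}")
                continue
            cd_type = cd_types.get(sid, "MODULATION")
            mod_class = _CD_MODIFIER_TO_MOD.get(cd_type)
            if mod_class is None:
                report.warn(f"unmapped modifier type {cd_type!r}; using 'modulation'")
                mod_class = "modulation"
            pdmap.add_modulation(Modulation(mod_class, pool, proc.identifier))
            report.arc_counts[mod_class] = report.arc_counts.get(mod_class, 0) + 1

    pdmap.validate()
    return pdmap, report
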