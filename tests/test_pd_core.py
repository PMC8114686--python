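"""Entity grammar, structural equality, SBGN-ML round trips, lookup."""

import pytest
from hypothesis import given, settings, strategies as st

import sbgnq as q
from sbgnq.pd_core import (
    Compartment,
    EntityPool,
    GrammarError,
    LogicalFunction,
    Modulation,
    PDMap,
    Process,
    StateVariable,
    UnsupportedLanguageError,
)
from sbgnq import synthetic_data as syn


# ---------------------------------------------------------------------------
# marker grammar
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "text, n_subunits, checks",
    [
        ("A", 0, lambda e: e.label == "A" and not e.state_variables),
        (
            "WEE1(P@Ser53)", 0,
            lambda e: e.state_variables == (StateVariable("P", "Ser53"),),
        ),
        (
            "CCND1:CDK6(P@Thr):CDKN1B", 3,
            lambda e: any(
                s.label == "CDK6"
                and s.state_variables == (StateVariable("P", "Thr"),)
                for s in e.subunits
            ),
        ),
        (
            "ARNTL(Ac@L538|P@S90):CLOCK(ADPr):CSNK2A", 3,
            lambda e: {s.label: len(s.state_variables) for s in e.subunits}
            == {"ARNTL": 2, "CLOCK": 1, "CSNK2A": 0},
        ),
        ("pRB(P|P)", 0, lambda e: len(e.state_variables) == 2),
    ],
)
def test_parse_entity_text(text, n_subunits, checks):
    entity = q.parse_entity_text(text)
    assert len(entity.subunits) == n_subunits
    assert checks(entity)


def test_clock_marker_sites():
    entity = q.parse_entity_text("ARNTL(Ac@L538|P@S90):CLOCK(ADPr):CSNK2A")
    arntl = next(s for s in entity.subunits if s.label == "ARNTL")
    assert set((sv.value, sv.site) for sv in arntl.state_variables) == {
        ("Ac", "L538"), ("P", "S90"),
    }
    clock = next(s for s in entity.subunits if s.label == "CLOCK")
    assert clock.state_variables == (StateVariable("ADPr", ""),)


@pytest.mark.parametrize(
    "bad, offset_pred",
    [
        ("A(P", lambda o: o == 1),      # unbalanced at the opening paren
        ("", lambda o: o == 0),
        ("A:", lambda o: o == 2),       # empty label after separator
        ("A()", lambda o: o >= 2),      # empty state variable
        ("A(P@)", lambda o: o >= 4),    # empty site
    ],
)
def test_grammar_errors_carry_offsets(bad, offset_pred):
    with pytest.raises(GrammarError) as exc:
        q.parse_entity_text(bad)
    assert offset_pred(exc.value.offset)


_MARKER_STRINGS = [
    "CCND1:CDK6(P@Thr):CDKN1B",
    "pRB:E2F1:DP1:SWI:SNF:HDAC1",
    "SWI:SNF:HDAC1:SUV39H1:pRB:E2F1:DP1",
    "CCND1:CDK4(P@Thr172):CDKN1B",
    "pRB:E2F1:DP1:SWI:SNF:HDAC1:SUV39H1:HP1gamma",
    "pRB(P):E2F1:DP1:SWI:SNF:HDAC1",
    "pRB(P|P):E2F1:DP1:SWI:SNF",
    "CCNE1:CDK2(P@Thr160)",
    "CCNA2:CDK2(P@Thr160)",
    "CCNB1:CDK1(P@Tyr15)",
    "CCNB1:CDK1(P@Tyr15|P@Thr14)",
    "CCNB1:CDK1",
    "CCNB1:CDK1(P@Thr14)",
    "CDC25(P)",
    "WEE1(P@Ser53)",
    "CCNB1:CDK1(P@Thr161)",
    "CDC20(P)",
    "RORG",
    "SIRT1",
    "ARNTL(Ac@L538|P@S90):CLOCK(ADPr):CSNK2A",
    "PER1:CRY1:CRY2:ARNTL(Ac@L538|P@S90):CLOCK(ADPr):PER2(Ac):CSNK1D:CSNK1E",
]


@pytest.mark.parametrize("text", _MARKER_STRINGS)
def test_render_is_inverse_of_parse_on_marker_tables(text):
    assert q.render_entity_text(q.parse_entity_text(text)) == text


_label = st.text(
    alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd")),
    min_size=1, max_size=6,
)
_sv = st.builds(
    StateVariable,
    value=st.sampled_from(["P", "Ac", "Ub", "ADPr"]),
    site=st.sampled_from(["", "Thr172", "S90", "L538"]),
)
_simple = st.builds(
    EntityPool,
    epn_class=st.just("macromolecule"),
    label=_label,
    compartment=st.none(),
    state_variables=st.lists(_sv, max_size=3).map(tuple),
)
_entity = st.one_of(
    _simple,
    st.builds(
        lambda subs: EntityPool("complex", "", None, (), tuple(subs)),
        st.lists(_simple, min_size=2, max_size=4),
    ),
)


@settings(derandomize=True, max_examples=200)
@given(_entity)
def test_parse_render_round_trip_property(entity):
    assert q.parse_entity_text(q.render_entity_text(entity)) == entity


# ---------------------------------------------------------------------------
# structural equality
# ---------------------------------------------------------------------------

def test_structural_equality_ignores_declaration_order():
    a = q.parse_entity_text("A:B(P@S1|Ac@S2)")
    b = q.parse_entity_text("B(Ac@S2|P@S1):A")
    assert a == b and hash(a) == hash(b)
    assert q.render_entity_text(a) != q.render_entity_text(b)  # order kept


def test_unsited_duplicates_distinguished_by_ordinal():
    e = q.parse_entity_text("pRB(P|P)")
    assert [sv.ordinal for sv in e.state_variables] == [0, 1]
    assert e != q.parse_entity_text("pRB(P)")
    assert e == q.parse_entity_text("pRB(P|P)")


def test_canonicalization_is_idempotent():
    e = q.parse_entity_text("B:A")
    again = EntityPool(
        e.epn_class, e.label, e.compartment, e.state_variables, e.subunits
    )
    assert again == e and again.subunits == e.subunits


def test_complex_invariants():
    with pytest.raises(ValueError):
        EntityPool("macromolecule", "A", subunits=(q.parse_entity_text("B"),))
    with pytest.raises(ValueError):
        EntityPool("complex", "C")
    with pytest.raises(ValueError):
        LogicalFunction("NOT", (q.parse_entity_text("A"), q.parse_entity_text("B")))
    with pytest.raises(ValueError):
        LogicalFunction("AND", (q.parse_entity_text("A"),))


# ---------------------------------------------------------------------------
# SBGN-ML round trips
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "factory",
    [syn.make_toy_clock, syn.make_nad_motif, syn.make_toy_coupled,
     syn.make_alternatives_motif],
)
def test_sbgnml_round_trip(tmp_path, factory):
    m = factory()
    path = tmp_path / "map.sbgn"
    q.write_sbgnml(m, path)
    m2, report = q.read_sbgnml(path)
    assert m2 == m
    assert sorted(m2.processes) == sorted(m.processes)
    assert not report.skipped


def test_empty_map_round_trip(tmp_path):
    path = tmp_path / "empty.sbgn"
    q.write_sbgnml(PDMap(), path)
    m, _ = q.read_sbgnml(path)
    assert not m.entity_pools and not m.processes and not m.modulations


def test_logic_gated_modulation_round_trip(tmp_path):
    m = PDMap()
    a, b = q.parse_entity_text("A"), q.parse_entity_text("B")
    target = q.parse_entity_text("T")
    m.add_process(Process("generic", (), (target,), "px"))
    gate = LogicalFunction("AND", (a, LogicalFunction("NOT", (b,))))
    m.add_modulation(Modulation("stimulation", gate, "px"))
    path = tmp_path / "logic.sbgn"
    q.write_sbgnml(m, path)
    m2, _ = q.read_sbgnml(path)
    assert m2 == m
    (mod,) = m2.modulations
    assert isinstance(mod.source, LogicalFunction)
    assert mod.source.operator == "AND"


def test_parse_report_counts_match_file(tmp_path):
    m = syn.make_nad_motif()
    path = tmp_path / "nad.sbgn"
    q.write_sbgnml(m, path)
    _, report = q.read_sbgnml(path)
    # nothing silently dropped: supported glyph/arc classes all accounted for
    assert sum(
        n for cls, n in report.glyph_counts.items()
        if cls in ("macromolecule", "simple chemical")
    ) == len(m.entity_pools)
    assert report.glyph_counts.get("process") == len(m.processes)
    n_mod_arcs = sum(
        n for cls, n in report.arc_counts.items()
        if cls not in ("consumption", "production", "logic arc")
    )
    assert n_mod_arcs == len(m.modulations)


def test_non_pd_language_rejected(tmp_path):
    path = tmp_path / "af.sbgn"
    path.write_text(
        '<sbgn xmlns="http://sbgn.org/libsbgn/0.3">'
        '<map language="activity flow" id="m"/></sbgn>'
    )
    with pytest.raises(UnsupportedLanguageError):
        q.read_sbgnml(path)


def test_malformed_xml_rejected(tmp_path):
    path = tmp_path / "broken.sbgn"
    path.write_text("<sbgn><map")
    with pytest.raises(GrammarError):
        q.read_sbgnml(path)


def test_unknown_glyph_class_skipped_with_warning(tmp_path):
    path = tmp_path / "odd.sbgn"
    path.write_text(
        '<sbgn xmlns="http://sbgn.org/libsbgn/0.2">'
        '<map language="process description" id="m">'
        '<glyph class="macromolecule" id="g1"><label text="A"/>'
        '<bbox x="0" y="0" w="1" h="1"/></glyph>'
        '<glyph class="submap" id="g2"><bbox x="0" y="0" w="1" h="1"/></glyph>'
        "</map></sbgn>"
    )
    m, report = q.read_sbgnml(path)
    assert len(m.entity_pools) == 1
    assert "submap" in report.skipped


def test_duplicate_glyphs_collapse(tmp_path):
    path = tmp_path / "dup.sbgn"
    path.write_text(
        '<sbgn xmlns="http://sbgn.org/libsbgn/0.3">'
        '<map language="process description" id="m">'
        '<glyph class="macromolecule" id="g1"><label text="A"/>'
        '<bbox x="0" y="0" w="1" h="1"/></glyph>'
        '<glyph class="macromolecule" id="g2"><label text="A"/>'
        '<bbox x="5" y="5" w="1" h="1"/></glyph>'
        "</map></sbgn>"
    )
    m, _ = q.read_sbgnml(path)
    assert len(m.entity_pools) == 1


# ---------------------------------------------------------------------------
# find_entity
# ---------------------------------------------------------------------------

def test_find_entity_basics(toy_clock):
    hit = q.find_entity(toy_clock, "A")
    assert hit is not None and hit.label == "A"
    assert q.find_entity(toy_clock, "ZZZ") is None


def test_find_entity_by_structure(nad_motif):
    probe = EntityPool("simple-chemical", "NAD", Compartment("cell"))
    assert q.find_entity(nad_motif, probe) is not None


def test_find_entity_colon_label_fallback():
    m = PDMap()
    swisnf = EntityPool(
        "complex", "", Compartment("cell"),
        subunits=(
            EntityPool("macromolecule", "SWI:SNF"),
            EntityPool("macromolecule", "HDAC1"),
        ),
    )
    m.add_entity(swisnf)
    # the query parses as three subunits, but rendered-text matching
    # recovers the two-subunit complex whose label contains ":"
    assert q.find_entity(m, "SWI:SNF:HDAC1") == swisnf


def test_find_entity_fuzzy_ambiguity(toy_coupled):
    with pytest.raises(q.AmbiguousMatchError):
        q.find_entity(toy_coupled, "X", fuzzy=True)
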