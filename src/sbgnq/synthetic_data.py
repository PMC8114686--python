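"""Deterministic fixture maps and a seeded random PD-map generator.

Every analysis stage is testable without downloading any curated map:

- ``make_toy_clock``: a two-entity negative-feedback oscillator, the
  smallest analogue of a transcriptional/translational clock loop;
- ``make_nad_motif``: a metabolic circular-dependency motif modelled on the
  NAD+/NMN/NAM salvage loop, whose marker is unreachable from seeds holding
  only NAM (the salvage enzyme's gene needs the marker itself);
- ``make_toy_coupled``: the toy clock driving a linear three-stage cycle
  through a necessary stimulation, the analogue of clock-to-cell-cycle
  coupling;
- ``make_alternatives_motif``: two translocation cycles and one
  three-metabolite cycle, so minimal precursor states factor as
  2 x 2 x 3 = 12 interchangeable alternatives;
- ``random_map``: seeded random connected PD maps for property testing.

Fixtures are hand-specified (expected verdicts derivable by hand and by
brute force) and live in a single compartment ("cell") so marker resolution
is unambiguous.  Their behaviors are frozen as regression tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .pd_core import (
    Compartment,
    EntityPool,
    Modulation,
    PDMap,
    Process,
    write_sbgnml,
)
from .phases import CycleSpec, Marker, Phase

__all__ = [
    "GeneratorParams",
    "make_toy_clock",
    "toy_clock_cycle",
    "make_nad_motif",
    "make_toy_coupled",
    "toy_coupled_cycle",
    "toy_coupled_partition",
    "make_alternatives_motif",
    "random_map",
    "write_fixtures",
]

_CELL = Compartment("cell")


def _mm(label: str, compartment: Compartment = _CELL) -> EntityPool:
    return EntityPool("macromolecule", label, compartment)


def _chem(label: str, compartment: Compartment = _CELL) -> EntityPool:
    return EntityPool("simple-chemical", label, compartment)


def make_toy_clock() -> PDMap:
    """Two-entity negative-feedback oscillator.

    A activates the production of its repressor B; B inhibits A's
    production and stimulates A's degradation; B decays unconditionally.
    Phases: P1 = {A}, P2 = {B}.
    """
    m = PDMap()
    a, b = _mm("A"), _mm("B")
    m.add_process(Process("generic", (), (a,), "tA"))
    m.add_process(Process("generic", (), (b,), "tB"))
    m.add_process(Process("generic", (a,), (), "dA"))
    m.add_process(Process("generic", (b,), (), "dB"))
    m.add_modulation(Modulation("inhibition", b, "tA"))
    m.add_modulation(Modulation("stimulation", a, "tB"))
    m.add_modulation(Modulation("stimulation", b, "dA"))
    return m


def toy_clock_cycle() -> CycleSpec:
    return CycleSpec(
        "toy clock",
        (
            Phase("P1", (Marker.from_text("A", "cell"),)),
            Phase("P2", (Marker.from_text("B", "cell"),)),
        ),
    )


def make_nad_motif() -> PDMap:
    """Metabolic circular-dependency motif (NAD+/NMN/NAM-like).

    The marker M needs NAD (necessary stimulation); NAD is made from NMN by
    the NMNAT enzyme; NMN is made from NAM by NAMPT — but NAMPT's own
    production needs M.  NMN also decays back to NAM.  Seeds holding NAM
    but not NMN/NAD can therefore never produce M.
    """
    m = PDMap()
    nam, nmn, nad = _chem("NAM"), _chem("NMN"), _chem("NAD")
    nmnat, nampt = _mm("NMNAT"), _mm("NAMPT")
    marker = _mm("M")
    m.add_process(Process("generic", (nmn,), (nad,), "p1"))
    m.add_process(Process("generic", (nam,), (nmn,), "p2"))
    m.add_process(Process("generic", (), (marker,), "p3"))
    m.add_process(Process("generic", (), (nampt,), "p4"))
    m.add_process(Process("generic", (nmn,), (nam,), "p5"))
    m.add_modulation(Modulation("catalysis", nmnat, "p1"))
    m.add_modulation(Modulation("catalysis", nampt, "p2"))
    m.add_modulation(Modulation("necessary-stimulation", nad, "p3"))
    m.add_modulation(Modulation("necessary-stimulation", marker, "p4"))
    return m


def make_toy_coupled() -> PDMap:
    """Toy clock coupled to a three-stage linear cycle.

    The clock's A entity necessarily stimulates production of W, and W is
    required (necessary stimulation) for the X2 -> X3 step — the analogue
    of a clock transcription factor gating a cell-cycle kinase.  Cycle
    phases: C1 = {X1}, C2 = {X2}, C3 = {X3}.
    """
    m = make_toy_clock()
    x1, x2, x3, w = _mm("X1"), _mm("X2"), _mm("X3"), _mm("W")
    a = next(e for e in m.entity_pools if e.label == "A")
    m.add_process(Process("generic", (), (x1,), "q1"))
    m.add_process(Process("generic", (x1,), (x2,), "q2"))
    m.add_process(Process("generic", (x2,), (x3,), "q3"))
    m.add_process(Process("generic", (), (w,), "qW"))
    m.add_process(Process("generic", (x3,), (), "q4"))
    m.add_modulation(Modulation("necessary-stimulation", w, "q3"))
    m.add_modulation(Modulation("necessary-stimulation", a, "qW"))
    return m


def toy_coupled_cycle() -> CycleSpec:
    return CycleSpec(
        "toy cycle",
        (
            Phase("C1", (Marker.from_text("X1", "cell"),)),
            Phase("C2", (Marker.from_text("X2", "cell"),)),
            Phase("C3", (Marker.from_text("X3", "cell"),)),
        ),
    )


def toy_coupled_partition() -> dict:
    """Provenance partition: which side of the coupling each entity is from."""
    return {
        "A": "clock", "B": "clock",
        "X1": "cycle", "X2": "cycle", "X3": "cycle", "W": "cycle",
    }


def make_alternatives_motif() -> PDMap:
    """Two translocation cycles and one three-metabolite cycle.

    Each translocated protein (T in compartments c1/c2, U in c1/c2) cycles
    between its two localizations, and metabolites a/b/c cycle a -> b -> c
    -> a, so a minimal precursor state picks exactly one representative per
    cycle: 2 x 2 x 3 = 12 optimal states.
    """
    m = PDMap()
    c1, c2 = Compartment("c1"), Compartment("c2")
    t1, t2 = _mm("T", c1), _mm("T", c2)
    u1, u2 = _mm("U", c1), _mm("U", c2)
    a, b, c = _chem("a", c1), _chem("b", c1), _chem("c", c1)
    m.add_process(Process("generic", (t1,), (t2,), "tT12"))
    m.add_process(Process("generic", (t2,), (t1,), "tT21"))
    m.add_process(Process("generic", (u1,), (u2,), "tU12"))
    m.add_process(Process("generic", (u2,), (u1,), "tU21"))
    m.add_process(Process("generic", (a,), (b,), "mab"))
    m.add_process(Process("generic", (b,), (c,), "mbc"))
    m.add_process(Process("generic", (c,), (a,), "mca"))
    return m


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the random PD-map generator.

    Counts are exact; modulation density is the mean number of modulation
    arcs per process; the two fractions split modulations into necessary
    stimulations, inhibitions, and (the remainder) stimulations.  The same
    params and seed always produce an identical map.
    """

    entities: int = 6
    processes: int = 5
    modulation_density: float = 1.0
    necessary_fraction: float = 0.2
    inhibition_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.entities < 0 or self.processes < 0:
            raise ValueError("counts must be non-negative")
        if self.modulation_density < 0:
            raise ValueError("modulation density must be non-negative")
        if self.processes > 0 and self.entities == 0:
            raise ValueError("cannot generate processes with no entities")


def random_map(params: GeneratorParams) -> PDMap:
    """Seeded random connected PD map.

    Every entity touches at least one process, at least one process is a
    source (so the producibility closure is non-trivial), and modulation
    sources are entities distinct from the process's participants where
    possible.  Deterministic per (params, seed)."""
    rng = random.Random(params.seed)
    m = PDMap()
    pools = [_mm(f"E{i + 1}") for i in range(params.entities)]
    for e in pools:
        m.add_entity(e)
    if not params.processes:
        return m

    procs = []
    for i in range(params.processes):
        if i == 0:  # guaranteed source process
            reactants = ()
        else:
            reactants = tuple(
                rng.sample(pools, rng.choice((1, 1, 2)))
            )
        remaining = [e for e in pools if e not in reactants] or pools
        products = tuple(
            rng.sample(remaining, min(len(remaining), rng.choice((1, 1, 2))))
        )
        if i > 0 and rng.random() < 0.15:
            products = ()  # occasional sink; never the guaranteed source
            if not reactants:
                reactants = (rng.choice(pools),)
        procs.append(
            m.add_process(
                Process("generic", reactants, products, f"r{i + 1}")
            )
        )

    # connectivity fix-up: orphan entities become products of a new source
    touched = {
        e for p in m.processes.values() for e in (*p.reactants, *p.products)
    }
    orphans = [e for e in pools if e not in touched]
    for j, e in enumerate(orphans):
        procs.append(
            m.add_process(Process("generic", (), (e,), f"fix{j + 1}"))
        )

    n_mods = round(params.modulation_density * len(procs))
    for _ in range(n_mods):
        target = rng.choice(procs)
        source = rng.choice(pools)
        u = rng.random()
        if u < params.necessary_fraction:
            cls = "necessary-stimulation"
        elif u < params.necessary_fraction + params.inhibition_fraction:
            cls = "inhibition"
        else:
            cls = "stimulation"
        m.add_modulation(Modulation(cls, source, target.identifier))
    return m


def write_fixtures(directory) -> list:
    """Write every deterministic fixture to SBGN-ML files; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for name, factory in (
        ("toy_clock", make_toy_clock),
        ("nad_motif", make_nad_motif),
        ("toy_coupled", make_toy_coupled),
        ("alternatives_motif", make_alternatives_motif),
    ):
        path = directory / f"{name}.sbgn"
        write_sbgnml(factory(), path)
        out.append(path)
    return out
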