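"""Named builders for the validated circuit topologies: the single-output
logic-gate panel, the compact MIMO gates, the analog ultrasensitivity and
bandpass circuits, and the four synonymous sensor-AND topologies.

Every entry returns a figure-faithful :class:`~cometsim.circuit.Circuit`
(promoters, fusion proteins, fixed helper doses, ligand conditions) plus the
default input dose grids and, for digital gates, the expected truth table
per reporter.  Input units are built at dose 0; sweeps set their doses.

Dose conventions: helper/reporter plasmid doses are fixed per entry; input
grids include zero plus log-spaced points (the figure-axis convention).
Doses are in ng of plasmid per well.  The intC-ZF inhibitor fragments carry
a stability multiplier of 4 (appending intC destabilizes the inhibitory
ZF, which is why their pre-splice inhibition is a modest, "dotted-line"
effect).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Dict, Optional, Sequence, Tuple, Union

import numpy as np

from .circuit import Circuit, SensorUnit, TranscriptionUnit
from .parts import parse_protein_name

__all__ = ["LibraryEntry", "catalog", "get_entry", "build_circuit"]

INTC_ZF_DESTABILIZATION = 4.0  # stability multiplier of intC-ZF inhibitor fragments

REPORTER_DOSE = 50.0
GATE_INPUT_GRID = (0.0, 1.0, 3.0, 10.0, 30.0)
ACT_INPUT_GRID = (0.0, 0.3, 1.0, 3.0, 10.0)
# zero + log-spaced doses for ultrasensitivity sweeps
HILL_GRID = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)
HILL_GRID_WIDE = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0)


def _p(name: str, stability: float = 1.0):
    prot = parse_protein_name(name)
    if stability != 1.0:
        prot = replace(prot, stability_multiplier=stability)
    return prot


def _intc_inhibitor(name: str):
    return _p(name, stability=INTC_ZF_DESTABILIZATION)


def _u(promoter: str, protein, dose: float, label: str = "") -> TranscriptionUnit:
    prot = protein if not isinstance(protein, str) else _p(protein)
    return TranscriptionUnit(promoter=promoter, protein=prot, dose=dose, label=label)


InputSpec = Union[str, Tuple[str, ...]]


@dataclass(frozen=True)
class LibraryEntry:
    """A registered topology: circuit, default input design and expectations."""

    id: str
    summary: str
    circuit: Circuit
    inputs: Tuple[InputSpec, ...]
    input_grids: Tuple[Tuple[float, ...], ...]
    truth: Optional[Dict[str, str]] = None  # reporter -> 4-corner truth string
    hill_input: Optional[InputSpec] = None
    hill_grid: Optional[Tuple[float, ...]] = None


_BUILDERS: Dict[str, Callable[[], LibraryEntry]] = {}


def _register(fn: Callable[[], LibraryEntry]) -> Callable[[], LibraryEntry]:
    entry = fn()
    _BUILDERS[entry.id] = fn
    return fn


def catalog() -> Tuple[str, ...]:
    """Sorted ids of every registered topology."""
    return tuple(sorted(_BUILDERS))


def get_entry(entry_id: str) -> LibraryEntry:
    try:
        return _BUILDERS[entry_id]()
    except KeyError:
        raise KeyError(
            f"unknown circuit id {entry_id!r}; available ids:\n  "
            + "\n  ".join(catalog())
        ) from None


def build_circuit(entry_id: str) -> Circuit:
    """The figure-faithful circuit for a registered id."""
    return get_entry(entry_id).circuit


# ---------------------------------------------------------------------------
# single-output logic gates


@_register
def _and_fig1c() -> LibraryEntry:
    """Splicing AND: the reporter is induced only when both TF fragments are
    present to reconstitute VP64-ZF1."""
    c = Circuit(
        units=(
            _u("CMV", "VP64-intN", 0.0),
            _u("CMV", _intc_inhibitor("intC-ZF1"), 0.0),
            _u("ZF1x6-C", "mKate2", REPORTER_DOSE),
        ),
        reporters=("mKate2",),
    )
    return LibraryEntry(
        id="AND_fig1C",
        summary="split-intein reconstitution of a ZF activator (AND gate)",
        circuit=c,
        inputs=("VP64-intN", "intC-ZF1"),
        input_grids=(GATE_INPUT_GRID, GATE_INPUT_GRID),
        truth={"mKate2": "0001"},
    )


@_register
def _imply_fig1d() -> LibraryEntry:
    """IMPLY: a constitutive activator is silenced only by unspliced
    DsDed-intC-ZF1 in excess over its VP64-intN splicing partner."""
    c = Circuit(
        units=(
            _u("CMV", "VP64-ZF1", 5.0, label="ZFa"),
            _u("CMV", "VP64-intN", 0.0),
            _u("CMV", "DsDed-intC-ZF1", 0.0),
            _u("ZF1x6-C", "mKate2", REPORTER_DOSE),
        ),
        reporters=("mKate2",),
    )
    return LibraryEntry(
        id="IMPLY_fig1D",
        summary="splice-reversible mixed inhibition of a constitutive activator",
        circuit=c,
        inputs=("VP64-intN", "DsDed-intC-ZF1"),
        input_grids=((0.0, 3.0, 10.0, 30.0, 90.0), GATE_INPUT_GRID),
        truth={"mKate2": "1011"},
    )


@_register
def _nand_fig1e() -> LibraryEntry:
    """NAND: DsDed-ZF1 is reconstituted from two inert(ish) fragments and
    shuts off a constitutive activator only when both are present."""
    c = Circuit(
        units=(
            _u("CMV", "VP64-ZF1", 5.0, label="ZFa"),
            _u("CMV", "DsDed-intN", 0.0),
            _u("CMV", _intc_inhibitor("intC-ZF1"), 0.0),
            _u("ZF1x6-C", "mKate2", REPORTER_DOSE),
        ),
        reporters=("mKate2",),
    )
    return LibraryEntry(
        id="NAND_fig1E",
        summary="splicing-reconstituted mixed inhibitor (NAND gate)",
        circuit=c,
        inputs=("DsDed-intN", "intC-ZF1"),
        input_grids=(GATE_INPUT_GRID, GATE_INPUT_GRID),
        truth={"mKate2": "1110"},
    )


@_register
def _nimply_zf_fig1f() -> LibraryEntry:
    c = Circuit(
        units=(
            _u("CMV", "VP64-ZF1", 0.0),
            _u("CMV", "ZF1", 0.0),
            _u("ZF1x6-C", "mKate2", REPORTER_DOSE),
        ),
        reporters=("mKate2",),
    )
    return LibraryEntry(
        id="NIMPLY_ZF_fig1F",
        summary="NIMPLY via competitive inhibition by a bare ZF",
        circuit=c,
        inputs=("VP64-ZF1", "ZF1"),
        input_grids=(ACT_INPUT_GRID, GATE_INPUT_GRID),
        truth={"mKate2": "0010"},
    )


@_register
def _nimply_dsded_fig1g() -> LibraryEntry:
    c = Circuit(
        units=(
            _u("CMV", "VP64-ZF1", 0.0),
            _u("CMV", "DsDed-ZF1", 0.0),
            _u("ZF1x6-C", "mKate2", REPORTER_DOSE),
        ),
        reporters=("mKate2",),
    )
    return LibraryEntry(
        id="NIMPLY_DSDED_fig1G",
        summary="NIMPLY via mixed (cooperativity-disrupting) inhibition",
        circuit=c,
        inputs=("VP64-ZF1", "DsDed-ZF1"),
        input_grids=(ACT_INPUT_GRID, GATE_INPUT_GRID),
        truth={"mKate2": "0010"},
    )


@_register
def _nimply_splice_fig1h() -> LibraryEntry:
    """NIMPLY via splicing: DsDed-intN converts the VP64-intC-ZF1 activator
    into a DsDed-ZF1 inhibitor (plus an inert VP64-intein byproduct)."""
    c = Circuit(
        units=(
            _u("CMV", "VP64-intC-ZF1", 0.0),
            _u("CMV", "DsDed-intN", 0.0),
            _u("ZF1x6-C", "mKate2", REPORTER_DOSE),
        ),
        reporters=("mKate2",),
    )
    return LibraryEntry(
        id="NIMPLY_SPLICE_fig1H",
        summary="activator-to-inhibitor conversion by trans-splicing",
        circuit=c,
        inputs=("VP64-intC-ZF1", "DsDed-intN"),
        input_grids=(GATE_INPUT_GRID, GATE_INPUT_GRID),
        truth={"mKate2": "0010"},
    )


@_register
def _nimply_cascade_fig1i() -> LibraryEntry:
    """NIMPLY via an inhibition cascade: the second input induces a
    PEST-tagged downstream inhibitor of the reporter."""
    c = Circuit(
        units=(
            _u("CMV", "VP64-ZF1", 0.0),
            _u("CMV", "VP64-ZF10", 0.0),
            _u("ZF10x6-C", "DsDed-ZF1-PEST", 20.0, label="cascade-inhibitor"),
            _u("ZF1x6-C", "mKate2", REPORTER_DOSE),
        ),
        reporters=("mKate2",),
    )
    return LibraryEntry(
        id="NIMPLY_CASCADE_fig1I",
        summary="NIMPLY through an induced downstream inhibitor",
        circuit=c,
        inputs=("VP64-ZF1", "VP64-ZF10"),
        input_grids=(ACT_INPUT_GRID, GATE_INPUT_GRID),
        truth={"mKate2": "0010"},
    )


@_register
def _cascade_and_fig1j() -> LibraryEntry:
    """AND via double inversion: the cascade's upstream inhibitor is split
    into DsDed-intN and intC-ZF10; only joint delivery reconstitutes
    DsDed-ZF10, which silences the PEST-tagged downstream inhibitor and
    thereby releases the reporter."""
    c = Circuit(
        units=(
            _u("CMV", "VP64-ZF1", 5.0, label="ZFa"),
            _u("CMV", "VP64-ZF10", 20.0, label="cascade-activator"),
            _u("ZF10x6-C", "DsDed-ZF1-PEST", 20.0, label="cascade-inhibitor"),
            _u("CMV", "DsDed-intN", 0.0),
            _u("CMV", _intc_inhibitor("intC-ZF10"), 0.0),
            _u("ZF1x6-C", "mKate2", REPORTER_DOSE),
        ),
        reporters=("mKate2",),
    )
    return LibraryEntry(
        id="CASCADE_AND_fig1J",
        summary="double-inversion cascade AND (ultrasensitive activation)",
        circuit=c,
        inputs=("DsDed-intN", "intC-ZF10"),
        input_grids=(GATE_INPUT_GRID, GATE_INPUT_GRID),
        truth={"mKate2": "0001"},
        hill_input=("DsDed-intN", "intC-ZF10"),
        hill_grid=HILL_GRID,
    )


# ---------------------------------------------------------------------------
# MIMO gates


@_register
def _nimplynot_fig2b() -> LibraryEntry:
    """Noncompact composite: a NIMPLY gate and a NOT gate simply co-delivered
    (input B is a co-titrated pair of inhibitors)."""
    c = Circuit(
        units=(
            _u("CMV", "VP64-ZF1", 0.0),
            _u("CMV", "ZF1", 0.0),
            _u("CMV", "DsDed-ZF10", 0.0),
            _u("CMV", "VP64-ZF10", 5.0, label="ZF10a"),
            _u("ZF1x6-C", "mKate2", REPORTER_DOSE),
            _u("ZF10x6-C", "EYFP", REPORTER_DOSE),
        ),
        reporters=("mKate2", "EYFP"),
    )
    return LibraryEntry(
        id="NIMPLYNOT_fig2B",
        summary="noncompact NIMPLY + NOT composite (MIMO base case)",
        circuit=c,
        inputs=("VP64-ZF1", ("ZF1", "DsDed-ZF10")),
        input_grids=(ACT_INPUT_GRID, GATE_INPUT_GRID),
        truth={"mKate2": "0010", "EYFP": "1010"},
    )


@_register
def _ifnimply_fig2c() -> LibraryEntry:
    """IF/NIMPLY: bispecific VP64-ZF1-intC-ZF10 activates both reporters;
    inert DsDed-intN splices it into a VP64-ZF1 activator plus a DsDed-ZF10
    inhibitor."""
    c = Circuit(
        units=(
            _u("CMV", "VP64-ZF1-intC-ZF10", 0.0),
            _u("CMV", "DsDed-intN", 0.0),
            _u("ZF1x6-C", "mKate2", REPORTER_DOSE),
            _u("ZF10x6-C", "EYFP", REPORTER_DOSE),
        ),
        reporters=("mKate2", "EYFP"),
    )
    return LibraryEntry(
        id="IFNIMPLY_fig2C",
        summary="bispecific activator split into activator + inhibitor",
        circuit=c,
        inputs=("VP64-ZF1-intC-ZF10", "DsDed-intN"),
        input_grids=(GATE_INPUT_GRID, GATE_INPUT_GRID),
        truth={"mKate2": "0011", "EYFP": "0010"},
    )


@_register
def _ifand_fig2d() -> LibraryEntry:
    """IF/AND: an activator and an inhibitor splice into a bispecific
    activator and an inert intein complex (inverse of IF/NIMPLY)."""
    c = Circuit(
        units=(
            _u("CMV", "VP64-ZF1-intN", 0.0),
            _u("CMV", _intc_inhibitor("intC-ZF10"), 0.0),
            _u("ZF1x6-C", "mKate2", REPORTER_DOSE),
            _u("ZF10x6-C", "EYFP", REPORTER_DOSE),
        ),
        reporters=("mKate2", "EYFP"),
    )
    return LibraryEntry(
        id="IFAND_fig2D",
        summary="splice-generated bispecific activator (IF/AND)",
        circuit=c,
        inputs=("VP64-ZF1-intN", "intC-ZF10"),
        input_grids=(GATE_INPUT_GRID, GATE_INPUT_GRID),
        truth={"mKate2": "0011", "EYFP": "0001"},
    )


@_register
def _nimplyand_fig2e() -> LibraryEntry:
    """NIMPLY/AND: VP64-intC-ZF1-DsDed and intN-ZF10 invert each other's
    activities -- splicing yields a ZF1-DsDed inhibitor and a
    VP64-intein-ZF10 activator."""
    c = Circuit(
        units=(
            _u("CMV", "VP64-intC-ZF1-DsDed", 0.0),
            _u("CMV", "intN-ZF10", 0.0),
            _u("ZF1x6-C", "mKate2", REPORTER_DOSE),
            _u("ZF10x6-C", "EYFP", REPORTER_DOSE),
        ),
        reporters=("mKate2", "EYFP"),
    )
    return LibraryEntry(
        id="NIMPLYAND_fig2E",
        summary="mutual activity inversion by splicing (NIMPLY/AND)",
        circuit=c,
        inputs=("VP64-intC-ZF1-DsDed", "intN-ZF10"),
        input_grids=(GATE_INPUT_GRID, GATE_INPUT_GRID),
        truth={"mKate2": "0010", "EYFP": "0001"},
    )


@_register
def _nimplynimply_fig2f() -> LibraryEntry:
    """NIMPLY/NIMPLY: two activators splice into a bifunctional ZF10-ZF1
    inhibitor plus an inert AD-intein byproduct; with a shared readout this
    would be a XOR gate."""
    c = Circuit(
        units=(
            _u("CMV", "VP64-intC-ZF1", 0.0),
            _u("CMV", "ZF10-intN-VP64", 0.0),
            _u("ZF1x6-C", "mKate2", REPORTER_DOSE),
            _u("ZF10x6-C", "EYFP", REPORTER_DOSE),
        ),
        reporters=("mKate2", "EYFP"),
    )
    return LibraryEntry(
        id="NIMPLYNIMPLY_fig2F",
        summary="two activators splice into one bifunctional inhibitor",
        circuit=c,
        inputs=("VP64-intC-ZF1", "ZF10-intN-VP64"),
        input_grids=(GATE_INPUT_GRID, GATE_INPUT_GRID),
        truth={"mKate2": "0010", "EYFP": "0100"},
    )


# ---------------------------------------------------------------------------
# analog circuits


@_register
def _ultra_base_fig3a() -> LibraryEntry:
    c = Circuit(
        units=(
            _u("CMV", "VP64-ZF1", 0.0),
            _u("ZF1x6-C", "EYFP", REPORTER_DOSE),
        ),
        reporters=("EYFP",),
    )
    return LibraryEntry(
        id="ULTRA_BASE_fig3A",
        summary="standard ZFa dose response (Hill-1 base case)",
        circuit=c,
        inputs=("VP64-ZF1",),
        input_grids=(HILL_GRID,),
        hill_input="VP64-ZF1",
        hill_grid=HILL_GRID,
    )


@_register
def _ultra_thresh_fig3b() -> LibraryEntry:
    """DsDed-ZF thresholding: constitutive mixed inhibitor suppresses output
    at low activator dose, steepening the response."""
    c = Circuit(
        units=(
            _u("CMV", "VP64-ZF1", 0.0),
            _u("CMV", "DsDed-ZF1", 5.0, label="threshold"),
            _u("ZF1x6-C", "EYFP", REPORTER_DOSE),
        ),
        reporters=("EYFP",),
    )
    return LibraryEntry(
        id="ULTRA_THRESH_fig3B",
        summary="ZFa activation thresholded by a mixed inhibitor",
        circuit=c,
        inputs=("VP64-ZF1",),
        input_grids=(HILL_GRID_WIDE,),
        hill_input="VP64-ZF1",
        hill_grid=HILL_GRID_WIDE,
    )


@_register
def _ultra_razfa_fig3c() -> LibraryEntry:
    """RaZFa reconstitution: rising VP16-FRB converts the FKBP-ZF1 brake
    into the RaZFa accelerator (rapamycin present)."""
    c = Circuit(
        units=(
            _u("CMV", "VP16-FRB", 0.0),
            _u("CMV", "FKBP-ZF1", 25.0, label="fkbp-zf"),
            _u("ZF1x6-C", "EYFP", REPORTER_DOSE),
        ),
        reporters=("EYFP",),
        ligands_present=frozenset({"rapamycin"}),
    )
    return LibraryEntry(
        id="ULTRA_RAZFA_fig3C",
        summary="brake-to-accelerator conversion by induced dimerization",
        circuit=c,
        inputs=("VP16-FRB",),
        input_grids=(HILL_GRID_WIDE,),
        hill_input="VP16-FRB",
        hill_grid=HILL_GRID_WIDE,
    )


@_register
def _fkbpzf_inhibition_fig3e() -> LibraryEntry:
    c = Circuit(
        units=(
            _u("CMV", "VP64-ZF1", 5.0, label="ZFa"),
            _u("CMV", "FKBP-ZF1", 0.0),
            _u("ZF1x6-C", "EYFP", REPORTER_DOSE),
        ),
        reporters=("EYFP",),
    )
    return LibraryEntry(
        id="FKBPZF_INHIBITION_fig3E",
        summary="FKBP-ZF acts as a competitive inhibitor without ligand",
        circuit=c,
        inputs=("FKBP-ZF1",),
        input_grids=(HILL_GRID,),
    )


@_register
def _bandpass_base_fig3f() -> LibraryEntry:
    """Soft bandpass: moderate FKBP-ZF reconstitutes RaZFa, excess FKBP-ZF
    competes at the reporter promoter (no sharp upper threshold)."""
    c = Circuit(
        units=(
            _u("CMV", "VP16-FRB", 10.0, label="frb"),
            _u("CMV", "FKBP-ZF1", 0.0),
            _u("ZF1x6-C", "EYFP", REPORTER_DOSE),
        ),
        reporters=("EYFP",),
        ligands_present=frozenset({"rapamycin"}),
    )
    return LibraryEntry(
        id="BANDPASS_BASE_fig3F",
        summary="RaZFa bandpass with a soft upper threshold",
        circuit=c,
        inputs=("FKBP-ZF1",),
        input_grids=(HILL_GRID_WIDE,),
        hill_input="FKBP-ZF1",
        hill_grid=HILL_GRID_WIDE,
    )


@_register
def _bandpass_sharp_fig3g() -> LibraryEntry:
    """Sharp bandpass: VP16-FRB is itself expressed from a dual-specificity
    promoter that RaZFa feeds back onto and excess FKBP-ZF1 inhibits, adding
    a second negative path that tightens the upper threshold."""
    c = Circuit(
        units=(
            _u("CMV", "VP16-ZF2", 3.0, label="ZF2a"),
            _u("ZF1/2x6-C", "VP16-FRB", 20.0, label="frb"),
            _u("CMV", "FKBP-ZF1", 0.0),
            _u("ZF1x6-C", "EYFP", REPORTER_DOSE),
        ),
        reporters=("EYFP",),
        ligands_present=frozenset({"rapamycin"}),
    )
    return LibraryEntry(
        id="BANDPASS_SHARP_fig3G",
        summary="bandpass with dual FKBP-ZF negative regulation + feedback",
        circuit=c,
        inputs=("FKBP-ZF1",),
        input_grids=(HILL_GRID_WIDE,),
        hill_input="FKBP-ZF1",
        hill_grid=HILL_GRID_WIDE,
    )


# ---------------------------------------------------------------------------
# sensor-linked AND topologies (direct ZFa-input mode)


def _sensor_entry(n: int, units, summary: str) -> LibraryEntry:
    c = Circuit(
        units=(
            _u("CMV", "VP64-ZF2", 0.0),
            _u("CMV", "VP64-ZF6", 0.0),
            *units,
        ),
        reporters=("mKate2",),
    )
    return LibraryEntry(
        id=f"SENSOR_AND_topology{n}_fig4C",
        summary=summary,
        circuit=c,
        inputs=("VP64-ZF2", "VP64-ZF6"),
        input_grids=(GATE_INPUT_GRID, GATE_INPUT_GRID),
        truth={"mKate2": "0001"},
    )


@_register
def _sensor_and_1() -> LibraryEntry:
    return _sensor_entry(
        1,
        (_u("(ZF2/ZF6)x3", "mKate2", REPORTER_DOSE),),
        "hybrid promoter with alternating ZF2/ZF6 sites",
    )


@_register
def _sensor_and_2() -> LibraryEntry:
    return _sensor_entry(
        2,
        (
            _u("ZF2x6-C", "VP64-intN", 20.0),
            _u("ZF6x6-C", _intc_inhibitor("intC-ZF1"), 20.0),
            _u("ZF1x6-C", "mKate2", REPORTER_DOSE),
        ),
        "AND via an induced splicing layer",
    )


@_register
def _sensor_and_3() -> LibraryEntry:
    return _sensor_entry(
        3,
        (
            _u("ZF2x6-C", "VP64-intN", 20.0),
            _u("ZF6x6-C", "DsDed-intC-ZF1", 5.0),
            _u("ZF1x6-C", "mKate2", REPORTER_DOSE),
        ),
        "AND via splicing with DsDed for tighter single-input inhibition",
    )


@_register
def _sensor_and_4() -> LibraryEntry:
    return _sensor_entry(
        4,
        (
            _u("ZF1/2x6-C", "VP64-intN", 20.0),
            _u("ZF6x6-C", _intc_inhibitor("intC-ZF1"), 20.0),
            _u("ZF1x6-C", "mKate2", REPORTER_DOSE),
        ),
        "AND via splicing with positive feedback through a dual promoter",
    )


def sensor_coupled(entry_id: str, ligands: Sequence[str] = ("ABA", "rapalog")) -> Circuit:
    """Replace the two direct ZFa input units of a sensor-AND topology by
    ligand-gated sensors (intracellular dimerizer releasing VP64-ZF2; MESA
    membrane receptor releasing VP64-ZF6) with the named ligands present."""
    entry = get_entry(entry_id)
    if not entry.id.startswith("SENSOR_AND_"):
        raise ValueError(f"{entry_id!r} is not a sensor-AND topology")
    keep = tuple(
        u for u in entry.circuit.units if u.label not in ("VP64-ZF2", "VP64-ZF6")
    )
    sensors = (
        SensorUnit(
            kind="intracellular-dimerizer",
            released_tf=_p("VP64-ZF2"),
            ligand="ABA",
            leak_fraction=1e-4,
            label="ABA-ZF2a",
        ),
        SensorUnit(
            kind="membrane-release",
            released_tf=_p("VP64-ZF6"),
            ligand="rapalog",
            leak_fraction=2e-4,
            label="Rapa-MESA-ZF6a",
        ),
    )
    return replace(
        entry.circuit,
        units=keep,
        sensors=sensors,
        ligands_present=entry.circuit.ligands_present | frozenset(ligands),
    )
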