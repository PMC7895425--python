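"""Circuit compilation: species closure, reaction emission, regulatory
edges, ablation, and serialization determinism."""

from collections import Counter

import numpy as np
import pytest

from cometsim.circuit import (
    Circuit,
    CompileError,
    ParamSet,
    TranscriptionUnit,
    apply_ablation,
    compile_circuit,
    list_regulatory_edges,
)
from cometsim.library import build_circuit, get_entry
from cometsim.metrics import complexity_report
from cometsim.parts import parse_protein_name
from cometsim.simulate import PopulationSettings, dose_response


def TU(promoter, protein, dose, label=""):
    return TranscriptionUnit(promoter=promoter, protein=protein, dose=dose, label=label)


# ---------------------------------------------------------------------------
# emission rules


def test_minimal_constitutive_unit_network(constitutive_circuit):
    net = compile_circuit(constitutive_circuit)
    kinds = Counter(s.kind for s in net.species)
    assert kinds == {"mrna": 1, "protein": 1}
    assert Counter(r.kind for r in net.reactions) == {
        "tx": 1, "mdeg": 1, "tl": 1, "pdeg": 1,
    }


def test_splicing_and_gate_network_contents():
    c = build_circuit("AND_fig1C").with_doses({"VP64-intN": 20, "intC-ZF1": 20})
    net = compile_circuit(c)
    names = set(net.species_names())
    # 3 mRNAs, 3 directly encoded proteins, 2 splice-derived species
    assert sum(s.kind == "mrna" for s in net.species) == 3
    assert {"VP64-intN", "intC-ZF1", "mKate2"} <= names
    assert {"VP64-ZF1", "intC/intN"} <= names  # splice product + spent intein
    assert len(net.species) == 8
    # tx/mdeg/tl per unit, pdeg per protein species, one splice reaction
    assert Counter(r.kind for r in net.reactions) == {
        "tx": 3, "mdeg": 3, "tl": 3, "pdeg": 5, "splice": 1,
    }
    edge_ids = {e.id for e in net.edges}
    assert {
        "activation:VP64-ZF1->mKate2",
        "splice:VP64-intN->VP64-ZF1+intC/intN",
        "splice:intC-ZF1->VP64-ZF1+intC/intN",
        # the unspliced intC-ZF1 fragment competes at the reporter promoter
        "inhibition-competitive:intC-ZF1->mKate2",
    } == edge_ids


def test_double_inversion_cascade_represses_the_repressor():
    edges = {e.id for e in list_regulatory_edges(build_circuit("CASCADE_AND_fig1J"))}
    # the reporter's inhibitor is itself repressed by the spliced product
    assert "inhibition-mixed:DsDed-ZF1-PEST->mKate2" in edges
    assert "inhibition-mixed:DsDed-ZF10->cascade-inhibitor" in edges


def test_pest_degron_accelerates_degradation(params):
    net = compile_circuit(build_circuit("CASCADE_AND_fig1J"))
    deg = {s.name: s.degradation for s in net.species if s.kind != "mrna"}
    kin = params.kinetics
    assert deg["DsDed-ZF1-PEST"] == pytest.approx(kin.delta_p * kin.rho_pest)
    assert deg["VP64-ZF1"] == pytest.approx(kin.delta_p)
    # intC-ZF10 ships with the destabilization multiplier
    assert deg["intC-ZF10"] > deg["VP64-ZF1"]


def test_mass_action_consistency_of_bimolecular_reactions():
    for cid in ("AND_fig1C", "NIMPLYAND_fig2E", "ULTRA_RAZFA_fig3C"):
        net = compile_circuit(build_circuit(cid))
        names = set(net.species_names())
        for r in net.reactions:
            assert set(r.reactants) <= names and set(r.products) <= names
            if r.kind == "splice":
                assert len(r.reactants) == 2 and len(r.products) == 2
            if r.kind == "dimer-on":
                assert len(r.reactants) == 2 and len(r.products) == 1


def test_splice_conservation_holds_network_wide():
    def counts(name):
        return Counter(
            d.name
            for d in parse_protein_name(name).domains
            if d.category not in ("intein-N", "intein-C", "spent-intein")
        )

    net = compile_circuit(build_circuit("NIMPLYAND_fig2E"))
    for r in net.reactions:
        if r.kind == "splice":
            a, b = r.reactants
            p, q = r.products
            assert counts(a) + counts(b) == counts(p) + counts(q)


def test_dimerization_requires_ligand_presence():
    c = build_circuit("ULTRA_RAZFA_fig3C")
    net = compile_circuit(c)
    assert any(r.kind == "dimer-on" for r in net.reactions)
    no_ligand = Circuit(
        units=c.units, reporters=c.reporters, ligands_present=frozenset()
    )
    net0 = compile_circuit(no_ligand)
    assert not any(r.kind == "dimer-on" for r in net0.reactions)


def test_dose_unit_conversion_to_gene_copies(params):
    c = Circuit(
        units=(TU("CMV", "mKate2", 2.0),), reporters=("mKate2",), dose_unit="ng"
    )
    net = compile_circuit(c, params)
    assert net.dose_map["mKate2"] == pytest.approx(2.0 * params.copies_per_ng)
    c2 = Circuit(
        units=(TU("CMV", "mKate2", 5e8),), reporters=("mKate2",), dose_unit="copies"
    )
    assert compile_circuit(c2, params).dose_map["mKate2"] == pytest.approx(5e8)


def test_compilation_is_deterministic():
    a = compile_circuit(build_circuit("NIMPLYNIMPLY_fig2F")).to_json()
    b = compile_circuit(build_circuit("NIMPLYNIMPLY_fig2F")).to_json()
    assert a == b


def test_unreachable_reporter_is_rejected_at_construction():
    with pytest.raises(ValueError, match="reporter"):
        Circuit(units=(TU("CMV", "VP64-ZF1", 1.0),), reporters=("mKate2",))


# ---------------------------------------------------------------------------
# regulatory edges and ablation


def test_single_zfa_circuit_has_one_edge(zfa_circuit):
    edges = list_regulatory_edges(zfa_circuit)
    assert [e.id for e in edges] == ["activation:VP64-ZF1->mKate2"]


def test_nimply_nimply_edges_include_bifunctional_inhibitor():
    edges = {e.id for e in list_regulatory_edges(build_circuit("NIMPLYNIMPLY_fig2F"))}
    assert "activation:VP64-intC-ZF1->mKate2" in edges
    assert "activation:ZF10-intN-VP64->EYFP" in edges
    assert "inhibition-competitive:ZF10-ZF1->mKate2" in edges
    assert "inhibition-competitive:ZF10-ZF1->EYFP" in edges


def test_ablating_sole_activation_path_flattens_response(zfa_circuit, single_cell):
    ablated = apply_ablation(zfa_circuit, "activation:VP64-ZF1->mKate2")
    doses = [0.0, 3.0, 30.0]
    dr = dose_response(ablated, "VP64-ZF1", doses, pop=single_cell)
    assert np.allclose(dr.outputs, dr.outputs[0], rtol=1e-6)
    # the original circuit is untouched and still responds
    intact = dose_response(zfa_circuit, "VP64-ZF1", doses, pop=single_cell)
    assert intact.outputs[-1] > 10 * intact.outputs[0]


def test_ablation_keeps_species_and_rejects_unknown_edges(zfa_circuit):
    ablated = apply_ablation(zfa_circuit, "activation:VP64-ZF1->mKate2")
    assert set(compile_circuit(ablated).species_names()) == set(
        compile_circuit(zfa_circuit).species_names()
    )
    with pytest.raises(KeyError, match="unknown edge"):
        apply_ablation(zfa_circuit, "activation:nobody->nothing")


def test_species_cap_guards_against_explosion():
    # many mutually spliceable fragment pairs blow past the species cap
    units = []
    for i in range(1, 9):
        units.append(TU("CMV", f"VP64-ZF{i}-intN", 1.0, label=f"n{i}"))
        units.append(TU("CMV", parse_protein_name(f"intC-ZF{i}"), 1.0, label=f"c{i}"))
    units.append(TU("ZF1x6-C", "mKate2", 50.0))
    with pytest.raises(CompileError, match="cap"):
        compile_circuit(Circuit(units=tuple(units), reporters=("mKate2",)))


# ---------------------------------------------------------------------------
# complexity counts


def test_complexity_minimal_circuit(zfa_circuit):
    rep = complexity_report(zfa_circuit)
    assert (rep.n_genes, rep.n_regulatory_connections, rep.n_regulatory_proteins) == (
        2, 1, 1,
    )


def test_complexity_constitutive_reporter_has_no_connections(constitutive_circuit):
    assert complexity_report(constitutive_circuit).n_regulatory_connections == 0


def test_complexity_splicing_and_gate():
    rep = complexity_report(build_circuit("AND_fig1C"))
    # two fragments + the spliced activator carry regulatory roles; the spent
    # intein complex and the reporter do not
    assert rep.n_regulatory_proteins == 3
    assert rep.n_genes == 3
    assert rep.n_regulatory_connections == 4
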