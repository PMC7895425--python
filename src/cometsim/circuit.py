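"""Compile a circuit description into a closed reaction network.

A :class:`Circuit` is a set of transcription units (promoter + fusion protein
+ plasmid dose), optional ligand-gated sensors, the set of ligands present in
the medium, and one or two designated reporter outputs.  Compilation emits,
per unit, transcription / mRNA degradation / translation / protein
degradation, then closes the species set under trans-splicing and
ligand-induced dimerization by fixed-point iteration, emitting an
irreversible second-order splice reaction for every complementary intein
pair and a reversible association for every ligand-bridged dimerizer pair.
Ligands are binary environmental conditions (present at saturating dose or
absent), not dynamic species.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Tuple

from .parts import (
    ComplexSpec,
    PromoterSpec,
    ProteinSpec,
    classify_roles,
    dimerize,
    parse_promoter_name,
    parse_protein_name,
    trans_splice,
)
from .registry import PartRegistry, default_params, default_registry

__all__ = [
    "TranscriptionUnit",
    "SensorUnit",
    "Circuit",
    "KineticParams",
    "ParamSet",
    "Reaction",
    "SpeciesDecl",
    "RegulatoryEdge",
    "ReactionNetwork",
    "CompileError",
    "compile_circuit",
    "list_regulatory_edges",
    "apply_ablation",
]


class CompileError(ValueError):
    pass


def _as_protein(p) -> ProteinSpec:
    return p if isinstance(p, ProteinSpec) else parse_protein_name(p)


def _as_promoter(p) -> PromoterSpec:
    return p if isinstance(p, PromoterSpec) else parse_promoter_name(p)


@dataclass(frozen=True)
class TranscriptionUnit:
    """One gene: promoter, encoded fusion protein, plasmid dose.

    ``label`` identifies the unit for dose sweeps and edge naming; it
    defaults to the encoded protein name.
    """

    promoter: PromoterSpec
    protein: ProteinSpec
    dose: float
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "promoter", _as_promoter(self.promoter))
        object.__setattr__(self, "protein", _as_protein(self.protein))
        if self.dose < 0:
            raise ValueError(f"unit {self.label or self.protein.name}: dose < 0")
        if not self.label:
            object.__setattr__(self, "label", self.protein.name)


@dataclass(frozen=True)
class SensorUnit:
    """Abstracted ligand-gated sensor that releases a transcription factor.

    Covers both intracellular dimerizer sensors and membrane receptors: the
    released TF is produced at ``release_rate`` with ligand and at
    ``leak_fraction * release_rate`` without.  ``release_rate=None`` uses the
    shipped default.
    """

    kind: str  # intracellular-dimerizer | membrane-release
    released_tf: ProteinSpec
    ligand: str
    leak_fraction: float = 0.0
    release_rate: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "released_tf", _as_protein(self.released_tf))
        if self.kind not in ("intracellular-dimerizer", "membrane-release"):
            raise ValueError(f"unknown sensor kind {self.kind!r}")
        if not 0 <= self.leak_fraction < 1:
            raise ValueError("leak_fraction must be in [0, 1)")
        roles = classify_roles(self.released_tf)
        if not roles.is_dna_binding:
            raise ValueError(
                f"sensor {self.label or self.ligand}: released TF "
                f"{self.released_tf.name} has no DNA-binding role"
            )
        if not self.label:
            object.__setattr__(self, "label", f"sensor[{self.ligand}]")


@dataclass(frozen=True)
class Circuit:
    """A genetic program: transcription units, sensors, ligand conditions and
    designated reporter output(s)."""

    units: Tuple[TranscriptionUnit, ...]
    sensors: Tuple[SensorUnit, ...] = ()
    ligands_present: frozenset = frozenset()
    reporters: Tuple[str, ...] = ()
    dose_unit: str = "ng"  # ng | copies
    ablated_edges: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", tuple(self.units))
        object.__setattr__(self, "sensors", tuple(self.sensors))
        object.__setattr__(self, "ligands_present", frozenset(self.ligands_present))
        object.__setattr__(self, "reporters", tuple(self.reporters))
        object.__setattr__(self, "ablated_edges", frozenset(self.ablated_edges))
        if not self.units:
            raise ValueError("a circuit needs at least one transcription unit")
        if self.dose_unit not in ("ng", "copies"):
            raise ValueError(f"unknown dose unit {self.dose_unit!r}")
        labels = [u.label for u in self.units]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate unit labels in {labels}")
        produced = {u.protein.name for u in self.units}
        for r in self.reporters:
            if r not in produced:
                raise ValueError(f"reporter {r!r} is not produced by any unit")

    def unit(self, label: str) -> TranscriptionUnit:
        for u in self.units:
            if u.label == label:
                return u
        raise KeyError(f"no unit labelled {label!r}")

    def with_doses(self, doses: Mapping[str, float]) -> "Circuit":
        """Copy of the circuit with the doses of the named units replaced."""
        for label in doses:
            self.unit(label)
        new_units = tuple(
            replace(u, dose=float(doses.get(u.label, u.dose))) for u in self.units
        )
        return replace(self, units=new_units)


@dataclass(frozen=True)
class KineticParams:
    """Global kinetic constants (units: hours, arbitrary concentration)."""

    k_tx: float = 5.0e-9
    k_tl: float = 1.0
    delta_m: float = 0.2
    delta_p: float = 0.05
    rho_pest: float = 5.0
    k_spl: float = 1.0e-4
    k_on: float = 1.0e-3
    k_off: float = 1.0
    sensor_release_rate: float = 4.0e3

    def __post_init__(self) -> None:
        vals = self.__dict__ if hasattr(self, "__dict__") else {}
        for f_ in (
            "k_tx", "k_tl", "delta_m", "delta_p", "rho_pest",
            "k_spl", "k_on", "k_off", "sensor_release_rate",
        ):
            if getattr(self, f_) <= 0:
                raise ValueError(f"{f_} must be positive")
        if self.rho_pest <= 1:
            raise ValueError("rho_pest must exceed 1")

    @property
    def K_dim(self) -> float:
        return self.k_off / self.k_on

    def replace(self, **kw) -> "KineticParams":
        return replace(self, **kw)


class ParamSet:
    """Bundle of kinetic constants, promoter parameters and dose conversion,
    resolved from the shipped defaults plus optional overrides."""

    def __init__(self, doc: Optional[dict] = None, registry: Optional[PartRegistry] = None):
        doc = doc if doc is not None else default_params()
        self.registry = registry or default_registry()
        kin = {k: float(v) for k, v in doc.get("kinetics", {}).items()}
        self.kinetics = KineticParams(**kin)
        self._prom_defaults = dict(doc.get("promoter_defaults", {}))
        self._prom_overrides = dict(doc.get("promoter_overrides", {}) or {})
        self.copies_per_ng = float(doc.get("dose", {}).get("copies_per_ng", 2.0e8))

    def promoter_params(self, promoter_name: str):
        from .promoter import PromoterParams

        d = dict(self._prom_defaults)
        d.update(self._prom_overrides.get(promoter_name, {}))
        return PromoterParams(
            background_rate=float(d.get("background_rate", 0.1)),
            unit_amplitude=float(d.get("unit_amplitude", 1.0)),
            cooperativity=float(d.get("cooperativity", 2.5)),
            K_default=float(d.get("K", 2.0e4)),
            K={k: float(v) for k, v in d.get("K_per_zf", {}).items()},
            inhibitor_affinity_fold=float(d.get("inhibitor_affinity_fold", 10.0)),
        )

    def constitutive_rate(self, promoter_name: str) -> float:
        return float(self.registry.constitutive_promoters[promoter_name])

    def with_kinetics(self, **kw) -> "ParamSet":
        import copy

        new = copy.copy(self)
        new.kinetics = self.kinetics.replace(**kw)
        return new


# ---------------------------------------------------------------------------
# network representation


@dataclass(frozen=True)
class SpeciesDecl:
    name: str
    kind: str  # mrna | protein | complex
    degradation: float  # first-order rate, h^-1
    roles: Tuple[str, ...] = ()
    zfs: Tuple[str, ...] = ()


@dataclass(frozen=True)
class Reaction:
    kind: str  # tx | mdeg | tl | pdeg | splice | dimer-on | dimer-off | sensor
    reactants: Tuple[str, ...]
    products: Tuple[str, ...]
    params: Tuple[Tuple[str, float], ...] = ()

    def param(self, key: str) -> float:
        return dict(self.params)[key]


@dataclass(frozen=True)
class RegulatoryEdge:
    source: str
    target: str
    sign: str  # + | -
    mechanism: str  # activation | inhibition-competitive | inhibition-mixed |
    #                 splice | dimerization | sensor-release

    @property
    def id(self) -> str:
        return f"{self.mechanism}:{self.source}->{self.target}"


@dataclass
class ReactionNetwork:
    """Closed species inventory + reaction list, ready for integration."""

    species: List[SpeciesDecl]
    reactions: List[Reaction]
    units: List[dict]  # per-unit transcription records (see compile_circuit)
    dose_map: Dict[str, float]  # unit label -> dose in gene copies
    readout: Tuple[str, ...]
    kinetics: KineticParams
    edges: List[RegulatoryEdge]

    def species_names(self) -> List[str]:
        return [s.name for s in self.species]

    def index(self, name: str) -> int:
        return self.species_names().index(name)

    def to_json(self) -> str:
        """Deterministic serialization for inspection and diffing."""
        doc = {
            "species": [
                {
                    "name": s.name,
                    "kind": s.kind,
                    "degradation": s.degradation,
                    "roles": list(s.roles),
                    "zfs": list(s.zfs),
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "kind": r.kind,
                    "reactants": list(r.reactants),
                    "products": list(r.products),
                    "params": {k: v for k, v in r.params},
                }
                for r in self.reactions
            ],
            "dose_map": dict(sorted(self.dose_map.items())),
            "readout": list(self.readout),
            "kinetics": {
                k: getattr(self.kinetics, k)
                for k in (
                    "k_tx", "k_tl", "delta_m", "delta_p", "rho_pest",
                    "k_spl", "k_on", "k_off", "sensor_release_rate",
                )
            },
            "edges": [e.id for e in self.edges],
        }
        return json.dumps(doc, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# compilation

MAX_SPECIES = 64


def _protein_key(p) -> str:
    return p.name


def _protein_degradation(p, kin: KineticParams) -> float:
    rate = kin.delta_p * p.stability_multiplier
    if p.has("degron"):
        rate *= kin.rho_pest
    return rate


def _splice_partners(a, b) -> bool:
    if isinstance(a, ComplexSpec) or isinstance(b, ComplexSpec):
        return False  # assembled complexes do not trans-splice
    return (a.has("intein-N") and b.has("intein-C")) or (
        a.has("intein-C") and b.has("intein-N")
    )


def _close_species(proteins, ligands, registry, cap=MAX_SPECIES):
    """Fixed-point closure of the protein set under splicing and dimerization.

    Returns (all proteins/complexes by name, splice pair list, dimer list).
    """
    pool: Dict[str, object] = {p.name: p for p in proteins}
    splices: List[Tuple[str, str, str, str]] = []  # a, b, product, byproduct
    dimers: List[Tuple[str, str, str, str]] = []  # a, b, complex, ligand
    seen_pairs = set()
    changed = True
    while changed:
        changed = False
        names = sorted(pool)
        for i, na in enumerate(names):
            for nb in names[i:]:
                a, b = pool[na], pool[nb]
                key = (na, nb)
                if key in seen_pairs:
                    continue
                if na != nb and _splice_partners(a, b):
                    prod, by = trans_splice(a, b, registry)
                    splices.append((na, nb, prod.name, by.name))
                    for sp in (prod, by):
                        if sp.name not in pool:
                            pool[sp.name] = sp
                            changed = True
                if not isinstance(a, ComplexSpec) and not isinstance(b, ComplexSpec):
                    for lig in sorted(ligands):
                        cx = dimerize(a, b, lig, registry)
                        if cx is not None:
                            dimers.append((na, nb, cx.name, lig))
                            if cx.name not in pool:
                                pool[cx.name] = cx
                                changed = True
                seen_pairs.add(key)
                if len(pool) > cap:
                    raise CompileError(
                        f"species closure exceeded the cap of {cap}; "
                        "check for a splice-product explosion"
                    )
    return pool, splices, dimers


def _binders_for(prom: PromoterSpec, pool: Mapping[str, object]):
    """DNA-binding species cognate to ``prom``: (name, zf, role) triples."""
    out = []
    for name in sorted(pool):
        sp = pool[name]
        roles = classify_roles(sp)
        if not roles.is_dna_binding:
            continue
        for zf in sp.zfs():
            if zf in prom.cognate_zfs:
                if "activator" in roles:
                    role = "activator"
                elif "mixed-inhibitor" in roles:
                    role = "mixed-inhibitor"
                else:
                    role = "competitive-inhibitor"
                out.append((name, zf, role))
                break  # one binding mode per species per promoter
    return out


def compile_circuit(
    circuit: Circuit,
    params: Optional[ParamSet] = None,
    registry: Optional[PartRegistry] = None,
) -> ReactionNetwork:
    """Compile ``circuit`` into a closed :class:`ReactionNetwork`.

    Deterministic: identical circuits yield byte-identical ``to_json()``
    output.  Raises :class:`CompileError` on an uncompilable circuit and
    warns when no production path reaches a reporter.
    """
    registry = registry or default_registry()
    params = params or ParamSet(registry=registry)
    kin = params.kinetics

    direct = [u.protein for u in circuit.units] + [
        s.released_tf for s in circuit.sensors
    ]
    # deduplicate by name, keeping the first occurrence
    seen = {}
    for p in direct:
        seen.setdefault(p.name, p)
    pool, splices, dimers = _close_species(
        seen.values(), circuit.ligands_present, registry
    )

    # ---- species -----------------------------------------------------------
    species: List[SpeciesDecl] = []
    for u in circuit.units:
        species.append(
            SpeciesDecl(name=f"mRNA[{u.label}]", kind="mrna", degradation=kin.delta_m)
        )
    for name in sorted(pool):
        sp = pool[name]
        roles = classify_roles(sp)
        kind = "complex" if isinstance(sp, ComplexSpec) else "protein"
        species.append(
            SpeciesDecl(
                name=name,
                kind=kind,
                degradation=_protein_degradation(sp, kin),
                roles=tuple(sorted(roles.roles)),
                zfs=sp.zfs(),
            )
        )

    # ---- doses -------------------------------------------------------------
    scale = params.copies_per_ng if circuit.dose_unit == "ng" else 1.0
    dose_map = {u.label: u.dose * scale for u in circuit.units}

    # ---- regulatory edges (pre-ablation) ------------------------------------
    edges: List[RegulatoryEdge] = []
    sign = {
        "activator": "+",
        "competitive-inhibitor": "-",
        "mixed-inhibitor": "-",
    }
    mech = {
        "activator": "activation",
        "competitive-inhibitor": "inhibition-competitive",
        "mixed-inhibitor": "inhibition-mixed",
    }
    unit_binders: Dict[str, list] = {}
    for u in circuit.units:
        if u.promoter.is_constitutive:
            unit_binders[u.label] = []
            continue
        binders = _binders_for(u.promoter, pool)
        unit_binders[u.label] = binders
        for name, zf, role in binders:
            edges.append(
                RegulatoryEdge(source=name, target=u.label, sign=sign[role], mechanism=mech[role])
            )
    for a, b, prod, by in splices:
        target = f"{prod}+{by}"
        for src in (a, b):
            edges.append(RegulatoryEdge(source=src, target=target, sign="+", mechanism="splice"))
    for a, b, cx, lig in dimers:
        for src in (a, b):
            edges.append(
                RegulatoryEdge(source=src, target=cx, sign="+", mechanism="dimerization")
            )
    for s in circuit.sensors:
        edges.append(
            RegulatoryEdge(
                source=s.ligand, target=s.released_tf.name, sign="+", mechanism="sensor-release"
            )
        )
    edges = sorted(set(edges), key=lambda e: e.id)

    unknown = circuit.ablated_edges - {e.id for e in edges}
    if unknown:
        raise CompileError(f"cannot ablate unknown edges: {sorted(unknown)}")

    # ---- reactions ----------------------------------------------------------
    reactions: List[Reaction] = []
    units_out: List[dict] = []
    for u in circuit.units:
        m = f"mRNA[{u.label}]"
        binders = [
            (name, zf, role)
            for (name, zf, role) in unit_binders[u.label]
            if RegulatoryEdge(name, u.label, sign[role], mech[role]).id
            not in circuit.ablated_edges
        ]
        if u.promoter.is_constitutive:
            const = params.constitutive_rate(u.promoter.name)
            prom_params = None
        else:
            const = None
            prom_params = params.promoter_params(u.promoter.name)
        units_out.append(
            {
                "label": u.label,
                "promoter": u.promoter,
                "promoter_params": prom_params,
                "constitutive_rate": const,
                "mrna": m,
                "protein": u.protein.name,
                "binders": binders,
            }
        )
        reactions.append(
            Reaction(kind="tx", reactants=(), products=(m,), params=(("unit", 0.0),))
        )
        reactions.append(
            Reaction(kind="mdeg", reactants=(m,), products=(), params=(("rate", kin.delta_m),))
        )
        reactions.append(
            Reaction(
                kind="tl",
                reactants=(m,),
                products=(m, u.protein.name),
                params=(("rate", kin.k_tl),),
            )
        )
    for name in sorted(pool):
        deg = _protein_degradation(pool[name], kin)
        reactions.append(
            Reaction(kind="pdeg", reactants=(name,), products=(), params=(("rate", deg),))
        )
    for a, b, prod, by in splices:
        eid_a = f"splice:{a}->{prod}+{by}"
        eid_b = f"splice:{b}->{prod}+{by}"
        if {eid_a, eid_b} & circuit.ablated_edges:
            continue
        reactions.append(
            Reaction(
                kind="splice",
                reactants=(a, b),
                products=(prod, by),
                params=(("rate", kin.k_spl),),
            )
        )
    for a, b, cx, lig in dimers:
        if {
            f"dimerization:{a}->{cx}",
            f"dimerization:{b}->{cx}",
        } & circuit.ablated_edges:
            continue
        reactions.append(
            Reaction(kind="dimer-on", reactants=(a, b), products=(cx,), params=(("rate", kin.k_on),))
        )
        reactions.append(
            Reaction(kind="dimer-off", reactants=(cx,), products=(a, b), params=(("rate", kin.k_off),))
        )
    for s in circuit.sensors:
        rate = s.release_rate if s.release_rate is not None else kin.sensor_release_rate
        eff = rate if s.ligand in circuit.ligands_present else rate * s.leak_fraction
        reactions.append(
            Reaction(
                kind="sensor",
                reactants=(),
                products=(s.released_tf.name,),
                params=(("rate", eff),),
            )
        )

    # ---- diagnostics --------------------------------------------------------
    names = {s.name for s in species}
    for r in reactions:
        for sp in r.reactants + r.products:
            if sp not in names:
                raise CompileError(f"reaction references unknown species {sp!r}")
    return ReactionNetwork(
        species=species,
        reactions=reactions,
        units=units_out,
        dose_map=dose_map,
        readout=tuple(circuit.reporters),
        kinetics=kin,
        edges=edges,
    )


def list_regulatory_edges(
    circuit: Circuit,
    params: Optional[ParamSet] = None,
    registry: Optional[PartRegistry] = None,
) -> List[RegulatoryEdge]:
    """Deterministic, sorted list of regulatory interactions in the compiled
    circuit (including those mediated by derived splice/dimer species)."""
    return compile_circuit(
        replace(circuit, ablated_edges=frozenset()), params, registry
    ).edges


def apply_ablation(circuit: Circuit, edge_id: str) -> Circuit:
    """Return a copy of ``circuit`` with one regulatory interaction disabled.

    The interaction is masked (binding ignored, or the splice/dimer reaction
    dropped) without removing any species.  Unknown edge ids raise.
    """
    known = {e.id for e in list_regulatory_edges(circuit)}
    if edge_id not in known:
        raise KeyError(
            f"unknown edge {edge_id!r}; known edges:\n  " + "\n  ".join(sorted(known))
        )
    return replace(circuit, ablated_edges=circuit.ablated_edges | {edge_id})
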