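"""Fusion-protein and promoter grammar, role classification, and the algebra
of split-intein trans-splicing and ligand-induced dimerization.

Proteins are named by their domains from N to C terminus, hyphen-separated
("VP64-intC-ZF1-DsDed").  COMET promoters are named
``[ZF domain]x[number of binding sites]-[arrangement]`` (e.g. ``ZF1x6-C``),
with two registered dual-specificity cases (``ZF1/2x6-C``, ``(ZF2/ZF6)x3``)
and the constitutive promoters CMV and EF1a.

Role vocabulary
---------------
activator              activation domain + ZF in one chain or one complex
competitive-inhibitor  ZF without AD: competes for promoter sites
mixed-inhibitor        DsRed/DsDed-ZF without AD: competes *and* reduces
                       the cooperativity of transcription initiation
inert                  no transcriptional role of its own
splice-donor-N/C       carries a free intN / intC half
dimerizer-half         carries a ligand-dependent heterodimerization domain
reporter               carries a fluorescent reporter domain
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Tuple

from .registry import DomainSpec, PartRegistry, default_registry

__all__ = [
    "ProteinSpec",
    "ComplexSpec",
    "PromoterSpec",
    "RoleSet",
    "ParseError",
    "SpliceError",
    "parse_protein_name",
    "parse_promoter_name",
    "classify_roles",
    "trans_splice",
    "dimerize",
]

ROLES = frozenset(
    {
        "activator",
        "competitive-inhibitor",
        "mixed-inhibitor",
        "inert",
        "splice-donor-N",
        "splice-donor-C",
        "dimerizer-half",
        "reporter",
    }
)


class ParseError(ValueError):
    """Malformed or unregistered part name."""


class SpliceError(ValueError):
    """Incompatible intein halves."""


@dataclass(frozen=True)
class ProteinSpec:
    """An ordered (N->C) fusion of registered domains.

    ``stability_multiplier`` scales the protein degradation rate (>1 means
    less stable); it is 1 unless set explicitly or a PEST degron is handled
    by the compiler.
    """

    domains: Tuple[DomainSpec, ...]
    stability_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError("a protein needs at least one domain")
        if self.stability_multiplier <= 0:
            raise ValueError("stability_multiplier must be positive")
        for half in ("intein-N", "intein-C"):
            if sum(d.category == half for d in self.domains) > 1:
                raise ParseError(f"at most one {half} domain per protein")

    # -- convenience views -------------------------------------------------
    @property
    def name(self) -> str:
        return "-".join(d.name for d in self.domains)

    def categories(self) -> Tuple[str, ...]:
        return tuple(d.category for d in self.domains)

    def has(self, category: str) -> bool:
        return any(d.category == category for d in self.domains)

    def zfs(self) -> Tuple[str, ...]:
        """DNA-binding domain names, N->C order, duplicates preserved."""
        return tuple(d.name for d in self.domains if d.category == "dna-binding")

    def dimerizer_halves(self) -> Tuple[DomainSpec, ...]:
        return tuple(d for d in self.domains if d.category == "dimerizer-half")

    def index_of(self, category: str) -> int:
        for i, d in enumerate(self.domains):
            if d.category == category:
                return i
        raise ValueError(f"no {category} domain in {self.name}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class ComplexSpec:
    """A ligand-assembled heterodimer.  Pools the domains of both chains for
    role classification; the chains remain distinct species stoichiometrically.
    """

    chains: Tuple[ProteinSpec, ProteinSpec]
    ligand: str

    @property
    def domains(self) -> Tuple[DomainSpec, ...]:
        return self.chains[0].domains + self.chains[1].domains

    @property
    def name(self) -> str:
        return f"{self.chains[0].name}:{self.chains[1].name}"

    @property
    def stability_multiplier(self) -> float:
        return max(c.stability_multiplier for c in self.chains)

    def has(self, category: str) -> bool:
        return any(d.category == category for d in self.domains)

    def zfs(self) -> Tuple[str, ...]:
        return tuple(d.name for d in self.domains if d.category == "dna-binding")


@dataclass(frozen=True)
class RoleSet:
    roles: frozenset

    def __post_init__(self) -> None:
        unknown = self.roles - ROLES
        if unknown:
            raise ValueError(f"unknown roles {sorted(unknown)}")

    def __contains__(self, role: str) -> bool:
        return role in self.roles

    @property
    def is_dna_binding(self) -> bool:
        return bool(
            self.roles & {"activator", "competitive-inhibitor", "mixed-inhibitor"}
        )


@dataclass(frozen=True)
class PromoterSpec:
    """A COMET (or constitutive) promoter: binding-site count and layout.

    ``per_zf_capacity`` caps how many of the ``sites`` can be simultaneously
    occupied by each cognate ZF class; for the alternating-dual layout the two
    ZF classes bind disjoint three-site pools, while the overlapping-dual
    layout exposes one shared six-site pool to both classes.
    """

    name: str
    sites: int
    site_layout: str  # single-ZF | overlapping-dual | alternating-dual | constitutive
    cognate_zfs: Tuple[str, ...]
    per_zf_capacity: dict
    arrangement_class: str = ""

    def __post_init__(self) -> None:
        if self.site_layout != "constitutive" and self.sites < 1:
            raise ValueError("site count must be >= 1")
        if self.site_layout == "single-ZF":
            (zf,) = self.cognate_zfs
            assert self.per_zf_capacity[zf] == self.sites
        elif self.site_layout == "alternating-dual":
            assert self.sites == sum(self.per_zf_capacity.values())
        elif self.site_layout == "overlapping-dual":
            assert all(c == self.sites for c in self.per_zf_capacity.values())

    @property
    def is_constitutive(self) -> bool:
        return self.site_layout == "constitutive"

    def pools(self) -> Tuple[Tuple[int, Tuple[str, ...]], ...]:
        """Site pools as (pool size, cognate ZFs of the pool).

        single-ZF and overlapping-dual promoters expose one pool; the
        alternating-dual promoter exposes one disjoint pool per ZF class.
        """
        if self.is_constitutive:
            return ()
        if self.site_layout == "alternating-dual":
            return tuple(
                (self.per_zf_capacity[zf], (zf,)) for zf in self.cognate_zfs
            )
        return ((self.sites, self.cognate_zfs),)


# ---------------------------------------------------------------------------
# parsing


def _tokenize(name: str, registry: PartRegistry) -> list:
    """Split a hyphen-delimited fusion name into registered domain tokens.

    Longest-match against the registry resolves hyphens *inside* multi-token
    domain names (e.g. "DsRed-Express2").
    """
    tokens = []
    rest = name
    while rest:
        for cand in registry._by_length:
            if rest == cand or rest.startswith(cand + "-"):
                tokens.append(cand)
                rest = rest[len(cand) + 1 :]
                break
        else:
            bad = rest.split("-", 1)[0]
            raise ParseError(f"unknown domain token {bad!r} in {name!r}")
    return tokens


def parse_protein_name(
    name: str, registry: Optional[PartRegistry] = None
) -> ProteinSpec:
    """Parse an N->C hyphen-delimited fusion name into a :class:`ProteinSpec`.

    Round-trips: ``parse_protein_name(p.name) == p``.
    """
    registry = registry or default_registry()
    if not name:
        raise ParseError("empty protein name")
    tokens = _tokenize(name, registry)
    return ProteinSpec(domains=tuple(registry.domain(t) for t in tokens))


_STANDARD = re.compile(r"^ZF(\d+)x(\d+)-([A-Za-z]+)$")
_CONSTITUTIVE_ALIASES = {"EF1α": "EF1a", "EF1alpha": "EF1a"}


def parse_promoter_name(
    name: str, registry: Optional[PartRegistry] = None
) -> PromoterSpec:
    """Parse a promoter name per the COMET grammar.

    Handles the standard ``ZF<k>x<s>-<arrangement>`` form, the two registered
    dual-specificity promoters, and constitutive promoters (zero cognate ZFs).
    """
    registry = registry or default_registry()
    name = _CONSTITUTIVE_ALIASES.get(name, name)
    if name in registry.constitutive_promoters:
        return PromoterSpec(
            name=name,
            sites=0,
            site_layout="constitutive",
            cognate_zfs=(),
            per_zf_capacity={},
        )
    if name == "ZF1/2x6-C":
        # Six compact overlapping sites shared by ZF1 and ZF2 (up to six per ZF).
        return PromoterSpec(
            name=name,
            sites=6,
            site_layout="overlapping-dual",
            cognate_zfs=("ZF1", "ZF2"),
            per_zf_capacity={"ZF1": 6, "ZF2": 6},
            arrangement_class="C",
        )
    if name == "(ZF2/ZF6)x3":
        # Six compact sites alternating between ZF2 and ZF6 (up to three per ZF).
        return PromoterSpec(
            name=name,
            sites=6,
            site_layout="alternating-dual",
            cognate_zfs=("ZF2", "ZF6"),
            per_zf_capacity={"ZF2": 3, "ZF6": 3},
            arrangement_class="C",
        )
    m = _STANDARD.match(name)
    if not m:
        raise ParseError(f"malformed promoter name {name!r}")
    zf, sites, arr = f"ZF{m.group(1)}", int(m.group(2)), m.group(3)
    if zf not in registry.domains or registry.domain(zf).category != "dna-binding":
        raise ParseError(f"unknown ZF domain {zf!r} in promoter {name!r}")
    if sites < 1:
        raise ValueError(f"promoter {name!r}: site count must be >= 1")
    return PromoterSpec(
        name=name,
        sites=sites,
        site_layout="single-ZF",
        cognate_zfs=(zf,),
        per_zf_capacity={zf: sites},
        arrangement_class=arr,
    )


# ---------------------------------------------------------------------------
# role classification


def classify_roles(p) -> RoleSet:
    """Deterministic role assignment for a protein or ligand-assembled complex.

    A single species may hold several roles at once (functional modularity):
    e.g. FKBP-ZF1 is both a competitive inhibitor and a dimerizer half.
    """
    roles = set()
    has_ad = p.has("activation-domain")
    has_zf = p.has("dna-binding")
    has_fluor = p.has("fluorophore-inhibitory")
    if has_ad and has_zf:
        roles.add("activator")
    elif has_zf and has_fluor:
        roles.add("mixed-inhibitor")
    elif has_zf:
        roles.add("competitive-inhibitor")
    if p.has("intein-N"):
        roles.add("splice-donor-N")
    if p.has("intein-C"):
        roles.add("splice-donor-C")
    if p.has("dimerizer-half"):
        roles.add("dimerizer-half")
    if p.has("reporter"):
        roles.add("reporter")
    if not roles & {"activator", "competitive-inhibitor", "mixed-inhibitor"}:
        roles.add("inert")
    return RoleSet(frozenset(roles))


# ---------------------------------------------------------------------------
# trans-splicing


def _spent_intein(registry: PartRegistry) -> DomainSpec:
    return registry.domain("intC/intN")


def trans_splice(
    a: ProteinSpec,
    b: ProteinSpec,
    registry: Optional[PartRegistry] = None,
) -> Tuple[ProteinSpec, ProteinSpec]:
    """Trans-splice two proteins carrying complementary intein halves.

    Returns ``(product, byproduct)``:

    * product  -- N-extein of the intN donor ligated to the C-extein of the
      intC donor (the covalent splice product);
    * byproduct -- the remaining exteins joined through the excised intein
      pair, modelled as a single stable species whose domains keep their
      functions (e.g. the VP64-ZF1-intC/intN activator).

    The multiset of non-intein domains is conserved across the two outputs.
    """
    registry = registry or default_registry()
    a_n, b_n = a.has("intein-N"), b.has("intein-N")
    a_c, b_c = a.has("intein-C"), b.has("intein-C")
    if (a_n and b_n) or (a_c and b_c):
        raise SpliceError(
            f"{a.name} and {b.name} carry the same intein half and cannot splice"
        )
    if a_n and b_c:
        ndonor, cdonor = a, b
    elif b_n and a_c:
        ndonor, cdonor = b, a
    else:
        raise SpliceError(
            f"{a.name} + {b.name}: need one free intN and one free intC"
        )
    i_n = ndonor.index_of("intein-N")
    i_c = cdonor.index_of("intein-C")
    n_extein, n_rest = ndonor.domains[:i_n], ndonor.domains[i_n + 1 :]
    c_rest, c_extein = cdonor.domains[:i_c], cdonor.domains[i_c + 1 :]
    product_domains = n_extein + c_extein
    byproduct_domains = c_rest + (_spent_intein(registry),) + n_rest
    if not product_domains:
        raise SpliceError(
            f"{a.name} + {b.name}: splice product would carry no domains"
        )
    stab = max(a.stability_multiplier, b.stability_multiplier)
    return (
        ProteinSpec(domains=product_domains, stability_multiplier=1.0),
        ProteinSpec(domains=byproduct_domains, stability_multiplier=stab),
    )


# ---------------------------------------------------------------------------
# ligand-induced dimerization


def dimerize(
    a: ProteinSpec,
    b: ProteinSpec,
    ligand: str,
    registry: Optional[PartRegistry] = None,
) -> Optional[ComplexSpec]:
    """Assemble a heterodimer if ``a`` and ``b`` carry the two halves bridged
    by ``ligand``.  Returns ``None`` (no complex) for non-cognate halves or an
    unregistered/absent ligand -- that is an expected outcome, not an error.
    """
    registry = registry or default_registry()
    if ligand not in registry.ligands:
        return None
    pair = registry.ligand_pair(ligand)
    for da in a.dimerizer_halves():
        for db in b.dimerizer_halves():
            if {da.name, db.name} == set(pair) and da.ligand_partner == db.name:
                return ComplexSpec(chains=(a, b), ligand=ligand)
    return None
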