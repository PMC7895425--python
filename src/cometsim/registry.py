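"""Closed part registry: protein domains, dimerizer ligands, promoters.

The registry is loaded once from the packaged YAML files and treated as
immutable.  Extending the part set is a configuration change (point
``load_registry`` at another file), never a code change.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import yaml

__all__ = [
    "DomainSpec",
    "PartRegistry",
    "load_registry",
    "default_registry",
    "default_params",
]

CATEGORIES = frozenset(
    {
        "activation-domain",
        "dna-binding",
        "intein-N",
        "intein-C",
        "spent-intein",
        "fluorophore-inhibitory",
        "dimerizer-half",
        "degron",
        "reporter",
    }
)


@dataclass(frozen=True)
class DomainSpec:
    """A single protein domain from the closed registry.

    ``ligand_partner`` is set only for dimerizer halves and names the
    complementary half (FRB <-> FKBP, PYL1 <-> ABI1).
    """

    name: str
    category: str
    ligand_partner: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown domain category {self.category!r}")
        if (self.category == "dimerizer-half") != (self.ligand_partner is not None):
            raise ValueError(
                f"domain {self.name!r}: dimerizer halves (and only they) "
                "must declare a ligand partner"
            )


@dataclass(frozen=True)
class PartRegistry:
    """Immutable lookup tables for domains, ligands and constitutive promoters."""

    domains: Mapping[str, DomainSpec]
    ligands: Mapping[str, frozenset]  # ligand -> pair of dimerizer-half names
    constitutive_promoters: Mapping[str, float]
    version: int = 1
    # Domain names sorted longest-first, for longest-match tokenization of
    # hyphenated names such as "DsRed-Express2".
    _by_length: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "_by_length",
            tuple(sorted(self.domains, key=len, reverse=True)),
        )

    def domain(self, name: str) -> DomainSpec:
        try:
            return self.domains[name]
        except KeyError:
            raise KeyError(f"unknown domain {name!r}") from None

    def ligand_pair(self, ligand: str) -> frozenset:
        try:
            return self.ligands[ligand]
        except KeyError:
            raise KeyError(f"unknown ligand {ligand!r}") from None


def _load_yaml(path_or_name):
    if hasattr(path_or_name, "read"):
        return yaml.safe_load(path_or_name)
    return yaml.safe_load(open(path_or_name))


def load_registry(source=None) -> PartRegistry:
    """Build a :class:`PartRegistry` from a YAML file (default: packaged)."""
    if source is None:
        with resources.files("cometsim.data").joinpath("parts.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = _load_yaml(source)
    domains = {
        name: DomainSpec(
            name=name,
            category=entry["category"],
            ligand_partner=entry.get("ligand_partner"),
        )
        for name, entry in raw["domains"].items()
    }
    ligands = {
        name: frozenset(pair) for name, pair in raw.get("ligands", {}).items()
    }
    return PartRegistry(
        domains=domains,
        ligands=ligands,
        constitutive_promoters=dict(raw.get("constitutive_promoters", {})),
        version=int(raw.get("version", 1)),
    )


@functools.lru_cache(maxsize=1)
def default_registry() -> PartRegistry:
    return load_registry()


@functools.lru_cache(maxsize=1)
def _default_params_raw() -> dict:
    with resources.files("cometsim.data").joinpath("params.yaml").open() as fh:
        return yaml.safe_load(fh)


def default_params() -> dict:
    """Deep-ish copy of the shipped default parameter document."""
    import copy

    return copy.deepcopy(_default_params_raw())
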