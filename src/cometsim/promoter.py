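"""Instantaneous transcriptional activity of COMET promoters.

Mechanistic picture
-------------------
Every DNA-binding species (activator, competitive inhibitor or mixed
DsRed/DsDed-ZF inhibitor) competes for the promoter's binding sites.
Binding to individual sites is noncooperative, so the fractional occupancy
of species *j* in a site pool follows the independent-site competition law

    theta_j = w_j / (1 + sum_k w_k),      w_j = beta_j * C_j / K_zf

where ``beta_j`` is 1 for activators and the promoter's
``inhibitor_affinity_fold`` for inhibitors: proteins that carry a ZF but no
bulky transactivation machinery engage their sites more avidly, which is
what makes COMET inhibitors potent at doses comparable to the activator.

Cooperativity lives downstream of binding, in transcription initiation:
the maximal rate scales supralinearly with the size of the contiguous
activator-occupied site ensemble (exponent ``gamma``), which keeps the dose
response in any single activator hyperbolic (Hill-1) while making compact
multisite promoters strongly inducible.  Mixed inhibitors physically break
that ensemble: their occupancy ``theta_D`` (evaluated over the
activator+mixed ensemble) both removes sites from it and pulls the
effective exponent toward 1,

    S_eff     = S * (1 - theta_D)
    gamma_eff = 1 + (gamma - 1) * (1 - theta_D)
    rate      = b_p + m_1 * S_eff ** gamma_eff * theta_A

Because activators displace mixed inhibitors from the ensemble, raising the
activator dose simultaneously increases theta_A and relieves the
cooperativity disruption -- the origin of inhibitor-thresholded
ultrasensitivity.  Plain competitive inhibitors act only through theta_A
(they lower it and never raise the rate).

For the alternating-dual layout the two ZF classes occupy disjoint
three-site pools whose contributions combine through a shared cooperative
ensemble: each pool contributes its own ``S_pool_eff ** gamma_eff`` term and
joint occupancy of both pools unlocks the full compact array,

    rate = b_p + m_1 * [ S1e**g * thA1 + S2e**g * thA2
                         + ((S1e+S2e)**g - S1e**g - S2e**g) * thA1 * thA2 ]

which is linear (Hill-1) in each activator separately but synergistic in
the pair -- the basis of the hybrid-promoter AND gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np

from .parts import PromoterSpec

__all__ = [
    "PromoterParams",
    "TFEntry",
    "site_occupancy",
    "transcription_rate",
    "constitutive_rate",
]

_INHIBITOR_ROLES = ("competitive-inhibitor", "mixed-inhibitor")


@dataclass(frozen=True)
class PromoterParams:
    """Parameters of the promoter transfer function (all positive).

    ``gamma = 1`` reproduces an additive, noncooperative-initiation
    promoter.  ``K`` maps ZF name -> binding constant; a ZF not listed falls
    back to ``K_default``.  ``inhibitor_affinity_fold`` multiplies the site
    weight of both inhibitor classes.
    """

    background_rate: float = 0.1
    unit_amplitude: float = 1.0
    cooperativity: float = 2.5
    K_default: float = 2.0e4
    K: Mapping[str, float] = field(default_factory=dict)
    inhibitor_affinity_fold: float = 10.0

    def __post_init__(self) -> None:
        if min(self.background_rate, self.unit_amplitude, self.K_default) <= 0:
            raise ValueError("promoter parameters must be positive")
        if self.cooperativity < 1:
            raise ValueError("cooperativity exponent must be >= 1")
        if self.inhibitor_affinity_fold <= 0:
            raise ValueError("inhibitor_affinity_fold must be positive")

    def k_for(self, zf: str) -> float:
        return float(self.K.get(zf, self.K_default))

    def weight(self, zf: str, role: str, concentration: float) -> float:
        """Statistical site weight of one bound species."""
        beta = self.inhibitor_affinity_fold if role in _INHIBITOR_ROLES else 1.0
        return beta * concentration / self.k_for(zf)


@dataclass(frozen=True)
class TFEntry:
    """One DNA-binding species at a promoter: identity, ZF, role, concentration."""

    species: str
    zf: str
    role: str  # activator | competitive-inhibitor | mixed-inhibitor
    concentration: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(
                f"negative concentration for {self.species}: {self.concentration}"
            )
        if self.role not in ("activator",) + _INHIBITOR_ROLES:
            raise ValueError(f"{self.species}: {self.role!r} is not a DNA-binding role")


def site_occupancy(
    prom: PromoterSpec,
    tfs: Iterable[TFEntry],
    params: PromoterParams,
) -> Dict[str, float]:
    """Per-species fractional site occupancy under competitive binding.

    Returns ``{species: theta}`` where ``theta`` is the fraction of the
    species' site pool it occupies.  Occupancies within a pool sum to <= 1;
    expected occupied sites per ZF therefore never exceed the promoter's
    per-ZF capacity.  Species whose ZF is not cognate contribute (and
    receive) zero.
    """
    tfs = list(tfs)
    if prom.is_constitutive:
        return {t.species: 0.0 for t in tfs}
    out: Dict[str, float] = {t.species: 0.0 for t in tfs}
    for _sites, pool_zfs in prom.pools():
        entries = [t for t in tfs if t.zf in pool_zfs]
        if not entries:
            continue
        w = np.array([params.weight(t.zf, t.role, t.concentration) for t in entries])
        denom = 1.0 + w.sum()
        for t, wi in zip(entries, w):
            out[t.species] += wi / denom
    return out


def _pool_state(pool_zfs, tfs, params) -> Tuple[float, float]:
    """(theta_A, theta_D) for one pool.

    theta_A is the activator occupancy under full competition; theta_D is
    the mixed-inhibitor occupancy of the activator+mixed initiation
    ensemble (plain competitive species excluded, so they can never relieve
    the cooperativity disruption).
    """
    w_act = w_mix = w_comp = 0.0
    for t in tfs:
        if t.zf not in pool_zfs:
            continue
        w = params.weight(t.zf, t.role, t.concentration)
        if t.role == "activator":
            w_act += w
        elif t.role == "mixed-inhibitor":
            w_mix += w
        else:
            w_comp += w
    theta_a = w_act / (1.0 + w_act + w_mix + w_comp)
    theta_d = w_mix / (1.0 + w_act + w_mix)
    return theta_a, theta_d


def transcription_rate(
    prom: PromoterSpec,
    tfs: Iterable[TFEntry],
    params: PromoterParams,
) -> float:
    """Instantaneous transcription rate (rate units per gene copy).

    Contracts: background rate with no TFs; nondecreasing and saturating in
    activator dose, hyperbolic (Hill-1) when no inhibitors are present;
    nonincreasing in both inhibitor classes; at matched dose the mixed
    inhibitor suppresses at least as strongly as the competitive one.
    """
    if prom.is_constitutive:
        raise ValueError(f"{prom.name} is constitutive; use constitutive_rate()")
    tfs = list(tfs)
    for t in tfs:
        if t.concentration < 0:
            raise ValueError(f"negative concentration for {t.species}")
    pools = prom.pools()
    g = params.cooperativity
    states = [_pool_state(pool_zfs, tfs, params) for _s, pool_zfs in pools]
    sites = np.array([s for s, _ in pools], dtype=float)
    theta_d_bar = float(
        np.dot(sites, [d for _a, d in states]) / sites.sum()
    )
    g_eff = 1.0 + (g - 1.0) * (1.0 - theta_d_bar)
    s_eff = [s * (1.0 - d) for (s, _), (_a, d) in zip(pools, states)]
    if len(pools) == 1:
        ensemble = s_eff[0] ** g_eff * states[0][0]
    else:
        s_tot = sum(s_eff)
        per_pool = sum(se**g_eff * a for se, (a, _d) in zip(s_eff, states))
        cross = s_tot**g_eff - sum(se**g_eff for se in s_eff)
        joint = float(np.prod([a for a, _d in states]))
        ensemble = per_pool + max(cross, 0.0) * joint
    return params.background_rate + params.unit_amplitude * float(ensemble)


def constitutive_rate(
    prom: PromoterSpec,
    registry_rates: Mapping[str, float],
) -> float:
    """Fixed activity of a constitutive promoter (TF-independent)."""
    if not prom.is_constitutive:
        raise ValueError(f"{prom.name} is not a constitutive promoter")
    return float(registry_rates[prom.name])
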