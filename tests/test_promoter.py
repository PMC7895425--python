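"""Promoter transfer function: competitive occupancy against a brute-force
partition-function oracle, and the behavioral contracts of the rate law."""

import itertools

import numpy as np
import pytest

from cometsim.metrics import fit_hill
from cometsim.parts import parse_promoter_name
from cometsim.promoter import (
    PromoterParams,
    TFEntry,
    constitutive_rate,
    site_occupancy,
    transcription_rate,
)
from cometsim.registry import default_registry

# ---------------------------------------------------------------------------
# independent oracle: enumerate every bound/unbound configuration of the
# promoter's sites, weight it by the product of statistical weights, and
# average per-species site counts over the partition function.


def enumeration_occupancy(prom, tfs, params):
    out = {t.species: 0.0 for t in tfs}
    for pool_sites, pool_zfs in prom.pools():
        entries = [t for t in tfs if t.zf in pool_zfs]
        options = [None] + entries  # per-site: empty or bound by one species
        z = 0.0
        counts = {t.species: 0.0 for t in entries}
        for config in itertools.product(options, repeat=pool_sites):
            w = 1.0
            for occ in config:
                if occ is not None:
                    w *= params.weight(occ.zf, occ.role, occ.concentration)
            z += w
            for occ in config:
                if occ is not None:
                    counts[occ.species] += w
        for t in entries:
            out[t.species] += counts[t.species] / (z * pool_sites)
    return out


def _act(name, zf, c):
    return TFEntry(species=name, zf=zf, role="activator", concentration=c)


def _inh(name, zf, c, mixed=False):
    role = "mixed-inhibitor" if mixed else "competitive-inhibitor"
    return TFEntry(species=name, zf=zf, role=role, concentration=c)


PARAMS = PromoterParams()
SHIPPED_PROMOTERS = ["ZF1x6-C", "ZF1x3-C", "ZF2x6-C", "ZF1/2x6-C", "(ZF2/ZF6)x3"]


def _tfs_for(prom):
    """A mixed cast of cognate and non-cognate species at awkward doses."""
    zfs = list(prom.cognate_zfs) or ["ZF1"]
    z0 = zfs[0]
    z1 = zfs[-1]
    return [
        _act("A0", z0, 1.7e4),
        _inh("I0", z0, 0.8e4),
        _inh("D1", z1, 2.3e4, mixed=True),
        _act("A1", z1, 0.4e4),
        _act("X", "ZF9", 9.9e4),  # non-cognate: must stay at zero
    ]


@pytest.mark.parametrize("prom_name", SHIPPED_PROMOTERS)
def test_occupancy_matches_partition_function_enumeration(prom_name):
    prom = parse_promoter_name(prom_name)
    tfs = _tfs_for(prom)
    closed = site_occupancy(prom, tfs, PARAMS)
    brute = enumeration_occupancy(prom, tfs, PARAMS)
    for sp in closed:
        assert closed[sp] == pytest.approx(brute[sp], rel=1e-9, abs=1e-15)
    assert closed["X"] == 0.0


@pytest.mark.parametrize("prom_name", SHIPPED_PROMOTERS)
def test_occupancy_normalization_and_capacity(prom_name):
    prom = parse_promoter_name(prom_name)
    tfs = _tfs_for(prom)
    occ = site_occupancy(prom, tfs, PARAMS)
    # occupancies are per-pool fractions; expected occupied sites per ZF
    # cannot exceed the promoter's per-ZF capacity
    for zf, cap in prom.per_zf_capacity.items():
        pools = [s for s, zs in prom.pools() if zf in zs]
        per_zf_sites = sum(
            occ[t.species] * pools[0] for t in tfs if t.zf == zf
        )
        assert per_zf_sites <= cap + 1e-12
    assert sum(occ.values()) <= len(prom.pools()) + 1e-12


def test_half_saturation_single_species():
    prom = parse_promoter_name("ZF1x6-C")
    occ = site_occupancy(prom, [_act("A", "ZF1", PARAMS.K_default)], PARAMS)
    assert occ["A"] == pytest.approx(0.5)


def test_equal_binding_constants_three_way_split():
    # one activator and one competitive inhibitor, both at C = K with equal
    # effective binding constants -> the activator holds 1/3 of the sites
    prom = parse_promoter_name("ZF1x6-C")
    equal = PromoterParams(inhibitor_affinity_fold=1.0)
    occ = site_occupancy(
        prom,
        [_act("A", "ZF1", equal.K_default), _inh("I", "ZF1", equal.K_default)],
        equal,
    )
    assert occ["A"] == pytest.approx(1.0 / 3.0)


def test_negative_concentration_rejected():
    with pytest.raises(ValueError, match="negative"):
        _act("A", "ZF1", -1.0)


# ---------------------------------------------------------------------------
# transcription rate contracts


def test_background_with_no_tfs():
    prom = parse_promoter_name("ZF1x6-C")
    assert transcription_rate(prom, [], PARAMS) == pytest.approx(
        PARAMS.background_rate
    )


def test_saturation_limit_no_inhibitors():
    prom = parse_promoter_name("ZF1x6-C")
    rate = transcription_rate(prom, [_act("A", "ZF1", 1e12)], PARAMS)
    expected = PARAMS.background_rate + PARAMS.unit_amplitude * 6**PARAMS.cooperativity
    assert rate == pytest.approx(expected, rel=1e-6)


@pytest.mark.parametrize("prom_name", SHIPPED_PROMOTERS)
def test_rate_matches_enumeration_expectation_midrange(prom_name):
    # with no mixed inhibitors the rate law is linear in activator occupancy,
    # so the closed form must equal the expectation of the same
    # statistical-weight model over all binding configurations
    prom = parse_promoter_name(prom_name)
    zfs = list(prom.cognate_zfs)
    tfs = [_act("A", zfs[0], 1.3e4), _inh("I", zfs[-1], 0.9e4)]
    closed = transcription_rate(prom, tfs, PARAMS)
    occ = enumeration_occupancy(prom, tfs, PARAMS)
    g = PARAMS.cooperativity
    if len(prom.pools()) == 1:
        s = prom.sites
        expected = PARAMS.background_rate + PARAMS.unit_amplitude * s**g * occ["A"]
    else:
        (s1, _), (s2, _) = prom.pools()
        th1 = occ["A"] if zfs[0] in prom.pools()[0][1] else 0.0
        th2 = 0.0  # the inhibitor contributes no activator occupancy
        expected = PARAMS.background_rate + PARAMS.unit_amplitude * (
            s1**g * th1 + s2**g * th2 + ((s1 + s2) ** g - s1**g - s2**g) * th1 * th2
        )
    assert closed == pytest.approx(expected, rel=1e-9)


def _random_params(rng):
    return PromoterParams(
        background_rate=10 ** rng.uniform(-2, 0),
        unit_amplitude=10 ** rng.uniform(-1, 1),
        cooperativity=rng.uniform(1.0, 3.5),
        K_default=10 ** rng.uniform(3, 5),
        inhibitor_affinity_fold=10 ** rng.uniform(0, 1.5),
    )


def test_hill_one_base_case_for_random_parameter_draws():
    # structural contract: TF binding is noncooperative, so the no-inhibitor
    # dose response is hyperbolic with Hill coefficient 1
    prom = parse_promoter_name("ZF1x6-C")
    rng = np.random.default_rng(7)
    for _ in range(20):
        p = _random_params(rng)
        doses = np.geomspace(p.K_default / 100, p.K_default * 100, 12)
        rates = [transcription_rate(prom, [_act("A", "ZF1", c)], p) for c in doses]
        fit = fit_hill(doses, rates)
        assert 0.95 <= fit.n <= 1.05


def test_monotonicity_in_activator_and_inhibitors():
    prom = parse_promoter_name("ZF1x6-C")
    rng = np.random.default_rng(11)
    for _ in range(20):
        p = _random_params(rng)
        k = p.K_default
        inh = [_inh("I", "ZF1", 0.5 * k), _inh("D", "ZF1", 0.7 * k, mixed=True)]
        rates = [
            transcription_rate(prom, [_act("A", "ZF1", c)] + inh, p)
            for c in np.geomspace(k / 30, k * 30, 9)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(rates, rates[1:]))
        # nonincreasing in either inhibitor class at fixed activator
        for mixed in (False, True):
            rates_i = [
                transcription_rate(
                    prom, [_act("A", "ZF1", k), _inh("I", "ZF1", c, mixed=mixed)], p
                )
                for c in np.geomspace(k / 30, k * 30, 9)
            ]
            assert all(b <= a + 1e-12 for a, b in zip(rates_i, rates_i[1:]))


def test_mixed_inhibitor_at_least_as_suppressive_as_competitive():
    prom = parse_promoter_name("ZF1x6-C")
    rng = np.random.default_rng(13)
    for _ in range(20):
        p = _random_params(rng)
        k = p.K_default
        for ci in (0.1 * k, k, 10 * k):
            act = _act("A", "ZF1", 2 * k)
            r_comp = transcription_rate(prom, [act, _inh("I", "ZF1", ci)], p)
            r_mix = transcription_rate(
                prom, [act, _inh("D", "ZF1", ci, mixed=True)], p
            )
            assert r_mix <= r_comp + 1e-12


def test_gamma_one_is_additive_noncooperative():
    prom = parse_promoter_name("ZF1x6-C")
    p = PromoterParams(cooperativity=1.0)
    rate = transcription_rate(prom, [_act("A", "ZF1", 1e12)], p)
    assert rate == pytest.approx(p.background_rate + p.unit_amplitude * 6.0, rel=1e-6)


# ---------------------------------------------------------------------------
# constitutive promoters


def test_constitutive_rates_and_tf_independence():
    reg = default_registry()
    cmv = parse_promoter_name("CMV")
    assert constitutive_rate(cmv, reg.constitutive_promoters) == pytest.approx(
        reg.constitutive_promoters["CMV"]
    )
    ef1a = parse_promoter_name("EF1a")
    assert constitutive_rate(ef1a, reg.constitutive_promoters) == pytest.approx(
        reg.constitutive_promoters["EF1a"]
    )
    with pytest.raises(ValueError):
        constitutive_rate(parse_promoter_name("ZF1x6-C"), reg.constitutive_promoters)
    with pytest.raises(ValueError):
        transcription_rate(cmv, [], PARAMS)
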