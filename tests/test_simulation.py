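"""Simulation engine: single-cell integration against closed forms,
population sampling, dose series and landscapes."""

import numpy as np
import pytest

from cometsim.circuit import Circuit, ParamSet, TranscriptionUnit, compile_circuit
from cometsim.library import build_circuit, get_entry
from cometsim.simulate import (
    PopulationSettings,
    SimulationSettings,
    dose_response,
    integrate_cell,
    landscape,
    simulate_population,
)


def TU(promoter, protein, dose, label=""):
    return TranscriptionUnit(promoter=promoter, protein=protein, dose=dose, label=label)


# ---------------------------------------------------------------------------
# single-cell integration vs the linear-chain closed form


def _linear_chain_protein(t, tx_rate, k_tl, dm, dp):
    """Analytic solution of m' = a - dm*m, p' = k_tl*m - dp*p, m(0)=p(0)=0."""
    a = tx_rate
    return (k_tl * a / dm) * (
        (1 - np.exp(-dp * t)) / dp - (np.exp(-dm * t) - np.exp(-dp * t)) / (dp - dm)
    )


def test_constitutive_endpoint_matches_transient_closed_form(
    constitutive_circuit, params
):
    net = compile_circuit(constitutive_circuit, params)
    settings = SimulationSettings()
    state = integrate_cell(net, settings)
    kin = params.kinetics
    tx = kin.k_tx * net.dose_map["mKate2"] * params.constitutive_rate("CMV")
    expected = _linear_chain_protein(
        settings.t_end, tx, kin.k_tl, kin.delta_m, kin.delta_p
    )
    assert state["mKate2"] == pytest.approx(expected, rel=1e-3)


def test_constitutive_steady_state_matches_analytic_fixed_point(
    constitutive_circuit, params
):
    net = compile_circuit(constitutive_circuit, params)
    state = integrate_cell(net, SimulationSettings(steady_state=True))
    kin = params.kinetics
    tx = kin.k_tx * net.dose_map["mKate2"] * params.constitutive_rate("CMV")
    p_star = tx * kin.k_tl / (kin.delta_m * kin.delta_p)
    assert state["mKate2"] == pytest.approx(p_star, rel=0.01)


def test_zero_dose_network_stays_at_zero(zfa_circuit):
    c = zfa_circuit.with_doses({"VP64-ZF1": 0.0, "mKate2": 0.0})
    state = integrate_cell(compile_circuit(c))
    assert all(v == 0.0 for v in state.values())


def test_splice_product_requires_both_partners():
    c = build_circuit("AND_fig1C").with_doses({"VP64-intN": 20.0, "intC-ZF1": 0.0})
    state = integrate_cell(compile_circuit(c))
    assert state["VP64-ZF1"] == 0.0
    assert state["VP64-intN"] > 0.0


def test_tightening_tolerances_changes_readout_marginally():
    net = compile_circuit(
        build_circuit("CASCADE_AND_fig1J").with_doses(
            {"DsDed-intN": 10.0, "intC-ZF10": 10.0}
        )
    )
    loose = integrate_cell(net, SimulationSettings(rtol=1e-6, atol=1e-3))
    tight = integrate_cell(net, SimulationSettings(rtol=1e-7, atol=1e-4))
    assert loose["mKate2"] == pytest.approx(tight["mKate2"], rel=1e-3)


def test_all_species_nonnegative_at_endpoint():
    net = compile_circuit(
        build_circuit("BANDPASS_SHARP_fig3G").with_doses({"FKBP-ZF1": 30.0})
    )
    assert all(v >= 0.0 for v in integrate_cell(net).values())


# ---------------------------------------------------------------------------
# population sampling


def test_degenerate_population_equals_single_cell(zfa_circuit, single_cell):
    c = zfa_circuit.with_doses({"VP64-ZF1": 5.0})
    res1 = simulate_population(c, pop=single_cell)
    res64 = simulate_population(
        c, pop=PopulationSettings(n_cells=64, uptake_sigma=0.0, seed=9)
    )
    assert res64.mean["mKate2"] == pytest.approx(res1.mean["mKate2"], rel=1e-12)


def test_same_seed_reproduces_per_cell_vectors_bit_identically(zfa_circuit):
    c = zfa_circuit.with_doses({"VP64-ZF1": 5.0})
    pop = PopulationSettings(n_cells=16, uptake_sigma=0.5, seed=42)
    a = simulate_population(c, pop=pop)
    b = simulate_population(c, pop=pop)
    assert np.array_equal(a.per_cell["mKate2"], b.per_cell["mKate2"])
    assert np.array_equal(a.uptake, b.uptake)


def test_lognormal_uptake_mean_identity(constitutive_circuit):
    # a linear circuit scales with uptake, so the ungated population mean over
    # log-normal(median 1, sigma) uptake approaches e^{sigma^2/2}
    sigma = 0.5
    pop = PopulationSettings(n_cells=3000, uptake_sigma=sigma, seed=3)
    res = simulate_population(constitutive_circuit, pop=pop)
    single = simulate_population(
        constitutive_circuit, pop=PopulationSettings(n_cells=1, uptake_sigma=0.0)
    )
    ratio = res.mean["mKate2"] / single.mean["mKate2"]
    assert ratio == pytest.approx(np.exp(sigma**2 / 2), rel=0.03)


def test_positive_gate_threshold_flags_empty_population(constitutive_circuit):
    pop = PopulationSettings(
        n_cells=8, uptake_sigma=0.1, positive_gate_threshold=1e9, seed=0
    )
    res = simulate_population(constitutive_circuit, pop=pop)
    assert res.empty and np.isnan(res.mean["mKate2"])


def test_population_mean_converges_with_cell_count(constitutive_circuit):
    # mean at n and at 4n agree within 2 SE(n) in >= 95% of repeated trials
    n = 24
    hits = 0
    trials = 20
    for t in range(trials):
        small = simulate_population(
            constitutive_circuit,
            pop=PopulationSettings(n_cells=n, uptake_sigma=0.5, seed=100 + t),
        )
        big = simulate_population(
            constitutive_circuit,
            pop=PopulationSettings(n_cells=4 * n, uptake_sigma=0.5, seed=500 + t),
        )
        vals = small.per_cell["mKate2"]
        se = vals.std(ddof=1) / np.sqrt(n)
        hits += abs(big.mean["mKate2"] - small.mean["mKate2"]) < 2 * se
    assert hits >= int(0.95 * trials) - 1


# ---------------------------------------------------------------------------
# dose series and landscapes


def test_zfa_dose_series_is_monotone(zfa_circuit, single_cell):
    dr = dose_response(
        zfa_circuit, "VP64-ZF1", [0, 0.5, 2, 8, 32], pop=single_cell
    )
    assert np.all(np.diff(dr.outputs) > 0)


def test_bandpass_dose_series_rises_then_falls(single_cell):
    e = get_entry("BANDPASS_BASE_fig3F")
    dr = dose_response(e.circuit, "FKBP-ZF1", np.asarray(e.hill_grid), pop=single_cell)
    k = int(np.argmax(dr.outputs))
    assert 0 < k < dr.doses.size - 1
    assert dr.outputs[-1] < 0.5 * dr.outputs[k]


def test_empty_dose_vector_rejected(zfa_circuit, single_cell):
    with pytest.raises(ValueError, match="empty"):
        dose_response(zfa_circuit, "VP64-ZF1", [], pop=single_cell)
    with pytest.raises(KeyError):
        dose_response(zfa_circuit, "nonexistent", [0, 1], pop=single_cell)


def test_and_landscape_zero_rows_stay_at_background(single_cell):
    c = build_circuit("AND_fig1C")
    maps = landscape(
        c, "VP64-intN", "intC-ZF1", [0, 10, 30], [0, 10, 30], pop=single_cell
    )
    v = maps["mKate2"].values
    background = v[0, 0]
    assert np.all(v[0, :] <= 1.05 * background)
    assert np.all(v[:, 0] <= 1.05 * background)
    assert v[-1, -1] > 50 * background


def test_max_scaling_is_a_single_positive_scalar(single_cell):
    c = build_circuit("AND_fig1C")
    kw = dict(pop=single_cell)
    raw = landscape(c, "VP64-intN", "intC-ZF1", [0, 10], [0, 10], **kw)["mKate2"]
    scaled = landscape(
        c, "VP64-intN", "intC-ZF1", [0, 10], [0, 10], scaling="max", **kw
    )["mKate2"]
    assert scaled.values.max() == pytest.approx(1.0)
    np.testing.assert_allclose(
        raw.values / raw.values.max(), scaled.values, rtol=1e-12
    )


def test_landscape_rejects_overlapping_inputs(zfa_circuit, single_cell):
    with pytest.raises(ValueError, match="distinct"):
        landscape(zfa_circuit, "VP64-ZF1", "VP64-ZF1", [0, 1], [0, 1], pop=single_cell)


def test_mimo_landscape_returns_one_map_per_reporter(single_cell):
    c = build_circuit("IFAND_fig2D")
    maps = landscape(
        c, "VP64-ZF1-intN", "intC-ZF10", [0, 30], [0, 30], pop=single_cell
    )
    assert set(maps) == {"mKate2", "EYFP"}


# ---------------------------------------------------------------------------
# multilayer feasibility


def test_two_layer_zfa_series_retains_fold_induction(single_cell):
    """A ZFa relay keeps at least half the single-layer fold induction in
    the sub-saturating input regime (steady-state structural property)."""
    settings = SimulationSettings(steady_state=True)
    one = Circuit(
        units=(TU("CMV", "VP64-ZF1", 0.0), TU("ZF1x6-C", "mKate2", 50.0)),
        reporters=("mKate2",),
    )
    two = Circuit(
        units=(
            TU("CMV", "VP64-ZF10", 0.0),
            TU("ZF10x6-C", "VP64-ZF1", 10.0, label="mid"),
            TU("ZF1x6-C", "mKate2", 50.0),
        ),
        reporters=("mKate2",),
    )
    doses = [0.0, 0.5]
    f1 = dose_response(one, "VP64-ZF1", doses, settings, single_cell)
    f2 = dose_response(two, "VP64-ZF10", doses, settings, single_cell)
    fold1 = f1.outputs[1] / f1.outputs[0]
    fold2 = f2.outputs[1] / f2.outputs[0]
    assert fold2 >= 0.5 * fold1
    assert fold1 > 20  # the single layer itself is strongly inducible
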