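"""Estimation of kinetic and promoter parameters from dose-response data.

``fit_parameters`` wraps seeded multi-start nonlinear least squares around
the full simulation pipeline: free parameters (e.g. the splicing rate
``k_spl`` or the promoter amplitude ``unit_amplitude``) are optimized in
log10 space so that simulated outcomes match observed dose series or
landscapes, by default after per-set max-scaling (the heatmap convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import lmfit
import numpy as np

from .circuit import Circuit, ParamSet
from .simulate import (
    DoseResponse,
    Landscape,
    PopulationSettings,
    SimulationSettings,
    dose_response,
    landscape,
)

__all__ = ["FitReport", "fit_parameters", "apply_free_params"]

_KINETIC_NAMES = (
    "k_tx", "k_tl", "delta_m", "delta_p", "rho_pest",
    "k_spl", "k_on", "k_off", "sensor_release_rate",
)
_PROMOTER_NAMES = ("background_rate", "unit_amplitude", "cooperativity", "K")


@dataclass
class FitReport:
    values: Dict[str, float]
    stderr_log10: Dict[str, Optional[float]]
    ci95: Dict[str, Tuple[float, float]]  # multiplicative 95% interval
    chisqr: float
    start_losses: List[float]
    selected_start: int
    unidentifiable: List[str] = field(default_factory=list)
    converged: bool = True


def _current_value(params: ParamSet, name: str) -> float:
    if name in _KINETIC_NAMES:
        return getattr(params.kinetics, name)
    if name in _PROMOTER_NAMES:
        key = "K" if name == "K" else name
        pp = params.promoter_params("__default__")
        return {
            "background_rate": pp.background_rate,
            "unit_amplitude": pp.unit_amplitude,
            "cooperativity": pp.cooperativity,
            "K": pp.K_default,
        }[name]
    raise KeyError(
        f"unknown free parameter {name!r}; choose from "
        f"{_KINETIC_NAMES + _PROMOTER_NAMES}"
    )


def apply_free_params(base: ParamSet, values: Mapping[str, float]) -> ParamSet:
    """New :class:`ParamSet` with the named parameters replaced."""
    import copy

    out = copy.copy(base)
    kin = {k: v for k, v in values.items() if k in _KINETIC_NAMES}
    if kin:
        out.kinetics = base.kinetics.replace(**kin)
    prom = {k: v for k, v in values.items() if k in _PROMOTER_NAMES}
    if prom:
        out._prom_defaults = dict(base._prom_defaults)
        for k, v in prom.items():
            out._prom_defaults[k] = v
    return out


def _simulate_like(
    circuit: Circuit,
    observed,
    params: ParamSet,
    settings: SimulationSettings,
    pop: PopulationSettings,
):
    """Re-simulate the design of an observed DoseResponse or Landscape."""
    if isinstance(observed, DoseResponse):
        dr = dose_response(
            circuit,
            observed.input_unit.split("+"),
            observed.doses,
            settings,
            pop,
            params,
            readout=observed.readout,
        )
        return dr.outputs
    if isinstance(observed, Landscape):
        la, lb = observed.input_units
        ls = landscape(
            circuit,
            la.split("+"),
            lb.split("+"),
            observed.grid_a,
            observed.grid_b,
            settings,
            pop,
            params,
        )[observed.readout]
        return ls.values.ravel()
    raise TypeError(f"unsupported observed data type {type(observed)!r}")


def _observed_values(observed) -> np.ndarray:
    if isinstance(observed, DoseResponse):
        return np.asarray(observed.outputs, dtype=float)
    return np.asarray(observed.values, dtype=float).ravel()


def fit_parameters(
    free_param_names: Sequence[str],
    datasets: Sequence[Tuple[Circuit, Union[DoseResponse, Landscape]]],
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    seed: int = 0,
    base_params: Optional[ParamSet] = None,
    settings: SimulationSettings = SimulationSettings(),
    pop: PopulationSettings = PopulationSettings(n_cells=1, uptake_sigma=0.0),
    sigma: Optional[Mapping[int, np.ndarray]] = None,
    scaling: str = "max",
    n_starts: int = 3,
) -> Tuple[ParamSet, FitReport]:
    """Seeded multi-start least squares over the named free parameters.

    ``bounds`` maps parameter name -> (lo, hi); defaults to a factor of 100
    around the current value.  ``sigma`` optionally maps dataset index ->
    per-point standard errors used to weight residuals.  Residuals are
    computed on per-set max-scaled values by default (``scaling="raw"``
    disables).  A parameter whose loss surface is flat across starts, or
    whose standard error is unavailable/huge, is flagged unidentifiable.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    base = base_params or ParamSet()
    free = list(free_param_names)
    current = {name: _current_value(base, name) for name in free}
    bounds = dict(bounds or {})
    for name in free:
        bounds.setdefault(name, (current[name] / 100.0, current[name] * 100.0))

    obs_sets = [_observed_values(obs) for _, obs in datasets]
    if scaling == "max":
        obs_scale = [o.max() if o.max() > 0 else 1.0 for o in obs_sets]
    else:
        obs_scale = [1.0 for _ in obs_sets]

    def residuals(p):
        vals = {name: 10.0 ** p[f"log10_{name}"].value for name in free}
        trial = apply_free_params(base, vals)
        out = []
        for i, (circuit, observed) in enumerate(datasets):
            sim = _simulate_like(circuit, observed, trial, settings, pop)
            s_scale = sim.max() if (scaling == "max" and sim.max() > 0) else 1.0
            r = sim / s_scale - obs_sets[i] / obs_scale[i]
            if sigma is not None and i in sigma:
                r = r / (np.asarray(sigma[i], dtype=float).ravel() / obs_scale[i])
            out.append(r)
        return np.concatenate(out)

    rng = np.random.default_rng(seed)
    starts = []
    for s in range(n_starts):
        if s == 0:
            start = {name: current[name] for name in free}
        else:
            start = {
                name: 10.0
                ** rng.uniform(np.log10(bounds[name][0]), np.log10(bounds[name][1]))
                for name in free
            }
        starts.append(start)

    results = []
    for start in starts:
        params = lmfit.Parameters()
        for name in free:
            lo, hi = bounds[name]
            params.add(
                f"log10_{name}",
                value=float(np.log10(start[name])),
                min=float(np.log10(lo)),
                max=float(np.log10(hi)),
            )
        # finite-difference steps must clear the ODE solver's discretization
        # jitter, or the covariance (hence the CIs) is garbage
        res = lmfit.minimize(
            residuals, params, method="least_squares", diff_step=1e-3
        )
        results.append(res)

    losses = [float(r.chisqr) for r in results]
    best_i = int(np.argmin(losses))
    best = results[best_i]

    values, se, ci = {}, {}, {}
    unident = []
    for name in free:
        p = best.params[f"log10_{name}"]
        values[name] = 10.0 ** p.value
        se[name] = p.stderr
        if p.stderr is None or not np.isfinite(p.stderr) or p.stderr > 1.0:
            unident.append(name)
            ci[name] = (bounds[name][0], bounds[name][1])
        else:
            ci[name] = (
                10.0 ** (p.value - 1.96 * p.stderr),
                10.0 ** (p.value + 1.96 * p.stderr),
            )
    # flat-loss unidentifiability: starts agree on loss but not on parameters
    if len(results) > 1:
        lo, hi = min(losses), max(losses)
        if hi <= lo * (1 + 1e-6) + 1e-12:
            for name in free:
                fitted = [10.0 ** r.params[f"log10_{name}"].value for r in results]
                if max(fitted) > 10 * min(fitted) and name not in unident:
                    unident.append(name)

    report = FitReport(
        values=values,
        stderr_log10=se,
        ci95=ci,
        chisqr=float(best.chisqr),
        start_losses=losses,
        selected_start=best_i,
        unidentifiable=unident,
        converged=bool(best.success),
    )
    return apply_free_params(base, values), report
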