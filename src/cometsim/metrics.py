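"""Quantitative metrics: modified Hill fitting, goodness of prediction (Q2),
fold difference, logic-gate corner fidelity, bandpass shape metrics and
circuit complexity counts.

The ultrasensitivity metric is the Hill coefficient ``n`` of the modified
Hill equation

    y = y0 + a * x^n / ((1/b)^n + x^n)

where ``x`` is input dose (ng of plasmid or gene copies), ``y`` the reporter
signal, ``y0`` the zero-input signal, ``a`` the amplitude and ``1/b`` the
half-maximal dose (EC50).  A response is called ultrasensitive iff n > 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import lmfit
import numpy as np

from .circuit import Circuit
from .simulate import DoseResponse, Landscape

__all__ = [
    "HillFit",
    "PredictionScore",
    "GateScore",
    "BandpassMetrics",
    "ComplexityReport",
    "fit_hill",
    "q_squared",
    "fold_difference",
    "gate_fidelity",
    "bandpass_metrics",
    "complexity_report",
]


# ---------------------------------------------------------------------------
# Hill fitting


@dataclass
class HillFit:
    y0: float
    a: float
    b: float  # inverse half-max dose; EC50 = 1/b
    n: float
    residual_norm: float
    converged: bool
    degenerate: bool = False
    stderr: Dict[str, Optional[float]] = field(default_factory=dict)

    @property
    def ec50(self) -> float:
        return 1.0 / self.b

    @property
    def ultrasensitive(self) -> bool:
        return self.n > 1.0

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return hill_curve(x, self.y0, self.a, self.b, self.n)


def hill_curve(x, y0, a, b, n):
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, float(y0))
    nz = x > 0
    xn = np.power(x[nz], n)
    out[nz] = y0 + a * xn / ((1.0 / b) ** n + xn)
    return out


def _hill_init(x, y):
    """Deterministic initialization: y0 = min, a = range, EC50 = dose at half
    range (log-interpolated on the nonzero doses), n = 1."""
    y0 = float(np.min(y))
    a = float(np.max(y) - np.min(y))
    half = y0 + 0.5 * a
    xs, ys = x[x > 0], y[x > 0]
    order = np.argsort(xs)
    xs, ys = xs[order], ys[order]
    above = np.nonzero(ys >= half)[0]
    if a > 0 and above.size and above[0] > 0:
        i = above[0]
        x1, x2 = xs[i - 1], xs[i]
        y1, y2 = ys[i - 1], ys[i]
        frac = (half - y1) / (y2 - y1) if y2 != y1 else 0.5
        ec50 = float(np.exp(np.log(x1) + frac * (np.log(x2) - np.log(x1))))
    else:
        ec50 = float(np.exp(np.mean(np.log(xs))))
    return y0, a, ec50


def fit_hill(
    doses: Sequence[float],
    responses: Sequence[float],
    n_bounds: Tuple[float, float] = (0.1, 10.0),
) -> HillFit:
    """Least-squares fit of the modified Hill equation.

    Deterministic given the data (fixed initialization policy, bounded
    n in ``n_bounds``).  Non-convergence or a constant response yields a
    flagged fit, not an exception.
    """
    x = np.asarray(list(doses), dtype=float)
    y = np.asarray(list(responses), dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 dose points")
    if np.unique(x[x > 0]).size < 3:
        raise ValueError("need at least 3 distinct nonzero doses")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    y0_init, a_init, ec50_init = _hill_init(x, y)
    if a_init <= 0:
        # constant response: n is unidentifiable
        return HillFit(
            y0=y0_init, a=0.0, b=1.0 / ec50_init, n=1.0,
            residual_norm=0.0, converged=True, degenerate=True,
        )
    yscale = float(np.max(np.abs(y))) or 1.0

    params = lmfit.Parameters()
    params.add("y0", value=y0_init, min=0.0)
    params.add("a", value=a_init, min=0.0)
    params.add("ec50", value=ec50_init, min=1e-12)
    params.add("n", value=1.0, min=n_bounds[0], max=n_bounds[1])

    def resid(p):
        return (
            hill_curve(x, p["y0"].value, p["a"].value, 1.0 / p["ec50"].value, p["n"].value)
            - y
        ) / yscale

    res = lmfit.minimize(resid, params, method="least_squares")
    p = res.params
    stderr = {k: (p[k].stderr if p[k].stderr is not None else None) for k in p}
    return HillFit(
        y0=float(p["y0"].value),
        a=float(p["a"].value),
        b=1.0 / float(p["ec50"].value),
        n=float(p["n"].value),
        residual_norm=float(np.linalg.norm(res.residual) * yscale),
        converged=bool(res.success),
        stderr=stderr,
    )


# ---------------------------------------------------------------------------
# Q^2


@dataclass(frozen=True)
class PredictionScore:
    q2: float
    n_points: int
    scaling: str  # none | max

    def __post_init__(self) -> None:
        if self.q2 > 1 + 1e-12:
            raise ValueError("Q^2 cannot exceed 1")


def _flat(v) -> np.ndarray:
    if isinstance(v, Landscape):
        v = v.values
    return np.asarray(v, dtype=float).ravel()


def q_squared(simulated, observed, scaling: str = "max") -> PredictionScore:
    """Goodness of prediction between paired simulated and observed sets.

    ``Q2 = 1 - sum((obs - sim)^2) / sum((obs - mean(obs))^2)`` after optional
    per-set max-scaling (the heatmap convention).  Q2 = 1 iff the prediction
    is exact; the mean predictor scores 0; worse-than-mean predictions are
    negative.
    """
    sim, obs = _flat(simulated), _flat(observed)
    if sim.shape != obs.shape:
        raise ValueError("simulated and observed sets must be paired")
    if sim.size < 2:
        raise ValueError("need at least 2 points")
    if np.allclose(obs, obs[0]):
        raise ValueError("observed set has zero variance")
    if scaling == "max":
        sim = sim / sim.max() if sim.max() > 0 else sim
        obs = obs / obs.max() if obs.max() > 0 else obs
    elif scaling != "none":
        raise ValueError("scaling must be 'max' or 'none'")
    ss_res = float(np.sum((obs - sim) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    return PredictionScore(q2=1.0 - ss_res / ss_tot, n_points=sim.size, scaling=scaling)


# ---------------------------------------------------------------------------
# fold difference


def fold_difference(on_signal: float, off_signal: float) -> float:
    """On/off ratio of background-subtracted signals; infinity whenever the
    denominator is <= 0 (the figure-legend convention)."""
    if off_signal <= 0:
        return math.inf
    return on_signal / off_signal


# ---------------------------------------------------------------------------
# gate fidelity


@dataclass
class GateScore:
    truth_table: Dict[Tuple[int, int], int]
    min_on: float
    max_off: float
    fidelity: float  # min_on / max_off, inf when max_off <= 0

    def passes(self, tau: float = 10.0) -> bool:
        return self.fidelity >= tau


def _parse_truth_table(tt) -> Dict[Tuple[int, int], int]:
    if isinstance(tt, str):
        if len(tt) != 4 or set(tt) - {"0", "1"}:
            raise ValueError("string truth table must be 4 binary digits "
                             "ordered (0,0),(0,1),(1,0),(1,1)")
        corners = [(0, 0), (0, 1), (1, 0), (1, 1)]
        return {c: int(ch) for c, ch in zip(corners, tt)}
    tt = dict(tt)
    if set(tt) != {(0, 0), (0, 1), (1, 0), (1, 1)}:
        raise ValueError("truth table must cover the four input corners")
    return {k: int(v) for k, v in tt.items()}


def gate_fidelity(landscape: Landscape, truth_table) -> GateScore:
    """Corner logic of a two-input landscape: minimum ON-corner output over
    maximum OFF-corner output.  Zero dose reads as logical 0 and the top
    dose as logical 1.  Invariant under max-scaling of the landscape.
    """
    tt = _parse_truth_table(truth_table)
    if not any(tt.values()) or all(tt.values()):
        raise ValueError("truth table needs at least one ON and one OFF corner")
    corners = landscape.corners()
    on = [corners[c] for c, v in tt.items() if v]
    off = [corners[c] for c, v in tt.items() if not v]
    min_on, max_off = min(on), max(off)
    fid = math.inf if max_off <= 0 else min_on / max_off
    return GateScore(truth_table=tt, min_on=min_on, max_off=max_off, fidelity=fid)


# ---------------------------------------------------------------------------
# bandpass metrics


@dataclass
class BandpassMetrics:
    peak_dose: float
    peak_value: float
    lower_threshold_dose: Optional[float]
    upper_threshold_dose: Optional[float]
    upper_slope_sharpness: Optional[float]  # max |d log y / d log x| above peak
    is_bandpass: bool


def _crossing(xs, ys, level, rising: bool) -> Optional[float]:
    """Dose at which the (log-x interpolated) response crosses ``level``."""
    for i in range(len(xs) - 1):
        y1, y2 = ys[i], ys[i + 1]
        if (rising and y1 < level <= y2) or (not rising and y1 >= level > y2):
            if xs[i] <= 0:
                return float(xs[i + 1])
            lx1, lx2 = np.log(xs[i]), np.log(xs[i + 1])
            frac = (level - y1) / (y2 - y1) if y2 != y1 else 0.5
            return float(np.exp(lx1 + frac * (lx2 - lx1)))
    return None


def bandpass_metrics(dr: DoseResponse) -> BandpassMetrics:
    """Peak position, half-peak threshold crossings and upper-edge sharpness.

    ``is_bandpass`` is true iff the peak is interior and both half-peak
    crossings exist.  A monotone response is simply not a bandpass (no
    error).  Sharpness is the maximum log-log downward slope above the peak.
    """
    if dr.doses.size < 7:
        raise ValueError("need at least 7 dose points spanning the peak")
    x, y = dr.doses, dr.outputs
    k = int(np.argmax(y))
    peak_dose, peak_value = float(x[k]), float(y[k])
    half = 0.5 * peak_value
    lower = _crossing(x[: k + 1], y[: k + 1], half, rising=True) if k > 0 else None
    upper = (
        _crossing(x[k:], y[k:], half, rising=False) if k < x.size - 1 else None
    )
    sharp = None
    if k < x.size - 1:
        xs, ys = x[k:], y[k:]
        good = (xs > 0) & (ys > 0)
        xs, ys = xs[good], ys[good]
        if xs.size >= 2:
            slopes = np.diff(np.log(ys)) / np.diff(np.log(xs))
            sharp = float(np.max(np.abs(slopes[slopes < 0]))) if np.any(slopes < 0) else 0.0
    interior = 0 < k < x.size - 1
    return BandpassMetrics(
        peak_dose=peak_dose,
        peak_value=peak_value,
        lower_threshold_dose=lower,
        upper_threshold_dose=upper,
        upper_slope_sharpness=sharp,
        is_bandpass=bool(interior and lower is not None and upper is not None),
    )


# ---------------------------------------------------------------------------
# complexity


@dataclass(frozen=True)
class ComplexityReport:
    n_genes: int
    n_regulatory_connections: int
    n_regulatory_proteins: int


def complexity_report(circuit: Circuit) -> ComplexityReport:
    """Genetic complexity counts: genes (all transcription units), regulatory
    connections (edges, including splice/dimer interactions), and distinct
    non-reporter protein species carrying a regulatory role (derived splice
    and dimer species included)."""
    from .circuit import compile_circuit

    net = compile_circuit(circuit)
    edges = net.edges
    regulatory = set()
    for s in net.species:
        if s.kind == "mrna":
            continue
        roles = set(s.roles)
        if s.name in circuit.reporters:
            continue
        if roles & {
            "activator",
            "competitive-inhibitor",
            "mixed-inhibitor",
            "splice-donor-N",
            "splice-donor-C",
            "dimerizer-half",
        }:
            regulatory.add(s.name)
    return ComplexityReport(
        n_genes=len(circuit.units) + len(circuit.sensors),
        n_regulatory_connections=len(edges),
        n_regulatory_proteins=len(regulatory),
    )
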