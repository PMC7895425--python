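"""Synthetic noisy dose-response datasets emulating calibrated flow-cytometry
readouts (reporter means in MEPTR-like arbitrary units).

The generator simulates the population-mean reporter signal for each
condition of a dose design, then draws biological replicates with
multiplicative log-normal noise plus an additive background floor --
the replicate structure of the experimental bar graphs (three biological
replicates per condition by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .circuit import Circuit, ParamSet
from .simulate import (
    DoseResponse,
    Landscape,
    PopulationSettings,
    SimulationSettings,
    dose_response,
    landscape,
)

__all__ = ["NoiseModel", "synthesize_dataset", "dataset_means"]


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-level noise: multiplicative log-normal CV across biological
    replicates plus a Gaussian additive background floor."""

    replicate_cv: float = 0.1
    background_level: float = 0.0
    background_sd: float = 0.0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.replicate_cv < 0 or self.background_sd < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _replicates(rng, mean: float, noise: NoiseModel) -> np.ndarray:
    if noise.replicate_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise.replicate_cv**2)))
        # mean-preserving multiplicative log-normal noise
        factors = np.exp(
            sigma * rng.standard_normal(noise.n_replicates) - 0.5 * sigma**2
        )
    else:
        factors = np.ones(noise.n_replicates)
    out = mean * factors + noise.background_level
    if noise.background_sd > 0:
        out = out + noise.background_sd * rng.standard_normal(noise.n_replicates)
    return np.maximum(out, 0.0)


def synthesize_dataset(
    circuit: Circuit,
    design: Union[DoseResponse, Landscape, None] = None,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    varied: Union[str, Sequence[str], Tuple] = None,
    doses=None,
    settings: SimulationSettings = SimulationSettings(),
    pop: PopulationSettings = PopulationSettings(),
    params: Optional[ParamSet] = None,
    readout: Optional[str] = None,
    output_unit: str = "MEPTR",
) -> pd.DataFrame:
    """Replicate-level observed-data table for a dose design.

    The design is given either as an existing :class:`DoseResponse` /
    :class:`Landscape` (its doses are reused) or as ``varied`` + ``doses``:
    one unit label and a dose vector, or a pair of labels and a pair of dose
    grids for a two-input design.  Returns the observed-data schema:
    ``input_1, dose_1[, input_2, dose_2], replicate, output, output_unit``.
    Seed-reproducible; with ``replicate_cv = 0`` and no background the
    replicates equal the simulated means exactly.
    """
    rng = np.random.default_rng(seed)
    readout = readout or circuit.reporters[0]

    if design is not None:
        if isinstance(design, DoseResponse):
            varied, doses = design.input_unit.split("+"), design.doses
        else:
            varied = (design.input_units[0].split("+"), design.input_units[1].split("+"))
            doses = (design.grid_a, design.grid_b)

    # two-input designs pass a pair of unit specs plus a pair of dose grids
    two_input = (
        isinstance(doses, (tuple, list))
        and len(doses) == 2
        and np.ndim(doses[0]) == 1
        and np.ndim(doses[1]) == 1
        and isinstance(varied, (tuple, list))
        and len(varied) == 2
    )

    rows = []
    if two_input:
        unit_a, unit_b = varied
        la = unit_a if isinstance(unit_a, str) else "+".join(unit_a)
        lb = unit_b if isinstance(unit_b, str) else "+".join(unit_b)
        ls = landscape(
            circuit, unit_a, unit_b, doses[0], doses[1], settings, pop, params
        )[readout]
        for i, da in enumerate(ls.grid_a):
            for j, db in enumerate(ls.grid_b):
                for r, val in enumerate(_replicates(rng, ls.values[i, j], noise), 1):
                    rows.append(
                        {
                            "input_1": la, "dose_1": da,
                            "input_2": lb, "dose_2": db,
                            "replicate": r, "output": val,
                            "output_unit": output_unit,
                        }
                    )
    else:
        dr = dose_response(
            circuit, varied, np.asarray(doses, dtype=float),
            settings, pop, params, readout=readout,
        )
        for d, mean in zip(dr.doses, dr.outputs):
            for r, val in enumerate(_replicates(rng, mean, noise), 1):
                rows.append(
                    {
                        "input_1": dr.input_unit, "dose_1": d,
                        "replicate": r, "output": val,
                        "output_unit": output_unit,
                    }
                )
    return pd.DataFrame(rows)


def dataset_means(table: pd.DataFrame) -> pd.DataFrame:
    """Condition-level replicate means (and SEM) of an observed-data table."""
    keys = [c for c in ("input_1", "dose_1", "input_2", "dose_2") if c in table]
    g = table.groupby(keys, sort=True)["output"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "output", "sem": "output_sem", "count": "n"})
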