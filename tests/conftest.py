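import numpy as np
import pytest

from cometsim.circuit import Circuit, ParamSet, TranscriptionUnit
from cometsim.simulate import PopulationSettings, SimulationSettings


@pytest.fixture(scope="session")
def params() -> ParamSet:
    return ParamSet()


@pytest.fixture
def single_cell() -> PopulationSettings:
    """Degenerate population: one cell, no uptake variation."""
    return PopulationSettings(n_cells=1, uptake_sigma=0.0, seed=0)


@pytest.fixture
def zfa_circuit() -> Circuit:
    """Minimal activator -> reporter circuit."""
    return Circuit(
        units=(
            TranscriptionUnit(promoter="CMV", protein="VP64-ZF1", dose=0.0),
            TranscriptionUnit(promoter="ZF1x6-C", protein="mKate2", dose=50.0),
        ),
        reporters=("mKate2",),
    )


@pytest.fixture
def constitutive_circuit() -> Circuit:
    return Circuit(
        units=(TranscriptionUnit(promoter="CMV", protein="mKate2", dose=10.0),),
        reporters=("mKate2",),
    )
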