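import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from lumibias.synthetic_data import (
    CompoundSpec,
    KineticModel,
    NoiseModel,
    SimulationSpec,
)

NOISELESS = NoiseModel(well_sigma=0.0, read_sigma=0.0, experiment_sigma=0.0, response_sigma=0.0)


@pytest.fixture
def noiseless_noise() -> NoiseModel:
    return NOISELESS


def make_spec(
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
    pathways=("barr2", "miniGq"),
    n_experiments: int = 3,
    compounds=None,
    **kwargs,
) -> SimulationSpec:
    """Small study: a reference plus one βarr2-biased test compound."""
    if compounds is None:
        compounds = (
            CompoundSpec(
                "REF",
                true_ec50={"barr2": 12.9e-9, "miniGq": 13.2e-9},
                true_emax={"barr2": 99.7, "miniGq": 100.0},
            ),
            CompoundSpec(
                "CPD",
                true_ec50={"barr2": 11.1e-9, "miniGq": 48.8e-9},
                true_emax={"barr2": 112.0, "miniGq": 28.0},
            ),
        )
    return SimulationSpec(
        compounds=compounds,
        reference="REF",
        pathways=pathways,
        n_experiments=n_experiments,
        noise=noise,
        seed=seed,
        **kwargs,
    )


@pytest.fixture
def noiseless_spec() -> SimulationSpec:
    return make_spec()


@pytest.fixture
def noisy_spec() -> SimulationSpec:
    return make_spec(noise=NoiseModel(), seed=7)
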