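import numpy as np
import pytest

from soxpax import DC5_FORWARD, DC5_REVERSE
from soxpax.equilibrium import BindingParameters, SpeciesTotals


@pytest.fixture
def dc5_forward():
    return DC5_FORWARD


@pytest.fixture
def dc5_reverse():
    return DC5_REVERSE


@pytest.fixture
def standard_totals():
    """The 300/300/300 nM conditions used for differential-assembly lanes."""
    return SpeciesTotals(dna_tot=300.0, sox_tot=300.0, pax_tot=300.0)


@pytest.fixture
def cooperative_params():
    return BindingParameters(kd_sox=100.0, kd_pax=100.0, omega=25.0, label="coop")


def random_params(rng: np.random.Generator) -> BindingParameters:
    """Random parameter draw over the documented solver validity ranges."""
    return BindingParameters(
        kd_sox=float(10 ** rng.uniform(1, 4)),
        kd_pax=float(10 ** rng.uniform(1, 4)),
        omega=float(10 ** rng.uniform(-1, 2)),
    )


def random_totals(rng: np.random.Generator) -> SpeciesTotals:
    return SpeciesTotals(
        dna_tot=float(rng.uniform(10, 1000)),
        sox_tot=float(rng.uniform(10, 1000)),
        pax_tot=float(rng.uniform(10, 1000)),
    )
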