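import numpy as np
import pytest

import itcmicelle as itc

# reference protocols: 32 x 8 uL into a 1.4 mL cell at 25 C, syringe at
# ~12x the CMC (0.04 M for the sulfobetaine DPS, 0.02 M for the
# phosphocholine DPC)
DPS_CMC = 3.6e-3
DPC_CMC = 1.5e-3
DH_DEMIC = 1.0e4  # J/mol, endothermic demicellization at 25 C


@pytest.fixture(scope="session")
def dps_protocol():
    return itc.TitrationProtocol(cell_volume=1.4e-3, injection_volume=8e-6,
                                 n_injections=32, syringe_conc=0.04)


@pytest.fixture(scope="session")
def dpc_protocol():
    return itc.TitrationProtocol(cell_volume=1.4e-3, injection_volume=8e-6,
                                 n_injections=32, syringe_conc=0.02)


@pytest.fixture(scope="session")
def dps_model(dps_protocol):
    """Mass-action DPS-in-water model, operationally calibrated (cached)."""
    raw = itc.MicellizationModel("mass_action", DPS_CMC, DH_DEMIC,
                                 agg_number=55)
    return itc.calibrate_mass_action(raw, dps_protocol)


@pytest.fixture(scope="session")
def dpc_model(dpc_protocol):
    raw = itc.MicellizationModel("mass_action", DPC_CMC, DH_DEMIC,
                                 agg_number=55)
    return itc.calibrate_mass_action(raw, dpc_protocol)


@pytest.fixture
def pseudophase_model():
    return itc.MicellizationModel("pseudophase", DPS_CMC, DH_DEMIC)


def random_sigmoid_params(rng, conc):
    """Well-conditioned random parameter draw for identifiability tests.

    The transition centre stays away from the data edges and the width is
    narrow enough to resolve but wide enough to sample.
    """
    span = conc[-1] - conc[0]
    return np.array([
        rng.uniform(5e3, 1.5e4),            # a1 pre-baseline intercept
        rng.uniform(-2e5, 2e5),             # a2 pre slope
        rng.uniform(-2e3, 2e3),             # a3 post intercept
        rng.uniform(-2e5, 2e5),             # a4 post slope
        rng.uniform(conc[0] + 0.25 * span, conc[-1] - 0.25 * span),  # a5
        rng.uniform(0.01, 0.08) * span,     # a6
    ])
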