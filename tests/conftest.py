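import numpy as np
import pytest

from lumifrontal.protocols import make_step_protocol
from lumifrontal.recordings import build_psth, window_rates
from lumifrontal.simulate import DEFAULT_ARCHETYPES, simulate_unit

INTENSITIES = (9.4, 10.4, 11.4, 12.4, 13.4, 14.4, 15.4)


@pytest.fixture(scope="session")
def step_protocol():
    """The full 7-intensity step protocol (20 reps of 10 s ON / 10 s OFF)."""
    return make_step_protocol(INTENSITIES, n_reps=20)


@pytest.fixture(scope="session")
def e_on_unit(step_protocol):
    """One simulated E_on unit (no heterogeneity) with PSTHs and window rates."""
    arch = DEFAULT_ARCHETYPES["E_on"]
    train = simulate_unit(arch, step_protocol, seed=42, unit_id="e_on")
    psths = build_psth(train, step_protocol, bin_s=0.1)
    wrates = {e: window_rates(p) for e, p in psths.items()}
    return {"arch": arch, "train": train, "psths": psths, "wrates": wrates}


@pytest.fixture(scope="session")
def null_unit(step_protocol):
    arch = DEFAULT_ARCHETYPES["NULL"]
    train = simulate_unit(arch, step_protocol, seed=7, unit_id="null")
    psths = build_psth(train, step_protocol, bin_s=0.1)
    wrates = {e: window_rates(p) for e, p in psths.items()}
    return {"arch": arch, "train": train, "psths": psths, "wrates": wrates}
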