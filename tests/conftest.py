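import numpy as np
import pytest

from ssipkit import PhaseSpec
from ssipkit.footprint import footprint
from ssipkit.ssimple import (
    ModelConstants,
    PhaseState,
    build_phase_state,
    make_phase_state,
    solve_speciation,
)
from ssipkit import synthetic

CONSTANTS = ModelConstants()


def make_state(epsilons, theta, temperature=298.0, solve=True) -> PhaseState:
    """Assemble (and optionally solve) a phase state from raw arrays."""
    state = make_phase_state(epsilons, theta, temperature, CONSTANTS)
    if solve:
        solve_speciation(state)
    return state


@pytest.fixture(scope="session")
def water_sample():
    return synthetic.make_water_like_sample()


@pytest.fixture(scope="session")
def water_ssips(water_sample):
    return footprint(water_sample, molecule_title="water-like")


@pytest.fixture(scope="session")
def solvent_library(water_ssips):
    return {
        "water": (water_ssips, synthetic.WATER_MOLAR_VOLUME),
        "ethanol": (synthetic.make_ethanol_like_ssip_set(),
                    synthetic.ETHANOL_MOLAR_VOLUME),
    }


@pytest.fixture(scope="session")
def water_state(solvent_library):
    state = build_phase_state(PhaseSpec(298.0, [("water", 1.0)]), solvent_library)
    return solve_speciation(state)


@pytest.fixture(scope="session")
def mix_state(solvent_library):
    spec = PhaseSpec(298.0, [("water", 0.75), ("ethanol", 0.25)])
    return solve_speciation(build_phase_state(spec, solvent_library))


@pytest.fixture()
def gas_state():
    return make_state([], [])
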