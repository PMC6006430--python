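import numpy as np
import pytest

from rcaxon import (
    ChannelGeometry,
    PulseSpec,
    SolutionState,
    build_axon_circuit,
    simulate_transient,
)
from rcaxon.quantification import DEFAULT_CALIBRATION_GRID, build_calibration


@pytest.fixture(scope="session")
def geometry():
    return ChannelGeometry()


@pytest.fixture(scope="session")
def pulse():
    return PulseSpec()


@pytest.fixture(scope="session")
def trace_source(geometry, pulse):
    """Noise-free simulator closure c (mol/L) -> Trace, memoised per concentration."""
    cache = {}

    def source(c_k2so4: float):
        if c_k2so4 not in cache:
            circuit = build_axon_circuit(SolutionState(c_k2so4), geometry)
            cache[c_k2so4] = simulate_transient(circuit, pulse)
        return cache[c_k2so4]

    return source


@pytest.fixture(scope="session")
def calibration(trace_source):
    """Default log-spaced calibration built from noise-free simulator traces."""
    return build_calibration(DEFAULT_CALIBRATION_GRID, trace_source)
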