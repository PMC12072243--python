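"""Shared fixtures: a few session-scoped simulations reused across tests."""

import numpy as np
import pytest

from habephys import StepProtocol, simulate_cell, simulate_pair
from habephys import phenotypes


@pytest.fixture(scope="session")
def hyper_protocol():
    return StepProtocol(t_total=7.0)


@pytest.fixture(scope="session")
def hyper_protocol_10s():
    return StepProtocol(t_total=10.0)


@pytest.fixture(scope="session")
def depol_protocol():
    return StepProtocol(amp_pA=100.0, t_total=2.5)


@pytest.fixture(scope="session")
def short_trace(hyper_protocol):
    return simulate_cell(phenotypes.short_rdp(), hyper_protocol)


@pytest.fixture(scope="session")
def long_trace(hyper_protocol_10s):
    return simulate_cell(phenotypes.long_rdp(), hyper_protocol_10s)


@pytest.fixture(scope="session")
def hf_depol_trace(depol_protocol):
    return simulate_cell(phenotypes.cell_params("short_rdp", "hf"),
                         depol_protocol)


@pytest.fixture(scope="session")
def lf_depol_trace(depol_protocol):
    return simulate_cell(phenotypes.cell_params("short_rdp", "lf"),
                         depol_protocol)


@pytest.fixture(scope="session")
def coupled_pair(hyper_protocol_10s):
    proto = StepProtocol(amp_pA=-200.0, t_total=10.0)
    return simulate_pair(phenotypes.long_rdp(), proto), proto


def synthetic_trace(v_mV, fs=20_000.0, i_pA=None):
    """Build a VoltageTrace from a raw voltage array."""
    from habephys import VoltageTrace

    v = np.asarray(v_mV, dtype=float)
    i = np.zeros_like(v) if i_pA is None else np.asarray(i_pA, dtype=float)
    return VoltageTrace(fs=fs, v_mV=v, i_pA=i, meta={"cell_id": "synthetic"})
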