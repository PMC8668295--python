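"""Shared fixtures: calibrated cells and full-protocol simulation runs.

Calibration and the 527-cell runs are the expensive pieces, so they are
session-scoped and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from dgnet import (
    SimConfig,
    StimulusProtocol,
    build_stimulation,
    generate_network,
    run_simulation,
)
from dgnet.cells import calibrated_params
from dgnet.engine import default_record_set

CELL_TYPES = ("GC", "MC", "BC", "HIPP")


@pytest.fixture(scope="session")
def cell_params():
    return {t: calibrated_params(t) for t in CELL_TYPES}


@pytest.fixture(scope="session")
def healthy_network():
    return generate_network(mode="healthy", seed=1)


def _protocol_run(mode, seed, cell_params, **net_kwargs):
    net = generate_network(mode=mode, seed=seed, **net_kwargs)
    rng = np.random.default_rng([seed, 11])
    stimulation = build_stimulation(StimulusProtocol(), net, rng)
    record = tuple(default_record_set(net, stimulation)) + tuple(
        (g, 0, 0) for g in net.populations["BC"].global_ids()
    )
    result = run_simulation(
        net, stimulation, SimConfig(seed=seed, record=record), cell_params=cell_params
    )
    return net, stimulation, result


@pytest.fixture(scope="session")
def healthy_run(cell_params):
    """Full 527-cell healthy-mode run under the standard protocol."""
    return _protocol_run("healthy", 1, cell_params)


@pytest.fixture(scope="session")
def pathological_run(cell_params):
    """Same seed and protocol with mossy-fiber sprouting (2 per GC)."""
    return _protocol_run("pathological", 1, cell_params, sprouting_degree=2, mc_loss=0)
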