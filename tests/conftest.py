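"""Shared fixtures: replicated engine runs reused across test modules.

All simulation inputs are generated programmatically; fixtures are
session-scoped because engine runs (and the first numba compilation) are
the dominant cost of the suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from spinesim import geometry as geo, presynaptic as presyn
from spinesim.engine import SimulationConfig, run_simulation


def single_release_runs(molecules, composition, n_seeds, duration,
                        extrasynaptic=None, seed_base=1000, **kw):
    g = kw.pop("geometry", None) or geo.build_geometry()
    out = []
    for i in range(n_seeds):
        rng = np.random.default_rng(seed_base + i)
        layout = geo.place_receptors(g, composition, rng,
                                     extrasynaptic=extrasynaptic)
        cfg = SimulationConfig(
            geometry=g, layout=layout,
            release=presyn.single_release(molecules, g),
            duration=duration, seed=seed_base + 7 * i, **kw)
        out.append(run_simulation(cfg))
    return out


@pytest.fixture(scope="session")
def nr2a_500_runs():
    """80 AMPAR + 20 NR2A, 500-molecule release (univesicular floor)."""
    return single_release_runs(500, {"AMPAR": 80, "NR2A": 20}, 10, 100.0)


@pytest.fixture(scope="session")
def nr2a_1500_runs():
    """80 AMPAR + 20 NR2A, 1500-molecule release (univesicular ceiling)."""
    return single_release_runs(1500, {"AMPAR": 80, "NR2A": 20}, 10, 150.0)


@pytest.fixture(scope="session")
def nr2b_1500_runs():
    """80 AMPAR + 20 NR2B, 1500 molecules; long window for slow kinetics."""
    return single_release_runs(1500, {"AMPAR": 80, "NR2B": 20}, 10, 250.0)


@pytest.fixture(scope="session")
def nr2b_10000_runs():
    """Multivesicular release onto an NR2B synapse."""
    return single_release_runs(10000, {"AMPAR": 80, "NR2B": 20}, 6, 150.0)


@pytest.fixture(scope="session")
def tri_10000_runs():
    """Multivesicular release onto a triheteromeric synapse."""
    return single_release_runs(10000, {"AMPAR": 80, "NR2A_NR2B": 20}, 6,
                               150.0)


@pytest.fixture(scope="session")
def tri_1500_runs():
    return single_release_runs(1500, {"AMPAR": 80, "NR2A_NR2B": 20}, 10,
                               150.0)
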