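"""Shared fixtures: the packaged toy system, its dual-basin model, and the
default forward/reverse targeted-MD runs (session-scoped — they are the
most expensive objects in the suite and several tests read them)."""

import numpy as np
import pytest

from tmdpath.geometry import kabsch_superpose
from tmdpath.pipeline import toy_tmd_protocol
from tmdpath.simulator import build_dual_basin, run_tmd
from tmdpath.synthetic_data import make_two_state_toy


@pytest.fixture(scope="session")
def toy():
    return make_two_state_toy(60, seed=0)


@pytest.fixture(scope="session")
def model(toy):
    return build_dual_basin(toy.open, toy.closed)


@pytest.fixture(scope="session")
def tmd_default_runs(toy, model):
    """Forward and reverse TMD at k = 0.5 under the packaged schedule.

    Returns {"forward": (SimResult, final_rmsd), "reverse": ...}.
    """
    protocol = toy_tmd_protocol()
    out = {}
    for name, (start, target) in (
        ("forward", (toy.open, toy.closed)),
        ("reverse", (toy.closed, toy.open)),
    ):
        res = run_tmd(model, start, target, k=0.5, protocol=protocol, seed=7)
        final = kabsch_superpose(
            res.final.coords, target.coords, start.masses
        ).rmsd
        out[name] = (res, final)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
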