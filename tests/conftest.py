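import numpy as np
import pytest

from loomlab.synthetic.behavior import BehaviorSimParams, gen_ler_session
from loomlab.synthetic.patch import PatchSimParams, gen_patch_cell
from loomlab.synthetic.visual import gen_checker_stimulus


@pytest.fixture(scope="session")
def wt_session():
    """One wild-type-like synthetic arena session with ground truth."""
    params = BehaviorSimParams(seed=42, session_length=540.0)
    tracked, stim, truth = gen_ler_session(params, n_days=1)
    return params, tracked, stim, truth


@pytest.fixture(scope="session")
def checker_stim():
    """Shared checkerboard white-noise movie (5 min at 20 Hz)."""
    return gen_checker_stimulus(n_frames=6000, grid=(40, 40), seed=7)


@pytest.fixture(scope="session")
def quiet_cell():
    """Noiseless current-step sweep set of the reference cell (R=1 GOhm,
    C=50 pF), shared across tests to amortise the integration cost."""
    return gen_patch_cell(
        PatchSimParams(leak_ns=1.0, capacitance_pf=50.0, seed=1), "current_steps"
    )
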