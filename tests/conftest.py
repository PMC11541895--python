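import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from ccmeldi.simulate import DEFAULT_STANDARD_PANEL, SimSpec, simulate_run


@pytest.fixture(scope="session")
def standard_run():
    """Zero-noise run of the 14-isomer monounsaturated FA standard panel."""
    spec = SimSpec(panel=DEFAULT_STANDARD_PANEL, seed=1)
    run, truth = simulate_run(spec)
    return spec, run, truth


@pytest.fixture(scope="session")
def jittered_run():
    """Same panel with 0.02 min apex jitter and 1% amplitude noise."""
    spec = SimSpec(
        panel=DEFAULT_STANDARD_PANEL, seed=11, rt_jitter_min=0.02, noise_cv=0.01
    )
    run, truth = simulate_run(spec)
    return spec, run, truth
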