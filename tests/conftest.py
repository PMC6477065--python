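import numpy as np
import pytest

from proalkit.task import canonical_schedule


@pytest.fixture(scope="session")
def schedule():
    return canonical_schedule()


@pytest.fixture(scope="session")
def fixed_inputs(schedule):
    """One fixed 150-trial binary input sequence from the canonical session."""
    from proalkit.task import generate_trials
    return [t.u for t in generate_trials(schedule, rng_seed=12345)]
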