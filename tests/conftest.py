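import numpy as np
import pytest

from unwindkit import UnwindingMechanism
from unwindkit.simulate import FORK_16BP, JUNCTION_16BP, fork_mechanism, junction_mechanism


@pytest.fixture
def quench_times():
    """Standard quench-flow design: 20 log-spaced times over 5-500 ms."""
    return np.geomspace(0.005, 0.5, 20)


@pytest.fixture
def junction_truth():
    return junction_mechanism(), JUNCTION_16BP


@pytest.fixture
def fork_truth():
    return fork_mechanism(), FORK_16BP


@pytest.fixture
def simple_mechanism():
    return UnwindingMechanism(3, 78.4, 12.0)
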