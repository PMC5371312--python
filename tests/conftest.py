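import dataclasses
import math

import pytest

from physarum import ResponseParams, TwoPathParams, run_ensemble


@pytest.fixture(scope="session")
def response():
    return ResponseParams(epsilon=0.2, mu=2.0, delta=1.0)


@pytest.fixture(scope="session")
def table1():
    """Canonical two-path experiment parameters."""
    return TwoPathParams()


@pytest.fixture(scope="session")
def small_ensemble(table1):
    """Short, medium-size ensemble reused by estimator and reduction tests."""
    params = dataclasses.replace(table1, t_end=40.0 * math.pi)
    return run_ensemble(params, 400, base_seed=123, record="full")
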