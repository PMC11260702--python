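import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from sbtox import LifeTable, default_fixtures, load_parameter_set
from sbtox.parameters import ParameterSet

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ps() -> ParameterSet:
    return load_parameter_set()


@pytest.fixture(scope="session")
def fx():
    return default_fixtures()


@pytest.fixture(scope="session")
def zero_lt() -> LifeTable:
    return LifeTable.zero()


def set_values(ps: ParameterSet, **overrides) -> ParameterSet:
    """Copy of ``ps`` with selected base values replaced (printed scale)."""
    params = dict(ps.parameters)
    for pid, value in overrides.items():
        params[pid] = dataclasses.replace(params[pid], base_value=value)
    return dataclasses.replace(ps, parameters=params)


def zero_toxicity(ps: ParameterSet) -> ParameterSet:
    """Variant with no first events and no recurrences."""
    zeros = {f"tox_grade{g}_imrt_igrt": 0.0 for g in range(1, 5)}
    zeros.update({f"p_rec{l}_{c}": 0.0
                  for l in range(1, 5) for c in ("surgery", "supportive")})
    return set_values(ps, **zeros)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240708)
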