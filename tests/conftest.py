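import dataclasses

import pytest

try:
    from hypothesis import settings

    settings.register_profile("repro", derandomize=True, max_examples=50)
    settings.load_profile("repro")
except ImportError:  # pragma: no cover
    pass

from abpcensus import default_constants, load_reference_table
from abpcensus.synth import SynthParams


@pytest.fixture(scope="session")
def records():
    return load_reference_table()


@pytest.fixture(scope="session")
def constants():
    return default_constants()


@pytest.fixture(scope="session")
def by_name(records):
    return {r.name: r for r in records}


@pytest.fixture
def small_params():
    """A reduced-size synthetic cell for fast image tests."""
    return dataclasses.replace(
        SynthParams(),
        cell_radius=1.6,
        n_structures=5,
        n_slices=21,
        seed=11,
    )
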