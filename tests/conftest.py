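import pytest

from epipetri.models import FIXTURE_NAMES, fixture


@pytest.fixture(scope="session")
def load():
    """Session-cached fixture loader (parsing is cheap but repeated)."""
    cache = {}

    def _load(name):
        if name not in cache:
            cache[name] = fixture(name)
        return cache[name]

    return _load


@pytest.fixture(scope="session")
def all_fixtures(load):
    return [load(name) for name in FIXTURE_NAMES]


@pytest.fixture(scope="session")
def partitioned_fixtures(all_fixtures):
    return [fx for fx in all_fixtures if fx.partition is not None]
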