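import pytest
from hypothesis import settings

from glucolog.core import TargetRange, Thresholds

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def band() -> TargetRange:
    return TargetRange(4.0, 10.0)


@pytest.fixture
def thresholds() -> Thresholds:
    return Thresholds()
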