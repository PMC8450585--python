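import pytest

from lncea import ParameterSet, load_default_parameters


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    """Base-case parameter set: published transitions + synthetic cost/utility."""
    return load_default_parameters()
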