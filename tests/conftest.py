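import pytest

from pmqc.quant import load_default_quant_config
from pmqc.rules import load_default_rules, load_table2_features, load_table2_library


@pytest.fixture(scope="session")
def features():
    """The shipped 25-compound CPM/PPM annotation fixture."""
    return load_table2_features()


@pytest.fixture(scope="session")
def library():
    return load_table2_library()


@pytest.fixture(scope="session")
def rule_base():
    return load_default_rules()


@pytest.fixture(scope="session")
def quant_config():
    return load_default_quant_config()
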