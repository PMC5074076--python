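import pytest

from renalreab.dataset import load_reference_set, load_table2
from renalreab.physiology import default_physiology


@pytest.fixture(scope="session")
def panel():
    """The packaged 45-drug evaluation panel."""
    return load_table2().drugs


@pytest.fixture(scope="session")
def reference_panel():
    """The packaged 11-drug calibration reference subset."""
    return load_reference_set().drugs


@pytest.fixture()
def physiology():
    return default_physiology()
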