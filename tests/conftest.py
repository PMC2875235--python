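import pytest

from mthaplopop.haplogroups import load_default_tree
from mthaplopop.notation import DistancePolicy, load_eljadida_fixture


@pytest.fixture(scope="session")
def eljadida():
    """The packaged 81-sample El Jadida fixture."""
    return load_eljadida_fixture()


@pytest.fixture(scope="session")
def tree():
    return load_default_tree()


@pytest.fixture(scope="session")
def policy():
    return DistancePolicy()
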