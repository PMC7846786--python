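import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from dutafab import FvSequence, assign_numbering
from dutafab.fv_numbering import VH3_TEMPLATE, VK1_TEMPLATE
from dutafab.fixtures import make_binder, make_scaffold


@pytest.fixture(scope="session")
def template_fv():
    return FvSequence(VH3_TEMPLATE, VK1_TEMPLATE, "template")


@pytest.fixture(scope="session")
def template_nfv(template_fv):
    return assign_numbering(template_fv)


@pytest.fixture(scope="session")
def scaffold_nfv():
    return assign_numbering(make_scaffold(11))


@pytest.fixture(scope="session")
def binder_pair(scaffold_nfv):
    h, h_set = make_binder(scaffold_nfv, "H-side", 6, 21)
    l, l_set = make_binder(scaffold_nfv, "L-side", 6, 22)
    return (assign_numbering(h), h_set, assign_numbering(l), l_set)
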