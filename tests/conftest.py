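import pytest

from permotif import (
    hammerhead_descriptor,
    layout_for,
    parse_descriptor,
    twister_descriptor,
)

# compact two-block motif whose search space is small enough for the
# enumerate-everything oracle used in completeness tests
MINI_DESCRIPTOR_TEXT = """\
motif mini
stem X len=3:4 wobble
stem Y len=2:3
linker 0:3
block A
  stem5 X
  seq CUGA
  stem5 Y
block B
  stem3 Y
  seq GAA
  stem3 X
"""


@pytest.fixture(scope="session")
def hammerhead():
    return hammerhead_descriptor()


@pytest.fixture(scope="session")
def twister():
    return twister_descriptor()


@pytest.fixture(scope="session")
def mini():
    return parse_descriptor(MINI_DESCRIPTOR_TEXT)


@pytest.fixture(scope="session")
def sgc_layout(hammerhead):
    return layout_for(hammerhead, "SGC")


@pytest.fixture(scope="session")
def csg_layout(hammerhead):
    return layout_for(hammerhead, "CSG")
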