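import pytest

from pcbtox import io as pcb_io


@pytest.fixture(scope="session")
def registry():
    return pcb_io.default_registry()


@pytest.fixture(scope="session")
def geometry():
    return pcb_io.default_geometry()


@pytest.fixture(scope="session")
def library():
    return pcb_io.default_library()
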