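import pytest

import phantomfield as pf

DIAMETER_MM = 240.80


@pytest.fixture(scope="session")
def layout() -> pf.MontageLayout:
    return pf.MontageLayout.standard(DIAMETER_MM)


@pytest.fixture(scope="session")
def recordings() -> pf.VoltageRecordingSet:
    return pf.load_condition_a_fixture()


@pytest.fixture(scope="session")
def field_table(recordings, layout):
    return pf.build_field_table(recordings, layout)


@pytest.fixture(scope="session")
def distances(layout):
    """Distance lookup (electrode, depth-name) -> mm, reference C3."""
    grid = pf.recording_grid(layout, "C3")
    return {(p.electrode, p.depth.name): p.distance for p in grid}
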