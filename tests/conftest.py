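import pytest

from paneldx import demo_panel_and_map


@pytest.fixture(scope="session")
def panel_and_map():
    """40-gene demo panel (4 X-linked, 1 Y gene) with AD/AR/XL disease map."""
    return demo_panel_and_map(n_genes=40, seed=1)


@pytest.fixture(scope="session")
def panel(panel_and_map):
    return panel_and_map[0]


@pytest.fixture(scope="session")
def dmap(panel_and_map):
    return panel_and_map[1]
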