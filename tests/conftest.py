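import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from lamnode.synthetic import SyntheticNodeSpec, build_toy_node


@pytest.fixture(scope="session")
def toy_node():
    """One audited toy polymer node with truth labels (seed 11)."""
    return build_toy_node(SyntheticNodeSpec(seed=11, noise_sigma=0.05))


@pytest.fixture(scope="session")
def toy_model(toy_node):
    return toy_node[0]


@pytest.fixture(scope="session")
def toy_truth(toy_node):
    return toy_node[1]


@pytest.fixture(scope="session")
def catalog_path():
    import lamnode

    return lamnode.packaged_catalog_path()


@pytest.fixture(scope="session")
def structure_dir():
    """Local directory of deposited benchmark structures (not shipped)."""
    return Path(__file__).resolve().parent.parent / "data" / "structures"
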