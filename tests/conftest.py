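import numpy as np
import pytest

from pycoloc.abf import TraitSpec
from pycoloc.cli import write_toy_fixture
from pycoloc.simulate import simulate_haplotype_panel, simulate_study
from pycoloc.summaries import read_summary_table


@pytest.fixture(scope="session")
def toy_paths(tmp_path_factory):
    """Deterministic 8-SNP toy region pair with one shared signal at rs3."""
    d = tmp_path_factory.mktemp("toy")
    return write_toy_fixture(d, seed=7)


@pytest.fixture(scope="session")
def toy_pair(toy_paths):
    p1, p2 = toy_paths
    d1 = read_summary_table(p1, TraitSpec("quantitative", 5000, sdY=1.0))
    d2 = read_summary_table(p2, TraitSpec("quantitative", 8000, sdY=1.0))
    return d1, d2


@pytest.fixture(scope="session")
def small_panel():
    return simulate_haplotype_panel(30, 400, seed=101)


@pytest.fixture(scope="session")
def null_study(small_panel):
    return simulate_study(small_panel, 500, {}, seed=102)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
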