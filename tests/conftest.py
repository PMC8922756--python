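import pytest

from plastidscape.alignment import GeneAlignment
from plastidscape.genetrees import read_newick
from plastidscape.simulate import (
    SimulationConfig,
    simulate_gene_trees,
    simulate_species_tree,
    write_dataset,
)


@pytest.fixture(scope="session")
def species8():
    return simulate_species_tree(8, 42)


@pytest.fixture(scope="session")
def gene_trees8(species8):
    return simulate_gene_trees(species8, [(5, 0), (5, 3)], seed=42)


@pytest.fixture
def toy_aln():
    return GeneAlignment(
        "toy",
        ["a", "b", "c", "d"],
        [
            "ACGTACGTAC",
            "ACGTACGTAC",
            "ACGAACGTAC",
            "ACGAACTTAC",
        ],
    )


@pytest.fixture
def quartet_trees():
    return {
        "ab_cd": read_newick("((A,B),(C,D));"),
        "ac_bd": read_newick("((A,C),(B,D));"),
        "ad_bc": read_newick("((A,D),(B,C));"),
    }


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A tiny but complete simulated study on disk (session-cached)."""
    out = tmp_path_factory.mktemp("dataset")
    cfg = SimulationConfig(
        seed=11,
        n_taxa=8,
        regimes=[(4, 0), (4, 2), (4, 5)],
        gene_length_range=(300, 600),
        delete_gene="rpl33",
    )
    truth = write_dataset(cfg, out)
    return out, cfg, truth
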