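import numpy as np
import pytest

from orthosweep.synthdata import (
    ContaminationSpec,
    MSCParams,
    simulate_dataset,
    simulate_gene_trees,
    simulate_species_tree,
)


@pytest.fixture(scope="session")
def clean_dataset():
    """Small contaminant-free simulated dataset shared across tests."""
    return simulate_dataset(MSCParams(n_species=8, n_genes=6, seed=11), None, n_codons=120)


@pytest.fixture(scope="session")
def contaminated_dataset():
    return simulate_dataset(
        MSCParams(n_species=12, n_genes=8, seed=13), ContaminationSpec(), n_codons=150
    )


@pytest.fixture(scope="session")
def gene_tree_panel():
    """Species tree plus 60 MSC gene trees on 8 taxa with clear signal."""
    sp = simulate_species_tree(8, rng=21, min_internal_branch=1.0)
    genes = simulate_gene_trees(sp, MSCParams(n_species=8, n_genes=60, seed=21))
    return sp, genes


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
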