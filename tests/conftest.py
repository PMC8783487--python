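import pytest

from taxg import simulate_pangenome


@pytest.fixture(scope="session")
def small_pangenome():
    """3 genomes, 20 core families, 3 private genes each, 5% divergence."""
    return simulate_pangenome(
        n_genomes=3, n_core_families=20, n_private_per_genome=3, p=0.05, seed=7
    )


@pytest.fixture()
def toy_assembly():
    from taxg import GenomeAssembly

    return GenomeAssembly("toy", [("c1", "ATGAAATAAGG"), ("c2", "TTACAT")])
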