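import pytest

from strandbias import SyntheticGenomeSpec, simulate_genome
from strandbias.io_tables import GeneRecord, ReplicationGeometry


@pytest.fixture(scope="session")
def small_synthetic():
    """One small simulated genome shared across read-only tests."""
    spec = SyntheticGenomeSpec(
        n_genes=300, chromosome_length=400_000, ter_position=200_000, seed=42
    )
    return simulate_genome(spec)


@pytest.fixture
def geometry():
    return ReplicationGeometry(
        chromosome_id="chr", length=1000, oric_position=100, ter_position=600
    )


@pytest.fixture
def wrapped_geometry():
    return ReplicationGeometry(
        chromosome_id="chr", length=1000, oric_position=900, ter_position=300
    )


def make_gene(gene_id="g1", start=200, end=400, strand="watson",
              chromosome_id="chr", wraps=False):
    return GeneRecord(gene_id, chromosome_id, start, end, strand, wraps=wraps)
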