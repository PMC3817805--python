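import numpy as np
import pytest

from paleorder.types import GeneRecord, GenomeOrder


def make_order(genome_id, chromosomes):
    """GenomeOrder from {chrom: [(gene_id, strand), ...]} with rank coordinates."""
    records = []
    for chrom, genes in chromosomes.items():
        for rank, (gene, strand) in enumerate(genes):
            records.append(
                GeneRecord(
                    gene_id=gene,
                    genome_id=genome_id,
                    chromosome=chrom,
                    start=rank + 1,
                    end=rank + 1,
                    strand=strand,
                )
            )
    return GenomeOrder(genome_id, records)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def identity_dataset():
    """Zero-rearrangement, perfect-detection simulation: truth is recoverable."""
    from paleorder.simulate import SimulationConfig, simulate

    config = SimulationConfig(
        n_genes=300,
        p=0.2,
        q={"A": 0.05, "B": 0.05, "C": 0.05},
        inversions_per_branch=0,
        fusions_per_branch=0,
        detection_rate=1.0,
        false_pair_rate=0.0,
        seed=7,
    )
    return simulate(config)


@pytest.fixture(scope="session")
def moderate_dataset():
    """Simulation at the package's default study conditions."""
    from paleorder.simulate import SimulationConfig, simulate

    return simulate(SimulationConfig(seed=1))
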