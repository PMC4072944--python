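import numpy as np
import pandas as pd
import pytest

from paralogbind import synthetic
from paralogbind.annotation import GeneModel


@pytest.fixture(scope="session")
def small_spec():
    return synthetic.SyntheticGenomeSpec(
        n_chromosomes=2,
        chrom_lengths=(200_000, 150_000),
        n_genes=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_genome(small_spec):
    genome, sequences = synthetic.generate_genome(small_spec)
    return genome, sequences


@pytest.fixture(scope="session")
def probes(small_genome):
    genome, _ = small_genome
    return synthetic.generate_probe_layout(genome, spacing=100, probe_length=50)


@pytest.fixture(scope="session")
def binding_truth(small_genome):
    genome, _ = small_genome
    return synthetic.plant_binding_events(genome, n_per_event=4, seed=5)


def make_layout(n: int, chrom: str = "chr1", spacing: int = 100, length: int = 50):
    """A simple single-chromosome tiled layout for hand-built tests."""
    starts = np.arange(n) * spacing
    return pd.DataFrame(
        {
            "probe_id": [f"{chrom}:{s}" for s in starts],
            "chrom": chrom,
            "start": starts,
            "end": starts + length,
        }
    )


def make_gene(gene_id, chrom, strand, start, end, exons=None, utrs=None):
    return GeneModel(gene_id, chrom, strand, start, end, exons or [(start, end)], utrs or [])
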