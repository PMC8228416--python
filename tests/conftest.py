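import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from rrbsdiff.annotation import GenomeAnnotation
from rrbsdiff.simulate import SimulationConfig, simulate_dataset, lid_like_effects


@pytest.fixture(scope="session")
def effects_dataset():
    """A seeded cohort with study-like shared and private effects."""
    config = SimulationConfig(seed=5, effect_table=lid_like_effects())
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def null_dataset():
    """A seeded cohort with no injected effects."""
    return simulate_dataset(SimulationConfig(seed=9))


@pytest.fixture()
def toy_annotation():
    """Two genes and one CGI on chr1, hand-placed for exact context checks.

    geneA: chr1:1000-2000 '+', one exon 1000-1400 -> TSS 1000, promoter
    window [0, 2000].
    geneB: chr1:10000-14000 '-', exons 10000-10500 and 13000-13500 ->
    TSS 13999, promoter [12999, 14999].
    CGI: chr1:30000-31000; shores reach 28000 and 33000.
    """
    genes = pd.DataFrame(
        {
            "gene_id": ["geneA", "geneB"],
            "chrom": ["chr1", "chr1"],
            "start": [1000, 10000],
            "end": [2000, 14000],
            "strand": ["+", "-"],
            "tss": [1000, 13999],
        }
    )
    exons = pd.DataFrame(
        {
            "gene_id": ["geneA", "geneB", "geneB"],
            "chrom": ["chr1"] * 3,
            "start": [1000, 10000, 13000],
            "end": [1400, 10500, 13500],
        }
    )
    cgis = pd.DataFrame({"chrom": ["chr1"], "start": [30000], "end": [31000]})
    return GenomeAnnotation(genes=genes, exons=exons, cgis=cgis)


def sites_frame(chrom_pos):
    """Helper: build a sites DataFrame from (chrom, pos) pairs."""
    return pd.DataFrame(
        {
            "chrom": [c for c, _ in chrom_pos],
            "pos": np.array([p for _, p in chrom_pos], dtype=np.int64),
            "strand": "+",
        }
    )
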