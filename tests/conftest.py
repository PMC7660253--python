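import pandas as pd
import pytest

from karyoshift.io_model import CopyNumberMatrix, GenomeMap


@pytest.fixture
def toy_genome() -> GenomeMap:
    """Two chromosomes, four genes: chrA carries 3 genes, chrB carries 1."""
    chroms = pd.DataFrame({"chrom": ["chrA", "chrB"], "length": [10_000, 8_000]})
    genes = pd.DataFrame(
        {
            "gene": ["g1", "g2", "g3", "g4"],
            "chrom": ["chrA", "chrA", "chrA", "chrB"],
            "start": [100, 2000, 5000, 300],
            "end": [900, 2800, 5900, 1200],
            "strand": ["+", "-", "+", "+"],
        }
    )
    return GenomeMap(chromosomes=chroms, genes=genes)


@pytest.fixture
def toy_copies() -> CopyNumberMatrix:
    """Four diploid strains over chromosomes A, B, C; three are aneuploid."""
    copies = pd.DataFrame(
        {
            "chrA": [3, 2, 3, 2],
            "chrB": [2, 2, 2, 2],
            "chrC": [2, 1, 2, 2],
        },
        index=pd.Index(["S1", "S2", "S3", "S4"], name="strain"),
    )
    return CopyNumberMatrix(
        copies=copies,
        baseline_ploidy=pd.Series([2, 2, 2, 2], index=copies.index),
    )
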