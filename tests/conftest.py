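import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from itrpred.regions import AnnotationSet, Gene, GenomicInterval


@pytest.fixture()
def toy_annotation() -> AnnotationSet:
    """A 10 kb single-chromosome annotation: two genes (one with an intron),
    one pseudogene, one unmappable stretch."""
    gene1 = Gene(
        "g1",
        (
            GenomicInterval("chr1", 1000, 1200, "+"),
            GenomicInterval("chr1", 1400, 1600, "+"),
        ),
    )
    gene2 = Gene("g2", (GenomicInterval("chr1", 3000, 3500, "-"),))
    return AnnotationSet(
        chrom_lengths={"chr1": 10_000},
        genes=[gene1, gene2],
        pseudogenes=[GenomicInterval("chr1", 5000, 5400)],
        unmappable=[GenomicInterval("chr1", 8000, 8100)],
    )


@pytest.fixture(scope="session")
def two_class_labels() -> pd.Series:
    ids = [f"pe{i}" for i in range(300)] + [f"ps{i}" for i in range(300)]
    return pd.Series(
        ["phenotype_exon"] * 300 + ["transcribed_pseudogene"] * 300, index=ids
    )
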