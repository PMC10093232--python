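import numpy as np
import pytest

from eccdiff.model import (
    CircleCall,
    CircleCatalog,
    GeneAnnotation,
    GeneRecord,
    PipelineParams,
)


@pytest.fixture
def params():
    return PipelineParams()


@pytest.fixture
def toy_catalog():
    """Ten circles exercising every filter: 2 mitochondrial, 1 oversize,
    2 that merge into one surviving circle, 2 sub-threshold singletons,
    and 3 ordinary survivors. The full chain leaves exactly 4."""
    calls = [
        CircleCall("chrM", 100, 400, 5),
        CircleCall("chrM", 200, 600, 3),
        CircleCall("chr1", 0, 12_000, 4),
        CircleCall("chr1", 1000, 1500, 1),
        CircleCall("chr1", 1005, 1495, 1),
        CircleCall("chr2", 100, 300, 1),
        CircleCall("chr2", 5000, 5400, 1),
        CircleCall("chr1", 2000, 2500, 2),
        CircleCall("chr1", 3000, 3600, 3),
        CircleCall("chr2", 9000, 9800, 7),
    ]
    return CircleCatalog("toy", "HC", calls)


@pytest.fixture
def small_annotation():
    return GeneAnnotation(
        [
            GeneRecord("chr1", 0, 2000, "GENE_A"),
            GeneRecord("chr1", 2050, 3000, "GENE_B"),
            GeneRecord("chr1", 5000, 6000, "GENE_C"),
            GeneRecord("chr2", 100, 1100, "GENE_D"),
        ]
    )


def random_catalog(rng: np.random.Generator, n: int, sample_id="s", group="G") -> CircleCatalog:
    """Random catalog with clustered breakpoints to stress merging."""
    calls = []
    for _ in range(n):
        chrom = rng.choice(["chr1", "chr2"])
        anchor = int(rng.integers(0, 2000))
        start = max(0, anchor + int(rng.integers(-15, 16)))
        length = int(rng.integers(50, 2000))
        end = start + length + int(rng.integers(-15, 16))
        if end <= start:
            end = start + 1
        calls.append(CircleCall(chrom, start, end, int(rng.integers(0, 10))))
    return CircleCatalog(sample_id, group, calls)
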