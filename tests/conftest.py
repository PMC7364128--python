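import numpy as np
import pandas as pd
import pytest

from qtlconverge.containers import GenotypeMatrix, MarkerMap, PhenotypeVector
from qtlconverge.genesets import GeneSet, GeneSetCorpus


def make_corpus(sets: dict[str, list[str]]) -> GeneSetCorpus:
    return GeneSetCorpus(
        [GeneSet(set_id=k, description="", genes=tuple(v)) for k, v in sets.items()]
    )


@pytest.fixture
def worked_corpus() -> GeneSetCorpus:
    """Three overlapping sets whose biclique structure is known by hand."""
    return make_corpus({"S1": ["a", "b", "c"], "S2": ["b", "c", "d"], "S3": ["c", "e"]})


@pytest.fixture
def small_map() -> MarkerMap:
    return MarkerMap(
        marker=["m1", "m2", "m3", "m4", "m5"],
        chrom=["4", "4", "4", "4", "4"],
        pos_bp=[10_000_000, 20_000_000, 30_000_000, 40_000_000, 50_000_000],
    )


@pytest.fixture
def tiny_genotypes(small_map) -> GenotypeMatrix:
    rng = np.random.default_rng(42)
    calls = rng.integers(0, 2, size=(20, len(small_map))).astype(float)
    return GenotypeMatrix([f"S{i:02d}" for i in range(20)], small_map, calls)


def phenotype_for(genotypes: GenotypeMatrix, values) -> PhenotypeVector:
    return PhenotypeVector(pd.Series(np.asarray(values, float), index=genotypes.strains))
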