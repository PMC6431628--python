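import numpy as np
import pytest

from aerotype.genome_io import GeneFeature, GenomeRecord
from aerotype.profiles import default_library

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def library():
    return default_library()


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA20), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_genome(
    genes,
    genome_id="toy",
    completeness=98.0,
    trna_count=24,
    gap=100,
    replicon="chr1",
):
    """Small in-memory genome: genes = [(gene_id, seq)] laid out with fixed gaps."""
    feats = []
    cursor = 1000
    for gid, seq in genes:
        start = cursor + gap
        end = start + 3 * len(seq) + 2
        feats.append(GeneFeature(gid, replicon, start, end, "+", seq))
        cursor = end
    return GenomeRecord(genome_id, feats, completeness, trna_count)


@pytest.fixture
def make_toy_genome():
    return make_genome
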