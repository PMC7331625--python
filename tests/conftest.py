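import numpy as np
import pytest

from shandiv.popdata import PopulationSample


TOY_GENEPOP = """Toy two-population microsatellite file
locA
locB
Pop
a1 , 0101 0203
a2 , 0102 0000
a3 , 0202 0303
Pop
b1 , 0303 0101
b2 , 0301 0102
b3 , 0103 0202
"""


@pytest.fixture
def toy_genepop(tmp_path):
    path = tmp_path / "toy.gen"
    path.write_text(TOY_GENEPOP)
    return path


@pytest.fixture
def two_locus_pop():
    """A hand-built population: locus A counts [1,1,2], locus B counts [2,2]."""
    geno = np.array(
        [
            [[0, 1], [0, 1]],
            [[2, 2], [0, 1]],
        ],
        dtype=np.int32,
    )
    return PopulationSample(population="toy", genotypes=geno, loci=["A", "B"])


@pytest.fixture
def random_polymorphic_pop():
    rng = np.random.default_rng(42)
    geno = rng.integers(0, 6, size=(40, 3, 2)).astype(np.int32)
    return PopulationSample(
        population="rand", genotypes=geno, loci=["L1", "L2", "L3"]
    )
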