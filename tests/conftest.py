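import pytest

from knockin.fixtures import FixtureSpec, GeneSpec, PlantSpec, generate_fixture
from knockin.genome import GenomeIndex


@pytest.fixture(scope="session")
def fx():
    """Standard mini-genome: two chromosomes, a plus- and a minus-strand
    gene, and ground-truth manifest."""
    spec = FixtureSpec(
        seed=7,
        chromosomes=[("chr1", 20000), ("chr2", 8000)],
        genes=[
            GeneSpec("FIXG1", "chr1", 4000, "+", n_exons=2, cds_len=300),
            GeneSpec("FIXG2", "chr1", 12000, "-", n_exons=3, cds_len=450),
        ],
    )
    return generate_fixture(spec)


@pytest.fixture(scope="session")
def genome(fx):
    return fx.genome


@pytest.fixture(scope="session")
def plus_model(fx):
    return fx.models["FIXG1.1"]


@pytest.fixture(scope="session")
def minus_model(fx):
    return fx.models["FIXG2.1"]


def make_genome(**chroms) -> GenomeIndex:
    return GenomeIndex(chroms)
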