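import numpy as np
import pytest

from antisd.genome_io import Feature, GenomeRecord, KIND_16S, RnaGeneContext
from antisd.simulate import FixtureConfig, make_genome

#: Printed 37-mers (last 24 helix-45 bases + 13-base tail) from the
#: multi-copy Alteromonas analysis.
ALTEROMONAS_CLASSIC = "TAACCCTAGGGGAACCTGGGGTTGGATCACCTCCTTA"
ALTEROMONAS_MINORITY = "TAACCCTAGGGGAACCTGGGGTTGGATCACCTTCAAT"


def make_context(window: str, annotated3_offset: int | None = None, strand: str = "+"):
    """Wrap a bare window string in an RnaGeneContext for unit tests."""
    if annotated3_offset is None:
        annotated3_offset = len(window)
    feature = Feature(
        contig_id="c1", start=1, end=len(window), strand=strand,
        kind=KIND_16S, feature_id="rna1", taxid="tax1",
    )
    return RnaGeneContext(
        feature=feature, window=window, window_origin=1,
        annotated3_offset=annotated3_offset,
    )


def simple_record(contig: str, features: list[Feature]) -> GenomeRecord:
    return GenomeRecord(contigs={"c1": contig}, features=features)


@pytest.fixture(scope="session")
def planted_genome():
    """Default synthetic genome: one foreshortened 16S, 100 CDS, 50% planted SD."""
    return make_genome(FixtureConfig(seed=7))


@pytest.fixture(scope="session")
def planted_record(planted_genome):
    return planted_genome.to_record(taxid="tax7")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
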