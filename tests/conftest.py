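import pytest

from dinoarch import simulate
from dinoarch.model import AnnotationSet, GeneRecord


@pytest.fixture(scope="session")
def taxon_map():
    return simulate.default_taxon_map()


def annotation_from_strands(strands, scaffold="s1", gene_len=100, gap=50):
    """Build a minimal annotation whose scaffold order follows ``strands``."""
    genes = []
    pos = 0
    for i, strand in enumerate(strands):
        genes.append(
            GeneRecord(
                gene_id=f"{scaffold}.g{i}",
                scaffold=scaffold,
                start=pos,
                end=pos + gene_len,
                strand=strand,
            )
        )
        pos += gene_len + gap
    return AnnotationSet(scaffolds=[scaffold], genes=genes)


@pytest.fixture
def strands_to_annotation():
    return annotation_from_strands
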