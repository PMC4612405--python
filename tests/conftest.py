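import numpy as np
import pytest

from graftmrna.alignio import Alignment
from graftmrna.genotyping import DiagnosticSNP


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_alignment(read_id="r1", library="lib", contig="chr1", start=1, strand="+",
                   seq="ACGT", mismatches=()):
    return Alignment(read_id=read_id, library=library, contig=contig, start=start,
                     strand=strand, seq=seq, mismatches=tuple(mismatches))


def make_snp(position, allele_a="A", allele_b="G", contig="chr1", gene_id=None):
    return DiagnosticSNP(contig=contig, position=position, genotype_1="A",
                         allele_1=allele_a, genotype_2="B", allele_2=allele_b,
                         gene_id=gene_id)


@pytest.fixture
def aln_factory():
    return make_alignment


@pytest.fixture
def snp_factory():
    return make_snp
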