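import pytest

from lofkit.io import VariantRecord


def make_variant(
    gene_id="GENE00000",
    pos=100,
    alt="T",
    ac=1,
    an=20000,
    lof_flag="HC",
    codon=None,
    exon=None,
):
    return VariantRecord(
        gene_id=gene_id,
        chrom="1",
        pos=pos,
        ref="A",
        alt=alt,
        csq_class="nonsense",
        lof_flag=lof_flag,
        allele_count=ac,
        allele_number=an,
        codon_index=codon,
        exon_id=exon,
    )


@pytest.fixture
def variant_factory():
    return make_variant


@pytest.fixture
def small_catalog():
    from lofkit.synthetic import simulate_catalog

    return simulate_catalog(20, (1e-4, 1e-2), seed=11)
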