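import pytest

from xnddcnv.annotate import GeneIndex, GeneModel, Transcript
from xnddcnv.genome import GenomicInterval, load_default_cytobands
from xnddcnv.io_formats import AnalysisConfig


@pytest.fixture(scope="session")
def cytobands():
    return load_default_cytobands()


@pytest.fixture()
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def fixture_bundle():
    """The packaged clinical-CNV table, classified once per session."""
    from xnddcnv.fixture import classify_fixture
    return classify_fixture()


def make_gene(gene_id="GENE1", chrom="1", start=1_000_000, end=1_100_000,
              n_exons=4, coding=True, **flags) -> GeneModel:
    """A synthetic gene whose first exon is UTR-only (no CDS)."""
    span = GenomicInterval(chrom, start, end)
    exon_len = 2_000
    gap = (end - start - n_exons * exon_len) // max(1, n_exons - 1)
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append(GenomicInterval(chrom, pos, pos + exon_len))
        pos += exon_len + gap
    cds = tuple(exons[1:]) if coding else ()
    flags.setdefault("is_lncrna", not coding)
    return GeneModel(
        gene_id=gene_id, symbol=flags.pop("symbol", gene_id), span=span,
        transcripts=(Transcript(f"{gene_id}-t1", tuple(exons), cds),),
        **flags,
    )


@pytest.fixture()
def small_gene_index():
    return GeneIndex([
        make_gene("CODING", "1", 1_000_000, 1_100_000, coding=True,
                  brain_expressed=True, pli=0.9, is_ndd=True),
        make_gene("LNC", "1", 2_000_000, 2_050_000, coding=False,
                  brain_expressed=True, is_lncrna=True),
        make_gene("OTHER", "2", 1_000_000, 1_200_000, coding=True,
                  brain_expressed=False, pli=0.1),
    ])
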