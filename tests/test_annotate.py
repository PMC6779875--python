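"""Gene-impact annotation: CDS/exon/span classes, full-transcript
duplications, flag predicates and GFF3 loading."""

import pytest

from conftest import make_gene
from xnddcnv.annotate import (CDS_DISRUPTED, EXON_ONLY, SPAN_ONLY,
                              AnnotationError, GeneIndex, annotate_gene_impact,
                              gene_flag_filter, load_default_gene_models,
                              read_gene_models)
from xnddcnv.genome import GenomicInterval


def impacts_for(index, chrom, start, end, cnv_type="DEL"):
    return annotate_gene_impact(GenomicInterval(chrom, start, end), cnv_type, index)


class TestImpactClasses:
    def test_disjoint_cnv_has_no_impacts(self, small_gene_index):
        assert impacts_for(small_gene_index, "1", 5_000_000, 5_100_000) == []

    def test_cds_overlap_wins(self, small_gene_index):
        # second exon of CODING is coding; gene spans 1.0-1.1 Mb
        gene = small_gene_index["CODING"]
        cds_exon = gene.transcripts[0].cds[0]
        [imp] = impacts_for(small_gene_index, "1", cds_exon.start, cds_exon.end)
        assert imp.gene_id == "CODING" and imp.impact_class == CDS_DISRUPTED

    def test_utr_exon_only(self, small_gene_index):
        first_exon = small_gene_index["CODING"].transcripts[0].exons[0]
        [imp] = impacts_for(small_gene_index, "1", first_exon.start, first_exon.end)
        assert imp.impact_class == EXON_ONLY

    def test_intronic_span_only(self, small_gene_index):
        exons = small_gene_index["CODING"].transcripts[0].exons
        intron_start, intron_end = exons[0].end + 10, exons[1].start - 10
        [imp] = impacts_for(small_gene_index, "1", intron_start, intron_end)
        assert imp.impact_class == SPAN_ONLY

    def test_lncrna_exon_hit_counts_as_exon_only(self, small_gene_index):
        exon = small_gene_index["LNC"].transcripts[0].exons[1]
        [imp] = impacts_for(small_gene_index, "1", exon.start, exon.end)
        assert imp.gene_id == "LNC" and imp.impact_class == EXON_ONLY

    def test_full_transcript_duplication_requires_containment(self, small_gene_index):
        g = small_gene_index["CODING"]
        [full] = impacts_for(small_gene_index, "1", g.span.start - 1_000,
                             g.span.end + 1_000, cnv_type="DUP")
        assert full.full_transcript_duplicated
        # 99% of the transcript does not qualify
        [partial] = impacts_for(small_gene_index, "1", g.span.start + 2_000,
                                g.span.end + 1_000, cnv_type="DUP")
        assert not partial.full_transcript_duplicated

    def test_deletion_never_full_duplicated(self, small_gene_index):
        g = small_gene_index["CODING"]
        [imp] = impacts_for(small_gene_index, "1", g.span.start - 1_000,
                            g.span.end + 1_000, cnv_type="DEL")
        assert not imp.full_transcript_duplicated

    def test_other_chromosome_genes_irrelevant(self, small_gene_index):
        got = impacts_for(small_gene_index, "1", 1_000_000, 1_100_000)
        extended = GeneIndex(list(small_gene_index.genes.values())
                             + [make_gene("FAR", "5", 1_000_000, 1_050_000)])
        got2 = impacts_for(extended, "1", 1_000_000, 1_100_000)
        assert [i.gene_id for i in got] == [i.gene_id for i in got2]


class TestFlagFilter:
    def test_pli_threshold_is_strict(self):
        at = make_gene("AT", pli=0.45, brain_expressed=True)
        above = make_gene("ABOVE", chrom="2", pli=0.46, brain_expressed=True)
        index = GeneIndex([at, above])
        impacts = (impacts_for(index, "1", 1_000_000, 1_100_000)
                   + impacts_for(index, "2", 1_000_000, 1_100_000))
        kept = gene_flag_filter(
            impacts, index, lambda g: g.brain_expressed and g.pli_constrained)
        assert [i.gene_id for i in kept] == ["ABOVE"]

    def test_missing_pli_fails_constraint_predicate(self):
        g = make_gene("NOPLI", pli=None)
        assert not g.pli_constrained

    def test_empty_input(self, small_gene_index):
        assert gene_flag_filter([], small_gene_index, lambda g: True) == []

    def test_gig_predicate(self, small_gene_index):
        extended = GeneIndex(list(small_gene_index.genes.values())
                             + [make_gene("REPAIR", "3", 1_000_000, 1_050_000,
                                          is_gig=True)])
        impacts = impacts_for(extended, "3", 1_000_000, 1_050_000)
        kept = gene_flag_filter(impacts, extended, lambda g: g.is_gig)
        assert [i.gene_id for i in kept] == ["REPAIR"]

    def test_unknown_gene_id_raises(self, small_gene_index):
        from xnddcnv.annotate import GeneImpact
        with pytest.raises(AnnotationError):
            gene_flag_filter([GeneImpact("NOPE", CDS_DISRUPTED, "DEL")],
                             small_gene_index, lambda g: True)


class TestGff3Loading:
    def test_structure_round_trip(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1\t.\tgene\t1001\t9000\t.\t+\t.\tID=G1;Name=G1\n"
            "1\t.\tmRNA\t1001\t9000\t.\t+\t.\tID=G1-t1;Parent=G1\n"
            "1\t.\texon\t1001\t2000\t.\t+\t.\tID=e1;Parent=G1-t1\n"
            "1\t.\texon\t8001\t9000\t.\t+\t.\tID=e2;Parent=G1-t1\n"
            "1\t.\tCDS\t8001\t9000\t.\t+\t0\tID=c1;Parent=G1-t1\n"
        )
        flags = tmp_path / "flags.tsv"
        flags.write_text("gene_id\tpli\tbrain_expressed\tis_ndd\tis_gig\tis_lncrna\n"
                         "G1\t0.46\t1\t0\t0\t0\n")
        index = read_gene_models(gff, flags)
        g = index["G1"]
        assert g.span == GenomicInterval("1", 1000, 9000)
        assert len(g.transcripts[0].exons) == 2
        assert len(g.transcripts[0].cds) == 1
        assert g.pli_constrained  # 0.46 > 0.45
        assert g.brain_expressed

    def test_lncrna_without_cds(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "1\t.\tlncRNA_gene\t1001\t5000\t.\t+\t.\tID=L1;biotype=lncRNA\n"
            "1\t.\tlnc_RNA\t1001\t5000\t.\t+\t.\tID=L1-t1;Parent=L1\n"
            "1\t.\texon\t1001\t1500\t.\t+\t.\tID=e1;Parent=L1-t1\n"
        )
        index = read_gene_models(gff)
        assert index["L1"].is_lncrna
        assert index["L1"].transcripts[0].cds == ()

    def test_orphan_transcript_rejected(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text("1\t.\tmRNA\t1\t100\t.\t+\t.\tID=T;Parent=MISSING\n")
        with pytest.raises(AnnotationError, match="unknown gene"):
            read_gene_models(gff)

    def test_genes_missing_from_flags_get_defaults(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text("1\t.\tgene\t1\t100\t.\t+\t.\tID=G1\n")
        flags = tmp_path / "flags.tsv"
        flags.write_text("gene_id\tpli\tbrain_expressed\tis_ndd\tis_gig\tis_lncrna\n")
        g = read_gene_models(gff, flags)["G1"]
        assert g.pli is None and not g.is_ndd and not g.brain_expressed


def test_packaged_gene_set_is_consistent():
    index = load_default_gene_models()
    nrxn1 = index.by_symbol("NRXN1")
    assert nrxn1.span.chromosome == "2"
    assert nrxn1.is_ndd and nrxn1.brain_expressed and nrxn1.pli_constrained
    ptchd1as = index.by_symbol("PTCHD1-AS")
    assert ptchd1as.is_lncrna and not ptchd1as.transcripts[0].cds
    for g in index.genes.values():
        for t in g.transcripts:
            assert g.span.contains(t.span)
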