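"""Five-category classification, locus matching, tiers and aggregation."""

import pytest

from xnddcnv.callset import StringentCnv
from xnddcnv.fixture import COHORT_SIZES, build_cohort_fixture
from xnddcnv.genome import GenomicInterval
from xnddcnv.inheritance import OriginAssignment
from xnddcnv.io_formats import AnalysisConfig
from xnddcnv.prioritize import (aggregate_cases, assign_categories,
                                load_default_loci, match_disorder_locus)


@pytest.fixture(scope="module")
def loci():
    return load_default_loci()


def make_cnv(chrom, start, end, cnv_type, sample="S1", origin="unknown",
             tier=None):
    iv = GenomicInterval(chrom, start, end)
    c = StringentCnv(sample_id=sample, interval=iv, union_span=iv,
                     cnv_type=cnv_type, supporting_callers=frozenset("ab"),
                     probe_count=10)
    c.annotations["origin"] = OriginAssignment(origin)
    if tier:
        c.annotations["expert_tier"] = tier
    return c


class TestLocusMatch:
    def test_proximal_16p11_duplication_matches(self, loci, config):
        # 625 kb duplication centred on the proximal 16p11.2 region
        span = GenomicInterval("16", 29_612_000, 30_237_000)
        locus = match_disorder_locus(span, "DUP", loci, config.locus_match_ro)
        assert locus is not None
        assert locus.name == "16p11.2_proximal_duplication"

    def test_huge_22q_duplication_fails_ro_and_falls_to_b(self, loci, config):
        # 12.5 Mb spanning far beyond the ~2.6 Mb 22q11.21 region
        span = GenomicInterval("22", 17_900_000, 30_418_000)
        assert match_disorder_locus(span, "DUP", loci, config.locus_match_ro) is None
        cnv = make_cnv("22", 17_900_000, 30_418_000, "DUP")
        [p] = assign_categories([cnv], loci, _empty_genes(), config)
        assert p.categories == frozenset("B")

    def test_type_constraint(self, loci, config):
        span = GenomicInterval("16", 29_650_000, 30_200_000)
        assert match_disorder_locus(span, "DUP", loci, config.locus_match_ro)
        # a deletion-only locus never matches the opposite type and vice versa
        sts = GenomicInterval("X", 6_455_000, 8_135_000)
        assert match_disorder_locus(sts, "DEL", loci, config.locus_match_ro)
        assert match_disorder_locus(sts, "DUP", loci, config.locus_match_ro) is None

    def test_best_of_alternative_regions_is_reported(self, loci, config):
        # a 3.2 Mb 16p13.11 duplication matches the LCR-extended region,
        # a 0.8 Mb one the canonical region
        big = GenomicInterval("16", 15_000_000, 18_200_000)
        small = GenomicInterval("16", 15_490_000, 16_290_000)
        assert match_disorder_locus(big, "DUP", loci, 0.5).name == \
            "16p13.11_p12.3_duplication"
        assert match_disorder_locus(small, "DUP", loci, 0.5).name == \
            "16p13.11_duplication"


def _empty_genes():
    from xnddcnv.annotate import GeneIndex
    return GeneIndex([])


class TestCategories:
    def test_large_de_novo_deletion_is_b_plus_d(self, config, small_gene_index):
        from xnddcnv.annotate import annotate_gene_impact
        cnv = make_cnv("1", 500_000, 5_801_000, "DEL", origin="de_novo")
        cnv.annotations["impacts"] = annotate_gene_impact(
            cnv.interval, "DEL", small_gene_index)  # overlaps the CODING gene
        [p] = assign_categories([cnv], [], small_gene_index, config)
        assert p.categories == frozenset({"B", "D"})

    def test_inherited_ndd_deletion_is_e(self, config, small_gene_index):
        gene = small_gene_index["CODING"]  # is_ndd=True
        cds = gene.transcripts[0].cds[0]
        cnv = make_cnv("1", cds.start - 10_000, cds.end + 10_000, "DEL",
                       origin="maternal")
        from xnddcnv.annotate import annotate_gene_impact
        cnv.annotations["impacts"] = annotate_gene_impact(
            cnv.interval, "DEL", small_gene_index)
        [p] = assign_categories([cnv], [], small_gene_index, config)
        assert p.categories == frozenset("E")

    def test_de_novo_ndd_hit_is_d_not_e(self, config, small_gene_index):
        gene = small_gene_index["CODING"]
        cds = gene.transcripts[0].cds[0]
        cnv = make_cnv("1", cds.start - 10_000, cds.end + 10_000, "DEL",
                       origin="de_novo")
        from xnddcnv.annotate import annotate_gene_impact
        cnv.annotations["impacts"] = annotate_gene_impact(
            cnv.interval, "DEL", small_gene_index)
        [p] = assign_categories([cnv], [], small_gene_index, config)
        assert p.categories == frozenset("D")

    def test_plain_rare_cnv_not_prioritized(self, config, small_gene_index):
        cnv = make_cnv("2", 5_000_000, 5_100_000, "DEL", origin="maternal")
        cnv.annotations["impacts"] = []
        assert assign_categories([cnv], [], small_gene_index, config) == []

    def test_exception_gene_exon_hit_qualifies_for_e(self, small_gene_index):
        config = AnalysisConfig(cds_exception_genes=("CODING",))
        utr_exon = small_gene_index["CODING"].transcripts[0].exons[0]
        cnv = make_cnv("1", utr_exon.start, utr_exon.end, "DEL", origin="maternal")
        from xnddcnv.annotate import annotate_gene_impact
        cnv.annotations["impacts"] = annotate_gene_impact(
            cnv.interval, "DEL", small_gene_index)
        assert cnv.annotations["impacts"][0].impact_class == "exon_only"
        [p] = assign_categories([cnv], [], small_gene_index, config)
        assert p.categories == frozenset("E")
        # without the exception the same CNV is not prioritized
        strict = AnalysisConfig(cds_exception_genes=())
        assert assign_categories([cnv], [], small_gene_index, strict) == []


class TestTiers:
    def test_expert_tier_always_wins(self, config, small_gene_index):
        cnv = make_cnv("1", 500_000, 5_600_000, "DEL", tier="LB")
        cnv.annotations["impacts"] = []
        [p] = assign_categories([cnv], [], small_gene_index, config)
        assert p.tier == "LB" and p.tier_source == "expert"

    def test_heuristic_tiers(self, config, small_gene_index, loci=None):
        b_cnv = make_cnv("1", 500_000, 5_600_000, "DEL")
        b_cnv.annotations["impacts"] = []
        [p] = assign_categories([b_cnv], [], small_gene_index, config)
        assert (p.tier, p.tier_source) == ("LCS", "heuristic")


class TestAggregation:
    def test_multi_category_case_counts_once_per_category(self, config,
                                                          small_gene_index):
        b = make_cnv("1", 500_000, 5_600_000, "DEL", sample="CASE1")
        b.annotations["impacts"] = []
        gene = small_gene_index["CODING"]
        cds = gene.transcripts[0].cds[0]
        e = make_cnv("1", cds.start - 5_000, cds.end + 5_000, "DEL",
                     sample="CASE1", origin="maternal")
        from xnddcnv.annotate import annotate_gene_impact
        e.annotations["impacts"] = annotate_gene_impact(e.interval, "DEL",
                                                        small_gene_index)
        prioritized = assign_categories([b, e], [], small_gene_index, config)
        agg = aggregate_cases(prioritized, {"CASE1": "ASD"})
        assert agg["category_cases"]["B"]["all"] == 1
        assert agg["category_cases"]["E"]["all"] == 1
        assert agg["unique_cases"]["all"] == 1
        assert agg["total_cnvs"]["all"] == 2
        assert agg["multi_cnv_cases"] == 1

    def test_empty_input_all_zero(self):
        agg = aggregate_cases([], {}, {"ASD": 10})
        assert agg["unique_cases"]["all"] == 0
        assert agg["total_cnvs"]["all"] == 0
        assert agg["cs_lcs_cnvs"] == 0


class TestLocusListDegradation:
    def test_removing_loci_reclassifies_c_records(self, config, fixture_bundle):
        fx, prioritized, _ = fixture_bundle
        with_loci = {id(p.cnv): p for p in prioritized}
        without = assign_categories(fx.cnvs, [], fx.genes, config)
        without_by_id = {id(p.cnv): p for p in without}
        for cnv_id, p in with_loci.items():
            if "C" not in p.categories:
                continue
            q = without_by_id.get(cnv_id)
            if p.cnv.size_bp > config.large_cnv_bp:
                assert q is not None and "B" in q.categories
            elif q is not None:
                # survives only through another route (D or E), never C/B
                assert not q.categories & {"B", "C"}
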