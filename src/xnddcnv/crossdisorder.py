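"""Cross-disorder recurrent-gene discovery and fragile-site overlap.

Recurrence scans rare CNVs of 20 kb - 3 Mb, excluding CNVs that match a
recurrent genomic-disorder locus, and counts *distinct cases* per gene:

* ``deletion_cds``: deletions disrupting the coding sequence of a
  brain-expressed, LoF-constrained (pLI > 0.45) gene;
* ``full_duplication``: duplications containing the entire longest
  transcript of a brain-expressed gene.

Genes hit in >= 2 cases are reported with their per-disorder breakdown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .annotate import CDS_DISRUPTED, GeneIndex, annotate_gene_impact
from .callset import StringentCnv
from .genome import GenomicInterval
from .io_formats import AnalysisConfig
from .prioritize import DisorderLocus, match_disorder_locus

DELETION_CDS = "deletion_cds"
FULL_DUPLICATION = "full_duplication"


@dataclass(frozen=True)
class RecurrentGeneRecord:
    gene_id: str
    mode: str
    case_ids: frozenset[str]
    disorders: frozenset[str]

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)


def recurrent_genes(cnvs: Iterable[StringentCnv],
                    genes: GeneIndex,
                    mode: str,
                    disorders: Mapping[str, str],
                    config: AnalysisConfig,
                    loci: list[DisorderLocus] | None = None,
                    families: Mapping[str, str] | None = None,
                    dedup_family: bool = False,
                    min_cases: int = 2) -> list[RecurrentGeneRecord]:
    """Genes recurrently hit across cases, sorted by case count then gene.

    ``families`` + ``dedup_family`` collapse same-family cases (twins,
    affected siblings) to one counting unit; by default related cases count
    individually.
    """
    if mode not in (DELETION_CDS, FULL_DUPLICATION):
        raise ValueError(f"unknown recurrence mode {mode!r}")
    want_type = "DEL" if mode == DELETION_CDS else "DUP"
    loci = loci or []
    lo, hi = config.recurrence_min_kb * 1000, config.recurrence_max_kb * 1000
    hits: dict[str, set[str]] = {}
    for cnv in cnvs:
        if cnv.cnv_type != want_type:
            continue
        if not lo <= cnv.size_bp <= hi:
            continue
        if match_disorder_locus(cnv.union_span, cnv.cnv_type, loci,
                                config.locus_match_ro) is not None:
            continue
        impacts = cnv.annotations.get("impacts")
        if impacts is None:
            impacts = annotate_gene_impact(cnv.interval, cnv.cnv_type, genes)
        for imp in impacts:
            gene = genes[imp.gene_id]
            if mode == DELETION_CDS:
                ok = (imp.impact_class == CDS_DISRUPTED
                      and gene.brain_expressed and gene.pli_constrained)
            else:
                ok = imp.full_transcript_duplicated and gene.brain_expressed
            if ok:
                hits.setdefault(gene.gene_id, set()).add(cnv.sample_id)
    out = []
    for gene_id, cases in hits.items():
        units = cases
        if dedup_family and families:
            by_fam: dict[str, str] = {}
            for c in sorted(cases):
                by_fam.setdefault(families.get(c, c), c)
            units = set(by_fam.values())
        if len(units) >= min_cases:
            out.append(RecurrentGeneRecord(
                gene_id=gene_id,
                mode=mode,
                case_ids=frozenset(units),
                disorders=frozenset(disorders[c] for c in units),
            ))
    out.sort(key=lambda r: (-r.n_cases, genes[r.gene_id].symbol))
    return out


def fragile_overlap_report(de_novo_cnvs: Iterable[StringentCnv],
                           fragile_sites: list[GenomicInterval],
                           genes: GeneIndex,
                           config: AnalysisConfig) -> tuple[float, list[str]]:
    """(fraction of de novo CNVs touching a fragile site, long genes hit).

    Fragile-site overlap is any-overlap (>= 1 bp); long genes are those with
    genomic span > the configured threshold (300 kb) intersecting any de
    novo CNV. Aneuploidies must be excluded upstream.
    """
    de_novo_cnvs = list(de_novo_cnvs)
    if not de_novo_cnvs:
        return 0.0, []
    n_overlap = 0
    long_genes: set[str] = set()
    for cnv in de_novo_cnvs:
        if any(cnv.interval.overlaps(site) for site in fragile_sites):
            n_overlap += 1
        for gene in genes.overlapping(cnv.interval):
            if len(gene.span) > config.long_gene_bp:
                long_genes.add(gene.symbol)
    return n_overlap / len(de_novo_cnvs), sorted(long_genes)
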