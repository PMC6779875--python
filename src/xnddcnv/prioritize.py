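"""Clinical prioritization: five CNV categories, tiers and cohort aggregation.

Categories (precedence A > C > B for the primary class; D is additive):

* **A** aneuploidies;
* **C** CNVs consistent with a known recurrent genomic disorder (best
  type-compatible locus at reciprocal overlap >= 0.5);
* **B** other large CNVs (> 3 Mb);
* **D** de novo CNVs impacting >= 1 gene -- added on top of A-C or standing
  alone;
* **E** the remainder: inherited/unknown-origin CNVs disrupting the coding
  sequence of a curated NDD gene (for configured exception genes such as
  *MBD5* and *PTCHD1-AS*, non-coding exon hits also qualify).

A CNV with no category is not prioritized. Clinical tiers (CS/LCS/VUS/LB/B)
come from expert review when provided; otherwise a clearly-labelled heuristic
stand-in is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional

from .annotate import CDS_DISRUPTED, EXON_ONLY, GeneIndex
from .callset import StringentCnv
from .genome import GenomicInterval, reciprocal_overlap
from .inheritance import DE_NOVO, AneuploidyCall, OriginAssignment, UNKNOWN_ORIGIN
from .io_formats import AnalysisConfig, read_region_set

TIERS = ("CS", "LCS", "VUS", "LB", "B")
CATEGORIES = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class DisorderLocus:
    name: str
    critical_region: GenomicInterval
    expected_type: str  # DEL | DUP | any


@dataclass
class PrioritizedCnv:
    cnv: StringentCnv
    categories: frozenset[str]
    matched_locus: Optional[str]
    origin: OriginAssignment
    tier: Optional[str]
    tier_source: str  # expert | heuristic
    aneuploidy: Optional[AneuploidyCall] = None

    @property
    def sample_id(self) -> str:
        return self.cnv.sample_id


def load_loci(path) -> list[DisorderLocus]:
    loci = []
    for iv, attrs in read_region_set(path, label="disorder_locus"):
        loci.append(DisorderLocus(
            name=attrs.get("name", str(iv)),
            critical_region=iv,
            expected_type=attrs.get("type", "any"),
        ))
    names = [l.name for l in loci]
    if len(names) != len(set(names)):
        raise ValueError("duplicate locus names in region file")
    return loci


def load_default_loci() -> list[DisorderLocus]:
    ref = resources.files("xnddcnv.data").joinpath("disorder_loci.bed")
    with resources.as_file(ref) as p:
        return load_loci(p)


def match_disorder_locus(span: GenomicInterval, cnv_type: str,
                         loci: Iterable[DisorderLocus],
                         ro: float) -> Optional[DisorderLocus]:
    """Best type-compatible locus with reciprocal overlap >= ``ro``, if any."""
    best: tuple[float, str] | None = None
    best_locus = None
    for locus in loci:
        if locus.expected_type not in ("any", cnv_type):
            continue
        r = reciprocal_overlap(span, locus.critical_region)
        if r < ro:
            continue
        key = (-r, locus.name)
        if best is None or key < best:
            best = key
            best_locus = locus
    return best_locus


def _ndd_cds_hit(cnv: StringentCnv, genes: GeneIndex,
                 config: AnalysisConfig) -> bool:
    for imp in cnv.annotations.get("impacts", ()):
        gene = genes[imp.gene_id]
        if not gene.is_ndd:
            continue
        if imp.impact_class == CDS_DISRUPTED:
            return True
        if gene.symbol in config.cds_exception_genes and imp.impact_class == EXON_ONLY:
            return True
    return False


def assign_categories(cnvs: Iterable[StringentCnv],
                      loci: list[DisorderLocus],
                      genes: GeneIndex,
                      config: AnalysisConfig) -> list[PrioritizedCnv]:
    """Classify annotated CNVs; unprioritized CNVs are dropped.

    Each CNV must carry ``origin`` (and, where applicable, ``aneuploidy`` and
    ``impacts``) annotations from the upstream stages.
    """
    out: list[PrioritizedCnv] = []
    for cnv in cnvs:
        origin: OriginAssignment = cnv.annotations.get(
            "origin", OriginAssignment(UNKNOWN_ORIGIN)
        )
        aneu: Optional[AneuploidyCall] = cnv.annotations.get("aneuploidy")
        impacts = cnv.annotations.get("impacts", ())
        cats: set[str] = set()
        matched = None
        if aneu is not None:
            cats.add("A")
        else:
            locus = match_disorder_locus(
                cnv.union_span, cnv.cnv_type, loci, config.locus_match_ro
            )
            if locus is not None:
                cats.add("C")
                matched = locus.name
            elif cnv.size_bp > config.large_cnv_bp:
                cats.add("B")
        if origin.origin == DE_NOVO and len(impacts) > 0:
            cats.add("D")
        if not cats and origin.origin != DE_NOVO and _ndd_cds_hit(cnv, genes, config):
            cats.add("E")
        if not cats:
            continue
        expert = cnv.annotations.get("expert_tier")
        pc = PrioritizedCnv(
            cnv=cnv,
            categories=frozenset(cats),
            matched_locus=matched,
            origin=origin,
            tier=None,
            tier_source="expert" if expert else "heuristic",
            aneuploidy=aneu,
        )
        pc.tier = expert if expert else auto_tier(pc, genes, config)
        out.append(pc)
    return out


def auto_tier(pc: PrioritizedCnv, genes: GeneIndex,
              config: AnalysisConfig) -> str:
    """Heuristic stand-in for expert ACMG review (never overrides experts)."""
    cats = pc.categories
    if "A" in cats:
        return "CS"
    if "C" in cats:
        return "CS" if pc.cnv.cnv_type == "DEL" else "LCS"
    if "B" in cats:
        return "LCS"
    if "D" in cats:
        return "LCS" if _ndd_cds_hit(pc.cnv, genes, config) else "VUS"
    return "VUS"  # category E


def aggregate_cases(prioritized: Iterable[PrioritizedCnv],
                    disorders: Mapping[str, str],
                    cohort_sizes: Mapping[str, int] | None = None) -> dict:
    """Per-disorder and overall case counts in the shape of the cohort
    summary table.

    ``disorders`` maps case/sample id -> disorder. A case carrying CNVs in
    several categories increments each of those category rows once; within a
    category a case is never double-counted. ``cohort_sizes`` (disorder ->
    number of screened cases) enables percentages.
    """
    prioritized = list(prioritized)
    dis_names = sorted({disorders[p.sample_id] for p in prioritized} |
                       (set(cohort_sizes) if cohort_sizes else set()))
    cat_cases: dict[str, dict[str, set[str]]] = {
        c: {d: set() for d in dis_names} for c in CATEGORIES
    }
    all_cases: dict[str, set[str]] = {d: set() for d in dis_names}
    cnv_per_case: dict[str, int] = {}
    cs_lcs_cnvs = 0
    cs_lcs_cases: set[str] = set()
    for p in prioritized:
        d = disorders[p.sample_id]
        for c in p.categories:
            cat_cases[c][d].add(p.sample_id)
        all_cases[d].add(p.sample_id)
        cnv_per_case[p.sample_id] = cnv_per_case.get(p.sample_id, 0) + 1
        if p.tier in ("CS", "LCS"):
            cs_lcs_cnvs += 1
            cs_lcs_cases.add(p.sample_id)

    def pct(n: int, d: str | None) -> Optional[float]:
        if not cohort_sizes:
            return None
        denom = cohort_sizes[d] if d else sum(cohort_sizes.values())
        return round(100.0 * n / denom, 2) if denom else None

    table = {}
    for c in CATEGORIES:
        row = {d: len(cat_cases[c][d]) for d in dis_names}
        row["all"] = len(set().union(*cat_cases[c].values()) if dis_names else set())
        table[c] = row
    unique_all = set().union(*all_cases.values()) if dis_names else set()
    return {
        "category_cases": table,
        "category_case_pct": {
            c: {**{d: pct(table[c][d], d) for d in dis_names},
                "all": pct(table[c]["all"], None)}
            for c in CATEGORIES
        },
        "unique_cases": {**{d: len(all_cases[d]) for d in dis_names},
                         "all": len(unique_all)},
        "total_cnvs": {**{d: sum(1 for p in prioritized
                                 if disorders[p.sample_id] == d)
                          for d in dis_names},
                       "all": len(prioritized)},
        "multi_cnv_cases": sum(1 for n in cnv_per_case.values() if n >= 2),
        "cs_lcs_cnvs": cs_lcs_cnvs,
        "cs_lcs_cases": len(cs_lcs_cases),
    }
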