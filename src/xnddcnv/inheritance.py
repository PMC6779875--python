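"""Parental origin of CNVs and whole-chromosome aneuploidy detection.

Origin rules: a CNV is maternal/paternal when a same-type parental stringent
CNV matches at reciprocal overlap >= the inheritance threshold (both parents
matching reports the higher-RO parent, flagged biparental); *de novo* only
when both parents are genotyped and neither matches; *unknown* whenever at
least one parent is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .callset import StringentCnv
from .genome import GenomicInterval, merge_intervals, reciprocal_overlap
from .io_formats import FEMALE, MALE, AnalysisConfig, PedigreeRecord

MATERNAL, PATERNAL, DE_NOVO, UNKNOWN_ORIGIN = "maternal", "paternal", "de_novo", "unknown"

ORIGIN_CODES = {"M": MATERNAL, "P": PATERNAL, "D": DE_NOVO, "U": UNKNOWN_ORIGIN}


class InheritanceError(ValueError):
    pass


@dataclass(frozen=True)
class OriginAssignment:
    origin: str
    maternal_ro: float = 0.0
    paternal_ro: float = 0.0
    biparental: bool = False


@dataclass(frozen=True)
class AneuploidyCall:
    sample_id: str
    karyotype_label: str
    chromosome: str
    direction: str  # gain | loss
    mosaic: bool = False


def _best_parent_ro(cnv: StringentCnv, parent_cnvs: Iterable[StringentCnv]) -> float:
    best = 0.0
    for p in parent_cnvs:
        if p.cnv_type != cnv.cnv_type:
            continue
        best = max(best, reciprocal_overlap(cnv.union_span, p.union_span))
    return best


def assign_origin(cnv: StringentCnv, pedigree: Mapping[str, PedigreeRecord],
                  parental_cnvs: Mapping[str, list[StringentCnv]],
                  ro: float) -> OriginAssignment:
    """Assign maternal/paternal/de novo/unknown origin for one CNV."""
    rec = pedigree.get(cnv.sample_id)
    if rec is None:
        raise InheritanceError(f"sample {cnv.sample_id} absent from pedigree")
    father_known = rec.father_id is not None and rec.father_id in parental_cnvs
    mother_known = rec.mother_id is not None and rec.mother_id in parental_cnvs
    m_ro = _best_parent_ro(cnv, parental_cnvs[rec.mother_id]) if mother_known else 0.0
    p_ro = _best_parent_ro(cnv, parental_cnvs[rec.father_id]) if father_known else 0.0
    m_match, p_match = m_ro >= ro, p_ro >= ro
    if m_match or p_match:
        origin = MATERNAL if m_ro >= p_ro else PATERNAL
        assignment = OriginAssignment(origin, m_ro, p_ro, biparental=m_match and p_match)
    elif father_known and mother_known:
        assignment = OriginAssignment(DE_NOVO, m_ro, p_ro)
    else:
        assignment = OriginAssignment(UNKNOWN_ORIGIN, m_ro, p_ro)
    cnv.annotations["origin"] = assignment
    return assignment


def _karyotype_label(chromosome: str, direction: str, sex: str) -> str:
    if chromosome == "X":
        if direction == "gain":
            return "47,XXY" if sex == MALE else "47,XXX"
        return "45,X"
    if chromosome == "Y":
        if direction == "gain" and sex == MALE:
            return "47,XYY"
        return f"chr{chromosome} {direction}"
    if direction == "gain":
        return f"trisomy {chromosome}"
    return f"monosomy {chromosome}"


def detect_aneuploidies(sample_cnvs: list[StringentCnv], sex: str,
                        chromosome_length: Mapping[str, int],
                        config: AnalysisConfig) -> list[AneuploidyCall]:
    """Flag chromosomes where merged same-type calls cover >=90% of the contig.

    The contributing CNVs get an ``aneuploidy`` annotation; a chromosome with
    both whole-chromosome gain and loss is a data error.
    """
    out: list[AneuploidyCall] = []
    by_key: dict[tuple[str, str], list[StringentCnv]] = {}
    for c in sample_cnvs:
        by_key.setdefault((c.interval.chromosome, c.cnv_type), []).append(c)
    hit_chroms: dict[str, str] = {}
    for (chrom, cnv_type), group in sorted(by_key.items()):
        covered = sum(len(iv) for iv in merge_intervals(c.interval for c in group))
        if covered < config.aneuploidy_chrom_fraction * chromosome_length[chrom]:
            continue
        direction = "gain" if cnv_type == "DUP" else "loss"
        if chrom in hit_chroms and hit_chroms[chrom] != direction:
            raise InheritanceError(
                f"chromosome {chrom} shows both whole-chromosome gain and loss"
            )
        hit_chroms[chrom] = direction
        mosaic = any(
            c.copy_number is None and c.annotations.get("mosaic") for c in group
        ) or any(c.annotations.get("mosaic") for c in group)
        call = AneuploidyCall(
            sample_id=group[0].sample_id,
            karyotype_label=_karyotype_label(chrom, direction, sex),
            chromosome=chrom,
            direction=direction,
            mosaic=bool(mosaic),
        )
        for c in group:
            c.annotations["aneuploidy"] = call
        out.append(call)
    return out
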