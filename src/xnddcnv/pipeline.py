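"""End-to-end orchestration: raw calls -> stringent -> rare -> annotated ->
origin-assigned -> prioritized -> aggregated, with a reproducible run
manifest.

Stages are pure functions of (inputs, config, seed); the manifest records
input digests, per-stage row counts, the resolved configuration and the
seed, so reruns are verifiable byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from . import __version__
from .annotate import GeneIndex, annotate_gene_impact
from .callset import StringentCnv, stringent_calls_for_sample
from .crossdisorder import DELETION_CDS, FULL_DUPLICATION, recurrent_genes
from .genome import GenomicInterval
from .inheritance import assign_origin, detect_aneuploidies
from .io_formats import (AnalysisConfig, CnvCall, ControlSet, PedigreeRecord,
                         write_summary)
from .prioritize import (DisorderLocus, PrioritizedCnv, aggregate_cases,
                         assign_categories)
from .rarity import ControlIndex, VariableRegionMask, rare_filter


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    stringent: dict[str, list[StringentCnv]]
    rare: dict[str, list[StringentCnv]]
    prioritized: list[PrioritizedCnv]
    aggregate: dict
    recurrent_del: list
    recurrent_dup: list
    manifest: dict


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(calls_by_caller: Mapping[str, list[CnvCall]],
                 pedigree: list[PedigreeRecord],
                 controls: ControlSet,
                 variable_regions: list[GenomicInterval],
                 genes: GeneIndex,
                 loci: list[DisorderLocus],
                 chromosome_length: Mapping[str, int],
                 config: AnalysisConfig,
                 cohort_sizes: Mapping[str, int] | None = None) -> PipelineResult:
    """Run every analysis stage on in-memory inputs."""
    t0 = time.time()
    counts: dict[str, int] = {}
    all_calls: dict[str, list[CnvCall]] = {}
    for caller, calls in calls_by_caller.items():
        for c in calls:
            all_calls.setdefault(c.sample_id, []).append(c)
    counts["raw_calls"] = sum(len(v) for v in calls_by_caller.values())

    ped_by_id = {p.sample_id: p for p in pedigree}
    unknown = set(all_calls) - set(ped_by_id)
    if unknown:
        raise PipelineError("stringent",
                            f"calls for samples absent from pedigree: "
                            f"{sorted(unknown)[:5]}")

    stringent: dict[str, list[StringentCnv]] = {}
    for sid in sorted(all_calls):
        stringent[sid] = stringent_calls_for_sample(all_calls[sid], config)
    counts["stringent"] = sum(len(v) for v in stringent.values())

    index = ControlIndex(controls)
    var_mask = VariableRegionMask(variable_regions)
    rare: dict[str, list[StringentCnv]] = {}
    for sid, cnvs in stringent.items():
        rare[sid] = rare_filter(cnvs, index, var_mask, config)
    counts["rare"] = sum(len(v) for v in rare.values())
    if not (counts["raw_calls"] >= counts["stringent"] >= counts["rare"]):
        raise PipelineError("rarity", "stage counts are not monotone non-increasing")

    for sid, cnvs in rare.items():
        for cnv in cnvs:
            cnv.annotations["impacts"] = annotate_gene_impact(
                cnv.interval, cnv.cnv_type, genes)

    cases = [p for p in pedigree if p.affected == "case"]
    parental_sets = {sid: cnvs for sid, cnvs in rare.items()}
    for p in cases:
        for cnv in rare.get(p.sample_id, ()):  # origins only meaningful for cases
            assign_origin(cnv, ped_by_id, parental_sets, config.inheritance_ro)
    for p in cases:
        detect_aneuploidies(rare.get(p.sample_id, []), p.sex,
                            chromosome_length, config)

    case_cnvs = [c for p in cases for c in rare.get(p.sample_id, ())]
    prioritized = assign_categories(case_cnvs, loci, genes, config)
    counts["prioritized"] = len(prioritized)

    disorders = {p.sample_id: (p.disorder or "unknown") for p in cases}
    aggregate = aggregate_cases(prioritized, disorders, cohort_sizes)

    families = {p.sample_id: p.family_id for p in pedigree}
    rec_del = recurrent_genes(case_cnvs, genes, DELETION_CDS, disorders,
                              config, loci=loci, families=families)
    rec_dup = recurrent_genes(case_cnvs, genes, FULL_DUPLICATION, disorders,
                              config, loci=loci, families=families)

    manifest = {
        "tool_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_counts": counts,
        "n_samples": len(ped_by_id),
        "n_cases": len(cases),
        "elapsed_s": round(time.time() - t0, 3),
    }
    return PipelineResult(stringent=stringent, rare=rare, prioritized=prioritized,
                          aggregate=aggregate, recurrent_del=rec_del,
                          recurrent_dup=rec_dup, manifest=manifest)


def result_tables(result: PipelineResult,
                  sample_meta: Mapping[str, Mapping] | None = None) -> dict:
    """Convert a PipelineResult into the writable table rows."""
    prows = []
    meta = sample_meta or {}
    for p in sorted(result.prioritized,
                    key=lambda p: (p.sample_id, p.cnv.interval.chromosome,
                                   p.cnv.interval.start)):
        m = meta.get(p.sample_id, {})
        prows.append([
            p.sample_id, p.sample_id, m.get("disorder", ""), m.get("sex", ""),
            p.cnv.annotations.get("cytoband", ""),
            p.cnv.interval.chromosome, p.cnv.interval.start, p.cnv.interval.end,
            p.cnv.cnv_type, round(p.cnv.size_bp / 1000, 1),
            p.origin.origin, ",".join(sorted(p.categories)),
            p.tier, p.tier_source, p.matched_locus or "",
        ])
    crows = []
    agg = result.aggregate
    for cat in "ABCDE":
        row = [cat]
        for d in ("ASD", "ADHD", "OCD", "SCZ"):
            row.append(agg["category_cases"][cat].get(d, 0))
            row.append(agg["category_case_pct"][cat].get(d, ""))
        row.append(agg["category_cases"][cat]["all"])
        row.append(agg["category_case_pct"][cat].get("all", ""))
        crows.append(row)
    grows = []
    for rec in result.recurrent_del + result.recurrent_dup:
        grows.append([rec.gene_id, rec.mode, rec.n_cases,
                      ",".join(sorted(rec.disorders)),
                      ",".join(sorted(rec.case_ids))])
    return {
        "prioritized": prows,
        "category_counts": crows,
        "recurrent_genes": grows,
        "burden": [],
        "manifest": result.manifest,
    }


def write_results(result: PipelineResult, out_dir,
                  sample_meta=None) -> None:
    write_summary(result_tables(result, sample_meta), out_dir)
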