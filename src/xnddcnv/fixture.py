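"""The packaged clinical-CNV fixture: 306 prioritized CNVs of a four-NDD
cohort (2,691 cases), transcribed row by row from the published
clinical-significance table, with multi-CNV case linkage reconstructed from
the cohort narrative.

The transcription stores, per table row: subject count, cytoband, CNV type,
size range (kb), sex/disorder/tier/origin multisets and a placement anchor.
:func:`build_cohort_fixture` expands rows into per-subject records with
deterministic GRCh37 coordinates:

* whole-chromosome records span their chromosome;
* karyotype-band records start at their cytoband span;
* recurrent-disorder records centre on the published critical region;
* gene records centre on the named gene's first coding exon.

The published category section labels (A-E) are kept as *expected values*
for validation and are never passed to the classifier.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .annotate import GeneIndex, annotate_gene_impact, load_default_gene_models
from .callset import StringentCnv
from .genome import CytobandMap, GenomicInterval, load_default_cytobands
from .inheritance import ORIGIN_CODES, OriginAssignment, detect_aneuploidies
from .io_formats import FEMALE, MALE, AnalysisConfig
from .prioritize import (DisorderLocus, PrioritizedCnv, aggregate_cases,
                         assign_categories, load_default_loci)

#: Published per-disorder case totals of the screened cohort.
COHORT_SIZES = {"ASD": 1838, "ADHD": 427, "OCD": 222, "SCZ": 204}

_SEX_MAP = {"F": FEMALE, "M": MALE}


class FixtureError(RuntimeError):
    """The packaged fixture failed its integrity checks."""


@dataclass
class FixtureRecord:
    record_id: str
    row_key: str
    section: str          # expected category label, validation only
    label: str
    cytoband: str
    sample_id: str        # case id (shared for multi-CNV cases)
    sex: str
    disorder: str
    cnv: StringentCnv
    size_kb: int
    origin_code: str      # M | P | D | U
    expert_tier: str


@dataclass
class CohortFixture:
    records: list[FixtureRecord]
    samples: dict[str, dict]          # sample_id -> {sex, disorder}
    cytobands: CytobandMap
    genes: GeneIndex
    loci: list[DisorderLocus]

    @property
    def cnvs(self) -> list[StringentCnv]:
        return [r.cnv for r in self.records]

    def expected_section(self, record_id: str) -> str:
        for r in self.records:
            if r.record_id == record_id:
                return r.section
        raise KeyError(record_id)


def _expand_tokens(spec: str, n: int) -> list[str]:
    """Expand ``"F(2),M(4)"`` to a length-``n`` list, refilling with the
    last token if the listed counts fall short."""
    out: list[str] = []
    for token in spec.split(","):
        token = token.strip()
        m = re.match(r"^(.+?)\((\d+)\)$", token)
        if m:
            out.extend([m.group(1)] * int(m.group(2)))
        elif token:
            out.append(token)
    if not out:
        raise FixtureError(f"empty token spec {spec!r}")
    while len(out) < n:
        out.append(out[-1])
    if len(out) != n:
        raise FixtureError(f"token spec {spec!r} expands to {len(out)} != {n}")
    return out


def _assign_origins(disorders: list[str], origin_tokens: list[str]) -> list[str]:
    """Pair origin tokens with subjects; ADHD subjects always receive ``U``
    (no ADHD parents were genotyped, so inheritance is never established)."""
    remaining = list(origin_tokens)
    origins: list[Optional[str]] = [None] * len(disorders)
    for i, d in enumerate(disorders):
        if d == "ADHD":
            if "U" not in remaining:
                raise FixtureError("ADHD subject without an available U origin")
            remaining.remove("U")
            origins[i] = "U"
    it = iter(remaining)
    for i in range(len(disorders)):
        if origins[i] is None:
            origins[i] = next(it)
    return origins  # type: ignore[return-value]


def _sizes(spec: str, n: int) -> list[int]:
    parts = spec.replace("–", "-").split("-")
    if len(parts) == 1:
        return [int(parts[0])] * n
    lo, hi = int(parts[0]), int(parts[1])
    if n == 1:
        return [lo]
    return [round(lo + (hi - lo) * i / (n - 1)) for i in range(n)]


def _cds_anchor_midpoint(genes: GeneIndex, symbol: str) -> GenomicInterval:
    gene = genes.by_symbol(symbol)
    tx = gene.longest_transcript
    parts = tx.cds if tx.cds else tx.exons
    first = parts[0]
    return first


def _place(anchor: str, cytoband: str, size_bp: int, bands: CytobandMap,
           genes: GeneIndex, loci_by_name: dict[str, DisorderLocus]) -> GenomicInterval:
    if anchor == "chrom":
        span = bands.span(cytoband)
        return GenomicInterval(span.chromosome, 0,
                               min(size_bp, bands.chromosome_length[span.chromosome]))
    if anchor == "band":
        span = bands.span(cytoband)
        chrom_len = bands.chromosome_length[span.chromosome]
        start = span.start
        end = min(start + size_bp, chrom_len)
        return GenomicInterval(span.chromosome, start, end)
    if anchor.startswith("gene:"):
        first_cds = _cds_anchor_midpoint(genes, anchor[5:])
        mid = (first_cds.start + first_cds.end) // 2
        chrom_len = bands.chromosome_length[first_cds.chromosome]
        start = max(0, min(mid - size_bp // 2, chrom_len - size_bp))
        return GenomicInterval(first_cds.chromosome, start, start + size_bp)
    if anchor.startswith("locus:"):
        names = anchor[6:].split("|")
        best = None
        for name in names:
            locus = loci_by_name[name]
            L = len(locus.critical_region)
            score = min(size_bp, L) / max(size_bp, L)
            if best is None or score > best[0]:
                best = (score, locus)
        locus = best[1]
        mid = (locus.critical_region.start + locus.critical_region.end) // 2
        chrom = locus.critical_region.chromosome
        chrom_len = bands.chromosome_length[chrom]
        start = max(0, min(mid - size_bp // 2, chrom_len - size_bp))
        return GenomicInterval(chrom, start, start + size_bp)
    raise FixtureError(f"unknown anchor {anchor!r}")


_SELECTOR_RE = re.compile(r"^(?P<row>[A-E]\d*)\[(?P<query>[^\]]*)\]$")


def build_cohort_fixture(config: AnalysisConfig | None = None) -> CohortFixture:
    """Expand the packaged transcription into the 306-record fixture."""
    config = config or AnalysisConfig()
    bands = load_default_cytobands()
    genes = load_default_gene_models()
    loci = load_default_loci()
    loci_by_name = {l.name: l for l in loci}
    return _build(config, bands, genes, loci, loci_by_name)


def _build(config, bands, genes, loci, loci_by_name) -> CohortFixture:
    data = resources.files("xnddcnv.data")
    records: list[FixtureRecord] = []
    with data.joinpath("clinical_cnv_rows.tsv").open("rt", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 13:
                raise FixtureError(f"fixture row needs 13 columns: {line[:60]!r}")
            (key, section, label, n_s, cytoband, cnv_type, size_s, sexes_s,
             disorders_s, tiers_s, origins_s, anchor, notes) = f
            n = int(n_s)
            disorders = _expand_tokens(disorders_s, n)
            sexes = _expand_tokens(sexes_s, n)
            tiers = _expand_tokens(tiers_s, n)
            origins = _assign_origins(disorders, _expand_tokens(origins_s, n))
            sizes = _sizes(size_s, n)
            for i in range(n):
                size_bp = sizes[i] * 1000
                iv = _place(anchor, cytoband, size_bp, bands, genes, loci_by_name)
                cnv = StringentCnv(
                    sample_id=f"{key}-s{i + 1}",
                    interval=iv,
                    union_span=iv,
                    cnv_type=cnv_type,
                    supporting_callers=frozenset({"curated"}),
                    probe_count=0,
                )
                cnv.annotations["origin"] = OriginAssignment(
                    ORIGIN_CODES[origins[i]]
                )
                cnv.annotations["expert_tier"] = tiers[i]
                if "mosaic" in notes:
                    cnv.annotations["mosaic"] = True
                cnv.annotations["cytoband"] = cytoband
                cnv.annotations["size_kb"] = sizes[i]
                cnv.annotations["row_label"] = label
                records.append(FixtureRecord(
                    record_id=f"{key}-s{i + 1}",
                    row_key=key,
                    section=section,
                    label=label,
                    cytoband=cytoband,
                    sample_id=f"{key}-s{i + 1}",
                    sex=_SEX_MAP[sexes[i]],
                    disorder=disorders[i],
                    cnv=cnv,
                    size_kb=sizes[i],
                    origin_code=origins[i],
                    expert_tier=tiers[i],
                ))

    _apply_case_links(records, data)

    for rec in records:
        rec.cnv.sample_id = rec.sample_id
        rec.cnv.annotations["impacts"] = annotate_gene_impact(
            rec.cnv.interval, rec.cnv.cnv_type, genes
        )

    # aneuploidy detection per sample
    by_sample: dict[str, list[FixtureRecord]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, []).append(rec)
    samples: dict[str, dict] = {}
    for sid, recs in by_sample.items():
        sexes = {r.sex for r in recs}
        disorders = {r.disorder for r in recs}
        if len(sexes) != 1 or len(disorders) != 1:
            raise FixtureError(f"case {sid} mixes sexes/disorders: {sexes} {disorders}")
        samples[sid] = {"sex": recs[0].sex, "disorder": recs[0].disorder}
        detect_aneuploidies([r.cnv for r in recs], recs[0].sex,
                            bands.chromosome_length, AnalysisConfig())

    if len(records) != 306:
        raise FixtureError(f"fixture holds {len(records)} records, expected 306")
    bad_origin = [r.record_id for r in records if r.origin_code not in "MPDU"]
    if bad_origin:
        raise FixtureError(f"bad origins: {bad_origin[:5]}")
    return CohortFixture(records=records, samples=samples, cytobands=bands,
                         genes=genes, loci=loci)


def _apply_case_links(records: list[FixtureRecord], data) -> None:
    by_row: dict[str, list[FixtureRecord]] = {}
    for r in records:
        by_row.setdefault(r.row_key, []).append(r)
    linked: set[str] = set()
    with data.joinpath("clinical_cnv_case_links.tsv").open("rt", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            case_id, members_s = line.rstrip("\n").split("\t")
            members = []
            for token in members_s.split(";"):
                m = _SELECTOR_RE.match(token.strip())
                if not m:
                    raise FixtureError(f"bad link selector {token!r}")
                row_key = m.group("row")
                query = dict(
                    part.split("=", 1)
                    for part in m.group("query").split(",") if part
                )
                set_sex = query.pop("set_sex", None)
                cand = None
                for rec in by_row.get(row_key, ()):
                    if rec.record_id in linked:
                        continue
                    if "disorder" in query and rec.disorder != query["disorder"]:
                        continue
                    if "origin" in query and rec.origin_code != query["origin"]:
                        continue
                    if "sex" in query and rec.sex != _SEX_MAP[query["sex"]]:
                        continue
                    cand = rec
                    break
                if cand is None:
                    raise FixtureError(f"link {case_id}: no match for {token!r}")
                linked.add(cand.record_id)
                if set_sex:
                    cand.sex = _SEX_MAP[set_sex]
                members.append(cand)
            sex = members[0].sex
            for rec in members:
                rec.sample_id = case_id
                rec.sex = sex


def classify_fixture(fixture: CohortFixture | None = None,
                     config: AnalysisConfig | None = None):
    """Run the category classifier on the fixture; returns
    (fixture, prioritized records, aggregate summary)."""
    config = config or AnalysisConfig()
    if fixture is None:
        fixture = build_cohort_fixture(config)
    prioritized = assign_categories(fixture.cnvs, fixture.loci, fixture.genes, config)
    disorders = {sid: info["disorder"] for sid, info in fixture.samples.items()}
    summary = aggregate_cases(prioritized, disorders, COHORT_SIZES)
    return fixture, prioritized, summary
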