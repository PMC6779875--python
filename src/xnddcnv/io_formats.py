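"""Readers and writers for the pipeline's external files, plus configuration.

File dialects
-------------
* caller calls: headered TSV ``sample_id chrom start end type cn probes caller``
  with 1-based inclusive coordinates (converted to 0-based half-open here);
* pedigree: 6-column PED (family, sample, father, mother, sex, phenotype)
  with an optional 7th disorder column;
* region sets: BED3/BED4/BED6(+type column);
* controls: BED-like TSV with a sample column;
* config: YAML/JSON mapping onto :class:`AnalysisConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml

from .genome import GenomeError, GenomicInterval, normalize_chromosome

logger = logging.getLogger("xnddcnv")

DEL = "DEL"
DUP = "DUP"
CNV_TYPES = (DEL, DUP)


class FormatError(ValueError):
    """Malformed input file."""


class PedigreeError(FormatError):
    """Structurally invalid pedigree (cycles, duplicate ids, sex conflicts)."""


# --------------------------------------------------------------------------
# Domain records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CnvCall:
    """One raw CNV call from a single detection algorithm."""

    sample_id: str
    interval: GenomicInterval
    cnv_type: str
    caller: str
    probe_count: int = 0
    copy_number: Optional[int] = None
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cnv_type not in CNV_TYPES:
            raise FormatError(f"bad CNV type {self.cnv_type!r}")
        if self.probe_count < 0:
            raise FormatError("negative probe count")
        if self.copy_number is not None:
            baseline = 2
            if self.cnv_type == DEL and self.copy_number >= baseline:
                raise FormatError(
                    f"DEL with copy number {self.copy_number} >= baseline {baseline}"
                )
            if self.cnv_type == DUP and self.copy_number <= baseline:
                raise FormatError(
                    f"DUP with copy number {self.copy_number} <= baseline {baseline}"
                )


MALE, FEMALE, UNKNOWN = "male", "female", "unknown"
_SEX_CODES = {"1": MALE, "2": FEMALE, "0": UNKNOWN, "M": MALE, "F": FEMALE}
_AFF_CODES = {"2": "case", "1": "unaffected", "0": "unknown", "-9": "unknown"}
DISORDERS = ("ASD", "ADHD", "SCZ", "OCD")


@dataclass(frozen=True)
class PedigreeRecord:
    family_id: str
    sample_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str
    affected: str
    disorder: Optional[str] = None


@dataclass
class ControlSet:
    """Population control CNVs with the control cohort size."""

    cnvs: list[tuple[GenomicInterval, str, str]]  # (interval, type, control sample)
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_controls <= 0:
            raise FormatError("control cohort size must be positive")


@dataclass
class AnalysisConfig:
    """All pipeline thresholds; defaults are the study's published settings."""

    min_size_bp: int = 20_000          # stringent set: minimum CNV size
    min_probes: int = 5                # ... minimum supporting probes
    min_callers: int = 2               # ... minimum independent algorithms
    rare_freq_max: float = 0.001       # control carrier frequency <= 0.1%
    stable_overlap_min: float = 0.75   # >=75% of the CNV in copy-number-stable genome
    large_cnv_bp: int = 3_000_000      # category-B size threshold
    concordance_ro: float = 0.50       # RO for multi-caller clustering
    rarity_ro: float = 0.50            # RO for control matching
    locus_match_ro: float = 0.50       # RO for genomic-disorder locus matching
    inheritance_ro: float = 0.50       # RO for parental-origin matching
    pli_min: float = 0.45              # LoF-constraint threshold (strict >)
    long_gene_bp: int = 300_000        # "long gene" span threshold (strict >)
    aneuploidy_chrom_fraction: float = 0.90
    cds_exception_genes: tuple[str, ...] = ("MBD5", "PTCHD1-AS")
    recurrence_min_kb: int = 20        # recurrent-gene scan size window
    recurrence_max_kb: int = 3_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rare_freq_max", "stable_overlap_min", "concordance_ro",
                     "rarity_ro", "locus_match_ro", "inheritance_ro",
                     "aneuploidy_chrom_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise FormatError(f"config {name}={v} outside (0, 1]")
        for name in ("min_size_bp", "min_probes", "min_callers", "large_cnv_bp",
                     "long_gene_bp"):
            if getattr(self, name) <= 0:
                raise FormatError(f"config {name} must be positive")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise FormatError(f"unknown config keys: {sorted(bad)}")
        if "cds_exception_genes" in data:
            data["cds_exception_genes"] = tuple(data["cds_exception_genes"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cds_exception_genes"] = list(self.cds_exception_genes)
        return d


# --------------------------------------------------------------------------
# Readers
# --------------------------------------------------------------------------

_CALL_COLUMNS = ("sample_id", "chrom", "start", "end", "type")


def read_caller_calls(path, caller: str | None = None) -> list[CnvCall]:
    """Read one caller's CNV table (1-based inclusive coordinates).

    Rows with unparseable or degenerate coordinates are skipped and counted
    in a log message; missing mandatory columns raise :class:`FormatError`.
    """
    path = Path(path)
    calls: list[CnvCall] = []
    skipped = 0
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise FormatError(f"{path}: empty file, expected a header row")
        cols = header.rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(cols)}
        for col in _CALL_COLUMNS:
            if col not in idx:
                raise FormatError(f"{path}: missing mandatory column {col!r}")
        if caller is None and "caller" not in idx:
            raise FormatError(f"{path}: no caller column and no caller given")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                start1 = int(f[idx["start"]])
                end1 = int(f[idx["end"]])
                # 1-based inclusive -> 0-based half-open
                iv = GenomicInterval(f[idx["chrom"]], start1 - 1, end1)
                calls.append(CnvCall(
                    sample_id=f[idx["sample_id"]],
                    interval=iv,
                    cnv_type=f[idx["type"]].upper(),
                    caller=caller or f[idx["caller"]],
                    probe_count=int(f[idx["probes"]]) if "probes" in idx and f[idx["probes"]] else 0,
                    copy_number=int(f[idx["cn"]]) if "cn" in idx and f[idx["cn"]] else None,
                ))
            except (ValueError, GenomeError, IndexError) as exc:
                if isinstance(exc, FormatError):
                    raise
                skipped += 1
                logger.warning("%s:%d skipped unparseable row (%s)", path, ln, exc)
    logger.info("%s: read %d calls, skipped %d rows", path, len(calls), skipped)
    read_caller_calls.last_skip_count = skipped  # type: ignore[attr-defined]
    return calls


def write_caller_calls(calls: Iterable[CnvCall], path) -> None:
    """Write calls in the unified caller TSV dialect (1-based inclusive)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("sample_id\tchrom\tstart\tend\ttype\tcn\tprobes\tcaller\n")
        for c in calls:
            fh.write("\t".join([
                c.sample_id, c.interval.chromosome,
                str(c.interval.start + 1), str(c.interval.end),
                c.cnv_type,
                "" if c.copy_number is None else str(c.copy_number),
                str(c.probe_count), c.caller,
            ]) + "\n")


def write_region_set(regions, path) -> None:
    """Write (interval, attrs) pairs as BED6(+type)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for iv, attrs in regions:
            name = attrs.get("name", ".")
            typ = attrs.get("type")
            cols = [iv.chromosome, str(iv.start), str(iv.end), name, "0", "."]
            if typ:
                cols.append(typ)
            fh.write("\t".join(cols) + "\n")


def write_controls(controls: "ControlSet", path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("chrom\tstart\tend\ttype\tsample_id\n")
        for iv, cnv_type, sample in controls.cnvs:
            fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{cnv_type}\t{sample}\n")


def read_pedigree(path) -> list[PedigreeRecord]:
    """Read a PED file and validate parental sex consistency and acyclicity."""
    records: list[PedigreeRecord] = []
    seen: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 6:
                raise FormatError(f"{path}:{ln}: PED rows need >=6 columns")
            fam, sid, fa, mo, sex, aff = f[:6]
            if sid in seen:
                raise PedigreeError(f"{path}:{ln}: duplicate sample id {sid!r}")
            seen.add(sid)
            disorder = f[6] if len(f) > 6 and f[6] in DISORDERS else None
            records.append(PedigreeRecord(
                family_id=fam,
                sample_id=sid,
                father_id=None if fa == "0" else fa,
                mother_id=None if mo == "0" else mo,
                sex=_SEX_CODES.get(sex.upper(), UNKNOWN),
                affected=_AFF_CODES.get(aff, "unknown"),
                disorder=disorder,
            ))
    by_id = {r.sample_id: r for r in records}
    for r in records:
        if r.father_id and by_id.get(r.father_id, None) is not None:
            if by_id[r.father_id].sex == FEMALE:
                raise PedigreeError(f"father {r.father_id} of {r.sample_id} is female")
        if r.mother_id and by_id.get(r.mother_id, None) is not None:
            if by_id[r.mother_id].sex == MALE:
                raise PedigreeError(f"mother {r.mother_id} of {r.sample_id} is male")
    # acyclicity: no sample may appear among its own ancestors
    for r in records:
        frontier = {p for p in (r.father_id, r.mother_id) if p}
        ancestors: set[str] = set()
        while frontier:
            nxt: set[str] = set()
            for pid in frontier:
                if pid == r.sample_id:
                    raise PedigreeError(f"{r.sample_id} is its own ancestor")
                if pid in ancestors:
                    continue
                ancestors.add(pid)
                prec = by_id.get(pid)
                if prec:
                    nxt.update(p for p in (prec.father_id, prec.mother_id) if p)
            frontier = nxt
    return records


def write_pedigree(records: Iterable[PedigreeRecord], path) -> None:
    sex_out = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}
    aff_out = {"case": "2", "unaffected": "1", "unknown": "0"}
    with open(path, "wt", encoding="utf-8") as fh:
        for r in records:
            cols = [r.family_id, r.sample_id, r.father_id or "0", r.mother_id or "0",
                    sex_out[r.sex], aff_out[r.affected]]
            if r.disorder:
                cols.append(r.disorder)
            fh.write("\t".join(cols) + "\n")


def read_region_set(path, label: str = "") -> list[tuple[GenomicInterval, dict]]:
    """Read BED3/BED4/BED6(+) regions; returns (interval, attributes) pairs.

    Attribute keys: ``name`` (column 4) and ``type`` (column 7, used for
    disorder-locus expected CNV type).
    """
    out: list[tuple[GenomicInterval, dict]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{ln}: BED line needs >=3 columns")
            try:
                iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
            except (ValueError, GenomeError) as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
            attrs: dict = {"label": label}
            if len(f) >= 4:
                attrs["name"] = f[3]
            if len(f) >= 7 and f[6] in CNV_TYPES + ("any",):
                attrs["type"] = f[6]
            out.append((iv, attrs))
    return out


def read_controls(path, n_controls: int) -> ControlSet:
    """Read a control CNV table: chrom start end type sample (BED-like TSV)."""
    cnvs = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for col in ("chrom", "start", "end", "type", "sample_id"):
            if col not in idx:
                raise FormatError(f"{path}: missing control column {col!r}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            iv = GenomicInterval(f[idx["chrom"]], int(f[idx["start"]]), int(f[idx["end"]]))
            cnvs.append((iv, f[idx["type"]].upper(), f[idx["sample_id"]]))
    return ControlSet(cnvs=cnvs, n_controls=n_controls)


# --------------------------------------------------------------------------
# Result writing
# --------------------------------------------------------------------------

def write_tsv(path, header: list[str], rows: Iterable[Iterable]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")


def write_summary(results, out_dir) -> list[Path]:
    """Write the result tables of a pipeline run; deterministic output.

    ``results`` is a mapping with optional keys ``prioritized`` (rows),
    ``category_counts`` (rows in the shape of the per-disorder category
    summary table), ``recurrent_genes``, ``burden`` and ``manifest``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    tables = {
        "prioritized_cnvs.tsv": (
            ["case_id", "sample_id", "disorder", "sex", "cytoband", "chrom", "start",
             "end", "type", "size_kb", "origin", "categories", "tier", "tier_source",
             "matched_locus"],
            results.get("prioritized", []),
        ),
        "category_counts.tsv": (
            ["category", "ASD", "ASD_pct", "ADHD", "ADHD_pct", "OCD", "OCD_pct",
             "SCZ", "SCZ_pct", "all", "all_pct"],
            results.get("category_counts", []),
        ),
        "recurrent_genes.tsv": (
            ["gene", "mode", "n_cases", "disorders", "case_ids"],
            results.get("recurrent_genes", []),
        ),
        "burden_results.tsv": (
            ["test", "estimate", "ci_low", "ci_high", "p_value", "fdr_q", "note"],
            results.get("burden", []),
        ),
    }
    for fname, (header, rows) in tables.items():
        p = out_dir / fname
        write_tsv(p, header, rows)
        written.append(p)
    manifest = results.get("manifest", {})
    p = out_dir / "run_manifest.json"
    with open(p, "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(p)
    return written
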