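"""Genomic coordinate model: intervals, cytobands and overlap arithmetic.

All coordinates are 0-based half-open (BED convention) on GRCh37. One-based
inclusive coordinates, as used by microarray caller exports, are converted at
the I/O boundary (:mod:`xnddcnv.io_formats`), never stored.

Reciprocal overlap (RO) -- ``min(ovl/len(a), ovl/len(b))`` -- is the symmetric
match criterion used throughout the pipeline: for multi-caller concordance,
for control-frequency matching, for parental-origin matching and for
recurrent genomic-disorder locus matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "GRCH37_CHROMOSOMES",
    "GenomicInterval",
    "CytobandMap",
    "reciprocal_overlap",
    "overlap_bp",
    "merge_intervals",
    "coverage_fraction",
    "cytoband_to_interval",
    "normalize_chromosome",
    "load_default_cytobands",
]

#: Ordered autosomes + sex chromosomes of GRCh37 (bare names, no "chr" prefix).
GRCH37_CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

_CHROM_SET = frozenset(GRCH37_CHROMOSOMES)


class GenomeError(ValueError):
    """Invalid genomic input (bad interval, unknown chromosome or band)."""


def normalize_chromosome(chrom: str) -> str:
    """Return the bare chromosome name (``chr1`` -> ``1``, ``23`` -> ``X``).

    Raises :class:`GenomeError` for contigs outside 1-22, X, Y.
    """
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c == "23":
        c = "X"
    elif c == "24":
        c = "Y"
    c = c.upper() if c in ("x", "y", "X", "Y") else c
    if c not in _CHROM_SET:
        raise GenomeError(f"unknown chromosome {chrom!r} (expected 1-22, X or Y)")
    return c


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a GRCh37 chromosome."""

    chromosome: str
    start: int
    end: int
    assembly: str = field(default="GRCh37", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.start < 0:
            raise GenomeError(f"negative start {self.start}")
        if self.end <= self.start:
            raise GenomeError(
                f"empty or inverted interval {self.chromosome}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chromosome}:{self.start}-{self.end}"


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Shared base pairs between two intervals (0 if disjoint or trans)."""
    if a.chromosome != b.chromosome:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(ovl/len(a), ovl/len(b)); 1.0 iff the intervals are identical."""
    if a.assembly != b.assembly:
        raise GenomeError(f"assembly mismatch: {a.assembly} vs {b.assembly}")
    ovl = overlap_bp(a, b)
    if ovl == 0:
        return 0.0
    return min(ovl / len(a), ovl / len(b))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: sorted, with overlapping/abutting runs merged."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chromosome, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        run_start = run_end = None
        for iv in sorted(by_chrom[chrom], key=lambda i: (i.start, i.end)):
            if run_start is None:
                run_start, run_end = iv.start, iv.end
            elif iv.start <= run_end:
                run_end = max(run_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, run_start, run_end))
                run_start, run_end = iv.start, iv.end
        if run_start is not None:
            merged.append(GenomicInterval(chrom, run_start, run_end))
    return merged


def coverage_fraction(covered: GenomicInterval, by: Iterable[GenomicInterval]) -> float:
    """Fraction of ``covered`` lying in the union of ``by`` (merged first)."""
    total = 0
    for iv in merge_intervals(by):
        total += overlap_bp(covered, iv)
    return total / len(covered)


# --------------------------------------------------------------------------
# Cytobands
# --------------------------------------------------------------------------

_BAND_RE = re.compile(r"^(?P<chrom>(?:chr)?(?:\d{1,2}|[XYxy]))(?P<band>[pq][\d.]*)$")


class CytobandMap:
    """Banded karyotype of one assembly, loaded from a UCSC-style table.

    Bands on each chromosome must be non-overlapping and tile the chromosome
    end to end. Band lookup supports ISCN prefix semantics: querying ``3p14``
    returns the union span of ``3p14.1``..``3p14.3``; querying a chromosome
    arm (``21p``) or a full chromosome is likewise the union of its bands.
    """

    def __init__(self, rows: Iterable[tuple[str, int, int, str, str]]):
        # rows: (chrom, start, end, band, stain)
        self._bands: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, band, _stain in rows:
            c = normalize_chromosome(chrom)
            self._bands.setdefault(c, []).append((int(start), int(end), band))
        self.chromosome_length: dict[str, int] = {}
        for c, bands in self._bands.items():
            bands.sort()
            prev = 0
            for start, end, band in bands:
                if start != prev:
                    raise GenomeError(
                        f"cytoband table does not tile chromosome {c} at {start} (band {band})"
                    )
                if end <= start:
                    raise GenomeError(f"empty band {c}{band}")
                prev = end
            self.chromosome_length[c] = prev

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._bands, key=GRCH37_CHROMOSOMES.index)

    def bands(self, chrom: str) -> list[tuple[int, int, str]]:
        return list(self._bands[normalize_chromosome(chrom)])

    def resolve(self, chrom: str, band: str) -> GenomicInterval:
        """Span of one band name, with prefix semantics (see class docstring)."""
        c = normalize_chromosome(chrom)
        band = band.strip()
        matches = [
            (s, e)
            for s, e, name in self._bands[c]
            if name == band or name.startswith(band + ".") or
            # "Xp22.3" also covers sub-sub-bands "Xp22.31".."Xp22.33"
            (("." in band) and name.startswith(band) and name != band)
            or (band in ("p", "q") and name.startswith(band))
        ]
        if not matches:
            raise GenomeError(f"unknown cytoband {c}{band}")
        return GenomicInterval(c, min(s for s, _ in matches), max(e for _, e in matches))

    def span(self, spec: str) -> GenomicInterval:
        """Resolve a band-range spec like ``"3p14.1-p13"`` or ``"16p11.2"``.

        The span runs from the start of the first named band to the end of the
        last. Both ends must be on the same chromosome; a second endpoint may
        omit the chromosome (``"21p13-q22.3"``).
        """
        parts = [p.strip() for p in spec.replace("–", "-").split("-")]
        if not 1 <= len(parts) <= 2:
            raise GenomeError(f"cannot parse cytoband spec {spec!r}")
        m = _BAND_RE.match(parts[0])
        if not m:
            raise GenomeError(f"cannot parse cytoband spec {spec!r}")
        chrom = normalize_chromosome(m.group("chrom"))
        first = self.resolve(chrom, m.group("band"))
        if len(parts) == 1:
            return first
        second = parts[1]
        m2 = _BAND_RE.match(second)
        if m2:  # endpoint may repeat the chromosome, e.g. "1p36.33-1p36.32"
            if normalize_chromosome(m2.group("chrom")) != chrom:
                raise GenomeError(f"cytoband range {spec!r} crosses chromosomes")
            second = m2.group("band")
        last = self.resolve(chrom, second)
        lo = min(first.start, last.start)
        hi = max(first.end, last.end)
        return GenomicInterval(chrom, lo, hi)


def cytoband_to_interval(spec: str, bands: CytobandMap) -> GenomicInterval:
    """Functional wrapper around :meth:`CytobandMap.span`."""
    return bands.span(spec)


def _read_cytoband_rows(handle) -> list[tuple[str, int, int, str, str]]:
    rows = []
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        chrom, start, end, band, stain = line.split("\t")
        rows.append((chrom, int(start), int(end), band, stain))
    return rows


def load_cytobands(path) -> CytobandMap:
    """Load a UCSC cytoBand-dialect table (chrom, start, end, band, stain)."""
    with open(path, "rt", encoding="utf-8") as fh:
        return CytobandMap(_read_cytoband_rows(fh))


def load_default_cytobands() -> CytobandMap:
    """The packaged GRCh37 cytoband table.

    Chromosome lengths are the exact GRCh37 contig lengths; band boundaries
    are approximate (rounded to ~100 kb, some neighbouring sub-bands merged)
    but tile each chromosome and carry standard ISCN names.
    """
    ref = resources.files("xnddcnv.data").joinpath("cytobands_grch37.tsv")
    with ref.open("rt", encoding="utf-8") as fh:
        return CytobandMap(_read_cytoband_rows(fh))
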