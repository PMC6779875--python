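"""Rarity filtering: control-population frequency and copy-number-stable overlap.

A stringent CNV is *rare* when (i) same-type control CNVs matching it at
reciprocal overlap >= the rarity threshold are carried by <= 0.1% of control
individuals (carrier frequency: multiple CNVs in one control count once), and
(ii) >= 75% of the CNV lies in the copy-number-stable genome, supplied as its
complement (a BED of copy-number-variable regions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable


from .callset import StringentCnv
from .genome import (GenomicInterval, coverage_fraction, merge_intervals,
                     reciprocal_overlap)
from .io_formats import AnalysisConfig, ControlSet


class RarityError(ValueError):
    pass


@dataclass(frozen=True)
class RarityAnnotation:
    control_carrier_count: int
    control_frequency: float
    stable_fraction: float
    passes_rarity: bool


class ControlIndex:
    """Vectorized index over a control CNV collection, grouped by
    (chromosome, CNV type); each carrier query computes reciprocal overlaps
    against the group in one numpy pass."""

    def __init__(self, controls: ControlSet):
        import numpy as np
        if controls.n_controls <= 0:
            raise RarityError("empty control cohort")
        self.n_controls = controls.n_controls
        self._np = np
        grouped: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
        for iv, cnv_type, sample in controls.cnvs:
            grouped.setdefault((iv.chromosome, cnv_type), []).append(
                (iv.start, iv.end, sample)
            )
        self._groups: dict[tuple[str, str], tuple] = {}
        for key, rows in grouped.items():
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            samples = np.array([r[2] for r in rows], dtype=object)
            self._groups[key] = (starts, ends, samples)

    def carriers(self, span: GenomicInterval, cnv_type: str, ro: float) -> set[str]:
        np = self._np
        group = self._groups.get((span.chromosome, cnv_type))
        if group is None:
            return set()
        starts, ends, samples = group
        ovl = np.minimum(ends, span.end) - np.maximum(starts, span.start)
        lens = ends - starts
        max_len = np.maximum(lens, len(span))
        hit = ovl >= ro * max_len  # min(ovl/la, ovl/lb) >= ro
        return set(samples[hit])


class VariableRegionMask:
    """Pre-merged copy-number-variable regions for fast coverage queries."""

    def __init__(self, variable_regions: Iterable[GenomicInterval]):
        from bisect import bisect_left
        self._bisect = bisect_left
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in merge_intervals(variable_regions):
            self._by_chrom.setdefault(iv.chromosome, []).append((iv.start, iv.end))

    def covered_bp(self, iv: GenomicInterval) -> int:
        segs = self._by_chrom.get(iv.chromosome)
        if not segs:
            return 0
        i = self._bisect(segs, (iv.start, -1))
        if i > 0 and segs[i - 1][1] > iv.start:
            i -= 1
        total = 0
        while i < len(segs) and segs[i][0] < iv.end:
            s, e = segs[i]
            total += max(0, min(e, iv.end) - max(s, iv.start))
            i += 1
        return total

    def stable_fraction(self, iv: GenomicInterval) -> float:
        return 1.0 - self.covered_bp(iv) / len(iv)


def control_frequency(cnv: StringentCnv, controls: ControlIndex,
                      ro: float) -> tuple[int, float]:
    """Distinct control carriers matching the CNV's union span, and frequency."""
    carriers = controls.carriers(cnv.union_span, cnv.cnv_type, ro)
    return len(carriers), len(carriers) / controls.n_controls


def stable_fraction(cnv: StringentCnv,
                    variable_regions: Iterable[GenomicInterval]) -> float:
    """1 - fraction of the CNV covered by copy-number-variable regions."""
    return 1.0 - coverage_fraction(cnv.interval, variable_regions)


def annotate_rarity(cnv: StringentCnv, controls: ControlIndex,
                    variable_regions: "list[GenomicInterval] | VariableRegionMask",
                    config: AnalysisConfig) -> RarityAnnotation:
    count, freq = control_frequency(cnv, controls, config.rarity_ro)
    if isinstance(variable_regions, VariableRegionMask):
        stable = variable_regions.stable_fraction(cnv.interval)
    else:
        stable = stable_fraction(cnv, variable_regions)
    ann = RarityAnnotation(
        control_carrier_count=count,
        control_frequency=freq,
        stable_fraction=stable,
        passes_rarity=(freq <= config.rare_freq_max
                       and stable >= config.stable_overlap_min),
    )
    cnv.annotations["rarity"] = ann
    cnv.is_rare = ann.passes_rarity
    return ann


def rare_filter(cnvs: Iterable[StringentCnv], controls: ControlSet | ControlIndex,
                variable_regions: list[GenomicInterval],
                config: AnalysisConfig) -> list[StringentCnv]:
    """Subset of CNVs passing both rarity rules, each carrying its annotation."""
    index = controls if isinstance(controls, ControlIndex) else ControlIndex(controls)
    if not isinstance(variable_regions, VariableRegionMask):
        variable_regions = VariableRegionMask(variable_regions)
    out = []
    for cnv in cnvs:
        if annotate_rarity(cnv, index, variable_regions, config).passes_rarity:
            out.append(cnv)
    return out
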