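"""Multi-caller consensus: build the stringent CNV set for one sample.

A stringent CNV is supported by at least two independent calling algorithms
(reciprocal overlap >= the concordance threshold, connected-component
grouping), spans >= 20 kb and >= 5 probes. Consensus coordinates are the
intersection of the member calls (conservative); the union span is kept for
locus and rarity matching.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Iterable, Optional

from .genome import GenomicInterval, reciprocal_overlap
from .io_formats import AnalysisConfig, CnvCall


class CallsetError(ValueError):
    pass


@dataclass
class StringentCnv:
    """A consensus CNV surviving the size/probe/caller filters."""

    sample_id: str
    interval: GenomicInterval          # intersection of member calls
    union_span: GenomicInterval        # union of member calls
    cnv_type: str
    supporting_callers: frozenset[str]
    probe_count: int                   # max over supporting calls
    member_calls: tuple[CnvCall, ...] = ()
    copy_number: Optional[int] = None  # modal member copy number
    is_rare: Optional[bool] = None
    annotations: dict[str, Any] = field(default_factory=dict)

    @property
    def size_bp(self) -> int:
        return len(self.interval)


def cluster_calls(calls: list[CnvCall], ro_threshold: float) -> list[list[CnvCall]]:
    """Partition one sample's same-type calls into RO-connected components.

    Within a component, at most one call per caller is kept: ties are broken
    by the larger reciprocal overlap with the cluster seed (the earliest-
    starting call), then by earlier start.
    """
    if not calls:
        return []
    samples = {c.sample_id for c in calls}
    if len(samples) > 1:
        raise CallsetError(f"cluster_calls got calls from {len(samples)} samples")

    clusters: list[list[CnvCall]] = []
    groups: dict[tuple[str, str], list[CnvCall]] = {}
    for c in calls:
        groups.setdefault((c.interval.chromosome, c.cnv_type), []).append(c)

    for key in sorted(groups):
        members = sorted(groups[key], key=lambda c: (c.interval.start, c.interval.end, c.caller))
        n = len(members)
        # union-find over the RO graph
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if members[j].interval.start >= members[i].interval.end:
                    break  # sorted by start; no further overlap with i
                if reciprocal_overlap(members[i].interval, members[j].interval) >= ro_threshold:
                    parent[find(i)] = find(j)
        comp: dict[int, list[CnvCall]] = {}
        for i, c in enumerate(members):
            comp.setdefault(find(i), []).append(c)
        for group in comp.values():
            group.sort(key=lambda c: (c.interval.start, c.interval.end, c.caller))
            seed = group[0]
            best: dict[str, CnvCall] = {}
            for c in group:
                cur = best.get(c.caller)
                if cur is None:
                    best[c.caller] = c
                    continue
                key_new = (-reciprocal_overlap(c.interval, seed.interval), c.interval.start)
                key_cur = (-reciprocal_overlap(cur.interval, seed.interval), cur.interval.start)
                if key_new < key_cur:
                    best[c.caller] = c
            clusters.append(sorted(best.values(), key=lambda c: (c.caller,)))
    clusters.sort(key=lambda g: (g[0].interval.chromosome, g[0].interval.start,
                                 g[0].cnv_type))
    return clusters


def build_stringent_set(clusters: Iterable[list[CnvCall]],
                        config: AnalysisConfig) -> list[StringentCnv]:
    """Turn multi-caller clusters into stringent CNVs, applying all filters."""
    out: list[StringentCnv] = []
    for group in clusters:
        callers = frozenset(c.caller for c in group)
        if len(callers) < config.min_callers:
            continue
        chrom = group[0].interval.chromosome
        inter_start = max(c.interval.start for c in group)
        inter_end = min(c.interval.end for c in group)
        if inter_end <= inter_start:
            continue  # members connected through a chain but no common core
        consensus = GenomicInterval(chrom, inter_start, inter_end)
        union = GenomicInterval(
            chrom,
            min(c.interval.start for c in group),
            max(c.interval.end for c in group),
        )
        probe_count = max(c.probe_count for c in group)
        if len(consensus) < config.min_size_bp or probe_count < config.min_probes:
            continue
        cns = [c.copy_number for c in group if c.copy_number is not None]
        modal_cn = Counter(cns).most_common(1)[0][0] if cns else None
        out.append(StringentCnv(
            sample_id=group[0].sample_id,
            interval=consensus,
            union_span=union,
            cnv_type=group[0].cnv_type,
            supporting_callers=callers,
            probe_count=probe_count,
            member_calls=tuple(group),
            copy_number=modal_cn,
        ))
    out.sort(key=lambda s: (s.interval.chromosome, s.interval.start, s.cnv_type))
    return out


def stringent_calls_for_sample(calls: list[CnvCall],
                               config: AnalysisConfig) -> list[StringentCnv]:
    return build_stringent_set(cluster_calls(calls, config.concordance_ro), config)
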