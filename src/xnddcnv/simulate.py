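"""Synthetic four-disorder cohort generator.

The simulator emulates the statistical structure the analysis assumes:

* families of configurable structure (proband-only, one-parent duos, trios,
  quartets) with per-disorder frequencies and sex ratios matching the
  published cohort stratification;
* a background of rare CNVs (~2.1 per person, log-normal lengths with a
  ~60 kb median) placed uniformly in the copy-number-stable genome, children
  inheriting each parental CNV with probability 1/2 plus a small true de
  novo rate;
* common copy-number polymorphisms shared with a large control cohort
  (these must fail the 0.1% rarity rule);
* clinically relevant implants at configured per-category prevalences
  (A aneuploidies, B >3 Mb CNVs, C recurrent-disorder loci, D de novo genic
  CNVs in fully genotyped offspring, E inherited NDD-gene CNVs);
* a multi-caller observation model: per-caller sensitivity, breakpoint
  jitter, probe counts from probe density, and single-caller false-positive
  calls;
* an optional genomic-instability effect multiplying the background CNV
  rate of GIG-CNV carriers.

Everything is drawn from one seeded generator, so a fixed seed reproduces
the cohort exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .annotate import GeneIndex, GeneModel, Transcript, annotate_gene_impact
from .genome import GenomicInterval, load_default_cytobands, reciprocal_overlap
from .io_formats import (DEL, DUP, FEMALE, MALE, AnalysisConfig, CnvCall,
                         ControlSet, PedigreeRecord)
from .prioritize import DisorderLocus, load_default_loci

#: family-structure mix per disorder: (proband_only, duo, trio, quartet)
STRUCTURE_MIX = {
    "ASD": (0.68, 0.05, 0.19, 0.08),
    "ADHD": (1.0, 0.0, 0.0, 0.0),
    "SCZ": (0.76, 0.18, 0.06, 0.0),
    "OCD": (0.22, 0.03, 0.75, 0.0),
}
DISORDER_FRACTIONS = {"ASD": 0.683, "ADHD": 0.159, "OCD": 0.082, "SCZ": 0.076}
SEX_RATIO = {"ASD": 4.0, "ADHD": 3.7, "SCZ": 2.0, "OCD": 0.9}  # male:female


@dataclass
class SimulationConfig:
    n_cases: int = 1000
    disorder_fractions: dict = field(default_factory=lambda: dict(DISORDER_FRACTIONS))
    structure_mix: dict = field(default_factory=lambda: dict(STRUCTURE_MIX))
    sex_ratio: dict = field(default_factory=lambda: dict(SEX_RATIO))
    background_cnv_rate: float = 2.1
    de_novo_background_rate: float = 0.05
    length_log_median_bp: float = 60_000.0
    length_log_sigma: float = 0.8
    max_background_bp: int = 2_900_000
    category_prevalence: dict = field(default_factory=lambda: {
        "A": 0.006, "B": 0.0085, "C": 0.043, "D": 0.056, "E": 0.044,
    })
    callers: tuple[str, ...] = ("chas", "ipattern", "nexus", "partek")
    caller_sensitivity: float = 0.9
    parental_caller_sensitivity: Optional[float] = None  # None -> same
    breakpoint_jitter_sd: float = 2_000.0
    false_positive_rate: float = 0.5       # per sample per caller
    probe_density_per_kb: float = 0.25     # 5 probes ~ 20 kb
    n_controls: int = 10_851
    control_cnv_rate: float = 2.1
    n_common_sites: int = 120
    common_site_freq: tuple[float, float] = (0.005, 0.05)
    n_genes: int = 400
    n_ndd_genes: int = 60
    n_gig_genes: int = 40
    lncrna_fraction: float = 0.15
    gig_effect_multiplier: float = 1.0
    n_fragile_sites: int = 30
    variable_genome_fraction: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for k, v in self.category_prevalence.items():
            if not 0 <= v <= 1:
                raise ValueError(f"prevalence {k}={v} outside [0, 1]")
        if self.background_cnv_rate < 0 or self.false_positive_rate < 0:
            raise ValueError("rates must be non-negative")
        for d, mix in self.structure_mix.items():
            if abs(sum(mix) - 1) > 1e-9:
                raise ValueError(f"structure mix for {d} must sum to 1")


@dataclass
class TrueCnv:
    sample_id: str
    interval: GenomicInterval
    cnv_type: str
    label: str                    # A/B/C/D/E implant, background, common
    inherited_from: Optional[str] = None  # parent sample id
    de_novo: bool = False
    locus: Optional[str] = None


@dataclass
class Truth:
    config: SimulationConfig
    pedigree: list[PedigreeRecord]
    cnvs: list[TrueCnv]
    genes: GeneIndex
    loci: list[DisorderLocus]
    variable_regions: list[GenomicInterval]
    fragile_sites: list[GenomicInterval]
    chromosome_length: dict[str, int]
    common_sites: list[tuple[GenomicInterval, str, float]] = field(default_factory=list)
    implant_carriers: dict[str, set[str]] = field(default_factory=dict)

    def cnvs_of(self, sample_id: str) -> list[TrueCnv]:
        return [c for c in self.cnvs if c.sample_id == sample_id]


# --------------------------------------------------------------------------
# genome scaffolding
# --------------------------------------------------------------------------

def _random_interval(rng, chrom_lengths: dict[str, int], size: int,
                     chrom: str | None = None) -> GenomicInterval:
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], float)
    if chrom is None:
        chrom = chroms[rng.choice(len(chroms), p=weights / weights.sum())]
    L = chrom_lengths[chrom]
    size = min(size, L - 1)
    start = int(rng.integers(0, L - size))
    return GenomicInterval(chrom, start, start + size)


def synthesize_genes(config: SimulationConfig, rng,
                     chrom_lengths: dict[str, int]) -> GeneIndex:
    """A deterministic random gene set with NDD/GIG/lncRNA/brain flags."""
    genes = []
    n = config.n_genes
    ndd_ids = set(range(config.n_ndd_genes))
    gig_ids = set(range(config.n_ndd_genes, config.n_ndd_genes + config.n_gig_genes))
    for i in range(n):
        span_len = int(np.exp(rng.normal(math.log(80_000), 1.0)))
        span_len = max(5_000, min(span_len, 2_000_000))
        span = _random_interval(rng, chrom_lengths, span_len)
        is_lnc = (i not in ndd_ids and i not in gig_ids
                  and rng.random() < config.lncrna_fraction)
        n_ex = max(2, min(8, span_len // 40_000 + 2))
        ex_len = max(150, span_len // (4 * n_ex))
        gap = (span_len - n_ex * ex_len) // max(1, n_ex - 1)
        exons = []
        pos = span.start
        for _ in range(n_ex):
            exons.append(GenomicInterval(span.chromosome, pos, pos + ex_len))
            pos += ex_len + gap
        cds = () if is_lnc else tuple(exons[1:])
        genes.append(GeneModel(
            gene_id=f"G{i:04d}",
            symbol=f"G{i:04d}",
            span=span,
            transcripts=(Transcript(f"G{i:04d}-t1", tuple(exons), cds),),
            pli=float(np.clip(rng.beta(0.4, 0.4), 0, 1)),
            brain_expressed=bool(rng.random() < 0.6),
            is_ndd=i in ndd_ids,
            is_gig=i in gig_ids,
            is_lncrna=is_lnc,
        ))
    return GeneIndex(genes)


class RegionMask:
    """Fast any-overlap test against a set of intervals."""

    def __init__(self, regions: list[GenomicInterval] = ()):
        from intervaltree import IntervalTree
        self._trees: dict[str, "IntervalTree"] = {}
        self._IntervalTree = IntervalTree
        for r in regions:
            self.add(r)

    def add(self, r: GenomicInterval) -> None:
        self._trees.setdefault(r.chromosome, self._IntervalTree()).addi(r.start, r.end)

    def hits(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.chromosome)
        return bool(tree is not None and tree.overlap(iv.start, iv.end))


def _forbidden_regions(genes: GeneIndex, loci) -> list[GenomicInterval]:
    """Regions background CNVs must avoid: NDD genes and disorder loci."""
    out = [l.critical_region for l in loci]
    for g in genes.genes.values():
        if g.is_ndd:
            out.append(g.span)
    return out


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> Truth:
    rng = np.random.default_rng(config.seed)
    bands = load_default_cytobands()
    chrom_lengths = dict(bands.chromosome_length)
    loci = load_default_loci()
    genes = synthesize_genes(config, rng, chrom_lengths)
    # variable (copy-number-polymorphic) genome avoids every gene span and
    # locus so that implants and genic CNVs stay in stable territory
    gene_mask = RegionMask([l.critical_region for l in loci]
                           + [g.span for g in genes.genes.values()])
    variable_regions = []
    target = config.variable_genome_fraction * sum(chrom_lengths.values())
    acc = 0
    while acc < target:
        size = int(np.exp(rng.normal(math.log(150_000), 0.7)))
        iv = _random_interval(rng, chrom_lengths, size)
        if not gene_mask.hits(iv):
            variable_regions.append(iv)
            acc += size
    fragile_sites = []
    for _ in range(config.n_fragile_sites):
        size = int(rng.integers(1_000_000, 3_000_000))
        fragile_sites.append(_random_interval(rng, chrom_lengths, size))

    common_sites = []
    lo, hi = config.common_site_freq
    for _ in range(config.n_common_sites):
        size = int(np.exp(rng.normal(math.log(80_000), 0.6)))
        iv = _random_interval(rng, chrom_lengths, size)
        if gene_mask.hits(iv):
            continue
        common_sites.append((iv, DEL if rng.random() < 0.5 else DUP,
                             float(rng.uniform(lo, hi))))
    # the variable map should catch the polymorphic sites
    variable_regions.extend(iv for iv, _, _ in common_sites)
    # rare background and implanted CNVs must avoid NDD genes, loci and the
    # variable genome
    avoid = RegionMask(_forbidden_regions(genes, loci) + variable_regions)

    pedigree: list[PedigreeRecord] = []
    cnvs: list[TrueCnv] = []
    implant_carriers: dict[str, set[str]] = {k: set() for k in "ABCDE"}

    def draw_len() -> int:
        L = int(np.exp(rng.normal(math.log(config.length_log_median_bp),
                                  config.length_log_sigma)))
        return max(20_000, min(L, config.max_background_bp))

    def background_set(sample_id: str, rate: float) -> list[TrueCnv]:
        out = []
        for _ in range(rng.poisson(rate)):
            for _attempt in range(50):
                iv = _random_interval(rng, chrom_lengths, draw_len())
                if not avoid.hits(iv):
                    break
            out.append(TrueCnv(sample_id, iv, DEL if rng.random() < 0.5 else DUP,
                               "background"))
        return out

    def common_set(sample_id: str) -> list[TrueCnv]:
        out = []
        for iv, cnv_type, freq in common_sites:
            if rng.random() < freq:
                out.append(TrueCnv(sample_id, iv, cnv_type, "common"))
        return out

    def apply_gig_multiplier(sample_id: str, own: list[TrueCnv]) -> list[TrueCnv]:
        if config.gig_effect_multiplier <= 1.0:
            return own
        carries_gig = any(
            any(genes[i.gene_id].is_gig and i.impact_class == "cds_disrupted"
                for i in annotate_gene_impact(c.interval, c.cnv_type, genes))
            for c in own
        )
        if carries_gig:
            extra_rate = config.background_cnv_rate * (config.gig_effect_multiplier - 1)
            own = own + background_set(sample_id, extra_rate)
        return own

    disorders = list(config.disorder_fractions)
    probs = np.array([config.disorder_fractions[d] for d in disorders], float)
    probs = probs / probs.sum()
    structures = ("proband", "duo", "trio", "quartet")

    fam_no = 0
    n_made = 0
    while n_made < config.n_cases:
        fam_no += 1
        disorder = disorders[rng.choice(len(disorders), p=probs)]
        mix = config.structure_mix[disorder]
        structure = structures[rng.choice(4, p=np.array(mix) / sum(mix))]
        n_children = 2 if structure == "quartet" else 1
        n_children = min(n_children, config.n_cases - n_made)
        fam = f"F{fam_no:05d}"
        father = mother = None
        parent_cnvs: dict[str, list[TrueCnv]] = {}
        if structure in ("trio", "quartet") or structure == "duo":
            if structure == "duo":
                which = rng.random() < 0.5
                father = f"{fam}-fa" if which else None
                mother = None if which else f"{fam}-mo"
            else:
                father, mother = f"{fam}-fa", f"{fam}-mo"
        for pid, sex in ((father, MALE), (mother, FEMALE)):
            if pid is None:
                continue
            pedigree.append(PedigreeRecord(fam, pid, None, None, sex,
                                           "unaffected", None))
            own = background_set(pid, config.background_cnv_rate) + common_set(pid)
            own = apply_gig_multiplier(pid, own)
            parent_cnvs[pid] = own
            cnvs.extend(own)

        ratio = config.sex_ratio[disorder]
        p_male = ratio / (1 + ratio)
        for ci in range(n_children):
            sid = f"{fam}-p{ci + 1}"
            sex = MALE if rng.random() < p_male else FEMALE
            pedigree.append(PedigreeRecord(fam, sid, father, mother, sex,
                                           "case", disorder))
            n_made += 1
            own: list[TrueCnv] = []
            if parent_cnvs:
                for pid, plist in parent_cnvs.items():
                    for c in plist:
                        if c.label in ("background", "common") and rng.random() < 0.5:
                            own.append(TrueCnv(sid, c.interval, c.cnv_type,
                                               c.label, inherited_from=pid))
                for t in background_set(sid, config.de_novo_background_rate):
                    t.de_novo = True
                    own.append(t)
            else:
                own = background_set(sid, config.background_cnv_rate) + common_set(sid)
            own = apply_gig_multiplier(sid, own)

            prev = config.category_prevalence
            if rng.random() < prev["A"]:
                own.append(_implant_aneuploidy(rng, sid, sex, chrom_lengths))
                implant_carriers["A"].add(sid)
            if rng.random() < prev["B"]:
                size = int(rng.integers(3_200_000, 8_000_000))
                locus_mask = RegionMask([l.critical_region for l in loci])
                for _ in range(50):
                    iv = _random_interval(rng, chrom_lengths, size)
                    if not locus_mask.hits(iv) and _variable_fraction_ok(
                            iv, variable_regions):
                        break
                t = TrueCnv(sid, iv, DEL if rng.random() < 0.5 else DUP, "B")
                t.de_novo = bool(father and mother)
                own.append(t)
                implant_carriers["B"].add(sid)
            if rng.random() < prev["C"]:
                locus = loci[rng.integers(len(loci))]
                r = locus.critical_region
                jit = int(rng.normal(0, 10_000))
                iv = GenomicInterval(r.chromosome, max(0, r.start + jit), r.end + abs(jit))
                t = TrueCnv(sid, iv, locus.expected_type, "C", locus=locus.name)
                if father and mother and rng.random() < 0.3:
                    t.de_novo = True
                elif parent_cnvs:
                    pid = sorted(parent_cnvs)[int(rng.integers(len(parent_cnvs)))]
                    pc = TrueCnv(pid, iv, t.cnv_type, "C", locus=locus.name)
                    parent_cnvs[pid].append(pc)
                    cnvs.append(pc)
                    t.inherited_from = pid
                own.append(t)
                implant_carriers["C"].add(sid)
            if father and mother and rng.random() < prev["D"]:
                own.append(_implant_genic(rng, sid, genes, chrom_lengths,
                                          label="D", de_novo=True, ndd=False,
                                          avoid=avoid))
                implant_carriers["D"].add(sid)
            if rng.random() < prev["E"]:
                t = _implant_genic(rng, sid, genes, chrom_lengths,
                                   label="E", de_novo=False, ndd=True,
                                   avoid=avoid)
                if parent_cnvs:
                    pid = sorted(parent_cnvs)[int(rng.integers(len(parent_cnvs)))]
                    pc = TrueCnv(pid, t.interval, t.cnv_type, "E")
                    parent_cnvs[pid].append(pc)
                    cnvs.append(pc)
                    t.inherited_from = pid
                own.append(t)
                implant_carriers["E"].add(sid)
            cnvs.extend(own)

    return Truth(config=config, pedigree=pedigree, cnvs=cnvs, genes=genes,
                 loci=loci, variable_regions=variable_regions,
                 fragile_sites=fragile_sites, chromosome_length=chrom_lengths,
                 common_sites=common_sites, implant_carriers=implant_carriers)


def _implant_aneuploidy(rng, sid: str, sex: str,
                        chrom_lengths: dict[str, int]) -> TrueCnv:
    if sex == MALE:
        kind = ("XXY", "XYY", "T21")[rng.integers(3)]
    else:
        kind = ("45X", "T21")[rng.integers(2)]
    chrom, cnv_type = {
        "XXY": ("X", DUP), "XYY": ("Y", DUP), "T21": ("21", DUP), "45X": ("X", DEL),
    }[kind]
    iv = GenomicInterval(chrom, 0, chrom_lengths[chrom])
    t = TrueCnv(sid, iv, cnv_type, "A")
    t.de_novo = True
    return t


def _implant_genic(rng, sid: str, genes: GeneIndex,
                   chrom_lengths: dict[str, int], label: str,
                   de_novo: bool, ndd: bool, avoid=None) -> TrueCnv:
    pool = sorted((g for g in genes.genes.values()
                   if (g.is_ndd if ndd else (not g.is_ndd and not g.is_lncrna))),
                  key=lambda g: g.gene_id)
    for _attempt in range(30):
        gene = pool[int(rng.integers(len(pool)))]
        target = gene.transcripts[0].cds[0] if gene.transcripts[0].cds else gene.span
        size = int(rng.integers(50_000, 800_000))
        mid = (target.start + target.end) // 2
        L = chrom_lengths[target.chromosome]
        start = max(0, min(mid - size // 2, L - size))
        iv = GenomicInterval(target.chromosome, start, start + size)
        # NDD genes are clear of the variable map by construction; for other
        # genes retry until the implant avoids variable/locus territory
        if ndd or avoid is None or not avoid.hits(iv):
            break
    t = TrueCnv(sid, iv, DEL if rng.random() < 0.5 else DUP, label)
    t.de_novo = de_novo
    return t


def _variable_fraction_ok(iv: GenomicInterval,
                          variable_regions: list[GenomicInterval],
                          max_fraction: float = 0.10) -> bool:
    from .genome import coverage_fraction
    if not variable_regions:
        return True
    return coverage_fraction(iv, variable_regions) <= max_fraction


# --------------------------------------------------------------------------
# observation model
# --------------------------------------------------------------------------

def simulate_observations(truth: Truth, seed: int | None = None
                          ) -> tuple[dict[str, list[CnvCall]], ControlSet]:
    """Per-caller raw call lists plus the simulated control cohort."""
    config = truth.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    cases = {p.sample_id for p in truth.pedigree if p.affected == "case"}
    sens_parent = (config.parental_caller_sensitivity
                   if config.parental_caller_sensitivity is not None
                   else config.caller_sensitivity)
    calls: dict[str, list[CnvCall]] = {c: [] for c in config.callers}
    samples = sorted({p.sample_id for p in truth.pedigree})
    by_sample: dict[str, list[TrueCnv]] = {}
    for t in truth.cnvs:
        by_sample.setdefault(t.sample_id, []).append(t)

    for sid in samples:
        sens = config.caller_sensitivity if sid in cases else sens_parent
        for t in by_sample.get(sid, ()):
            for caller in config.callers:
                if rng.random() >= sens:
                    continue
                j1 = int(rng.normal(0, config.breakpoint_jitter_sd))
                j2 = int(rng.normal(0, config.breakpoint_jitter_sd))
                L = truth.chromosome_length[t.interval.chromosome]
                start = max(0, min(t.interval.start + j1, L - 1_000))
                end = max(start + 1_000, min(t.interval.end + j2, L))
                iv = GenomicInterval(t.interval.chromosome, start, end)
                calls[caller].append(CnvCall(
                    sample_id=sid, interval=iv, cnv_type=t.cnv_type,
                    caller=caller,
                    probe_count=max(1, round(len(iv) / 1000 * config.probe_density_per_kb)),
                ))
        # single-caller false positives
        for caller in config.callers:
            for _ in range(rng.poisson(config.false_positive_rate)):
                size = max(20_000, int(np.exp(rng.normal(math.log(40_000), 0.5))))
                iv = _random_interval(rng, truth.chromosome_length, size)
                calls[caller].append(CnvCall(
                    sample_id=sid, interval=iv,
                    cnv_type=DEL if rng.random() < 0.5 else DUP,
                    caller=caller,
                    probe_count=max(1, round(len(iv) / 1000 * config.probe_density_per_kb)),
                ))

    control_cnvs: list[tuple[GenomicInterval, str, str]] = []
    forbidden_mask = RegionMask(_forbidden_regions(truth.genes, truth.loci))
    common_sites = [(iv, t) for iv, t, _f in truth.common_sites]
    freqs = {iv: f for iv, _t, f in truth.common_sites}
    for i in range(config.n_controls):
        cid = f"CTRL{i:05d}"
        for _ in range(rng.poisson(config.control_cnv_rate)):
            size = max(20_000, int(np.exp(rng.normal(
                math.log(config.length_log_median_bp), config.length_log_sigma))))
            for _attempt in range(50):
                iv = _random_interval(rng, truth.chromosome_length,
                                      min(size, config.max_background_bp))
                if not forbidden_mask.hits(iv):
                    break
            control_cnvs.append((iv, DEL if rng.random() < 0.5 else DUP, cid))
        for iv, cnv_type in common_sites:
            if rng.random() < freqs[iv]:
                control_cnvs.append((iv, cnv_type, cid))
    controls = ControlSet(cnvs=control_cnvs, n_controls=config.n_controls)
    return calls, controls
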