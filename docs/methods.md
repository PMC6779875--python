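# Methods

`xnddcnv` implements a cross-disorder rare copy-number-variant (CNV)
analysis for neurodevelopmental-disorder (NDD) cohorts — autism spectrum
disorder (ASD), attention deficit hyperactivity disorder (ADHD),
obsessive-compulsive disorder (OCD) and schizophrenia (SCZ) — from raw
multi-algorithm microarray calls through clinical prioritization and burden
statistics. This note documents the models, the defaults and the reasoning
behind design choices the source material left open.

## Coordinate model

All intervals are 0-based half-open on GRCh37; 1-based inclusive
coordinates are converted at the I/O boundary. Reciprocal overlap (RO),
`min(ovl/len(a), ovl/len(b))`, is the single symmetric match criterion used
for caller concordance, control matching, parental-origin matching and
genomic-disorder locus matching. The packaged cytoband table carries the
exact GRCh37 contig lengths; band boundaries are rounded to ~100 kb and a
few neighbouring sub-bands are merged, which is sufficient for karyotype
parsing and whole-chromosome arithmetic but not for base-accurate band
assignment. Band lookup uses ISCN prefix semantics (`3p14` is the union of
`3p14.1`–`3p14.3`). A karyotype band range such as `del(3)(p14.1p13)` names
the *breakpoint* bands; the resolved span is therefore an upper bound on
the CNV size, never an estimate of it.

## Stringent consensus calls

Raw calls from the four detection algorithms are clustered per sample and
per (chromosome, DEL/DUP) as connected components of the RO >= 0.5 graph,
keeping at most one call per algorithm per cluster (ties resolved toward
the cluster seed). A cluster becomes a *stringent* CNV when it has >= 2
distinct algorithms, an intersection >= 20 kb and >= 5 supporting probes
(maximum over members). Consensus coordinates are the member intersection —
the conservative choice, since the intersection cannot extend past any
caller's evidence — while the union span is retained for the matching
steps, which tolerate breakpoint jitter better with the wider interval.
The concordance threshold RO = 0.5 is the field's conventional value; the
source pipeline does not print one. DEL and DUP never merge; copy-number
levels within a type do (modal copy number kept).

## Rarity

A stringent CNV is *rare* when (i) its control carrier frequency is
<= 0.1% — carriers are distinct control individuals among 10,851 whose
same-type CNVs match at RO >= 0.5 — and (ii) >= 75% of it lies in the
copy-number-stable genome. The stable map is supplied as its complement
(a BED of copy-number-variable regions), because published population maps
enumerate the variable regions. Carrier frequency (not CNV frequency) is
used so that several CNVs in one control count once.

## Gene impact

Genes are held as span + transcripts (exons, CDS). Per (CNV, gene) the
impact class is `cds_disrupted` (>= 1 coding base), else `exon_only` (UTR
or lncRNA exons), else `span_only`. A duplication containing a gene's
*longest transcript* end-to-end is additionally `full_transcript_duplicated`;
"longest" means maximal genomic span (ties: summed exon length, then
transcript id), since the source phrase "full transcript length" does not
define length. Strand is ignored — CNVs are unstranded.

## Inheritance and aneuploidy

A case CNV is maternal/paternal when a same-type parental stringent CNV
matches at RO >= 0.5 (both parents matching reports the higher-RO parent,
flagged biparental); *de novo* only when both parents are genotyped and
neither matches; *unknown* otherwise — so a cohort with no genotyped
parents (the ADHD arm) can never produce a false de novo. Hemizygous male
X CNVs use the same rule. A chromosome is called aneuploid when merged
same-type calls cover >= 90% of its length (the threshold tolerates
acrocentric and centromeric probe deserts); karyotype labels follow
chromosome, direction and sex (X gain in a male -> 47,XXY; X loss in a
female -> 45,X; Y gain -> 47,XYY; chr21 gain -> trisomy 21). Mosaic input
flags propagate to the call without level estimation.

## Five-category prioritization

* **A** — aneuploidies.
* **C** — CNVs consistent with a known recurrent genomic disorder: the
  type-compatible packaged locus with maximal RO >= 0.5 against the union
  span. The packaged list uses published critical regions
  (DECIPHER/ClinGen-style, rounded); for 16p13.11 both the canonical and
  the LCR-extended (into p12.3) regions are listed because the observed
  events span a fourfold size range no single region can match at RO 0.5.
* **B** — remaining CNVs > 3 Mb.
* **D** — de novo CNVs impacting >= 1 gene; additive on top of A–C, since
  the source counts de novo aneuploidies, large CNVs and locus CNVs in its
  de novo category.
* **E** — the remainder with a coding hit in a curated NDD gene and
  non-de-novo origin. For configured exception genes (*MBD5*,
  *PTCHD1-AS*), non-coding exon hits qualify (the source flags UTR-exon
  events in these genes; *PTCHD1-AS* is a lncRNA with no CDS at all).

Precedence A > C > B was chosen because it reproduces the published
separation of a 12.5 Mb 22q11.21-q12.3 duplication (category B; RO with the
~2.6 Mb 22q11.21 region is ~0.2) from bona fide 22q11.21 duplications
(category C), and keeps the 4.9–6.2 Mb 15q11-q13 duplications in C rather
than B. Clinical tiers (CS/LCS/VUS/LB/B) come from expert review whenever
supplied; otherwise a clearly-labelled heuristic stands in (A -> CS, C
deletion -> CS / duplication -> LCS, B -> LCS, D -> LCS if an NDD-gene CDS
is hit else VUS, E -> VUS). The heuristic is a triage aid, not an ACMG
evidence engine.

## Cross-disorder recurrence and fragile sites

The recurrence scan covers rare CNVs of 20 kb–3 Mb, excluding
locus-matched CNVs, and counts distinct cases per gene: deletions
disrupting the CDS of brain-expressed, LoF-constrained genes (pLI strictly
> 0.45; missing pLI fails), and duplications containing a brain-expressed
gene's full longest transcript. Related cases count individually by
default (published counts include twin pairs); `dedup_family` collapses
same-family cases to one unit. De novo CNVs (aneuploidies excluded) are
intersected with fragile-site regions at any-overlap (>= 1 bp), and genes
with genomic span > 300 kb touched by a de novo CNV are reported as long
genes.

## Burden statistics

Controls are parents of cases. The burden model is a logistic regression
of case status on a per-sample gene-hit count (protein-coding CDS hits or
lncRNA exon hits, DEL/DUP separately, optionally brain-expressed only),
adjusted for sex, the first three ancestry principal components and total
rare-CNV length; multivariate fits include several hit counts jointly.
Perfect separation and singular designs are detected and reported as
errors rather than fitted. Group comparisons of CNV counts and cumulative
lengths use the two-sided Mann-Whitney U test (exact null for both groups
<= 8, normal approximation with tie correction otherwise) — a rank test
was chosen because cumulative CNV length is heavy-tailed. Carrier
enrichment uses Fisher's exact test; the odds ratio is the conditional
maximum-likelihood estimate with the exact (conditional-distribution
inversion) 95% CI, the convention that pairs with an exact test. Multiple
testing across the univariate burden family uses Benjamini–Hochberg;
summaries flag 0.05 < p < 0.1 as nearly significant, mirroring the
reporting convention of the source cohort.

The genomic-instability (GIG) analysis runs: case-control GIG-CNV carriage;
rank tests of CNV count and cumulative length between GIG carriers and
non-carriers among cases with the GIG-CNVs themselves removed from the
measure; NDD-CNV x GIG-CNV enrichment with a sensitivity rerun excluding
aneuploid samples and samples where one CNV supplies both flags; and a
parent-carrier comparison excluding cases with de novo GIG-CNVs.

## Synthetic cohorts

The simulator's defaults are the study conditions: 1,000 cases split
0.683/0.159/0.082/0.076 across ASD/ADHD/OCD/SCZ with the published
family-structure mixes (ADHD entirely proband-only; OCD mostly trios) and
sex ratios (4.0/3.7/0.9/2.0 male:female); background rare-CNV rate 2.1 per
person with log-normal lengths (median 60 kb, sigma 0.8, capped at
2.9 Mb); category prevalences A 0.006, B 0.0085, C 0.043, D 0.056 (among
fully genotyped offspring, matching how the de novo rate is measured) and
E 0.044; four callers at sensitivity 0.9 with 2 kb breakpoint jitter,
probe density 0.25/kb (five probes ~ 20 kb) and 0.5 single-caller false
positives per sample per caller; 10,851 controls; ~120 common
polymorphic sites at 0.5–5% frequency shared between cohort and controls.
Children inherit each parental background CNV with probability 1/2 plus a
small true de novo background (0.05/child). Background CNVs and implants
avoid NDD genes, disorder loci and the variable genome so that implanted
category prevalences are identifiable; polymorphic sites form most of the
variable map. An optional multiplier inflates the background rate of
GIG-CNV carriers to emulate a genomic-instability effect. Everything
derives from one seeded generator.

What the simulation does *not* emulate: caller-specific biases beyond
sensitivity/jitter/false positives, array intensity or B-allele data,
population structure in the principal components, mosaicism, and linkage
between loci. Green simulation tests therefore certify the pipeline's
logic under the stated generative model, not performance on real arrays.

## The packaged clinical-CNV fixture

The 306-record fixture transcribes the published clinical-significance
table row by row (cytoband, type, size range, per-row sex/disorder/
tier/origin multisets) and expands it to per-subject records with
deterministic coordinates: whole-chromosome for aneuploidies, cytoband
anchored for karyotype rows, critical-region centred for recurrent-disorder
rows and first-coding-exon centred for gene rows (sizes within a printed
range are evenly spaced; only counts, never sizes, are validated).
Multi-CNV case linkage (12 ASD, 3 ADHD, 3 OCD, 1 SCZ multi-CNV cases plus
one case holding two de novo 21q22.3 duplications) follows the cohort
narrative; the few pairs whose identities were not narrated are
reconstructed to satisfy the published per-disorder CNV and unique-case
totals, and are labelled as reconstructed in the data file. Published
section labels are stored separately as expected values and never reach
the classifier. Known transcription reconciliations (a one-subject
undercount in one section, two cytoband typos, the ADHD multi-CNV case
count) are documented in the data file headers. The gene models packaged
with the fixture are synthetic: spans approximate the named genes' true
GRCh37 loci, but exon/CDS structure is generated.

## Numerical and degenerate-input conventions

Zero-length or inverted intervals are rejected at construction, never
clamped. Empty control sets make every CNV rare; a zero-sized control
cohort is an error. A Fisher table with a zero margin returns p = 1 with
the odds ratio flagged undefined. Rank tests require two non-empty groups.
Cluster tie-breaks are deterministic (seed = earliest-starting call;
larger seed overlap, then earlier start, wins within a caller). All
outputs are byte-identical across reruns with the same inputs, config and
seed.

## Problem sizes used in validation

The test suite and acceptance checks run the classifier on the full
306-record fixture; simulation checks use 1,000-case cohorts with the full
10,851-control panel; calibration uses 500 permuted-label regressions and
200 effect-recovery replicates at n = 2,000; exact-test oracles enumerate
all 2x2 tables up to total 20 plus randomized larger tables, and all rank
configurations for group sizes up to 8.

## Known limitations

Real caller output formats are not parsed (a unified TSV contract is the
input); uniparental disomy, mosaic-level estimation and liftover are out
of scope; the heuristic tier is not an ACMG engine; the cytoband table is
approximate away from chromosome ends; recurrence significance is
reported as counts, not tests.
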