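"""Gene models and CNV gene-impact annotation.

Impact classes per (CNV, gene):

* ``cds_disrupted`` -- the CNV overlaps >=1 coding base of any transcript;
* ``exon_only`` -- exonic but not coding overlap (UTRs, lncRNA exons);
* ``span_only`` -- intronic/span overlap only;
* ``full_transcript_duplicated`` -- a duplication containing the gene's
  longest transcript end to end (recorded alongside ``cds_disrupted`` for
  coding genes).

"Longest transcript" means maximal genomic span, ties broken by summed exon
length then transcript id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Optional

from intervaltree import IntervalTree

from .genome import GenomicInterval, normalize_chromosome

CDS_DISRUPTED = "cds_disrupted"
EXON_ONLY = "exon_only"
SPAN_ONLY = "span_only"
FULL_DUP = "full_transcript_duplicated"


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.exons[0].chromosome,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
        )

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    span: GenomicInterval
    transcripts: tuple[Transcript, ...]
    pli: Optional[float] = None
    brain_expressed: bool = False
    is_ndd: bool = False
    is_gig: bool = False
    is_lncrna: bool = False

    def __post_init__(self) -> None:
        for t in self.transcripts:
            if self.is_lncrna and t.cds:
                raise AnnotationError(f"lncRNA gene {self.gene_id} has CDS features")
            for e in t.exons:
                if not self.span.contains(e):
                    raise AnnotationError(
                        f"exon {e} outside gene span of {self.gene_id}"
                    )

    @property
    def longest_transcript(self) -> Transcript:
        return max(
            self.transcripts,
            key=lambda t: (len(t.span), t.exonic_length, t.transcript_id),
        )

    @property
    def pli_constrained(self) -> bool:
        """Strictly above the 0.45 LoF-constraint cut; missing pLI fails."""
        return self.pli is not None and self.pli > 0.45


@dataclass(frozen=True)
class GeneImpact:
    gene_id: str
    impact_class: str
    cnv_type: str
    full_transcript_duplicated: bool = False


class GeneIndex:
    """Genes indexed by chromosome for interval queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise AnnotationError(f"duplicate gene id {g.gene_id}")
            self.genes[g.gene_id] = g
            self._trees.setdefault(g.span.chromosome, IntervalTree()).addi(
                g.span.start, g.span.end, g.gene_id
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def by_symbol(self, symbol: str) -> GeneModel:
        for g in self.genes.values():
            if g.symbol == symbol:
                return g
        raise KeyError(symbol)

    def overlapping(self, iv: GenomicInterval) -> list[GeneModel]:
        tree = self._trees.get(iv.chromosome)
        if tree is None:
            return []
        return sorted(
            (self.genes[hit.data] for hit in tree.overlap(iv.start, iv.end)),
            key=lambda g: (g.span.start, g.gene_id),
        )


def _overlaps_any(iv: GenomicInterval, parts: Iterable[GenomicInterval]) -> bool:
    return any(iv.overlaps(p) for p in parts)


def annotate_gene_impact(cnv_interval: GenomicInterval, cnv_type: str,
                         genes: GeneIndex) -> list[GeneImpact]:
    """Classify the impact of one CNV on every overlapped gene."""
    impacts: list[GeneImpact] = []
    for gene in genes.overlapping(cnv_interval):
        cds_hit = any(
            _overlaps_any(cnv_interval, t.cds) for t in gene.transcripts
        )
        exon_hit = cds_hit or any(
            _overlaps_any(cnv_interval, t.exons) for t in gene.transcripts
        )
        full_dup = (
            cnv_type == "DUP"
            and cnv_interval.contains(gene.longest_transcript.span)
        )
        if cds_hit:
            klass = CDS_DISRUPTED
        elif exon_hit:
            klass = EXON_ONLY
        else:
            klass = SPAN_ONLY
        impacts.append(GeneImpact(
            gene_id=gene.gene_id,
            impact_class=klass,
            cnv_type=cnv_type,
            full_transcript_duplicated=full_dup,
        ))
    return impacts


def gene_flag_filter(impacts: Iterable[GeneImpact], genes: GeneIndex,
                     require: Callable[[GeneModel], bool]) -> list[GeneImpact]:
    """Keep impacts whose gene satisfies ``require`` (e.g. brain + pLI>0.45)."""
    out = []
    for imp in impacts:
        if imp.gene_id not in genes.genes:
            raise AnnotationError(f"impact references unknown gene {imp.gene_id}")
        if require(genes[imp.gene_id]):
            out.append(imp)
    return out


# --------------------------------------------------------------------------
# GFF3 + flags loading
# --------------------------------------------------------------------------

def _parse_attrs(s: str) -> dict:
    out = {}
    for part in s.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_models(gff_path, flags_path=None) -> GeneIndex:
    """Load genes from GFF3 (gene/transcript/exon/CDS) plus a flags table.

    Genes absent from the flags table get all-false flags and missing pLI.
    A transcript referencing an unknown gene is a structure error.
    """
    genes_raw: dict[str, dict] = {}
    tx_parent: dict[str, str] = {}
    tx_feats: dict[str, dict[str, list[GenomicInterval]]] = {}

    with open(gff_path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise AnnotationError(f"malformed GFF3 line: {line[:80]!r}")
            chrom, _src, ftype, start1, end1, _score, _strand, _phase, attrs = f
            a = _parse_attrs(attrs)
            iv = GenomicInterval(chrom, int(start1) - 1, int(end1))
            if ftype in ("gene", "lncRNA_gene", "ncRNA_gene", "pseudogene"):
                gid = a["ID"]
                genes_raw[gid] = {
                    "symbol": a.get("Name", gid),
                    "span": iv,
                    "lnc": a.get("biotype", "") in ("lncRNA", "lincRNA", "ncRNA"),
                }
            elif ftype in ("mRNA", "transcript", "lnc_RNA", "ncRNA"):
                tid, parent = a["ID"], a.get("Parent")
                if parent not in genes_raw:
                    raise AnnotationError(
                        f"transcript {tid} references unknown gene {parent!r}"
                    )
                tx_parent[tid] = parent
                tx_feats[tid] = {"exon": [], "CDS": []}
            elif ftype in ("exon", "CDS"):
                parent = a.get("Parent")
                if parent not in tx_feats:
                    raise AnnotationError(
                        f"{ftype} references unknown transcript {parent!r}"
                    )
                tx_feats[parent][ftype if ftype == "CDS" else "exon"].append(iv)

    flags: dict[str, dict] = {}
    if flags_path is not None:
        with open(flags_path, "rt", encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for line in fh:
                if not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                pli_s = f[idx["pli"]] if "pli" in idx else ""
                flags[f[idx["gene_id"]]] = {
                    "pli": float(pli_s) if pli_s else None,
                    "brain_expressed": f[idx["brain_expressed"]] == "1",
                    "is_ndd": f[idx["is_ndd"]] == "1",
                    "is_gig": f[idx["is_gig"]] == "1",
                    "is_lncrna": f[idx["is_lncrna"]] == "1",
                }

    models = []
    for gid, info in genes_raw.items():
        txs = []
        for tid, parent in tx_parent.items():
            if parent != gid:
                continue
            exons = tuple(sorted(tx_feats[tid]["exon"], key=lambda e: e.start))
            cds = tuple(sorted(tx_feats[tid]["CDS"], key=lambda e: e.start))
            if not exons:
                exons = (info["span"],)
            txs.append(Transcript(tid, exons, cds))
        if not txs:
            txs = [Transcript(f"{gid}-t", (info["span"],), ())]
        fl = flags.get(gid, {})
        is_lnc = fl.get("is_lncrna", info["lnc"])
        models.append(GeneModel(
            gene_id=gid,
            symbol=info["symbol"],
            span=info["span"],
            transcripts=tuple(txs),
            pli=fl.get("pli"),
            brain_expressed=fl.get("brain_expressed", False),
            is_ndd=fl.get("is_ndd", False),
            is_gig=fl.get("is_gig", False),
            is_lncrna=is_lnc,
        ))
    return GeneIndex(models)


def write_gene_models(index: GeneIndex, gff_path, flags_path) -> None:
    """Write a GeneIndex back to GFF3 + flags TSV (inverse of the reader)."""
    with open(gff_path, "wt", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(index.genes):
            g = index[gid]
            gtype = "lncRNA_gene" if g.is_lncrna else "gene"
            bt = "lncRNA" if g.is_lncrna else "protein_coding"
            c = g.span.chromosome
            fh.write(f"{c}\txnddcnv\t{gtype}\t{g.span.start + 1}\t{g.span.end}"
                     f"\t.\t+\t.\tID={gid};Name={g.symbol};biotype={bt}\n")
            for t in g.transcripts:
                ttype = "lnc_RNA" if g.is_lncrna else "mRNA"
                fh.write(f"{c}\txnddcnv\t{ttype}\t{t.span.start + 1}\t{t.span.end}"
                         f"\t.\t+\t.\tID={t.transcript_id};Parent={gid}\n")
                for i, e in enumerate(t.exons, 1):
                    fh.write(f"{c}\txnddcnv\texon\t{e.start + 1}\t{e.end}\t.\t+\t.\t"
                             f"ID={t.transcript_id}-e{i};Parent={t.transcript_id}\n")
                for i, e in enumerate(t.cds, 1):
                    fh.write(f"{c}\txnddcnv\tCDS\t{e.start + 1}\t{e.end}\t.\t+\t0\t"
                             f"ID={t.transcript_id}-c{i};Parent={t.transcript_id}\n")
    with open(flags_path, "wt", encoding="utf-8") as fh:
        fh.write("gene_id\tsymbol\tpli\tbrain_expressed\tis_ndd\tis_gig\tis_lncrna\n")
        for gid in sorted(index.genes):
            g = index[gid]
            pli = "" if g.pli is None else f"{g.pli:.4f}"
            fh.write(f"{gid}\t{g.symbol}\t{pli}\t{int(g.brain_expressed)}"
                     f"\t{int(g.is_ndd)}\t{int(g.is_gig)}\t{int(g.is_lncrna)}\n")


def load_default_gene_models() -> GeneIndex:
    """The packaged synthetic GRCh37 gene set (see data file headers)."""
    data = resources.files("xnddcnv.data")
    with resources.as_file(data.joinpath("gene_models_synthetic.gff3")) as gff, \
            resources.as_file(data.joinpath("gene_flags.tsv")) as fl:
        return read_gene_models(gff, fl)
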