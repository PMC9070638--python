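"""CP/NCP origin classification of single-locus peptide placements.

A peptide is a conventional peptide (CP) when its genomic span lies
entirely within one CDS part of a same-strand gene and is in phase with
that CDS — i.e. it could be a fragment of the annotated protein.
Everything else is a non-conventional peptide (NCP), categorised by the
annotation feature it overlaps most: out-of-frame or antisense CDS
overlap is exonic, then 5'UTR, 3'UTR, intron, upstream (within a window
5' of the gene's TSS, 1 kb by default), downstream (mirrored window), and
finally intergenic when no feature or window is hit.

Ties between equal overlaps break by the fixed precedence
exonic > 5UTR > 3UTR > intron > upstream > downstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .catalog import LocatedPeptide
from .genome import GeneModel, Genome, GenomicInterval

__all__ = [
    "CATEGORIES",
    "OriginCall",
    "GeneIndex",
    "classify_placement",
    "start_codon",
    "classify_all",
]

CATEGORIES = (
    "CP",
    "NCP_exonic",
    "NCP_5UTR",
    "NCP_3UTR",
    "NCP_intron",
    "NCP_upstream",
    "NCP_downstream",
    "NCP_intergenic",
)

# NCP tie-break precedence (lower = wins)
_PRECEDENCE = {
    "NCP_exonic": 0,
    "NCP_5UTR": 1,
    "NCP_3UTR": 2,
    "NCP_intron": 3,
    "NCP_upstream": 4,
    "NCP_downstream": 5,
}


@dataclass(frozen=True)
class OriginCall:
    peptide: str
    category: str
    gene_id: str | None
    overlap_bp: int
    start_codon: str
    is_aug: bool
    strand: str


@dataclass(frozen=True)
class _Feature:
    kind: str  # cds / 5UTR / 3UTR / intron / upstream / downstream
    gene: GeneModel
    cds_part: GenomicInterval | None = None
    phase: int = 0


class GeneIndex:
    """Per-chromosome interval tree over gene features and flank windows."""

    def __init__(self, genes: list[GeneModel], upstream_bp: int = 1000, downstream_bp: int = 1000):
        self.upstream_bp = upstream_bp
        self.downstream_bp = downstream_bp
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self._trees.setdefault(g.interval.chrom, IntervalTree())
            for t in g.transcripts:
                for cds, phase in zip(t.cds, t.phases):
                    tree.addi(cds.start, cds.end, _Feature("cds", g, cds_part=cds, phase=phase))
            for u in g.utr5:
                tree.addi(u.start, u.end, _Feature("5UTR", g))
            for u in g.utr3:
                tree.addi(u.start, u.end, _Feature("3UTR", g))
            for it in g.introns:
                tree.addi(it.start, it.end, _Feature("intron", g))
            for kind, iv in self._flanks(g):
                tree.addi(iv.start, iv.end, _Feature(kind, g))

    def _flanks(self, g: GeneModel):
        iv = g.interval
        if iv.strand == "+":
            up = (max(0, iv.start - self.upstream_bp), iv.start)
            down = (iv.end, iv.end + self.downstream_bp)
        else:
            up = (iv.end, iv.end + self.upstream_bp)
            down = (max(0, iv.start - self.downstream_bp), iv.start)
        if up[0] < up[1]:
            yield "upstream", GenomicInterval(iv.chrom, up[0], up[1], iv.strand)
        if down[0] < down[1]:
            yield "downstream", GenomicInterval(iv.chrom, down[0], down[1], iv.strand)

    def query(self, iv: GenomicInterval) -> list[tuple[_Feature, int]]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        out = []
        for hit in tree.overlap(iv.start, iv.end):
            width = min(hit.end, iv.end) - max(hit.begin, iv.start)
            out.append((hit.data, width))
        return out


def _in_frame(placement: GenomicInterval, cds: GenomicInterval, phase: int) -> bool:
    """Does the placement share the phase-adjusted reading frame of *cds*?

    On '+', codon starts sit at cds.start + phase + 3k; on '-', the first
    coded base is cds.end-1 and codon starts (in reading direction) at
    genomic cds.end-1-phase-3k, so a placement ending at e is in frame iff
    (cds.end - phase - e) % 3 == 0.
    """
    if cds.strand == "+":
        return (placement.start - cds.start - phase) % 3 == 0
    return (cds.end - phase - placement.end) % 3 == 0


def classify_placement(
    peptide: str,
    interval: GenomicInterval,
    index: GeneIndex,
    genome: Genome | None = None,
) -> OriginCall:
    """Assign one placement its CP/NCP category."""
    hits = index.query(interval)

    # CP test: fully inside one same-strand CDS part, in frame.
    best_ncp: tuple[int, int, _Feature] | None = None  # (-overlap, precedence, feat)
    for feat, width in hits:
        if feat.kind == "cds":
            contained = (
                feat.cds_part.start <= interval.start and interval.end <= feat.cds_part.end
            )
            if (
                contained
                and feat.gene.interval.strand == interval.strand
                and _in_frame(interval, feat.cds_part, feat.phase)
            ):
                codon, is_aug = _start_codon_of(interval, genome)
                return OriginCall(
                    peptide=peptide,
                    category="CP",
                    gene_id=feat.gene.gene_id,
                    overlap_bp=len(interval),
                    start_codon=codon,
                    is_aug=is_aug,
                    strand=interval.strand,
                )
            kind = "NCP_exonic"
        else:
            kind = f"NCP_{feat.kind}"
        key = (-width, _PRECEDENCE[kind], kind, feat)
        if best_ncp is None or key[:2] < best_ncp[:2]:
            best_ncp = key

    codon, is_aug = _start_codon_of(interval, genome)
    if best_ncp is None:
        return OriginCall(peptide, "NCP_intergenic", None, 0, codon, is_aug, interval.strand)
    neg_width, _, kind, feat = best_ncp
    return OriginCall(peptide, kind, feat.gene.gene_id, -neg_width, codon, is_aug, interval.strand)


def start_codon(interval: GenomicInterval, genome: Genome) -> tuple[str, bool]:
    """First codon of the peptide's genomic span (strand-aware) and
    whether it is ATG.  Ambiguous bases make is_aug False."""
    if interval.strand == "-":
        codon = genome.fetch(
            GenomicInterval(interval.chrom, interval.end - 3, interval.end, "-")
        )
    else:
        codon = genome.fetch(
            GenomicInterval(interval.chrom, interval.start, interval.start + 3, "+")
        )
    return codon, codon == "ATG"


def _start_codon_of(interval: GenomicInterval, genome: Genome | None) -> tuple[str, bool]:
    if genome is None:
        return "NNN", False
    return start_codon(interval, genome)


def classify_all(
    located: list[LocatedPeptide],
    genes: list[GeneModel],
    genome: Genome | None = None,
    upstream_bp: int = 1000,
    downstream_bp: int = 1000,
) -> tuple[pd.DataFrame, Counter, Counter]:
    """Classify every single-locus peptide; returns the call table plus
    category and strand counters."""
    index = GeneIndex(genes, upstream_bp=upstream_bp, downstream_bp=downstream_bp)
    calls = []
    for lp in located:
        if lp.locus_status != "single_locus":
            continue
        iv = lp.placements[0].interval
        calls.append(classify_placement(lp.sequence, iv, index, genome))
    category_counts = Counter(c.category for c in calls)
    strand_counts = Counter(c.strand for c in calls)
    table = pd.DataFrame(
        [
            {
                "peptide": c.peptide,
                "category": c.category,
                "gene_id": c.gene_id or "",
                "overlap_bp": c.overlap_bp,
                "start_codon": c.start_codon,
                "is_aug": c.is_aug,
                "strand": c.strand,
            }
            for c in calls
        ],
        columns=["peptide", "category", "gene_id", "overlap_bp", "start_codon", "is_aug", "strand"],
    )
    return table, category_counts, strand_counts
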