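"""Genome and gene-model containers with a single coordinate convention.

All coordinates inside the package are 0-based half-open ``[start, end)``.
Conversion from 1-based inclusive conventions (GFF3, labelled TSV) happens
only at file boundaries.  The "TSS" of a gene is the 5' end of its gene
feature: ``start`` on the + strand, ``end - 1`` on the - strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "Genome",
    "GeneModel",
    "Transcript",
    "read_genome",
    "write_genome",
    "read_annotation",
    "tss_of",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Width in bp of the overlap with *other* (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to_point(self, pos: int) -> int:
        """Distance from the interval to a point; 0 if the point is inside."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - (self.end - 1)
        return 0


class Genome:
    """Ordered chromosome id -> uppercase nucleotide sequence."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("genome has no sequences")
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in self.sequences:
                raise ValueError(f"duplicate chromosome id {name!r}")
            self.sequences[name] = seq.upper()

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def chrom_ids(self) -> list[str]:
        return list(self.sequences)

    def validate(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.sequences:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > len(self.sequences[iv.chrom]):
            raise ValueError(
                f"interval end {iv.end} beyond {iv.chrom} length "
                f"{len(self.sequences[iv.chrom])}"
            )

    def fetch(self, iv: GenomicInterval) -> str:
        """Extract the sequence of *iv*, reverse-complemented on '-'."""
        self.validate(iv)
        seq = self.sequences[iv.chrom][iv.start : iv.end]
        if iv.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class Transcript:
    transcript_id: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval]
    phases: list[int]  # one per CDS part, in genomic order


@dataclass
class GeneModel:
    """A gene with exon/CDS structure and derived UTRs and introns.

    Where several isoforms exist, ``exons``/``cds`` hold the per-isoform
    structures while the union properties below give the gene-level view
    used for classification.
    """

    gene_id: str
    interval: GenomicInterval
    transcripts: list[Transcript] = field(default_factory=list)

    def _union(self, parts: list[GenomicInterval]) -> list[GenomicInterval]:
        return merge_intervals(parts)

    @property
    def exon_union(self) -> list[GenomicInterval]:
        return self._union([e for t in self.transcripts for e in t.exons])

    @property
    def cds_union(self) -> list[GenomicInterval]:
        return self._union([c for t in self.transcripts for c in t.cds])

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gaps between exons of the gene-level exon union."""
        exons = self.exon_union
        out = []
        for a, b in zip(exons, exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.interval.chrom, a.end, b.start, self.interval.strand)
                )
        return out

    @property
    def utr5(self) -> list[GenomicInterval]:
        return self._utrs()[0]

    @property
    def utr3(self) -> list[GenomicInterval]:
        return self._utrs()[1]

    def _utrs(self) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
        """Exon-minus-CDS pieces, split into 5' and 3' by strand."""
        cds = self.cds_union
        if not cds:
            return [], []
        cds_lo, cds_hi = cds[0].start, cds[-1].end
        left, right = [], []
        for ex in self.exon_union:
            for s, e in subtract_interval(ex.start, ex.end, cds):
                piece = GenomicInterval(ex.chrom, s, e, self.interval.strand)
                if e <= cds_lo:
                    left.append(piece)
                elif s >= cds_hi:
                    right.append(piece)
                else:  # internal exon gap inside the CDS span: not a UTR
                    continue
        if self.interval.strand == "-":
            return right, left
        return left, right

    @property
    def tss(self) -> int:
        return tss_of(self)


def merge_intervals(parts: list[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping/adjacent intervals (strand of the first kept)."""
    if not parts:
        return []
    parts = sorted(parts, key=lambda p: (p.chrom, p.start, p.end))
    out = [parts[0]]
    for p in parts[1:]:
        last = out[-1]
        if p.chrom == last.chrom and p.start <= last.end:
            if p.end > last.end:
                out[-1] = GenomicInterval(last.chrom, last.start, p.end, last.strand)
        else:
            out.append(p)
    return out


def subtract_interval(
    start: int, end: int, holes: list[GenomicInterval]
) -> list[tuple[int, int]]:
    """``[start, end)`` minus the (sorted, merged) *holes*, as raw pairs."""
    pieces = []
    cur = start
    for h in holes:
        if h.end <= start or h.start >= end:
            continue
        if h.start > cur:
            pieces.append((cur, h.start))
        cur = max(cur, h.end)
    if cur < end:
        pieces.append((cur, end))
    return pieces


def tss_of(gene: GeneModel) -> int:
    """5' end of the gene feature: start on '+', end-1 on '-'."""
    if gene.interval.strand == "+":
        return gene.interval.start
    if gene.interval.strand == "-":
        return gene.interval.end - 1
    raise ValueError(f"gene {gene.gene_id} is unstranded")


def read_genome(path: str) -> Genome:
    """Read a FASTA file into a :class:`Genome` (uppercased, order kept)."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA record id {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(sequences)


def write_genome(genome: Genome, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_annotation(path: str, genome: Genome) -> list[GeneModel]:
    """Parse a GFF3 file into gene models.

    GFF3 1-based inclusive coordinates become 0-based half-open here.
    Transcripts whose CDS parts fall outside their exons, or with an
    unknown strand, are skipped with a warning; features on chromosomes
    absent from *genome* are rejected.
    """
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        if g.seqid not in genome:
            log.warning("gene %s on unknown chromosome %s: rejected", g.id, g.seqid)
            continue
        if g.strand not in ("+", "-"):
            log.warning("gene %s has unknown strand: skipped", g.id)
            continue
        interval = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand)
        if interval.end > genome.lengths[g.seqid]:
            log.warning("gene %s extends beyond chromosome end: rejected", g.id)
            continue
        model = GeneModel(gene_id=g.id, interval=interval)
        for t in db.children(g, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = [
                GenomicInterval(e.seqid, e.start - 1, e.end, g.strand)
                for e in db.children(t, featuretype="exon", order_by="start")
            ]
            cds_feats = list(db.children(t, featuretype="CDS", order_by="start"))
            cds = [GenomicInterval(c.seqid, c.start - 1, c.end, g.strand) for c in cds_feats]
            phases = [int(c.frame) if c.frame in ("0", "1", "2") else 0 for c in cds_feats]
            if not _cds_within_exons(cds, exons):
                log.warning("transcript %s: CDS outside exons, skipped", t.id)
                continue
            model.transcripts.append(
                Transcript(transcript_id=t.id, exons=exons, cds=cds, phases=phases)
            )
        genes.append(model)
    return genes


def _cds_within_exons(cds: list[GenomicInterval], exons: list[GenomicInterval]) -> bool:
    for c in cds:
        if not any(e.start <= c.start and c.end <= e.end for e in exons):
            return False
    return True
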