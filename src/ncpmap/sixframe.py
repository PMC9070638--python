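"""Six-frame stop-to-stop peptidogenomic database construction.

Each chromosome is translated in all six reading frames and split at stop
codons; every maximal stop-free amino-acid run becomes a segment that
carries its exact genomic interval, so any peptide hit inside a segment
can be converted back to genomic coordinates by pure arithmetic.

Coordinate arithmetic: a frame ``+k`` (k in 1..3) translates the forward
strand from offset ``k-1``; residues ``[a, b)`` of the translation occupy
genomic ``[off + 3a, off + 3b)``.  A frame ``-k`` translates the reverse
complement from offset ``k-1``; residues ``[a, b)`` occupy genomic
``[L - off - 3b, L - off - 3a)`` where ``L`` is the chromosome length.

Codons containing any non-ACGT base translate to ``X``; an ``X`` never
terminates a segment (ambiguity is not evidence of a stop), only ``*``
does.  Leading and trailing stop-less runs are kept as segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .genome import Genome, GenomicInterval

__all__ = [
    "FRAMES",
    "SixFrameSegment",
    "translate_frame",
    "segment_frame",
    "build_sixframe_db",
    "write_db_fasta",
    "read_db_fasta",
    "write_db_bed",
]

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")

# Standard genetic code (NCBI table 1); anything else (N, IUPAC codes,
# short codon) is X.  Stops are '*'.
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"


@dataclass(frozen=True)
class SixFrameSegment:
    """One stop-to-stop translation segment with its genomic interval."""

    segment_id: str
    frame: str  # one of FRAMES
    interval: GenomicInterval
    sequence: str  # aa over 20 letters + X, no internal '*'
    leading: bool  # no stop codon precedes it in its frame
    trailing: bool  # no stop codon follows it

    @property
    def contains_x(self) -> bool:
        return "X" in self.sequence

    def __post_init__(self) -> None:
        if len(self.interval) != 3 * len(self.sequence):
            raise ValueError(
                f"{self.segment_id}: interval length {len(self.interval)} != "
                f"3 x {len(self.sequence)} residues"
            )


def translate_frame(seq: str, frame: str) -> str:
    """Translate one frame of *seq*, keeping ``*`` for stops and ``X`` for
    codons with non-ACGT bases.  The trailing partial codon is dropped."""
    if frame not in FRAMES:
        raise ValueError(f"invalid frame {frame!r}")
    offset = int(frame[1]) - 1
    s = seq.upper()
    if frame[0] == "-":
        s = str(Seq(s).reverse_complement())
    s = s[offset:]
    n = len(s) - len(s) % 3
    return "".join(CODON_TABLE.get(s[i : i + 3], "X") for i in range(0, n, 3))


def _frame_offset(frame: str) -> int:
    return int(frame[1]) - 1


def segment_frame(
    aa: str, frame: str, chrom: str, chrom_len: int, id_start: int = 1
) -> list[SixFrameSegment]:
    """Split a frame translation at stop codons into located segments."""
    strand = frame[0] if frame[0] == "-" else "+"
    off = _frame_offset(frame)
    segments: list[SixFrameSegment] = []
    pieces = aa.split("*")
    n_pieces = len(pieces)
    a = 0  # residue cursor in the translation, counting stops
    for i, piece in enumerate(pieces):
        if piece:
            b = a + len(piece)
            if strand == "+":
                iv = GenomicInterval(chrom, off + 3 * a, off + 3 * b, "+")
            else:
                iv = GenomicInterval(chrom, chrom_len - off - 3 * b, chrom_len - off - 3 * a, "-")
            segments.append(
                SixFrameSegment(
                    segment_id=f"SEG{id_start + len(segments)}",
                    frame=frame,
                    interval=iv,
                    sequence=piece,
                    leading=(i == 0),
                    trailing=(i == n_pieces - 1),
                )
            )
        a += len(piece) + 1  # skip the stop residue
    return segments


def build_sixframe_db(genome: Genome, min_len: int = 1) -> list[SixFrameSegment]:
    """Segment all six frames of every chromosome.

    Segment ids are deterministic: numbered consecutively in (chromosome
    order, frame order +1,+2,+3,-1,-2,-3, position-in-frame order).
    """
    segments: list[SixFrameSegment] = []
    counter = 1
    for chrom, seq in genome.sequences.items():
        for frame in FRAMES:
            aa = translate_frame(seq, frame)
            segs = segment_frame(aa, frame, chrom, len(seq), id_start=counter)
            segs = [s for s in segs if len(s.sequence) >= min_len]
            # renumber after the min_len filter so ids stay consecutive
            for s in segs:
                segments.append(
                    SixFrameSegment(
                        segment_id=f"SEG{counter}",
                        frame=s.frame,
                        interval=s.interval,
                        sequence=s.sequence,
                        leading=s.leading,
                        trailing=s.trailing,
                    )
                )
                counter += 1
    return segments


def write_db_fasta(segments: Iterable[SixFrameSegment], path: str, width: int = 60) -> None:
    """Serialize segments; header fields are pipe-delimited:

    ``>SEG{n}|{chrom}|{frame}|{start}|{end}|{strand}|L={0/1}|T={0/1}``
    with start/end 0-based half-open.
    """
    with open(path, "w") as fh:
        for s in segments:
            iv = s.interval
            fh.write(
                f">{s.segment_id}|{iv.chrom}|{s.frame}|{iv.start}|{iv.end}|"
                f"{iv.strand}|L={int(s.leading)}|T={int(s.trailing)}\n"
            )
            for i in range(0, len(s.sequence), width):
                fh.write(s.sequence[i : i + width] + "\n")


def read_db_fasta(path: str) -> list[SixFrameSegment]:
    """Round-trip reader for the :func:`write_db_fasta` dialect."""
    segments = []
    with open(path) as fh:
        header = None
        chunks: list[str] = []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    segments.append(_parse_entry(header, "".join(chunks)))
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
        if header is not None:
            segments.append(_parse_entry(header, "".join(chunks)))
    return segments


def _parse_entry(header: str, seq: str) -> SixFrameSegment:
    seg_id, chrom, frame, start, end, strand, lflag, tflag = header.split("|")
    return SixFrameSegment(
        segment_id=seg_id,
        frame=frame,
        interval=GenomicInterval(chrom, int(start), int(end), strand),
        sequence=seq,
        leading=lflag == "L=1",
        trailing=tflag == "T=1",
    )


def write_db_bed(segments: Iterable[SixFrameSegment], path: str) -> None:
    """BED6 export of segment intervals (score = segment length in aa)."""
    with open(path, "w") as fh:
        for s in segments:
            iv = s.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.segment_id}\t"
                f"{len(s.sequence)}\t{iv.strand}\n"
            )


def iter_frame_translations(genome: Genome) -> Iterator[tuple[str, str, str]]:
    """Yield (chrom, frame, translation) over the whole genome."""
    for chrom, seq in genome.sequences.items():
        for frame in FRAMES:
            yield chrom, frame, translate_frame(seq, frame)
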