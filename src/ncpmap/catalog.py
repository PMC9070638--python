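"""Identified-peptide catalog: ingestion, mass/m-z computation and
placement of peptides in the six-frame database.

Masses are computed from sequence (theoretical), monoisotopic by default;
observed values from the search-engine export are carried through for QC
deltas only.  m/z follows (M + z * m_proton) / z with the proton at
1.007276 Da.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomicInterval
from .sixframe import SixFrameSegment

log = logging.getLogger(__name__)

__all__ = [
    "IdentifiedPeptide",
    "Placement",
    "LocatedPeptide",
    "read_identifications",
    "deduplicate",
    "monoisotopic_mass",
    "average_mass",
    "theoretical_mz",
    "locate_peptides",
    "summarize_catalog",
    "write_placements_bed",
]

PROTON_MASS = 1.007276  # Da
WATER_MONO = 18.0105646863  # Da
WATER_AVG = 18.01528  # Da

# Residue (amino-acid minus water) masses, monoisotopic / average, Da.
MONO_RESIDUE = {
    "G": 57.02146372, "A": 71.03711379, "S": 87.03202841, "P": 97.05276385,
    "V": 99.06841392, "T": 101.04767847, "C": 103.00918496, "L": 113.08406398,
    "I": 113.08406398, "N": 114.04292744, "D": 115.02694302, "Q": 128.05857751,
    "K": 128.09496302, "E": 129.04259309, "M": 131.04048509, "H": 137.05891186,
    "F": 147.06841391, "R": 156.10111102, "Y": 163.06332853, "W": 186.07931295,
}
AVG_RESIDUE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

STANDARD_RESIDUES = frozenset(MONO_RESIDUE)

_MOD_RE = re.compile(r"\([^)]*\)|\[[^\]]*\]")


@dataclass(frozen=True)
class IdentifiedPeptide:
    sequence: str
    sample: str
    charge: int
    mz: float
    mass: float
    score: float = float("nan")

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise ValueError(f"non-standard residues {sorted(bad)} in {self.sequence}")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")


@dataclass(frozen=True)
class Placement:
    segment_id: str
    offset: int  # residue offset within the segment
    interval: GenomicInterval
    frame: str


@dataclass
class LocatedPeptide:
    sequence: str
    placements: list[Placement] = field(default_factory=list)

    @property
    def locus_status(self) -> str:
        n = len(self.placements)
        if n == 0:
            return "unplaced"
        return "single_locus" if n == 1 else "multi_locus"


def strip_modifications(seq: str) -> str:
    """Drop PEAKS-style modification annotations: ``PEPT(+15.99)IDE`` -> ``PEPTIDE``."""
    return _MOD_RE.sub("", seq).strip()


def read_identifications(path: str) -> list[IdentifiedPeptide]:
    """Read a PEAKS-export-style CSV (columns Peptide, Sample, z, m/z, Mass,
    optionally Score; extras ignored).  Rows with non-standard residues
    after modification stripping are rejected with a logged count."""
    df = pd.read_csv(path)
    required = ["Peptide", "Sample", "z", "m/z", "Mass"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s) {missing} in {path}")
    peptides: list[IdentifiedPeptide] = []
    rejected = 0
    for row in df.to_dict("records"):
        seq = strip_modifications(str(row["Peptide"]))
        if not seq or set(seq) - STANDARD_RESIDUES:
            rejected += 1
            continue
        peptides.append(
            IdentifiedPeptide(
                sequence=seq,
                sample=str(row["Sample"]),
                charge=int(row["z"]),
                mz=float(row["m/z"]),
                mass=float(row["Mass"]),
                score=float(row.get("Score", float("nan"))),
            )
        )
    if rejected:
        log.info("rejected %d rows with non-standard residues", rejected)
    return peptides


def deduplicate(
    peptides: list[IdentifiedPeptide],
) -> tuple[list[str], dict[str, set[str]]]:
    """Non-redundant sequences, globally (first-seen order) and per sample."""
    seen: dict[str, None] = {}
    per_sample: dict[str, set[str]] = {}
    for p in peptides:
        seen.setdefault(p.sequence, None)
        per_sample.setdefault(p.sample, set()).add(p.sequence)
    return list(seen), per_sample


def monoisotopic_mass(seq: str) -> float:
    """Peptide monoisotopic mass in Da: residue masses plus one water."""
    if not seq:
        raise ValueError("empty sequence")
    try:
        return sum(MONO_RESIDUE[r] for r in seq) + WATER_MONO
    except KeyError as e:
        raise ValueError(f"unknown residue {e.args[0]!r}") from None


def average_mass(seq: str) -> float:
    """Peptide average mass in Da."""
    if not seq:
        raise ValueError("empty sequence")
    try:
        return sum(AVG_RESIDUE[r] for r in seq) + WATER_AVG
    except KeyError as e:
        raise ValueError(f"unknown residue {e.args[0]!r}") from None


def theoretical_mz(mass: float, z: int) -> float:
    """m/z in Th for a peptide of the given neutral mass and charge."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (mass + z * PROTON_MASS) / z


class SegmentIndex:
    """Concatenated-text substring index over segment sequences.

    Segments are joined with a sentinel so a peptide can never span two
    segments; hits are mapped back to (segment, residue offset) via a
    sorted offset table.
    """

    def __init__(self, segments: list[SixFrameSegment], il_equivalent: bool = False):
        self.segments = segments
        self.il_equivalent = il_equivalent
        self._offsets: list[int] = []
        parts = []
        pos = 0
        for s in segments:
            self._offsets.append(pos)
            parts.append(s.sequence)
            pos += len(s.sequence) + 1
        text = "#".join(parts)
        self._text = text.replace("I", "L") if il_equivalent else text

    def find(self, peptide: str) -> list[tuple[int, int]]:
        """All (segment index, residue offset) occurrences of *peptide*."""
        query = peptide.replace("I", "L") if self.il_equivalent else peptide
        hits = []
        start = self._text.find(query)
        while start != -1:
            seg_i = bisect_right(self._offsets, start) - 1
            hits.append((seg_i, start - self._offsets[seg_i]))
            start = self._text.find(query, start + 1)
        return hits


def placement_interval(segment: SixFrameSegment, offset: int, pep_len: int) -> GenomicInterval:
    """Genomic interval of a peptide at residue *offset* within *segment*."""
    iv = segment.interval
    if iv.strand == "+":
        s = iv.start + 3 * offset
        return GenomicInterval(iv.chrom, s, s + 3 * pep_len, "+")
    e = iv.end - 3 * offset
    return GenomicInterval(iv.chrom, e - 3 * pep_len, e, "-")


def locate_peptides(
    sequences: list[str],
    db: list[SixFrameSegment],
    il_equivalent: bool = False,
) -> list[LocatedPeptide]:
    """Exact substring search of each peptide in the six-frame database.

    With ``il_equivalent`` on, I and L are interchangeable (MS cannot
    distinguish them).  All occurrences are reported; no hit means
    ``unplaced``.
    """
    index = SegmentIndex(db, il_equivalent=il_equivalent)
    located = []
    for seq in sequences:
        lp = LocatedPeptide(sequence=seq)
        for seg_i, offset in index.find(seq):
            seg = db[seg_i]
            lp.placements.append(
                Placement(
                    segment_id=seg.segment_id,
                    offset=offset,
                    interval=placement_interval(seg, offset, len(seq)),
                    frame=seg.frame,
                )
            )
        located.append(lp)
    return located


def summarize_catalog(
    sequences_by_group: dict[str, list[str]],
    mass_kind: str = "monoisotopic",
    mass_cutoff: float = 2500.0,
    length_quantile: float = 0.9,
) -> pd.DataFrame:
    """Per-group count, length median/quantiles, mean mass (AMV), fraction
    below the mass cutoff and the 90th-percentile length cutoff."""
    mass_fn = monoisotopic_mass if mass_kind == "monoisotopic" else average_mass
    rows = []
    for group, seqs in sequences_by_group.items():
        if not seqs:
            rows.append(
                {"group": group, "count": 0, "median_length": np.nan,
                 "q25_length": np.nan, "q75_length": np.nan,
                 "length_q90": np.nan, "mean_mass_da": np.nan,
                 "frac_below_mass_cutoff": np.nan}
            )
            continue
        lengths = np.array([len(s) for s in seqs], dtype=float)
        masses = np.array([mass_fn(s) for s in seqs])
        rows.append(
            {
                "group": group,
                "count": len(seqs),
                "median_length": float(np.median(lengths)),
                "q25_length": float(np.quantile(lengths, 0.25)),
                "q75_length": float(np.quantile(lengths, 0.75)),
                "length_q90": float(np.quantile(lengths, length_quantile)),
                "mean_mass_da": float(masses.mean()),
                "frac_below_mass_cutoff": float((masses < mass_cutoff).mean()),
            }
        )
    return pd.DataFrame(rows)


def write_placements_bed(
    located: list[LocatedPeptide], path: str, scores: dict[str, float] | None = None
) -> None:
    """BED6 of single-locus placements (name = peptide, score = id score)."""
    scores = scores or {}
    with open(path, "w") as fh:
        for lp in located:
            if lp.locus_status != "single_locus":
                continue
            iv = lp.placements[0].interval
            score = scores.get(lp.sequence, 0)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{lp.sequence}\t{score}\t{iv.strand}\n"
            )
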