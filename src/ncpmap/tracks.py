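"""External interval tracks (QTLs, LTR retrotransposons, domestication
sweeps, lncRNA loci, long-read alignments) and peptide-track overlap.

Tracks are unstranded by default: QTL and sweep intervals carry no strand,
and the overlap question is purely positional.  BED input is 0-based
half-open; the labelled TSV dialect (chrom, start, end, label...) is
1-based inclusive and converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .genome import GenomicInterval

log = logging.getLogger(__name__)

__all__ = ["FeatureTrack", "read_track", "overlap_peptides"]


@dataclass
class Feature:
    interval: GenomicInterval
    labels: dict[str, str] = field(default_factory=dict)


@dataclass
class FeatureTrack:
    name: str
    features: list[Feature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)


def read_track(
    path: str,
    name: str | None = None,
    fmt: str = "bed",
    chrom_lengths: dict[str, int] | None = None,
    label_names: tuple[str, ...] = ("label",),
) -> FeatureTrack:
    """Read a BED (0-based half-open) or labelled TSV (1-based inclusive)
    interval file.

    Intervals extending past a chromosome end are clipped with a logged
    count; malformed lines are skipped.  A file whose every line is
    malformed is a hard error.
    """
    if fmt not in ("bed", "tsv"):
        raise ValueError(f"unknown track format {fmt!r}")
    track = FeatureTrack(name=name or path)
    n_lines = n_bad = n_clipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            n_lines += 1
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                chrom = fields[0]
                if fmt == "bed":
                    start, end = int(fields[1]), int(fields[2])
                    extras = fields[3:4]  # BED name column
                else:
                    start, end = int(fields[1]) - 1, int(fields[2])
                    extras = fields[3:]
                if chrom_lengths is not None:
                    if chrom not in chrom_lengths:
                        raise ValueError(f"unknown chromosome {chrom}")
                    if end > chrom_lengths[chrom]:
                        end = chrom_lengths[chrom]
                        n_clipped += 1
                    if start < 0:
                        start = 0
                        n_clipped += 1
                iv = GenomicInterval(chrom, start, end)
            except (ValueError, IndexError) as e:
                log.warning("skipping malformed track line %r (%s)", line, e)
                n_bad += 1
                continue
            labels = dict(zip(label_names, extras))
            track.features.append(Feature(iv, labels))
    if n_lines and n_bad == n_lines:
        raise ValueError(f"all {n_lines} lines of {path} are malformed")
    if n_clipped:
        log.info("%d interval bound(s) clipped to chromosome ends in %s", n_clipped, path)
    return track


def overlap_peptides(
    placements: dict[str, GenomicInterval],
    track: FeatureTrack,
    min_overlap_bp: int = 1,
    label_key: str = "label",
    stranded: bool = False,
) -> tuple[pd.DataFrame, dict[str, int], float]:
    """Assign each peptide to every track feature it overlaps by at least
    *min_overlap_bp*.

    Returns the assignment table, per-label peptide counts (a peptide may
    count under several labels but once per label), and the overall
    fraction of peptides overlapping at least one feature.  Strand is
    ignored unless *stranded* is set.
    """
    trees: dict[str, IntervalTree] = {}
    for f in track.features:
        trees.setdefault(f.interval.chrom, IntervalTree()).addi(
            f.interval.start, f.interval.end, f
        )
    rows = []
    label_sets: dict[str, set[str]] = {}
    n_overlapping = 0
    for peptide, iv in placements.items():
        tree = trees.get(iv.chrom)
        assigned = False
        for hit in sorted(tree.overlap(iv.start, iv.end)) if tree else []:
            f: Feature = hit.data
            if stranded and f.interval.strand not in (".", iv.strand):
                continue
            width = iv.overlap(f.interval)
            if width < min_overlap_bp:
                continue
            assigned = True
            label = f.labels.get(label_key, "")
            label_sets.setdefault(label, set()).add(peptide)
            rows.append(
                {
                    "peptide": peptide,
                    "track": track.name,
                    "feature_chrom": f.interval.chrom,
                    "feature_start": f.interval.start,
                    "feature_end": f.interval.end,
                    "label": label,
                    "overlap_bp": width,
                }
            )
        if assigned:
            n_overlapping += 1
    table = pd.DataFrame(
        rows,
        columns=[
            "peptide", "track", "feature_chrom", "feature_start",
            "feature_end", "label", "overlap_bp",
        ],
    )
    counts = {label: len(peps) for label, peps in sorted(label_sets.items())}
    fraction = n_overlapping / len(placements) if placements else 0.0
    return table, counts, fraction
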