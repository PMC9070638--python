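"""Genome-distribution statistics for mapped peptides.

Covers the chromosome-scale questions: how peptide placements tile the
genome in 1-Mb windows, where density hotspots ("intensive regions") sit,
how close consecutive peptides are, how far peptides lie from the nearest
gene 5' end (TSS), whether per-chromosome counts track chromosome length,
and how developmental-stage peptide sets intersect.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel, GenomicInterval

__all__ = [
    "WindowDensity",
    "window_density",
    "intensive_regions",
    "neighbor_distances",
    "tss_distances",
    "count_length_correlation",
    "stage_overlap",
]


@dataclass(frozen=True)
class WindowDensity:
    chrom: str
    window_index: int
    interval: GenomicInterval
    count: int
    intensive: bool = False


def _position(iv: GenomicInterval, anchor: str) -> int:
    if anchor == "midpoint":
        return (iv.start + iv.end - 1) // 2
    return iv.start


def window_density(
    placements: list[GenomicInterval],
    chrom_lengths: dict[str, int],
    window_bp: int = 1_000_000,
    anchor: str = "start",
) -> list[WindowDensity]:
    """Count placements per non-overlapping window tile (1 Mb default).

    A placement counts in the window containing its anchor position
    (genomic start by default); the last window of a chromosome is
    truncated at the chromosome end.
    """
    by_chrom: dict[str, list[int]] = {c: [] for c in chrom_lengths}
    for p in placements:
        by_chrom[p.chrom].append(_position(p, anchor))
    out: list[WindowDensity] = []
    for chrom, length in chrom_lengths.items():
        n_windows = max(1, -(-length // window_bp))
        counts = np.zeros(n_windows, dtype=int)
        for pos in by_chrom[chrom]:
            counts[pos // window_bp] += 1
        for i in range(n_windows):
            start = i * window_bp
            end = min(length, (i + 1) * window_bp)
            out.append(
                WindowDensity(chrom, i, GenomicInterval(chrom, start, end), int(counts[i]))
            )
    return out


def intensive_regions(
    densities: list[WindowDensity], threshold: int = 2
) -> tuple[list[GenomicInterval], float]:
    """Merge adjacent windows holding >= *threshold* placements into
    regions; also report the fraction of all placements inside them."""
    regions: list[GenomicInterval] = []
    total = sum(d.count for d in densities)
    inside = 0
    prev: WindowDensity | None = None
    for d in sorted(densities, key=lambda w: (w.chrom, w.window_index)):
        if d.count >= threshold:
            inside += d.count
            if (
                regions
                and prev is not None
                and prev.count >= threshold
                and prev.chrom == d.chrom
                and prev.window_index == d.window_index - 1
            ):
                last = regions[-1]
                regions[-1] = GenomicInterval(last.chrom, last.start, d.interval.end)
            else:
                regions.append(d.interval)
        prev = d
    fraction = inside / total if total else 0.0
    return regions, fraction


def neighbor_distances(
    placements: list[GenomicInterval], cutoff_bp: int = 500_000, anchor: str = "start"
) -> tuple[dict[str, np.ndarray], float]:
    """Consecutive start-to-start distances per chromosome and the overall
    fraction of distances at or below *cutoff_bp* (500 kb default)."""
    by_chrom: dict[str, list[int]] = {}
    for p in placements:
        by_chrom.setdefault(p.chrom, []).append(_position(p, anchor))
    distances = {
        c: np.diff(np.sort(np.array(v, dtype=np.int64))) for c, v in by_chrom.items()
    }
    alldist = np.concatenate([d for d in distances.values() if d.size]) if any(
        d.size for d in distances.values()
    ) else np.array([], dtype=np.int64)
    fraction = float((alldist <= cutoff_bp).mean()) if alldist.size else float("nan")
    return distances, fraction


def tss_distances(
    placements: list[GenomicInterval],
    genes: list[GeneModel],
    cutoff_bp: int = 2000,
) -> tuple[np.ndarray, float]:
    """Distance of each placement to the nearest gene TSS on either strand.

    The distance is interval-to-point: 0 when a TSS falls inside the
    peptide span, otherwise the gap to the nearer span edge.  Returns NaN
    distances when the chromosome has no gene.
    """
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.interval.chrom, [])
    for g in genes:
        tss_by_chrom[g.interval.chrom].append(g.tss)  # type: ignore[attr-defined]
    tss_by_chrom = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in tss_by_chrom.items()}

    out = np.empty(len(placements))
    for i, p in enumerate(placements):
        sites = tss_by_chrom.get(p.chrom)
        if sites is None or sites.size == 0:
            out[i] = np.nan
            continue
        j = np.searchsorted(sites, p.start)
        candidates = sites[max(0, j - 1) : j + 2]
        out[i] = min(p.distance_to_point(int(t)) for t in candidates)
    valid = out[~np.isnan(out)]
    fraction = float((valid <= cutoff_bp).mean()) if valid.size else float("nan")
    return out, fraction


def count_length_correlation(
    placements: list[GenomicInterval], chrom_lengths: dict[str, int]
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between per-chromosome
    placement counts and chromosome lengths."""
    if len(chrom_lengths) < 3:
        raise ValueError("need at least 3 chromosomes for a correlation")
    counts = {c: 0 for c in chrom_lengths}
    for p in placements:
        counts[p.chrom] += 1
    x = np.array([chrom_lengths[c] for c in chrom_lengths], dtype=float)
    y = np.array([counts[c] for c in chrom_lengths], dtype=float)
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def stage_overlap(sample_sets: dict[str, set[str]]) -> dict[frozenset, int]:
    """Venn partition of peptide sets across samples.

    Maps each non-empty sample combination to the number of peptides
    present in exactly those samples.  Values sum to |union|.
    """
    if len(sample_sets) < 2:
        raise ValueError("need at least 2 samples")
    samples = list(sample_sets)
    partition: dict[frozenset, int] = {}
    for k in range(1, len(samples) + 1):
        for combo in combinations(samples, k):
            exact = set.intersection(*(sample_sets[s] for s in combo))
            for other in samples:
                if other not in combo:
                    exact -= sample_sets[other]
            partition[frozenset(combo)] = len(exact)
    return partition


def stage_overlap_table(partition: dict[frozenset, int]) -> pd.DataFrame:
    rows = [
        {"samples": "&".join(sorted(combo)), "n_samples": len(combo), "count": n}
        for combo, n in sorted(partition.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    ]
    return pd.DataFrame(rows, columns=["samples", "n_samples", "count"])
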