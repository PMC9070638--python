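import numpy as np
import pytest

from ncpmap.distribution import (
    count_length_correlation,
    intensive_regions,
    neighbor_distances,
    stage_overlap,
    stage_overlap_table,
    tss_distances,
    window_density,
)
from ncpmap.genome import GeneModel, GenomicInterval


def iv(chrom, start, length=30):
    return GenomicInterval(chrom, start, start + length)


def test_window_density_counts():
    placements = [iv("c1", 10), iv("c1", 999_999), iv("c1", 1_500_000)]
    densities = window_density(placements, {"c1": 2_500_000})
    assert [d.count for d in densities] == [2, 1, 0]
    assert densities[-1].interval.end == 2_500_000  # truncated last window


def test_window_density_boundary_and_empty():
    densities = window_density([iv("c1", 1_000_000)], {"c1": 2_000_000, "c2": 500_000})
    counts = {(d.chrom, d.window_index): d.count for d in densities}
    assert counts[("c1", 0)] == 0 and counts[("c1", 1)] == 1  # half-open boundary
    assert counts[("c2", 0)] == 0


def test_window_counts_conserve_totals(dataset, analyzed):
    placements = [
        lp.placements[0].interval for lp in analyzed["located"] if lp.locus_status == "single_locus"
    ]
    densities = window_density(placements, dataset.genome.lengths)
    assert sum(d.count for d in densities) == len(placements)


def test_intensive_regions_merge_and_fraction():
    densities = window_density(
        [iv("c1", 10), iv("c1", 20), iv("c1", 1_000_010)], {"c1": 3_000_000}
    )
    regions, fraction = intensive_regions(densities, threshold=2)
    assert len(regions) == 1
    assert fraction == pytest.approx(2 / 3)
    regions5, _ = intensive_regions(densities, threshold=5)
    assert regions5 == []


def test_intensive_adjacent_windows_merge():
    placements = [iv("c1", 10), iv("c1", 20), iv("c1", 1_000_010), iv("c1", 1_000_020)]
    densities = window_density(placements, {"c1": 3_000_000})
    regions, fraction = intensive_regions(densities, threshold=2)
    assert len(regions) == 1
    assert (regions[0].start, regions[0].end) == (0, 2_000_000)
    assert fraction == 1.0


def test_neighbor_distances():
    dists, frac = neighbor_distances([iv("c1", 0), iv("c1", 100), iv("c1", 300)], cutoff_bp=150)
    assert list(dists["c1"]) == [100, 200]
    assert frac == pytest.approx(0.5)


def test_neighbor_distances_single_placement_per_chrom():
    dists, frac = neighbor_distances([iv("c1", 0), iv("c2", 5)])
    assert all(d.size == 0 for d in dists.values())
    assert np.isnan(frac)


def _gene(chrom, start, end, strand="+"):
    return GeneModel("g", GenomicInterval(chrom, start, end, strand))


def test_tss_distances_definition():
    genes = [_gene("c1", 100, 500)]
    dists, _ = tss_distances([iv("c1", 100)], genes)
    assert dists[0] == 0  # TSS inside the span
    dists, _ = tss_distances([iv("c1", 50)], genes)
    assert dists[0] == 21  # 100 - 79
    genes2 = [_gene("c1", 0, 50), _gene("c1", 1000, 1100)]
    dists, _ = tss_distances([iv("c1", 400)], genes2)
    assert dists[0] == 400  # nearer of TSS 0 and 1000


def test_tss_distances_no_genes_is_nan():
    dists, frac = tss_distances([iv("c1", 50)], [])
    assert np.isnan(dists[0]) and np.isnan(frac)


def test_tss_distance_mirror_invariance(dataset, analyzed):
    """Reflecting all coordinates genome-wide leaves TSS distances unchanged."""
    placements = [
        lp.placements[0].interval for lp in analyzed["located"] if lp.locus_status == "single_locus"
    ][:40]
    genes = dataset.genes
    L = dataset.genome.lengths
    d1, _ = tss_distances(placements, genes)
    mirrored_p = [
        GenomicInterval(p.chrom, L[p.chrom] - p.end, L[p.chrom] - p.start, p.strand)
        for p in placements
    ]
    mirrored_g = []
    for g in genes:
        giv = g.interval
        flipped = "-" if giv.strand == "+" else "+"
        mirrored_g.append(
            GeneModel(g.gene_id, GenomicInterval(giv.chrom, L[giv.chrom] - giv.end, L[giv.chrom] - giv.start, flipped))
        )
    d2, _ = tss_distances(mirrored_p, mirrored_g)
    np.testing.assert_array_equal(d1, d2)


def test_count_length_correlation():
    lengths = {"c1": 1_000_000, "c2": 2_000_000, "c3": 3_000_000}
    placements = [iv(c, 10 * i) for c, n in [("c1", 2), ("c2", 4), ("c3", 6)] for i in range(n)]
    r, p = count_length_correlation(placements, lengths)
    assert r == pytest.approx(1.0)
    # constant counts -> undefined correlation
    flat = [iv(c, 0) for c in lengths]
    r, p = count_length_correlation(flat, lengths)
    assert np.isnan(r)
    with pytest.raises(ValueError):
        count_length_correlation([], {"c1": 100, "c2": 200})


def test_count_length_correlation_uniform_simulation():
    rng = np.random.default_rng(5)
    lengths = {f"c{i}": int(l) for i, l in enumerate(rng.integers(500_000, 5_000_000, size=12))}
    placements = []
    for c, L in lengths.items():
        for _ in range(rng.poisson(L / 10_000)):
            placements.append(iv(c, int(rng.integers(0, L - 30))))
    r, p = count_length_correlation(placements, lengths)
    assert r > 0.95 and p < 1e-4


def test_stage_overlap_examples():
    part = stage_overlap({"A": {"p1", "p2"}, "B": {"p2", "p3"}})
    assert part[frozenset({"A", "B"})] == 1
    assert part[frozenset({"A"})] == 1 and part[frozenset({"B"})] == 1
    disjoint = stage_overlap({"A": {"p1"}, "B": {"p2"}})
    assert disjoint[frozenset({"A", "B"})] == 0
    same = stage_overlap({"A": {"p1", "p2"}, "B": {"p1", "p2"}, "C": {"p1", "p2"}})
    assert same[frozenset({"A", "B", "C"})] == 2


def test_stage_overlap_partition_sums_to_union(dataset):
    _, per_sample = (None, {s: set() for s in dataset.spec.samples})
    for rec in dataset.truth.values():
        for s in rec.samples:
            per_sample[s].add(rec.sequence)
    part = stage_overlap(per_sample)
    union = set().union(*per_sample.values())
    assert sum(part.values()) == len(union)
    table = stage_overlap_table(part)
    assert table["count"].sum() == len(union)


def test_stage_overlap_needs_two_samples():
    with pytest.raises(ValueError):
        stage_overlap({"A": {"p"}})
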