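"""Genome-distribution statistics: 1-Mb window densities, intensive
regions, neighbor and TSS distances, and the count-length correlation."""

from ncpmap import SimulationSpec, simulate_dataset, build_sixframe_db, locate_peptides
from ncpmap.distribution import (
    count_length_correlation, intensive_regions, neighbor_distances,
    stage_overlap, tss_distances, window_density,
)

ds = simulate_dataset(SimulationSpec(seed=11))
db = build_sixframe_db(ds.genome, min_len=5)
located = locate_peptides(sorted(ds.truth), db)
placements = [lp.placements[0].interval for lp in located if lp.locus_status == "single_locus"]

densities = window_density(placements, ds.genome.lengths, window_bp=100_000)
regions, frac = intensive_regions(densities, threshold=5)
print(f"{len(placements)} placements over {len(densities)} 100-kb windows")
print(f"{len(regions)} intensive regions (>=5 peptides/window) hold {frac:.1%} of peptides")

_, frac_neighbor = neighbor_distances(placements, cutoff_bp=50_000)
print(f"fraction of consecutive peptides within 50 kb: {frac_neighbor:.2%}")

_, frac_tss = tss_distances(placements, ds.genes, cutoff_bp=2_000)
print(f"fraction within 2 kb of the nearest gene 5' end: {frac_tss:.2%}")

r, p = count_length_correlation(placements, ds.genome.lengths)
print(f"per-chromosome count vs length: Pearson r = {r:.3f} (p = {p:.3g})")

per_sample = {s: set() for s in ds.spec.samples}
for rec in ds.truth.values():
    for s in rec.samples:
        per_sample[s].add(rec.sequence)
venn = stage_overlap(per_sample)
for combo, n in sorted(venn.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))):
    print(f"  detected in exactly {'&'.join(sorted(combo))}: {n}")
# The Venn partition sums to the union of all three developmental stages.
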