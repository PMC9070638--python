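"""End-to-end pipeline: build database -> locate -> classify ->
distributions -> track overlaps -> SNP-flank enrichment.

One :class:`RunConfig` carries every path and parameter; a single seed
governs all stochastic stages (per-stage seeds are derived from it and
logged).  Every stage writes a TSV and the run ends with a manifest
recording inputs, parameters and stage counts.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from . import __version__
from .catalog import (
    deduplicate,
    locate_peptides,
    read_identifications,
    summarize_catalog,
    write_placements_bed,
)
from .classify import classify_all
from .distribution import (
    count_length_correlation,
    intensive_regions,
    neighbor_distances,
    stage_overlap,
    stage_overlap_table,
    tss_distances,
    window_density,
)
from .enrichment import enrichment_test, matched_background, snp_flanks
from .genome import read_annotation, read_genome
from .sixframe import build_sixframe_db, write_db_fasta
from .tracks import overlap_peptides, read_track

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    genome: str
    annotation: str
    identifications: str
    outdir: str
    snps: str | None = None
    tracks: dict[str, str] = field(default_factory=dict)  # name -> BED path
    min_len: int = 1
    window_bp: int = 1_000_000
    intensive_threshold: int = 2
    upstream_bp: int = 1000
    downstream_bp: int = 1000
    flank_bp: int = 10_000
    n_replicates: int = 100
    seed: int = 0
    il_equivalent: bool = False
    neighbor_cutoff_bp: int = 500_000
    tss_cutoff_bp: int = 2000
    mass_cutoff_da: float = 2500.0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for name in ("genome", "annotation", "identifications"):
            p = getattr(self, name)
            if not os.path.exists(p):
                raise FileNotFoundError(f"config {name} path not found: {p}")
        if self.snps and not os.path.exists(self.snps):
            raise FileNotFoundError(f"SNP table not found: {self.snps}")
        for name, p in self.tracks.items():
            if not os.path.exists(p):
                raise FileNotFoundError(f"track {name!r} not found: {p}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)  # noqa: E731
    manifest: dict = {"version": __version__, "parameters": asdict(config), "counts": {}}

    genome = read_genome(config.genome)
    genes = read_annotation(config.annotation, genome)
    manifest["counts"]["chromosomes"] = len(genome.chrom_ids())
    manifest["counts"]["genes"] = len(genes)

    db = build_sixframe_db(genome, min_len=config.min_len)
    write_db_fasta(db, out("sixframe_db.fa"))
    manifest["counts"]["db_segments"] = len(db)

    identified = read_identifications(config.identifications)
    sequences, per_sample = deduplicate(identified)
    manifest["counts"]["identifications"] = len(identified)
    manifest["counts"]["nonredundant_peptides"] = len(sequences)

    located = locate_peptides(sequences, db, il_equivalent=config.il_equivalent)
    status = pd.Series([lp.locus_status for lp in located]).value_counts().to_dict()
    manifest["counts"]["locus_status"] = status
    scores = {p.sequence: p.score for p in identified}
    write_placements_bed(located, out("placements.bed"), scores=scores)

    table, cat_counts, strand_counts = classify_all(
        located, genes, genome,
        upstream_bp=config.upstream_bp, downstream_bp=config.downstream_bp,
    )
    table.to_csv(out("classification.tsv"), sep="\t", index=False)
    manifest["counts"]["categories"] = dict(cat_counts)
    manifest["counts"]["strands"] = dict(strand_counts)

    by_peptide = {
        lp.sequence: lp.placements[0].interval
        for lp in located
        if lp.locus_status == "single_locus"
    }
    cat_of = dict(zip(table["peptide"], table["category"]))
    ncp_ivs = [iv for p, iv in by_peptide.items() if cat_of.get(p, "").startswith("NCP")]
    cp_set = [p for p in by_peptide if cat_of.get(p) == "CP"]
    ncp_set = [p for p in by_peptide if cat_of.get(p, "").startswith("NCP")]
    summary = summarize_catalog(
        {"CP": cp_set, "NCP": ncp_set}, mass_cutoff=config.mass_cutoff_da
    )
    summary.to_csv(out("catalog_summary.tsv"), sep="\t", index=False)

    placements = list(by_peptide.values())
    densities = window_density(placements, genome.lengths, window_bp=config.window_bp)
    pd.DataFrame(
        [
            {"chrom": d.chrom, "window": d.window_index, "start": d.interval.start,
             "end": d.interval.end, "count": d.count}
            for d in densities
        ]
    ).to_csv(out("window_density.tsv"), sep="\t", index=False)
    regions, frac_inside = intensive_regions(densities, threshold=config.intensive_threshold)
    pd.DataFrame(
        [{"chrom": r.chrom, "start": r.start, "end": r.end} for r in regions]
    ).to_csv(out("intensive_regions.tsv"), sep="\t", index=False)
    manifest["counts"]["intensive_regions"] = len(regions)
    manifest["intensive_fraction"] = frac_inside

    _, frac_neighbor = neighbor_distances(placements, cutoff_bp=config.neighbor_cutoff_bp)
    dists, frac_tss = tss_distances(placements, genes, cutoff_bp=config.tss_cutoff_bp)
    pd.DataFrame({"tss_distance": dists}).to_csv(out("tss_distances.tsv"), sep="\t", index=False)
    manifest["neighbor_fraction"] = frac_neighbor
    manifest["tss_fraction"] = frac_tss
    try:
        r, p = count_length_correlation(placements, genome.lengths)
        manifest["count_length_r"] = r
        manifest["count_length_p"] = p
    except ValueError:
        manifest["count_length_r"] = None

    if len(per_sample) >= 2:
        partition = stage_overlap(per_sample)
        stage_overlap_table(partition).to_csv(out("stage_overlap.tsv"), sep="\t", index=False)

    ncp_placements = {p: by_peptide[p] for p in ncp_set}
    for name, path in config.tracks.items():
        track = read_track(path, name=name, fmt="bed", chrom_lengths=genome.lengths)
        t, counts, frac = overlap_peptides(ncp_placements, track)
        t.to_csv(out(f"overlap_{name}.tsv"), sep="\t", index=False)
        manifest["counts"][f"overlap_{name}"] = int(t["peptide"].nunique()) if len(t) else 0
        manifest[f"overlap_{name}_fraction"] = frac

    if config.snps:
        snp_df = pd.read_csv(config.snps, sep="\t")
        positions: dict[str, list[int]] = {}
        for row in snp_df.itertuples(index=False):
            positions.setdefault(str(row.chrom), []).append(int(row.position) - 1)
        flanks = snp_flanks(positions, genome.lengths, flank_bp=config.flank_bp)
        backgrounds = matched_background(
            ncp_ivs, genome.lengths, n_replicates=config.n_replicates, seed=config.seed
        )
        result = enrichment_test(ncp_ivs, flanks, backgrounds)
        pd.DataFrame(
            {"replicate": range(1, result.n_replicates + 1), "count": result.replicate_counts}
        ).to_csv(out("enrichment_replicates.tsv"), sep="\t", index=False)
        manifest["enrichment"] = {
            "observed": result.observed, "mean": result.mean, "sd": result.sd,
            "z": result.z, "p_normal": result.p_normal,
            "p_empirical": result.p_empirical, "degenerate": result.degenerate,
        }

    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("pipeline finished: %s", manifest["counts"])
    return manifest
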