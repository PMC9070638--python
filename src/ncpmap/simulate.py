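"""Synthetic genomes, annotations, planted peptides, identification
tables and feature/SNP tracks with full ground truth.

The generator emulates the inputs of a berry peptidomics study at desk
scale: a small multi-chromosome genome; protein-coding gene models with
UTRs and introns (ATG...stop enforced by writing valid coding sequence
into the genome at CDS sites); peptides planted in known origin
categories so that end-to-end classification can be checked against
truth; a PEAKS-export-style identification table over three
developmental-stage samples with Bernoulli detection and mass noise; and
QTL/LTR/sweep/lncRNA/read tracks plus a SNP table with a controllable
planted association fraction ``rho`` (the fraction of intergenic
non-conventional peptides forced into SNP-flank regions, so that flank
enrichment is real, not accidental).

Every planted peptide is guaranteed to occur exactly once in the
six-frame database (verified by literal search, with rejection
re-sampling), so the truth table is an exact oracle for placement and
classification.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import (
    MONO_RESIDUE,
    SegmentIndex,
    monoisotopic_mass,
    theoretical_mz,
)
from .genome import (
    GeneModel,
    Genome,
    GenomicInterval,
    Transcript,
    merge_intervals,
    subtract_interval,
    write_genome,
)
from .sixframe import CODON_TABLE, build_sixframe_db
from .enrichment import snp_flanks

__all__ = [
    "SimulationSpec",
    "PlantedPeptide",
    "SyntheticDataset",
    "simulate_genome",
    "simulate_annotation",
    "plant_peptides",
    "simulate_identifications",
    "simulate_tracks",
    "simulate_dataset",
]

AA20 = sorted(MONO_RESIDUE)
# codons per amino acid, deterministic order
CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    if _aa != "*":
        CODONS_FOR.setdefault(_aa, []).append(_codon)

DEFAULT_PLANTS = {
    "CP": 15,
    "NCP_intergenic": 80,
    "NCP_intron": 10,
    "NCP_upstream": 8,
    "NCP_downstream": 8,
    "NCP_exonic": 8,
    "NCP_5UTR": 6,
    "NCP_3UTR": 5,
}


@dataclass(frozen=True)
class SimulationSpec:
    """Knobs of the synthetic study.

    Defaults mirror the study conditions at desk scale: three
    developmental-stage samples, peptide lengths 5-30 with mode ~10,
    an intergenic-dominated origin mix, 10-kb SNP flanks.
    """

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (500_000, 450_000, 350_000)
    gc: float = 0.35  # grape-like AT-rich genome
    genes_per_mb: float = 40.0
    plants: dict = field(default_factory=lambda: dict(DEFAULT_PLANTS))
    length_n: int = 25  # peptide length = 5 + Binomial(length_n, length_p)
    length_p: float = 0.2  # -> support 5..30, mode 10
    samples: tuple[str, ...] = ("EL32", "EL34", "EL36")
    detection_prob: float = 0.6
    n_decoys: int = 10
    snp_count: int = 20
    flank_bp: int = 10_000
    rho: float = 0.0  # fraction of intergenic NCP plants forced into SNP flanks
    qtl_count: int = 12
    ltr_count: int = 30
    sweep_count: int = 8
    lncrna_count: int = 20
    read_count: int = 150

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if any(v < 0 for v in self.plants.values()):
            raise ValueError("plant counts must be >= 0")
        if min(self.chrom_lengths) < 1000:
            raise ValueError("chromosomes must be >= 1 kb")


@dataclass
class PlantedPeptide:
    sequence: str
    interval: GenomicInterval
    category: str
    gene_id: str | None
    samples: set = field(default_factory=set)
    in_flank: bool = False


@dataclass
class SyntheticDataset:
    spec: SimulationSpec
    genome: Genome
    genes: list[GeneModel]
    truth: dict[str, PlantedPeptide]
    identifications: pd.DataFrame
    snp_positions: dict[str, list[int]]
    tracks: dict[str, list[tuple[GenomicInterval, str]]]

    def write(self, outdir: str) -> dict[str, str]:
        """Emit all files in the dialects the pipeline consumes."""
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "genome": os.path.join(outdir, "genome.fa"),
            "annotation": os.path.join(outdir, "annotation.gff3"),
            "identifications": os.path.join(outdir, "identifications.csv"),
            "snps": os.path.join(outdir, "snps.tsv"),
            "truth": os.path.join(outdir, "truth.tsv"),
        }
        write_genome(self.genome, paths["genome"])
        write_gff3(self.genes, paths["annotation"])
        self.identifications.to_csv(paths["identifications"], index=False)
        with open(paths["snps"], "w") as fh:
            fh.write("chrom\tposition\ttrait\n")
            for chrom, positions in self.snp_positions.items():
                for pos in positions:
                    fh.write(f"{chrom}\t{pos + 1}\ttrait1\n")  # 1-based on disk
        for name, feats in self.tracks.items():
            p = os.path.join(outdir, f"{name}.bed")
            paths[name] = p
            with open(p, "w") as fh:
                for iv, label in feats:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")
        with open(paths["truth"], "w") as fh:
            fh.write("peptide\tchrom\tstart\tend\tstrand\tcategory\tgene_id\tsamples\tin_flank\n")
            for p in self.truth.values():
                iv = p.interval
                fh.write(
                    f"{p.sequence}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                    f"{p.category}\t{p.gene_id or ''}\t{','.join(sorted(p.samples))}\t"
                    f"{int(p.in_flank)}\n"
                )
        return paths


def simulate_genome(spec: SimulationSpec, rng: np.random.Generator | None = None) -> Genome:
    """I.i.d. bases at the requested GC fraction, reproducible from seed."""
    rng = rng or np.random.default_rng(spec.seed)
    probs = [(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2]
    sequences = {}
    for i, length in enumerate(spec.chrom_lengths, start=1):
        bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)
        sequences[f"chr{i}"] = bases.tobytes().decode("ascii")
    return Genome(sequences)


def _coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random non-stop codons + one stop codon."""
    non_stop = [c for c, a in sorted(CODON_TABLE.items()) if a != "*"]
    body = rng.choice(non_stop, size=max(0, n_codons - 2))
    stop = rng.choice(["TAA", "TAG", "TGA"])
    return "ATG" + "".join(body) + stop


def simulate_annotation(
    genome: Genome, spec: SimulationSpec, rng: np.random.Generator | None = None
) -> tuple[Genome, list[GeneModel]]:
    """Lay out non-overlapping gene models and rewrite the genome at CDS
    sites so every CDS is ATG...stop with no internal stop.

    Returns the edited genome and the gene models.  Genes are spaced by
    >= 3 kb so 1-kb flank windows never collide, which keeps planted-site
    classification unambiguous.
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    editable = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}
    genes: list[GeneModel] = []
    counter = 1
    for chrom, length in genome.lengths.items():
        n_genes = int(round(spec.genes_per_mb * length / 1e6))
        if n_genes == 0:
            continue
        # spread genes over the chromosome: gaps sized to the spacing budget
        target = max(3200, length // (n_genes + 1) - 2000)
        cursor = 2000
        for _ in range(n_genes):
            gap = int(rng.integers(3000, max(3001, target)))
            start = cursor + gap
            model, end = _make_gene(chrom, start, f"gene{counter}", rng, editable[chrom])
            if model is None or end > length - 2000:
                break
            genes.append(model)
            counter += 1
            cursor = end
    edited = Genome({c: b.decode("ascii") for c, b in editable.items()})
    return edited, genes


def _make_gene(
    chrom: str, start: int, gene_id: str, rng: np.random.Generator, seq: bytearray
) -> tuple[GeneModel | None, int]:
    strand = "+" if rng.random() < 0.5 else "-"
    u5 = int(rng.integers(120, 250))
    u3 = int(rng.integers(120, 250))
    n_codons = int(rng.integers(60, 150))
    clen = 3 * n_codons
    tlen = u5 + clen + u3  # spliced transcript length
    n_exons = int(rng.integers(1, 4))
    # cut the transcript into exons at interior points, introns between
    if n_exons > 1:
        cuts = sorted(rng.choice(np.arange(50, tlen - 50), size=n_exons - 1, replace=False))
    else:
        cuts = []
    bounds = [0, *cuts, tlen]
    intron_lens = [int(rng.integers(150, 400)) for _ in range(n_exons - 1)]

    # genomic exon layout
    exons: list[GenomicInterval] = []
    g = start
    for i in range(n_exons):
        ex_len = bounds[i + 1] - bounds[i]
        exons.append(GenomicInterval(chrom, g, g + ex_len, strand))
        g += ex_len
        if i < n_exons - 1:
            g += intron_lens[i]
    gene_end = g

    # transcript-coordinate CDS range; on '-', the transcript reads
    # right-to-left, so the 5'UTR occupies the genomic right end
    if strand == "+":
        t_cds = (u5, u5 + clen)
    else:
        t_cds = (u3, u3 + clen)

    # map transcript coords to genomic CDS parts
    cds_parts: list[GenomicInterval] = []
    t_off = 0
    for ex in exons:
        ex_len = len(ex)
        lo = max(t_cds[0], t_off)
        hi = min(t_cds[1], t_off + ex_len)
        if lo < hi:
            cds_parts.append(
                GenomicInterval(chrom, ex.start + (lo - t_off), ex.start + (hi - t_off), strand)
            )
        t_off += ex_len

    # write coding sequence into the genome along the reading direction
    coding = _coding_sequence(n_codons, rng)
    order = cds_parts if strand == "+" else list(reversed(cds_parts))
    pos = 0
    phases: list[int] = [0] * len(cds_parts)
    for idx, part in enumerate(order):
        chunk = coding[pos : pos + len(part)]
        phases_idx = idx if strand == "+" else len(cds_parts) - 1 - idx
        phases[phases_idx] = (3 - pos % 3) % 3
        if strand == "+":
            seq[part.start : part.end] = chunk.encode("ascii")
        else:
            seq[part.start : part.end] = _revcomp(chunk).encode("ascii")
        pos += len(part)

    interval = GenomicInterval(chrom, start, gene_end, strand)
    transcript = Transcript(
        transcript_id=f"{gene_id}.t1", exons=exons, cds=cds_parts, phases=phases
    )
    return GeneModel(gene_id=gene_id, interval=interval, transcripts=[transcript]), gene_end


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def write_gff3(genes: list[GeneModel], path: str) -> None:
    """Emit gene/mRNA/exon/CDS features, 1-based inclusive, with phases."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tsim\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for t in g.transcripts:
                fh.write(
                    f"{iv.chrom}\tsim\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{e.chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t{iv.strand}\t.\t"
                        f"Parent={t.transcript_id}\n"
                    )
                for c, ph in zip(t.cds, t.phases):
                    fh.write(
                        f"{c.chrom}\tsim\tCDS\t{c.start + 1}\t{c.end}\t.\t{iv.strand}\t{ph}\t"
                        f"Parent={t.transcript_id}\n"
                    )


def _sample_length(rng: np.random.Generator, spec: SimulationSpec) -> int:
    return 5 + int(rng.binomial(spec.length_n, spec.length_p))


def _random_peptide(length: int, rng: np.random.Generator) -> tuple[str, str]:
    """A random peptide and one nucleotide encoding of it (no stops)."""
    aas = rng.choice(AA20, size=length)
    codons = [CODONS_FOR[a][int(rng.integers(0, len(CODONS_FOR[a])))] for a in aas]
    return "".join(aas), "".join(codons)


class _RegionPools:
    """Candidate plant regions per origin category, with margins chosen so
    a peptide fully inside a pool piece classifies unambiguously."""

    def __init__(self, genome: Genome, genes: list[GeneModel], margin: int = 8):
        self.margin = margin
        self.pools: dict[str, list[GenomicInterval]] = {k: [] for k in DEFAULT_PLANTS}
        by_chrom_genes: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom_genes.setdefault(g.interval.chrom, []).append(g)
        for g in genes:
            strand = g.interval.strand
            for part in g.cds_union:
                self.pools["CP"].append(part)
                self.pools["NCP_exonic"].append(part)
            for part in g.utr5:
                self.pools["NCP_5UTR"].append(self._shrink(part, margin))
            for part in g.utr3:
                self.pools["NCP_3UTR"].append(self._shrink(part, margin))
            for part in g.introns:
                self.pools["NCP_intron"].append(self._shrink(part, margin))
            tss = g.tss
            if strand == "+":
                up = GenomicInterval(g.interval.chrom, max(0, tss - 1000), tss)
                down = GenomicInterval(
                    g.interval.chrom, g.interval.end, g.interval.end + 1000
                )
            else:
                up = GenomicInterval(g.interval.chrom, tss + 1, tss + 1 + 1000)
                down = GenomicInterval(
                    g.interval.chrom, max(0, g.interval.start - 1000), g.interval.start
                )
            self.pools["NCP_upstream"].append(self._shrink(up, margin))
            self.pools["NCP_downstream"].append(self._shrink(down, margin))
        # intergenic: > 1 kb + margin away from any gene
        for chrom, length in genome.lengths.items():
            pad = 1000 + margin
            holes = merge_intervals(
                [
                    GenomicInterval(
                        chrom,
                        max(0, g.interval.start - pad),
                        min(length, g.interval.end + pad),
                    )
                    for g in by_chrom_genes.get(chrom, [])
                ]
            )
            for s, e in subtract_interval(margin, length - margin, holes):
                if e - s > 120:
                    self.pools["NCP_intergenic"].append(GenomicInterval(chrom, s, e))
        self.pools = {k: [p for p in v if p is not None] for k, v in self.pools.items()}

    @staticmethod
    def _shrink(iv: GenomicInterval, margin: int) -> GenomicInterval | None:
        if iv.end - iv.start <= 2 * margin:
            return None
        return GenomicInterval(iv.chrom, iv.start + margin, iv.end - margin, iv.strand)


def _intersect_pool(
    pool: list[GenomicInterval], windows: list[GenomicInterval]
) -> list[GenomicInterval]:
    merged = merge_intervals(windows)
    out = []
    for p in pool:
        for w in merged:
            if w.chrom != p.chrom:
                continue
            s, e = max(p.start, w.start), min(p.end, w.end)
            if s < e:
                out.append(GenomicInterval(p.chrom, s, e, p.strand))
    return out


class _SiteSampler:
    """Draw non-colliding plant windows from region pools."""

    def __init__(self, rng: np.random.Generator, pad: int = 6):
        self.rng = rng
        self.pad = pad
        self.used: dict[str, list[tuple[int, int]]] = {}

    def collides(self, chrom: str, start: int, end: int) -> bool:
        return any(
            s < end + self.pad and start - self.pad < e
            for s, e in self.used.get(chrom, [])
        )

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.used.setdefault(chrom, []).append((start, end))

    def draw(self, pool: list[GenomicInterval], span: int, tries: int = 60):
        candidates = [p for p in pool if len(p) >= span]
        if not candidates:
            return None
        weights = np.array([len(p) - span + 1 for p in candidates], dtype=float)
        weights /= weights.sum()
        for _ in range(tries):
            p = candidates[int(self.rng.choice(len(candidates), p=weights))]
            start = int(self.rng.integers(p.start, p.end - span + 1))
            if not self.collides(p.chrom, start, start + span):
                return p, start
        return None


def plant_peptides(
    genome: Genome,
    genes: list[GeneModel],
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
    flanks: list[GenomicInterval] | None = None,
) -> tuple[Genome, dict[str, PlantedPeptide]]:
    """Plant peptides of each requested origin category.

    Categories outside annotated CDS get their site rewritten with codons
    encoding a random peptide (strand-aware); CP and out-of-frame exonic
    peptides are read off the existing coding sequence (rejection-sampled
    for the exonic case until a stop-free window is found) so the
    annotated reading frame is never disturbed.  With ``rho > 0`` and
    *flanks* given, that fraction of intergenic plants is drawn from the
    intersection of the intergenic pool with the SNP flanks.  After
    planting, every peptide is verified to occur exactly once in the
    six-frame database; offenders are re-planted.
    """
    rng = rng or np.random.default_rng(spec.seed + 2)
    for category, count in spec.plants.items():
        if category not in DEFAULT_PLANTS:
            raise ValueError(f"unknown origin category {category!r}")
    pools = _RegionPools(genome, genes)
    for category, count in spec.plants.items():
        if count > 0 and not pools.pools[category]:
            raise ValueError(f"no {category} regions available to plant in")
    editable = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}
    sampler = _SiteSampler(rng)
    gene_by_cds: list[tuple[GenomicInterval, GeneModel, int]] = []
    for g in genes:
        for t in g.transcripts:
            for cds, ph in zip(t.cds, t.phases):
                gene_by_cds.append((cds, g, ph))

    flank_pool = None
    if flanks and spec.rho > 0:
        flank_pool = _intersect_pool(pools.pools["NCP_intergenic"], flanks)

    truth: dict[str, PlantedPeptide] = {}

    def plant_one(category: str, force_flank: bool) -> PlantedPeptide | None:
        length = _sample_length(rng, spec)
        span = 3 * length
        if category == "CP":
            return _plant_cp(length)
        if category == "NCP_exonic":
            return _plant_exonic(length)
        pool = pools.pools[category]
        if force_flank and flank_pool:
            pool = flank_pool
        hit = sampler.draw(pool, span)
        if hit is None:
            return None
        piece, start = hit
        strand = "+" if rng.random() < 0.5 else "-"
        peptide, nt = _random_peptide(length, rng)
        if peptide in truth:
            return None
        if strand == "-":
            nt = _revcomp(nt)
        editable[piece.chrom][start : start + span] = nt.encode("ascii")
        sampler.reserve(piece.chrom, start, start + span)
        iv = GenomicInterval(piece.chrom, start, start + span, strand)
        return PlantedPeptide(peptide, iv, category, None)

    def _plant_cp(length: int) -> PlantedPeptide | None:
        span = 3 * length
        for _ in range(40):
            cds, g, phase = gene_by_cds[int(rng.integers(0, len(gene_by_cds)))]
            strand = cds.strand
            # in-frame codon-start positions, avoiding the stop codon
            if strand == "+":
                first = cds.start + phase
                last = cds.end - span - 3
            else:
                first = cds.start + (cds.end - phase - cds.start) % 3 + 3
                last = cds.end - span
            if last < first:
                continue
            k = int(rng.integers(0, (last - first) // 3 + 1))
            start = first + 3 * k
            if sampler.collides(cds.chrom, start, start + span):
                continue
            iv = GenomicInterval(cds.chrom, start, start + span, strand)
            peptide = _translate_nt(genome_fetch(editable, iv))
            if "*" in peptide or "X" in peptide or peptide in truth:
                continue
            sampler.reserve(cds.chrom, start, start + span)
            return PlantedPeptide(peptide, iv, "CP", g.gene_id)
        return None

    def _plant_exonic(length: int) -> PlantedPeptide | None:
        span = 3 * length
        for _ in range(80):
            cds, g, phase = gene_by_cds[int(rng.integers(0, len(gene_by_cds)))]
            if len(cds) < span + 8:
                continue
            # same strand, shifted frame, or the antisense strand
            antisense = rng.random() < 0.4
            strand = ("-" if cds.strand == "+" else "+") if antisense else cds.strand
            start0 = int(rng.integers(cds.start, cds.end - span + 1))
            if not antisense:
                shift = int(rng.integers(1, 3))
                if strand == "+":
                    frame0 = (cds.start + phase) % 3
                    start = start0 + ((frame0 + shift) - start0) % 3
                else:
                    # out of frame relative to (cds.end - phase - end) % 3 == 0
                    end0 = start0 + span
                    end = end0 - ((end0 - (cds.end - phase)) + shift) % 3
                    start = end - span
            else:
                start = start0
            end = start + span
            if start < cds.start or end > cds.end:
                continue
            if sampler.collides(cds.chrom, start, end):
                continue
            iv = GenomicInterval(cds.chrom, start, end, strand)
            peptide = _translate_nt(genome_fetch(editable, iv))
            if "*" in peptide or "X" in peptide or peptide in truth:
                continue
            sampler.reserve(cds.chrom, start, end)
            return PlantedPeptide(peptide, iv, "NCP_exonic", g.gene_id)
        return None

    # first pass
    for category, count in spec.plants.items():
        n_flank = (
            int(round(spec.rho * count)) if category == "NCP_intergenic" and flank_pool else 0
        )
        planted = 0
        attempts = 0
        while planted < count and attempts < 60 * count:
            attempts += 1
            rec = plant_one(category, force_flank=planted < n_flank)
            if rec is not None:
                truth[rec.sequence] = rec
                planted += 1
        if planted < count:
            raise ValueError(
                f"could only plant {planted}/{count} {category} peptides; "
                "enlarge the genome or reduce counts"
            )

    # uniqueness verification: every planted peptide exactly once in the DB
    for _ in range(4):
        edited = Genome({c: b.decode("ascii") for c, b in editable.items()})
        db = build_sixframe_db(edited, min_len=5)
        index = SegmentIndex(db)
        offenders = [s for s in truth if len(index.find(s)) != 1]
        if not offenders:
            return edited, truth
        for seq in offenders:
            rec = truth.pop(seq)
            replanted = None
            for _ in range(80):
                replanted = plant_one(rec.category, force_flank=rec.in_flank)
                if replanted is not None:
                    break
            if replanted is None:
                raise ValueError(f"could not re-plant a unique {rec.category} peptide")
            truth[replanted.sequence] = replanted
    raise ValueError("failed to reach a unique planting after 4 rounds")


def genome_fetch(editable: dict[str, bytearray], iv: GenomicInterval) -> str:
    s = editable[iv.chrom][iv.start : iv.end].decode("ascii")
    return _revcomp(s) if iv.strand == "-" else s


def _translate_nt(nt: str) -> str:
    return "".join(CODON_TABLE.get(nt[i : i + 3], "X") for i in range(0, len(nt) - 2, 3))


def simulate_identifications(
    truth: dict[str, PlantedPeptide],
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
    db_index: SegmentIndex | None = None,
) -> pd.DataFrame:
    """PEAKS-export-style table: per sample, each planted peptide detected
    with ``detection_prob``; masses are theoretical + N(0, 0.01 Da) noise;
    decoys are random sequences verified absent from the database."""
    rng = rng or np.random.default_rng(spec.seed + 3)
    rows = []
    for rec in truth.values():
        for sample in spec.samples:
            if rng.random() < spec.detection_prob:
                rec.samples.add(sample)
                rows.append(_id_row(rec.sequence, sample, rng))
    n_made = 0
    guard = 0
    while n_made < spec.n_decoys and guard < 50 * max(1, spec.n_decoys):
        guard += 1
        seq, _ = _random_peptide(_sample_length(rng, spec), rng)
        if seq in truth:
            continue
        if db_index is not None and db_index.find(seq):
            continue
        rows.append(_id_row(seq, str(rng.choice(list(spec.samples))), rng))
        n_made += 1
    return pd.DataFrame(rows, columns=["Peptide", "Sample", "z", "m/z", "Mass", "Score"])


def _id_row(seq: str, sample: str, rng: np.random.Generator) -> dict:
    z = int(rng.integers(1, 4))
    mass = monoisotopic_mass(seq) + rng.normal(0, 0.01)
    return {
        "Peptide": seq,
        "Sample": sample,
        "z": z,
        "m/z": round(theoretical_mz(mass, z), 5),
        "Mass": round(mass, 5),
        "Score": round(float(rng.uniform(30, 95)), 2),
    }


_TRAITS = (
    "berry_weight", "berry_shape", "berry_color", "flower_sex",
    "intrinsic_quality", "disease_resistance", "stress", "leaf_physiology",
)


def simulate_snps(
    genome: Genome, spec: SimulationSpec, rng: np.random.Generator | None = None
) -> dict[str, list[int]]:
    """Uniform SNP positions, allocated to chromosomes by length."""
    rng = rng or np.random.default_rng(spec.seed + 4)
    lengths = genome.lengths
    chroms = list(lengths)
    probs = np.array([lengths[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    positions: dict[str, list[int]] = {c: [] for c in chroms}
    for _ in range(spec.snp_count):
        c = chroms[int(rng.choice(len(chroms), p=probs))]
        positions[c].append(int(rng.integers(0, lengths[c])))
    return {c: sorted(v) for c, v in positions.items() if v}


def simulate_tracks(
    genome: Genome,
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
) -> dict[str, list[tuple[GenomicInterval, str]]]:
    """Uniformly placed interval tracks with field-typical size ranges."""
    rng = rng or np.random.default_rng(spec.seed + 5)
    lengths = genome.lengths
    chroms = list(lengths)
    probs = np.array([lengths[c] for c in chroms], dtype=float)
    probs /= probs.sum()

    def uniform_track(count: int, lo: int, hi: int, labels: tuple[str, ...]) -> list:
        feats = []
        for i in range(count):
            c = chroms[int(rng.choice(len(chroms), p=probs))]
            size = int(rng.integers(lo, hi))
            size = min(size, lengths[c] - 1)
            start = int(rng.integers(0, lengths[c] - size))
            label = str(rng.choice(list(labels))) if labels else f"f{i + 1}"
            feats.append((GenomicInterval(c, start, start + size), label))
        return feats

    return {
        "qtl": uniform_track(spec.qtl_count, 30_000, 80_000, _TRAITS),
        "ltr": uniform_track(spec.ltr_count, 2_000, 12_000, ()),
        "sweep": uniform_track(spec.sweep_count, 20_000, 50_000, ()),
        "lncrna": uniform_track(spec.lncrna_count, 1_000, 5_000, ()),
        "reads": uniform_track(spec.read_count, 1_000, 3_000, ()),
    }


def simulate_dataset(spec: SimulationSpec) -> SyntheticDataset:
    """Run the full generator: genome -> annotation -> SNPs -> planted
    peptides (rho-aware) -> identifications -> tracks, all from one seed."""
    base = simulate_genome(spec)
    genome, genes = simulate_annotation(base, spec)
    snps = simulate_snps(genome, spec)
    flanks = snp_flanks(snps, genome.lengths, flank_bp=spec.flank_bp) if snps else []
    genome, truth = plant_peptides(genome, genes, spec, flanks=flanks)
    # mark in-flank truth flags from final placements
    if flanks:
        from .enrichment import count_overlapping

        for rec in truth.values():
            rec.in_flank = count_overlapping([rec.interval], flanks) == 1
    db_index = SegmentIndex(build_sixframe_db(genome, min_len=5))
    ids = simulate_identifications(truth, spec, db_index=db_index)
    tracks = simulate_tracks(genome, spec)
    return SyntheticDataset(
        spec=spec,
        genome=genome,
        genes=genes,
        truth=truth,
        identifications=ids,
        snp_positions=snps,
        tracks=tracks,
    )
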