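# Methods

## Coordinate model

All coordinates are 0-based half-open `[start, end)` internally; GFF3 and
labelled TSV inputs (1-based inclusive) are converted at the file
boundary, BED is consumed as-is. The "TSS" used for upstream windows and
distance statistics is the 5′ end of the annotated *gene* feature
(`start` on `+`, `end − 1` on `−`). This deliberately conflates
transcription and translation starts: the analysis operates on gene-level
annotation records, not transcript models, and when several isoforms
exist the union of exons/CDS across isoforms is used for classification
while the gene interval supplies the 5′ end.

## Six-frame stop-to-stop database

Each chromosome is translated with the standard genetic code in frames
+1/+2/+3 (forward, offsets 0/1/2) and −1/−2/−3 (reverse complement, same
offsets); the trailing partial codon is dropped. Any codon containing a
base outside ACGT translates to `X`; `X` never terminates a segment
because ambiguity is not evidence of a stop. Translations are split at
`*`, empty pieces dropped, and each piece keeps its genomic interval via
the linear frame arithmetic (interval length = 3 × residue count,
exactly). Leading and trailing stop-less pieces are retained as segments:
the construction splits purely at stops, and discarding chromosome-end
runs would lose genuine loci. Segment ids are deterministic (chromosome
order, frame order, position order), and the FASTA header dialect
(`>SEGn|chrom|frame|start|end|strand|L=0/1|T=0/1`) round-trips all
fields. The minimum segment length defaults to 1 residue and is exposed
as a knob; the count of such a database is sensitive to this option and
to the treatment of end segments, which is why external database-size
comparisons must state both.

## Peptide placement

Identified peptides are parsed from a PEAKS-export-style CSV
(`Peptide,Sample,z,m/z,Mass[,Score]`); modification annotations in
parentheses/brackets are stripped and rows with non-standard residues
rejected with a logged count. Deduplication is by exact sequence string,
globally and per sample. Placement is exact substring search over the
segment sequences (implemented as one concatenated sentinel-separated
text with offset mapping, so all occurrences are found); an optional flag
treats I and L as interchangeable, since their residue masses are
identical and MS cannot distinguish them — off by default. Downstream
genomic analyses use single-locus peptides only; multi-locus and unplaced
peptides are reported separately. Summaries use theoretical monoisotopic
masses computed from sequence (full-precision residue tables, water
18.0105647 Da, proton 1.007276 Da); observed masses are carried through
for QC only, and an average-mass table is provided as an option.

## Origin classification

A placement is **CP** iff it lies entirely within a single CDS part of a
same-strand gene and shares its phase-adjusted reading frame
(`(start − cds.start − phase) mod 3 = 0` on `+`;
`(cds.end − phase − end) mod 3 = 0` on `−`). Containment within one
contiguous CDS part is required because six-frame peptides are unspliced;
placements straddling a CDS boundary cannot be fragments of the annotated
protein and fall to NCP_exonic. Antisense CDS overlap is likewise
NCP_exonic: out-of-frame and antisense peptides equally cannot derive
from the annotated protein. NCP categories are assigned by largest
feature overlap with ties broken by the fixed precedence
exonic > 5′UTR > 3′UTR > intron > upstream > downstream; intergenic means
no feature overlap and no gene flank window hit. The upstream window is
1 kb from the TSS; the downstream window mirrors it at 1 kb (only the
upstream width is conventionally fixed; the mirror is this package's
choice). The start-codon report reads the first codon of the peptide's
own genomic span (reverse-complemented on `−`); the alternative — the
start of a containing upstream ORF — is a different question and is not
computed.

## Distribution statistics

Window densities use non-overlapping 1-Mb tiles (step = width), counting
each placement in the window containing its genomic start; a midpoint
anchor is available. "Intensive regions" are windows holding at least a
threshold count (default 2, configurable — there is no field-standard
cutoff) with adjacent qualifying windows merged. Neighbor distances are
consecutive start-to-start gaps per chromosome (summary fraction
≤ 500 kb); TSS distances are interval-to-point distances to the nearest
gene 5′ end on either strand, 0 when the TSS falls inside the span
(summary fraction ≤ 2 kb). The count-length association is a Pearson
correlation across chromosomes with a two-sided p (≥ 3 chromosomes
required; constant counts yield NA). Stage comparison is the exact Venn
partition of per-sample non-redundant peptide sets.

## Track overlap

Tracks (QTL with trait labels, LTR retrotransposons, sweeps, lncRNAs,
read alignments) are unstranded interval sets; a peptide is assigned to
every feature it overlaps by ≥ 1 bp (threshold configurable; any-overlap
rather than containment, flagged as a choice since no convention exists).
A peptide counts once per label regardless of how many same-label
features it hits; the overall fraction is peptides with ≥ 1 hit over
total.

## SNP-flank enrichment

Flanks are `[pos − 10 kb, pos + 10 kb + 1)` per SNP, clipped to the
chromosome and merged before counting, so a peptide near two SNPs counts
once. The background is *matched*: each of 100 replicates draws, per
chromosome, exactly as many fragments as real placements there, fragment
*i* inheriting the length of the *i*-th real placement, starts uniform in
`[0, L − len]`; fragments may overlap each other (no rejection — uniform
placement is the simplest faithful null). The observed overlap count is
scored by the upper tail of Normal(μ, σ) with μ, σ the replicate mean and
sample SD; because 100 replicates make the normal fit rough, the
empirical p `(1 + #{rep ≥ obs})/(n + 1)` is always reported alongside.
σ = 0 is a flagged degenerate path (p_normal = 1 when obs ≤ μ, ≈ 0
otherwise). Holding backgrounds fixed, p_normal is non-increasing in the
observed count.

## Synthetic data generator

The generator emulates the study conditions at desk scale: a
3-chromosome ≈ 1.3-Mb AT-rich genome (GC 0.35), 40 genes/Mb with 1–3
exons, 120–250-bp UTRs, 150–400-bp introns and 60–150-codon CDSs whose
coding sequence (ATG…stop, no internal stop) is written into the genome
so annotation and sequence agree by construction; three
developmental-stage samples (EL32/EL34/EL36) with Bernoulli detection at
0.6 per sample; peptide lengths 5 + Binomial(25, 0.2) (support 5–30, mode
10, echoing observed berry peptide length medians near 10); an
origin-category mix dominated by intergenic plants; 10 genome-absent
decoys; 20 SNPs with 10-kb flanks. Plant sites are drawn from
category-specific region pools with margins, and genes are spaced ≥ 3 kb
so flank windows never collide — planted sites are classifiable
unambiguously. Categories outside CDS are planted by rewriting the site
with codons encoding a random peptide (strand-aware); CP and
out-of-frame exonic peptides are instead *read off* the existing coding
sequence (rejection-sampled until stop-free), so the annotated reading
frame is never disturbed. Every planted peptide is verified to occur
exactly once in the six-frame database by literal search, with offenders
re-planted. With association fraction ρ > 0, that fraction of intergenic
plants is drawn from the intersection of the intergenic pool with the
SNP flanks.

What the generator does **not** emulate: spectral noise, missed
cleavages, PTMs, FDR structure, repeat families, spliced peptides, or
realistic gene density/LD. Passing tests therefore demonstrate
correctness of the coordinate arithmetic, classification logic and
statistics — not performance on real search-engine output, where
multi-locus rates (repeats) and modification handling dominate.

## Numerical and testing choices

Problem sizes were chosen so the whole suite runs in minutes on one CPU:
oracle equivalence on 200 random ≤ 1-kb sequences against an independent
brute-force codon walk; 100% extract-and-translate round-trip on a 1-Mb
genome with embedded N runs; planted-origin recovery ≥ 99% across 10
simulation seeds; monoisotopic mass/m-z agreement with an independent
residue table within 1e-4 Da on 1000 peptides; enrichment null
calibration over 200 uniform datasets (empirical rejection rate at 5%
must lie in [0.02, 0.09] — the empirical p is slightly conservative by
construction) and power ≥ 90% at ρ = 0.30 over 50 datasets. The
acceptance script uses the same study conditions with 120 calibration
datasets. Degenerate inputs (empty groups, single placements, constant
counts, σ = 0, genomes of all N) return NA or flagged results rather than
raising, except where the contract is a hard error (duplicate FASTA ids,
missing columns, zero charge, empty peptide sets).

## Known limitations

Spliced (exon-junction) peptides are invisible to a genomic six-frame
database — a limitation shared with the approach itself. Classification
trusts the annotation; unannotated genes make true CPs look intergenic.
The normal approximation for enrichment is rough at 100 replicates
(hence the empirical p), and the matched background conditions on
per-chromosome counts and lengths but not on local sequence composition.
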