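import pytest

from ncpmap.classify import GeneIndex, classify_all, classify_placement, start_codon
from ncpmap.genome import GeneModel, Genome, GenomicInterval, Transcript


@pytest.fixture
def simple_gene():
    """+ strand gene [100, 400): exon [100,400), CDS [150, 350) phase 0."""
    g = GeneModel("g1", GenomicInterval("c1", 100, 400, "+"))
    g.transcripts.append(
        Transcript(
            "g1.t1",
            exons=[GenomicInterval("c1", 100, 400, "+")],
            cds=[GenomicInterval("c1", 150, 350, "+")],
            phases=[0],
        )
    )
    return g


@pytest.fixture
def index(simple_gene):
    return GeneIndex([simple_gene])


def _call(iv, index):
    return classify_placement("PEP", iv, index)


def test_in_frame_cds_containment_is_cp(index):
    call = _call(GenomicInterval("c1", 150, 180, "+"), index)
    assert call.category == "CP"
    assert call.gene_id == "g1"
    assert call.overlap_bp == 30


def test_out_of_frame_is_ncp_exonic(index):
    assert _call(GenomicInterval("c1", 151, 181, "+"), index).category == "NCP_exonic"
    assert _call(GenomicInterval("c1", 152, 182, "+"), index).category == "NCP_exonic"


def test_antisense_cds_overlap_is_ncp_exonic(index):
    assert _call(GenomicInterval("c1", 150, 180, "-"), index).category == "NCP_exonic"


def test_cds_straddling_is_ncp_exonic(index):
    # in-frame lattice but extends past the CDS into the UTR
    assert _call(GenomicInterval("c1", 330, 360, "+"), index).category == "NCP_exonic"


def test_utr_categories(index):
    assert _call(GenomicInterval("c1", 110, 140, "+"), index).category == "NCP_5UTR"
    assert _call(GenomicInterval("c1", 360, 390, "+"), index).category == "NCP_3UTR"


def test_upstream_within_1kb(index):
    call = _call(GenomicInterval("c1", 50, 80, "+"), index)
    assert call.category == "NCP_upstream"
    assert call.gene_id == "g1"


def test_downstream_window(index):
    assert _call(GenomicInterval("c1", 500, 530, "+"), index).category == "NCP_downstream"


def test_intergenic_beyond_windows(index):
    assert _call(GenomicInterval("c1", 5000, 5030, "+"), index).category == "NCP_intergenic"


def test_largest_overlap_wins():
    """A placement 20 bp in the 5'UTR and 10 bp upstream is 5'UTR."""
    g = GeneModel("g1", GenomicInterval("c1", 100, 400, "+"))
    g.transcripts.append(
        Transcript(
            "t", exons=[GenomicInterval("c1", 100, 400, "+")],
            cds=[GenomicInterval("c1", 200, 350, "+")], phases=[0],
        )
    )
    index = GeneIndex([g])
    call = classify_placement("P", GenomicInterval("c1", 90, 120, "+"), index)
    assert call.category == "NCP_5UTR"
    assert call.overlap_bp == 20


def test_intron_category():
    g = GeneModel("g1", GenomicInterval("c1", 100, 400, "+"))
    g.transcripts.append(
        Transcript(
            "t",
            exons=[GenomicInterval("c1", 100, 200, "+"), GenomicInterval("c1", 300, 400, "+")],
            cds=[GenomicInterval("c1", 100, 200, "+"), GenomicInterval("c1", 300, 400, "+")],
            phases=[0, 2],
        )
    )
    index = GeneIndex([g])
    assert classify_placement("P", GenomicInterval("c1", 220, 250, "+"), index).category == "NCP_intron"


def test_minus_strand_frame_rule():
    """On '-', in-frame means (cds.end - phase - placement.end) % 3 == 0."""
    g = GeneModel("g1", GenomicInterval("c1", 100, 400, "-"))
    g.transcripts.append(
        Transcript(
            "t", exons=[GenomicInterval("c1", 100, 400, "-")],
            cds=[GenomicInterval("c1", 150, 350, "-")], phases=[0],
        )
    )
    index = GeneIndex([g])
    # cds.end = 350, phase 0: in-frame placements end at 350 - 3k
    assert classify_placement("P", GenomicInterval("c1", 200, 230, "-"), index).category == "CP"
    assert classify_placement("P", GenomicInterval("c1", 201, 231, "-"), index).category == "NCP_exonic"
    assert classify_placement("P", GenomicInterval("c1", 202, 232, "-"), index).category == "NCP_exonic"


def test_start_codon():
    genome = Genome({"c1": "ATGAAATAGGGC"})
    codon, is_aug = start_codon(GenomicInterval("c1", 0, 6, "+"), genome)
    assert (codon, is_aug) == ("ATG", True)
    codon, is_aug = start_codon(GenomicInterval("c1", 4, 10, "+"), genome)
    assert (codon, is_aug) == ("AAT", False)
    # '-' strand: first codon read from the right end, reverse-complemented
    codon, is_aug = start_codon(GenomicInterval("c1", 0, 12, "-"), genome)
    assert codon == "GCC" and not is_aug


def test_start_codon_ambiguous():
    genome = Genome({"c1": "ATNAAATAGGGC"})
    codon, is_aug = start_codon(GenomicInterval("c1", 0, 6, "+"), genome)
    assert codon == "ATN" and not is_aug


def test_classify_all_partition(dataset, analyzed):
    """Every single-locus peptide gets exactly one category; counts sum."""
    table, cats, strands = analyzed["table"], analyzed["cats"], analyzed["strands"]
    n_single = sum(lp.locus_status == "single_locus" for lp in analyzed["located"])
    assert sum(cats.values()) == n_single == len(table)
    assert sum(strands.values()) == n_single
    assert set(table.category) <= {
        "CP", "NCP_exonic", "NCP_5UTR", "NCP_3UTR", "NCP_intron",
        "NCP_upstream", "NCP_downstream", "NCP_intergenic",
    }


def test_classify_all_empty(simple_gene):
    table, cats, strands = classify_all([], [simple_gene])
    assert len(table) == 0 and not cats and not strands


def test_cp_sequences_are_protein_substrings(dataset, analyzed):
    """Frame-rule soundness: every CP is a substring of its supporting
    gene's translated protein (single-part CDS genes)."""
    from ncpmap.sixframe import translate_frame

    genes = {g.gene_id: g for g in dataset.genes}
    checked = 0
    for row in analyzed["table"].itertuples():
        if row.category != "CP":
            continue
        g = genes[row.gene_id]
        cds = g.cds_union
        if len(cds) != 1:
            continue
        protein = translate_frame(dataset.genome.fetch(cds[0]), "+1")
        assert row.peptide in protein
        checked += 1
    assert checked > 0
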