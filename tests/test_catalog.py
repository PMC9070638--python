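import numpy as np
import pytest
from pyteomics import mass as pyteomics_mass

from ncpmap.catalog import (
    IdentifiedPeptide,
    average_mass,
    deduplicate,
    locate_peptides,
    monoisotopic_mass,
    read_identifications,
    strip_modifications,
    summarize_catalog,
    theoretical_mz,
)
from ncpmap.genome import Genome
from ncpmap.sixframe import build_sixframe_db, translate_frame

AA20 = "ACDEFGHIKLMNPQRSTVWY"

CSV = """Peptide,Sample,z,m/z,Mass,Score
PEPTIDE,EL32,2,400.69,799.36,80.1
PEPT(+15.99)IDE,EL34,2,408.68,815.35,70.0
AAK,EL32,1,289.19,288.18,55.5
ABZ,EL32,1,100.0,99.0,10.0
"""


def test_read_identifications(tmp_path):
    path = tmp_path / "ids.csv"
    path.write_text(CSV)
    peptides = read_identifications(str(path))
    # modification stripped; non-standard residue row rejected
    assert [p.sequence for p in peptides] == ["PEPTIDE", "PEPTIDE", "AAK"]
    assert peptides[0].sample == "EL32" and peptides[0].charge == 2


def test_read_identifications_missing_column(tmp_path):
    path = tmp_path / "ids.csv"
    path.write_text("Peptide,Sample\nAAA,EL32\n")
    with pytest.raises(ValueError, match="Mass"):
        read_identifications(str(path))


def test_strip_modifications():
    assert strip_modifications("PEPT(+15.99)IDE") == "PEPTIDE"
    assert strip_modifications("M(ox)K[42.01]R") == "MKR"


def test_identified_peptide_invariants():
    with pytest.raises(ValueError):
        IdentifiedPeptide("", "EL32", 2, 1.0, 1.0)
    with pytest.raises(ValueError):
        IdentifiedPeptide("AAB", "EL32", 2, 1.0, 1.0)
    with pytest.raises(ValueError):
        IdentifiedPeptide("AAK", "EL32", 0, 1.0, 1.0)


def test_deduplicate():
    mk = lambda s, sample: IdentifiedPeptide(s, sample, 2, 1.0, 1.0)
    seqs, per_sample = deduplicate(
        [mk("AAA", "EL32"), mk("AAA", "EL32"), mk("AAK", "EL32"), mk("AAA", "EL36")]
    )
    assert seqs == ["AAA", "AAK"]
    assert per_sample == {"EL32": {"AAA", "AAK"}, "EL36": {"AAA"}}
    assert deduplicate([]) == ([], {})


def test_mass_examples():
    assert monoisotopic_mass("G") == pytest.approx(75.03203, abs=1e-4)
    assert monoisotopic_mass("PEPTIDE") == pytest.approx(799.3600, abs=1e-3)
    with pytest.raises(ValueError):
        monoisotopic_mass("")
    with pytest.raises(ValueError):
        monoisotopic_mass("AZ")


def test_mass_additivity():
    water = monoisotopic_mass("G") + monoisotopic_mass("K") - monoisotopic_mass("GK")
    assert water == pytest.approx(18.010565, abs=1e-6)


def test_mass_against_pyteomics():
    rng = np.random.default_rng(11)
    for _ in range(200):
        seq = "".join(rng.choice(list(AA20), size=int(rng.integers(1, 31))))
        assert monoisotopic_mass(seq) == pytest.approx(
            pyteomics_mass.calculate_mass(sequence=seq, monoisotopic=True), abs=1e-4
        )
        # average masses depend on the standard-atomic-weight convention;
        # agreement to ~0.1 Da over a 30-mer is the realistic bound
        assert average_mass(seq) == pytest.approx(
            pyteomics_mass.calculate_mass(sequence=seq, average=True), abs=0.1
        )


def test_theoretical_mz():
    assert theoretical_mz(799.3600, 2) == pytest.approx(400.6873, abs=1e-4)
    assert theoretical_mz(75.03203, 1) == pytest.approx(76.03931, abs=1e-4)
    with pytest.raises(ValueError):
        theoretical_mz(100.0, 0)
    # inverse identity
    mz = theoretical_mz(1234.5, 3)
    assert mz * 3 - 3 * 1.007276 == pytest.approx(1234.5, abs=1e-9)


def test_locate_single_and_multi_locus(toy_genome):
    db = build_sixframe_db(toy_genome)
    located = {lp.sequence: lp for lp in locate_peptides(["MK", "ZZZZ".replace("Z", "W")], db)}
    mk = located["MK"]
    assert mk.locus_status == "single_locus"
    iv = mk.placements[0].interval
    assert (iv.start, iv.end, iv.strand) == (0, 6, "+")
    assert located["WWWW"].locus_status == "unplaced"


def test_locate_multi_locus():
    genome = Genome({"c1": "GGGTAAGGG"})  # G segments in +1 before and after stop
    db = build_sixframe_db(genome)
    (lp,) = locate_peptides(["G"], db)
    assert lp.locus_status == "multi_locus"
    assert len(lp.placements) >= 2


def test_locate_il_equivalence():
    genome = Genome({"c1": "ATGATTAAG"})  # +1 translates to MIK
    db = build_sixframe_db(genome)
    (off,) = locate_peptides(["MLK"], db, il_equivalent=False)
    assert off.locus_status == "unplaced"
    (on,) = locate_peptides(["MLK"], db, il_equivalent=True)
    assert any(p.interval.start == 0 and p.interval.end == 9 for p in on.placements)


def test_placement_count_matches_bruteforce(dataset, analyzed):
    """Each peptide's placement count equals its occurrence count in a
    literal scan over all segment strings."""
    db = analyzed["db"]
    rng = np.random.default_rng(3)
    sample = rng.choice(sorted(dataset.truth), size=20, replace=False)
    for seq in sample:
        brute = sum(_count_overlapping_occurrences(s.sequence, seq) for s in db)
        (lp,) = locate_peptides([seq], db)
        assert len(lp.placements) == brute == 1


def _count_overlapping_occurrences(text, pat):
    n = start = 0
    while (i := text.find(pat, start)) != -1:
        n += 1
        start = i + 1
    return n


def test_placements_retranslate(dataset, analyzed):
    """translate(extract(interval)) equals the peptide for every placement."""
    for lp in analyzed["located"]:
        for p in lp.placements:
            nt = dataset.genome.fetch(p.interval)
            assert translate_frame(nt, "+1") == lp.sequence


def test_summarize_catalog():
    table = summarize_catalog({"A": ["GGGGGGGG", "G" * 10, "G" * 12], "B": []})
    row = table[table.group == "A"].iloc[0]
    assert row["count"] == 3
    assert row.median_length == 10
    assert row.frac_below_mass_cutoff == 1.0
    assert np.isnan(table[table.group == "B"].iloc[0].median_length)
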