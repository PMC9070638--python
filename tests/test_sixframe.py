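import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncpmap.genome import Genome, GenomicInterval
from ncpmap.sixframe import (
    FRAMES,
    build_sixframe_db,
    read_db_fasta,
    segment_frame,
    translate_frame,
    write_db_fasta,
)

from .conftest import random_dna
from .oracles import brute_force_sixframe, revcomp

dna = st.text(alphabet="ACGTN", min_size=0, max_size=120)


@pytest.mark.parametrize(
    "seq,frame,expected",
    [
        ("ATGAAATAGGGC", "+1", "MK*G"),
        ("ATGAAATAGGGC", "-1", "ALFH"),  # revcomp = GCCCTATTTCAT
        ("ATNAAA", "+1", "XK"),  # ambiguous codon -> X
        ("ATGAAATAGGGC", "+2", "*NR"),
        ("AT", "+1", ""),  # too short after offset
        ("ATGA", "+3", ""),
    ],
)
def test_translate_frame_examples(seq, frame, expected):
    assert translate_frame(seq, frame) == expected


def test_translate_frame_rejects_bad_frame():
    with pytest.raises(ValueError):
        translate_frame("ATG", "+4")


def test_segment_frame_plus_coordinates():
    segs = segment_frame("MK*G", "+1", "c1", 12)
    assert [(s.sequence, s.interval.start, s.interval.end, s.interval.strand) for s in segs] == [
        ("MK", 0, 6, "+"),
        ("G", 9, 12, "+"),
    ]
    assert segs[0].leading and not segs[0].trailing
    assert segs[1].trailing and not segs[1].leading


def test_segment_frame_offset_and_minus():
    (seg,) = segment_frame("*NR", "+2", "c1", 12)
    assert (seg.sequence, seg.interval.start, seg.interval.end) == ("NR", 4, 10)
    assert seg.trailing and not seg.leading
    (seg,) = segment_frame("ALFH", "-1", "c1", 12)
    assert (seg.sequence, seg.interval.start, seg.interval.end, seg.interval.strand) == (
        "ALFH", 0, 12, "-",
    )
    assert seg.leading and seg.trailing


def test_build_db_matches_bruteforce_on_toy(toy_genome):
    db = build_sixframe_db(toy_genome)
    got = {(s.frame, s.sequence, s.interval.start, s.interval.end, s.interval.strand) for s in db}
    expected = set(brute_force_sixframe(toy_genome["c1"]))
    assert got == expected


def test_all_n_genome_single_x_segment_per_frame():
    genome = Genome({"c1": "N" * 30})
    db = build_sixframe_db(genome)
    assert len(db) == 6  # one unbroken all-X segment per frame
    assert all(set(s.sequence) == {"X"} for s in db)


def test_min_len_filter(toy_genome):
    db = build_sixframe_db(toy_genome, min_len=3)
    assert all(len(s.sequence) >= 3 for s in db)
    assert {s.sequence for s in db} <= {s.sequence for s in build_sixframe_db(toy_genome)}


def test_segment_ids_deterministic_and_ordered(toy_genome):
    db = build_sixframe_db(toy_genome)
    assert [s.segment_id for s in db] == [f"SEG{i}" for i in range(1, len(db) + 1)]
    frame_order = [FRAMES.index(s.frame) for s in db]
    assert frame_order == sorted(frame_order)


def test_db_fasta_roundtrip(tmp_path, toy_genome):
    db = build_sixframe_db(toy_genome)
    path = tmp_path / "db.fa"
    write_db_fasta(db, str(path))
    header = path.read_text().splitlines()[0]
    assert header == ">SEG1|c1|+1|0|6|+|L=1|T=0"
    assert read_db_fasta(str(path)) == db


def test_db_fasta_empty(tmp_path):
    path = tmp_path / "db.fa"
    write_db_fasta([], str(path))
    assert path.read_text() == ""
    assert read_db_fasta(str(path)) == []


def _extract_translate(genome: Genome, seg) -> str:
    nt = genome.fetch(seg.interval)
    return translate_frame(nt, "+1")


def test_oracle_equivalence_random_sequences():
    """Segments and coordinates match the brute-force oracle exactly on
    random sequences with ambiguous bases."""
    rng = np.random.default_rng(42)
    for _ in range(60):
        seq = random_dna(rng, int(rng.integers(1, 400)), n_frac=0.01)
        genome = Genome({"c": seq}) if len(seq) else None
        got = {
            (s.frame, s.sequence, s.interval.start, s.interval.end, s.interval.strand)
            for s in build_sixframe_db(genome)
        }
        assert got == set(brute_force_sixframe(seq))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seq=st.text(alphabet="ACGTN", min_size=12, max_size=200))
def test_roundtrip_property(seq):
    """Extract-and-translate at each segment interval reproduces the
    stored sequence, on both strands and through X runs."""
    genome = Genome({"c": seq})
    for seg in build_sixframe_db(genome):
        assert _extract_translate(genome, seg) == seg.sequence


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seq=st.text(alphabet="ACGT", min_size=12, max_size=150))
def test_revcomp_symmetry(seq):
    """Building the DB on the reverse complement swaps +/- frame segment
    sets with mirrored intervals."""
    L = len(seq)
    fwd = build_sixframe_db(Genome({"c": seq}))
    rev = build_sixframe_db(Genome({"c": revcomp(seq)}))
    mirror = {
        (s.sequence, L - s.interval.end, L - s.interval.start, {"+": "-", "-": "+"}[s.interval.strand])
        for s in fwd
    }
    got = {(s.sequence, s.interval.start, s.interval.end, s.interval.strand) for s in rev}
    assert got == mirror


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seq=st.text(alphabet="ACGTN", min_size=3, max_size=200))
def test_residue_conservation(seq):
    """3 x (residues incl. stops) + dropped partial codon = length - offset."""
    for frame in FRAMES:
        off = int(frame[1]) - 1
        aa = translate_frame(seq, frame)
        dropped = (len(seq) - off) % 3 if len(seq) >= off else len(seq) - off
        assert 3 * len(aa) + max(0, dropped) == max(0, len(seq) - off)
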