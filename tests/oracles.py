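"""Independent brute-force oracles used only by the tests.

These reimplement the core operations in the most literal way possible —
position-by-position codon walks and all-pairs interval scans — so that
the package's faster implementations can be checked against them.
"""

from __future__ import annotations

_CODE = {}


def _build_code():
    # literal standard genetic code, spelled out independently of the package
    bases = "TCAG"
    aas = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                _CODE[b1 + b2 + b3] = aas[i]
                i += 1


_build_code()

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq))


def brute_force_sixframe(seq: str) -> list[tuple[str, str, int, int, str]]:
    """All stop-to-stop segments of all six frames of *seq*.

    Returns tuples (frame, aa_sequence, genomic_start, genomic_end, strand)
    built by a literal codon walk with explicit coordinate bookkeeping.
    """
    seq = seq.upper()
    L = len(seq)
    out = []
    for sign in ("+", "-"):
        working = seq if sign == "+" else revcomp(seq)
        for off in range(3):
            frame = f"{sign}{off + 1}"
            run = []
            run_start = None  # codon index within this frame
            for ci, i in enumerate(range(off, L - 2, 3)):
                codon = working[i : i + 3]
                aa = _CODE.get(codon, "X") if set(codon) <= set("ACGT") else "X"
                if aa == "*":
                    if run:
                        out.append(_locate(frame, "".join(run), run_start, ci, off, L, sign))
                    run, run_start = [], None
                else:
                    if not run:
                        run_start = ci
                    run.append(aa)
            if run:
                n_codons = (L - off) // 3
                out.append(_locate(frame, "".join(run), run_start, n_codons, off, L, sign))
    return out


def _locate(frame, aa, a, b, off, L, sign):
    if sign == "+":
        return (frame, aa, off + 3 * a, off + 3 * b, "+")
    return (frame, aa, L - off - 3 * b, L - off - 3 * a, "-")


def all_pairs_overlap(
    queries: list[tuple[str, int, int]], features: list[tuple[str, int, int]], min_bp: int = 1
) -> list[set[int]]:
    """For each query, the set of feature indices overlapping >= min_bp."""
    hits = []
    for qc, qs, qe in queries:
        s = set()
        for i, (fc, fs, fe) in enumerate(features):
            if qc == fc and min(qe, fe) - max(qs, fs) >= min_bp:
                s.add(i)
        hits.append(s)
    return hits
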