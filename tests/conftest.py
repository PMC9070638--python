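import numpy as np
import pytest

from ncpmap.catalog import locate_peptides
from ncpmap.classify import classify_all
from ncpmap.genome import Genome
from ncpmap.simulate import SimulationSpec, simulate_dataset
from ncpmap.sixframe import build_sixframe_db


@pytest.fixture(scope="session")
def toy_genome():
    """12-nt chromosome whose six frames are all hand-checkable."""
    return Genome({"c1": "ATGAAATAGGGC"})


@pytest.fixture(scope="session")
def dataset():
    """One full synthetic study shared across test modules."""
    return simulate_dataset(SimulationSpec(seed=7))


@pytest.fixture(scope="session")
def analyzed(dataset):
    """Database, located truth peptides and classification for `dataset`."""
    db = build_sixframe_db(dataset.genome, min_len=5)
    located = locate_peptides(sorted(dataset.truth), db)
    table, cats, strands = classify_all(located, dataset.genes, dataset.genome)
    return {"db": db, "located": located, "table": table, "cats": cats, "strands": strands}


def random_dna(rng: np.random.Generator, length: int, n_frac: float = 0.0) -> str:
    bases = rng.choice(list("ACGT"), size=length)
    if n_frac > 0:
        mask = rng.random(length) < n_frac
        bases[mask] = "N"
    return "".join(bases)
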