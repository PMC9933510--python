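import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ssrcore import GenotypeMatrix, GenotypeSimConfig, generate_genotypes


def make_matrix(rows: dict[str, list], locus_ids: list[str]) -> GenotypeMatrix:
    """Compact literal constructor: rows maps accession -> list of calls."""
    calls = {}
    for acc, vec in rows.items():
        for loc, call in zip(locus_ids, vec):
            calls[(acc, loc)] = call
    return GenotypeMatrix(list(rows), locus_ids, calls)


@pytest.fixture
def biallelic_equal():
    """One locus, allele frequencies exactly (0.5, 0.5): equal homozygote
    counts, so Ne=2, I=ln 2, Nei=0.5."""
    rows = {f"a{i}": [("A", "A")] for i in range(4)}
    rows.update({f"b{i}": [("B", "B")] for i in range(4)})
    return make_matrix(rows, ["L1"])


@pytest.fixture
def toy6():
    """Six accessions, three loci; accessions a0/a1 jointly carry every
    allele, so the minimum allele cover has size 2."""
    rows = {
        "a0": [("A", "B"), ("C", "C"), ("E", "F")],
        "a1": [("C", "C"), ("A", "B"), ("G", "G")],
        "a2": [("A", "A"), ("A", "A"), ("E", "E")],
        "a3": [("B", "B"), ("B", "B"), ("F", "F")],
        "a4": [("A", "B"), ("A", "C"), ("E", "G")],
        "a5": [("A", "A"), ("B", "C"), ("F", "G")],
    }
    return make_matrix(rows, ["L1", "L2", "L3"])


@pytest.fixture(scope="session")
def synthetic_160x40():
    """The study-scale synthetic collection: 160 accessions x 40 loci,
    2-5 alleles per locus, 2% missing data."""
    matrix, truth = generate_genotypes(
        GenotypeSimConfig(
            n_accessions=160, n_loci=40, alleles_per_locus=None,
            missing_rate=0.02, seed=11,
        )
    )
    return matrix, truth
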