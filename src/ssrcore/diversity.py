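"""Per-locus codominant diversity statistics.

Implements the seven statistics conventionally reported for SSR surveys
(as computed by GenAlEx / Popgene / PowerMarker):

* ``na``  — observed number of alleles,
* ``ne``  — effective number of alleles, :math:`1/\\sum p_i^2`,
* ``i``   — Shannon information index, :math:`-\\sum p_i \\ln p_i`,
* ``ho``  — observed heterozygosity (heterozygous / typed accessions),
* ``he``  — unbiased expected heterozygosity, :math:`\\frac{2N}{2N-1}(1-\\sum p_i^2)`,
* ``nei`` — Nei's gene diversity, :math:`1-\\sum p_i^2`,
* ``pic`` — polymorphism information content (Botstein),
  :math:`1-\\sum p_i^2-\\sum_{i<j} 2 p_i^2 p_j^2`.

Missing calls are excluded per locus (pairwise deletion), so the typed
sample size N varies across loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "AlleleFrequencies",
    "LocusDiversity",
    "allele_frequencies",
    "locus_diversity",
    "collection_summary",
    "round_half_up",
]

STAT_COLUMNS = ["na", "ne", "i", "ho", "he", "nei", "pic"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention of printed SSR tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AlleleFrequencies:
    locus_id: str
    n_typed: int
    freqs: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies sum to {total}, not 1")
        if any(p <= 0 for p in self.freqs.values()):
            raise ValueError("listed alleles must have positive frequency")


@dataclass(frozen=True)
class LocusDiversity:
    locus_id: str
    na: int
    ne: float
    i: float
    ho: float
    he: float
    nei: float
    pic: float


def allele_frequencies(matrix: GenotypeMatrix, locus: str) -> AlleleFrequencies:
    """Allele frequencies at one locus from typed accessions (2N draws)."""
    counts: dict[str, int] = {}
    n_typed = 0
    for call in matrix.locus_calls(locus):
        if call is None:
            continue
        n_typed += 1
        for allele in call:
            counts[allele] = counts.get(allele, 0) + 1
    if n_typed == 0:
        raise ValueError(f"locus {locus!r} has no typed accessions")
    total = 2 * n_typed
    freqs = {a: c / total for a, c in sorted(counts.items())}
    return AlleleFrequencies(locus_id=locus, n_typed=n_typed, freqs=freqs)


def locus_diversity(
    freqs: AlleleFrequencies, matrix: GenotypeMatrix, locus: str
) -> LocusDiversity:
    """The seven diversity statistics for one locus."""
    p = np.array(list(freqs.freqs.values()), dtype=float)
    sum_p2 = float(np.sum(p**2))
    na = len(p)
    ne = 1.0 / sum_p2
    shannon = float(-np.sum(p * np.log(p)))
    nei = 1.0 - sum_p2
    n = freqs.n_typed
    he = (2 * n / (2 * n - 1)) * nei if n > 0 else 0.0
    # Botstein PIC: 1 - sum p^2 - sum_{i<j} 2 p_i^2 p_j^2
    pic = nei - float((np.sum(p**2) ** 2 - np.sum(p**4)))  # = nei - sum_{i!=j} p_i^2 p_j^2
    typed = [c for c in matrix.locus_calls(locus) if c is not None]
    n_het = sum(1 for a, b in typed if a != b)
    ho = n_het / len(typed) if typed else 0.0
    return LocusDiversity(
        locus_id=freqs.locus_id,
        na=na,
        ne=ne,
        i=shannon,
        ho=ho,
        he=he,
        nei=nei,
        pic=pic,
    )


def collection_summary(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus diversity table with an unweighted ``Mean`` row.

    Rows are loci in matrix order; columns ``na ne i ho he nei pic``.  The
    final row, indexed ``Mean``, holds arithmetic column means over loci
    (``na`` mean is the mean allele count; total alleles is the column sum
    over locus rows).
    """
    if matrix.n_loci < 1:
        raise ValueError("matrix has no loci")
    rows = []
    for locus in matrix.locus_ids:
        freqs = allele_frequencies(matrix, locus)
        div = locus_diversity(freqs, matrix, locus)
        rows.append(
            {
                "na": div.na,
                "ne": div.ne,
                "i": div.i,
                "ho": div.ho,
                "he": div.he,
                "nei": div.nei,
                "pic": div.pic,
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(matrix.locus_ids, name="locus"))
    table.loc["Mean"] = table.mean(axis=0)
    return table


def total_alleles(summary: pd.DataFrame) -> int:
    """Total distinct alleles across loci (sum of the ``na`` column)."""
    return int(summary.drop(index="Mean")["na"].sum())


def rounded_summary(summary: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Table rounded half-away-from-zero, as printed in reports."""
    out = summary.copy()
    for col in out.columns:
        out[col] = [round_half_up(v, ndigits) for v in out[col]]
    return out
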