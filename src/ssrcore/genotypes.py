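"""Codominant diploid genotype matrix: accessions x SSR loci.

Calls are unordered allele pairs (``("A", "B")`` equals ``("B", "A")``);
allele labels are opaque tokens.  Missing calls are ``None`` and always
explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = ["Genotype", "GenotypeMatrix"]

Genotype = tuple[str, str] | None


def _norm(call: Genotype) -> Genotype:
    if call is None:
        return None
    a, b = call
    return (a, b) if a <= b else (b, a)


@dataclass
class GenotypeMatrix:
    """Rectangular accession-by-locus table of diploid codominant calls."""

    accession_ids: list[str]
    locus_ids: list[str]
    calls: dict[tuple[str, str], Genotype] = field(repr=False)

    def __init__(
        self,
        accession_ids: Sequence[str],
        locus_ids: Sequence[str],
        calls: dict[tuple[str, str], Genotype],
    ) -> None:
        if len(set(accession_ids)) != len(accession_ids):
            raise ValueError("duplicate accession ids")
        if len(set(locus_ids)) != len(locus_ids):
            raise ValueError("duplicate locus ids")
        self.accession_ids = list(accession_ids)
        self.locus_ids = list(locus_ids)
        self.calls = {}
        for acc in self.accession_ids:
            for loc in self.locus_ids:
                self.calls[(acc, loc)] = _norm(calls.get((acc, loc)))

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def call(self, accession: str, locus: str) -> Genotype:
        return self.calls[(accession, locus)]

    def locus_calls(self, locus: str) -> list[Genotype]:
        """Calls at one locus, in accession order."""
        if locus not in self.locus_ids:
            raise KeyError(f"unknown locus {locus!r}")
        return [self.calls[(acc, locus)] for acc in self.accession_ids]

    def accession_calls(self, accession: str) -> list[Genotype]:
        if accession not in self.accession_ids:
            raise KeyError(f"unknown accession {accession!r}")
        return [self.calls[(accession, loc)] for loc in self.locus_ids]

    def subset(self, accessions: Iterable[str]) -> "GenotypeMatrix":
        """Sub-matrix restricted to the given accessions (order preserved)."""
        accs = list(accessions)
        unknown = set(accs) - set(self.accession_ids)
        if unknown:
            raise KeyError(f"accessions not in matrix: {sorted(unknown)}")
        keep = [a for a in self.accession_ids if a in set(accs)]
        calls = {
            (a, l): self.calls[(a, l)] for a in keep for l in self.locus_ids
        }
        return GenotypeMatrix(keep, list(self.locus_ids), calls)

    def distinct_alleles(self) -> set[tuple[str, str]]:
        """All observed (locus, allele) pairs."""
        out: set[tuple[str, str]] = set()
        for (_, loc), call in self.calls.items():
            if call is not None:
                out.add((loc, call[0]))
                out.add((loc, call[1]))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and self.locus_ids == other.locus_ids
            and self.calls == other.calls
        )
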