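"""Independent brute-force oracles used to check the implementation.

These deliberately re-derive expected results by a different route than
the package (regex scans, exhaustive enumeration, direct linear algebra)
and stay free of package internals beyond public data types.
"""

from __future__ import annotations

import itertools
import math
import re

import numpy as np

DEFAULT_THRESHOLDS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


def _reducible(motif: str) -> bool:
    n = len(motif)
    return any(
        n % p == 0 and motif == motif[:p] * (n // p) for p in range(1, n)
    )


def regex_ssr_scan(seq: str, thresholds=None) -> set[tuple[int, int, str, int]]:
    """Brute-force regex scan for maximal perfect repeats.

    Returns {(start_1based, end_1based, motif, n_repeats)} after applying
    the same documented reporting conventions: leftmost phase of each
    maximal run, whole-copy truncation, irreducible motifs only, and
    suppression of loci fully contained in a longer locus (shorter motif
    preferred on identical spans).
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS
    seq = seq.upper()
    raw: list[tuple[int, int, str, int]] = []
    for m in range(1, 7):
        k = thresholds[m]
        pat = re.compile(r"([ACGT]{%d})\1{%d,}" % (m, k - 1))
        pos = 0
        while True:
            match = pat.search(seq, pos)
            if not match:
                break
            motif = match.group(1)
            if _reducible(motif):
                pos = match.start() + 1
                continue
            reps = len(match.group(0)) // m
            raw.append((match.start() + 1, match.start() + reps * m, motif, reps))
            pos = match.end() - m + 1
    out = set()
    for cand in raw:
        s, e, motif, _ = cand
        nested = any(
            other != cand
            and other[0] <= s
            and e <= other[1]
            and (
                other[1] - other[0] > e - s
                or ((other[0], other[1]) == (s, e) and len(other[2]) < len(motif))
            )
            for other in raw
        )
        if not nested:
            out.add(cand)
    return out


def exhaustive_best_subset(matrix, size: int, objective) -> float:
    """Best objective value over all C(n, size) accession subsets."""
    best = -math.inf
    for combo in itertools.combinations(matrix.accession_ids, size):
        best = max(best, objective(matrix.subset(list(combo))))
    return best


def subset_allele_count(sub) -> float:
    return float(len(sub.distinct_alleles()))


def subset_gene_diversity(sub) -> float:
    """Mean per-locus Nei gene diversity, direct counting."""
    vals = []
    for loc in sub.locus_ids:
        counts: dict[str, int] = {}
        for call in sub.locus_calls(loc):
            if call is None:
                continue
            for a in call:
                counts[a] = counts.get(a, 0) + 1
        tot = sum(counts.values())
        if tot:
            vals.append(1.0 - sum((c / tot) ** 2 for c in counts.values()))
    return float(np.mean(vals)) if vals else 0.0


def minimum_cover_size(matrix) -> int:
    """Smallest subset covering all alleles, by exhaustive search."""
    target = matrix.distinct_alleles()
    for size in range(1, matrix.n_accessions + 1):
        for combo in itertools.combinations(matrix.accession_ids, size):
            if matrix.subset(list(combo)).distinct_alleles() == target:
                return size
    raise AssertionError("unreachable: full collection covers itself")


def classical_mds(distances: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hand-rolled classical scaling: eigendecomposition of the Gower matrix.

    Returns (eigenvalues descending, coordinates over positive axes).
    """
    d2 = np.asarray(distances, dtype=float) ** 2
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-12
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    return vals, coords
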