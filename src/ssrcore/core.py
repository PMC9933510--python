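"""Core-collection construction from codominant genotype data.

Three selection strategies over an accessions-by-loci genotype matrix:

* **M strategy** (:func:`greedy_m_core`) — greedy allele-coverage
  maximization: accessions are added in order of how many not-yet-covered
  alleles they contribute, stopping when every allele observed in the
  full collection is covered.  The subset size is data-driven and the
  allele coverage is 100% by construction.
* **Simulated annealing at fixed size** (:func:`anneal_core`) — stochastic
  search over fixed-size subsets by single-accession swap moves with
  Metropolis acceptance and geometric cooling, maximizing either the
  total number of distinct alleles (allele-number criterion) or mean
  per-locus gene diversity (gene-diversity criterion).
* **Mixed distance/diversity objective** (:func:`mixed_objective_core`) —
  the same annealer maximizing a weighted sum of mean pairwise Modified
  Rogers distance within the subset and the subset's Shannon diversity
  normalized by the full collection's (so both terms are comparable),
  the criterion pair used by Core Hunter-style selectors.

Missing calls contribute nothing to allele counts or frequencies; the
Modified Rogers distance is computed over pairwise-typed loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import collection_summary
from .genotypes import GenotypeMatrix

__all__ = [
    "CoreObjective",
    "AnnealSchedule",
    "CoreSubset",
    "mr_distance",
    "mr_distance_matrix",
    "greedy_m_core",
    "anneal_core",
    "mixed_objective_core",
]


@dataclass(frozen=True)
class CoreObjective:
    kind: str = "allele_count"  # allele_count | gene_diversity | mixed
    mr_weight: float = 0.5
    sh_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in {"allele_count", "gene_diversity", "mixed"}:
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.mr_weight < 0 or self.sh_weight < 0:
            raise ValueError("objective weights must be nonnegative")
        if self.kind == "mixed" and abs(self.mr_weight + self.sh_weight - 1) > 1e-9:
            raise ValueError("mixed-objective weights must sum to 1")


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric-cooling schedule; ``initial_temperature=None`` auto-calibrates
    so roughly half of worsening moves are accepted at the start."""

    initial_temperature: float | None = None
    cooling_factor: float = 0.95
    steps: int = 200
    moves_per_step: int | None = None  # default: n_accessions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_temperature is not None and self.initial_temperature <= 0:
            raise ValueError("initial temperature must be positive")
        if not 0.0 < self.cooling_factor < 1.0:
            raise ValueError("cooling factor must lie in (0, 1)")


@dataclass
class CoreSubset:
    """A selected accession subset with its quality summary."""

    method: str
    accession_ids: list[str]
    collection_ids: list[str] = field(repr=False)
    sampling_ratio: float = 0.0
    allele_coverage: float = 0.0
    objective_value: float = 0.0
    diversity: pd.DataFrame | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Modified Rogers distance


def _allele_profile(matrix: GenotypeMatrix):
    """Per-accession within-locus allele "frequencies" (0, 0.5 or 1).

    Returns (X, typed, columns): X is accessions x allele-columns, typed a
    boolean accessions x loci mask, columns the (locus, allele) labels.
    """
    columns: list[tuple[str, str]] = []
    col_index: dict[tuple[str, str], int] = {}
    for loc in matrix.locus_ids:
        alleles = set()
        for call in matrix.locus_calls(loc):
            if call is not None:
                alleles.update(call)
        for a in sorted(alleles):
            col_index[(loc, a)] = len(columns)
            columns.append((loc, a))
    n, m = matrix.n_accessions, len(columns)
    X = np.zeros((n, m))
    typed = np.zeros((n, matrix.n_loci), dtype=bool)
    for i, acc in enumerate(matrix.accession_ids):
        for j, loc in enumerate(matrix.locus_ids):
            call = matrix.call(acc, loc)
            if call is None:
                continue
            typed[i, j] = True
            for allele in call:
                X[i, col_index[(loc, allele)]] += 0.5
    return X, typed, columns


def mr_distance(
    a: list, b: list, locus_ids: list[str] | None = None
) -> float:
    """Modified Rogers distance between two accessions' genotype vectors.

    ``a`` and ``b`` are equal-length lists of unordered allele pairs (or
    None for missing).  d = sqrt((1/(2L)) * sum over pairwise-typed loci of
    the squared differences of within-locus allele frequencies (0/0.5/1)),
    where L is the number of pairwise-typed loci.  Ranges over [0, 1].
    """
    if len(a) != len(b):
        raise ValueError("genotype vectors differ in length")
    total = 0.0
    n_shared = 0
    for ga, gb in zip(a, b):
        if ga is None or gb is None:
            continue
        n_shared += 1
        alleles = set(ga) | set(gb)
        for allele in alleles:
            xa = (ga.count(allele)) / 2.0
            xb = (gb.count(allele)) / 2.0
            total += (xa - xb) ** 2
    if n_shared == 0:
        raise ValueError("accessions share no typed locus")
    return math.sqrt(total / (2 * n_shared))


def mr_distance_matrix(matrix: GenotypeMatrix) -> np.ndarray:
    """Symmetric matrix of pairwise Modified Rogers distances."""
    n = matrix.n_accessions
    rows = [matrix.accession_calls(acc) for acc in matrix.accession_ids]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = mr_distance(rows[i], rows[j])
    return D


# ---------------------------------------------------------------------------
# greedy M strategy


def greedy_m_core(matrix: GenotypeMatrix) -> CoreSubset:
    """Greedy allele-coverage core (M strategy).

    Repeatedly adds the accession contributing the most not-yet-covered
    alleles (ties: larger gene-diversity gain, then lexicographic id)
    until all alleles of the full collection are covered.  Coverage is
    1.0 by construction; the subset size is data-driven.
    """
    if matrix.n_accessions < 1:
        raise ValueError("empty collection")
    target = matrix.distinct_alleles()
    acc_alleles: dict[str, set[tuple[str, str]]] = {}
    for acc in matrix.accession_ids:
        alleles: set[tuple[str, str]] = set()
        for loc, call in zip(matrix.locus_ids, matrix.accession_calls(acc)):
            if call is not None:
                alleles.add((loc, call[0]))
                alleles.add((loc, call[1]))
        acc_alleles[acc] = alleles

    chosen: list[str] = []
    covered: set[tuple[str, str]] = set()
    remaining = sorted(matrix.accession_ids)
    while covered != target:
        best_acc = None
        best_key: tuple | None = None
        for acc in remaining:
            gain = len(acc_alleles[acc] - covered)
            if gain == 0:
                continue
            key = (gain, _diversity_gain(matrix, chosen, acc), _NegStr(acc))
            if best_key is None or key > best_key:
                best_key, best_acc = key, acc
        if best_acc is None:  # pragma: no cover - target built from same calls
            break
        chosen.append(best_acc)
        covered |= acc_alleles[best_acc]
        remaining.remove(best_acc)

    return _finish_subset(matrix, chosen, "mstrategy", float(len(covered)))


class _NegStr(str):
    """String ordered reversed, so max() prefers the lexicographically
    smallest accession id on full ties."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def _diversity_gain(matrix: GenotypeMatrix, chosen: list[str], cand: str) -> float:
    """Mean per-locus gene diversity of chosen + candidate (tie-break only)."""
    sub = matrix.subset(chosen + [cand])
    return _mean_nei(sub)


def _mean_nei(sub: GenotypeMatrix) -> float:
    total, n_loci = 0.0, 0
    for loc in sub.locus_ids:
        counts: dict[str, int] = {}
        for call in sub.locus_calls(loc):
            if call is None:
                continue
            for allele in call:
                counts[allele] = counts.get(allele, 0) + 1
        tot = sum(counts.values())
        if tot == 0:
            continue
        n_loci += 1
        total += 1.0 - sum((c / tot) ** 2 for c in counts.values())
    return total / n_loci if n_loci else 0.0


# ---------------------------------------------------------------------------
# simulated annealing


def _subset_objective(
    members: np.ndarray,
    objective: CoreObjective,
    X: np.ndarray,
    typed: np.ndarray,
    columns: list[tuple[str, str]],
    locus_of_col: np.ndarray,
    n_loci: int,
    D: np.ndarray | None,
    sh_full: float | None,
) -> float:
    idx = np.flatnonzero(members)
    Xs, ts = X[idx], typed[idx]
    if objective.kind == "allele_count":
        return float(np.count_nonzero(Xs.sum(axis=0) > 0))
    # per-locus allele frequencies within the subset
    col_sums = Xs.sum(axis=0)
    locus_tot = np.zeros(n_loci)
    np.add.at(locus_tot, locus_of_col, col_sums)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(locus_tot[locus_of_col] > 0, col_sums / locus_tot[locus_of_col], 0.0)
    if objective.kind == "gene_diversity":
        sum_p2 = np.zeros(n_loci)
        np.add.at(sum_p2, locus_of_col, p**2)
        live = locus_tot > 0
        return float(np.mean(1.0 - sum_p2[live])) if live.any() else 0.0
    # mixed: mr_weight * mean pairwise MR + sh_weight * SH / SH_full
    assert D is not None and sh_full is not None
    if len(idx) > 1:
        sub_d = D[np.ix_(idx, idx)]
        mean_mr = float(sub_d[np.triu_indices(len(idx), 1)].mean())
    else:
        mean_mr = 0.0
    pos = p > 0
    sh = float(-(p[pos] * np.log(p[pos])).sum())
    sh_term = sh / sh_full if sh_full > 0 else 0.0
    return objective.mr_weight * mean_mr + objective.sh_weight * sh_term


def _anneal(
    matrix: GenotypeMatrix,
    size: int,
    objective: CoreObjective,
    schedule: AnnealSchedule,
    method: str,
) -> CoreSubset:
    n = matrix.n_accessions
    if not 1 <= size <= n:
        raise ValueError(f"core size {size} outside [1, {n}]")
    X, typed, columns = _allele_profile(matrix)
    loci = matrix.locus_ids
    locus_of_col = np.array([loci.index(loc) for loc, _ in columns])
    D = sh_full = None
    if objective.kind == "mixed":
        D = mr_distance_matrix(matrix)
        sh_full = _shannon_total(X, locus_of_col, len(loci))

    def score(members: np.ndarray) -> float:
        return _subset_objective(
            members, objective, X, typed, columns, locus_of_col, len(loci), D, sh_full
        )

    rng = np.random.default_rng(schedule.seed)
    members = np.zeros(n, dtype=bool)
    members[rng.choice(n, size=size, replace=False)] = True
    current = score(members)
    best_members, best = members.copy(), current

    moves = schedule.moves_per_step or n
    temp = schedule.initial_temperature
    if temp is None:
        temp = _calibrate_temperature(rng, members, score, size, n)

    if size < n:
        for _ in range(schedule.steps):
            for _ in range(moves):
                inside = np.flatnonzero(members)
                outside = np.flatnonzero(~members)
                i = inside[rng.integers(len(inside))]
                j = outside[rng.integers(len(outside))]
                members[i], members[j] = False, True
                new = score(members)
                delta = new - current
                if delta >= 0 or rng.random() < math.exp(delta / temp):
                    current = new
                    if new > best:
                        best, best_members = new, members.copy()
                else:
                    members[i], members[j] = True, False
            temp *= schedule.cooling_factor

    chosen = [matrix.accession_ids[i] for i in np.flatnonzero(best_members)]
    return _finish_subset(matrix, chosen, method, best)


def _shannon_total(X: np.ndarray, locus_of_col: np.ndarray, n_loci: int) -> float:
    col_sums = X.sum(axis=0)
    locus_tot = np.zeros(n_loci)
    np.add.at(locus_tot, locus_of_col, col_sums)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(locus_tot[locus_of_col] > 0, col_sums / locus_tot[locus_of_col], 0.0)
    pos = p > 0
    return float(-(p[pos] * np.log(p[pos])).sum())


def _calibrate_temperature(rng, members, score, size, n) -> float:
    """Temperature at which ~half of observed worsening moves are accepted."""
    if size >= n:
        return 1.0
    deltas = []
    trial = members.copy()
    current = score(trial)
    for _ in range(50):
        inside = np.flatnonzero(trial)
        outside = np.flatnonzero(~trial)
        i = inside[rng.integers(len(inside))]
        j = outside[rng.integers(len(outside))]
        trial[i], trial[j] = False, True
        new = score(trial)
        if new < current:
            deltas.append(current - new)
        trial[i], trial[j] = True, False
    if not deltas:
        return 1.0
    return float(np.median(deltas) / math.log(2.0))


def anneal_core(
    matrix: GenotypeMatrix,
    size: int,
    objective: CoreObjective | None = None,
    schedule: AnnealSchedule | None = None,
) -> CoreSubset:
    """Fixed-size core by simulated annealing on allele number (SANA-style,
    ``kind="allele_count"``) or gene diversity (SAGD-style,
    ``kind="gene_diversity"``)."""
    objective = objective or CoreObjective(kind="allele_count")
    if objective.kind == "mixed":
        raise ValueError("use mixed_objective_core for the mixed criterion")
    schedule = schedule or AnnealSchedule()
    method = "sana" if objective.kind == "allele_count" else "sagd"
    return _anneal(matrix, size, objective, schedule, method)


def mixed_objective_core(
    matrix: GenotypeMatrix,
    size: int,
    mr_weight: float = 0.5,
    sh_weight: float = 0.5,
    schedule: AnnealSchedule | None = None,
) -> CoreSubset:
    """Fixed-size core maximizing mr_weight * mean pairwise Modified Rogers
    distance + sh_weight * (subset Shannon diversity / full-collection
    Shannon diversity), the Core Hunter-style mixed criterion."""
    objective = CoreObjective(kind="mixed", mr_weight=mr_weight, sh_weight=sh_weight)
    schedule = schedule or AnnealSchedule()
    return _anneal(matrix, size, objective, schedule, "mixed")


def _finish_subset(
    matrix: GenotypeMatrix,
    chosen: list[str],
    method: str,
    objective_value: float,
) -> CoreSubset:
    sub = matrix.subset(chosen)
    coverage = (
        len(sub.distinct_alleles()) / len(matrix.distinct_alleles())
        if matrix.distinct_alleles()
        else 0.0
    )
    return CoreSubset(
        method=method,
        accession_ids=sorted(chosen),
        collection_ids=list(matrix.accession_ids),
        sampling_ratio=len(chosen) / matrix.n_accessions,
        allele_coverage=coverage,
        objective_value=objective_value,
        diversity=collection_summary(sub),
    )
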