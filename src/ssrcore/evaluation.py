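"""Evaluation of core subsets against the full collection.

* :func:`compare_core` — per-parameter two-sided t-tests (Welch by
  default, paired optional) of per-locus diversity statistics between a
  core subset and the full collection, plus allele retention.
* :func:`pcoa` — classical metric scaling (principal coordinates) of a
  genetic distance matrix, for core-vs-all ordination plots.
* :func:`intersect_methods` — accession overlap across method outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .core import CoreSubset
from .diversity import STAT_COLUMNS, collection_summary
from .genotypes import GenotypeMatrix

__all__ = ["ComparisonReport", "PCoAResult", "compare_core", "pcoa", "intersect_methods"]


@dataclass
class ComparisonReport:
    """Full-vs-core diversity comparison (the core-evaluation table)."""

    table: pd.DataFrame  # rows: na ne i ho he nei pic; cols: full, core, p_value
    allele_retention: float
    test: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_retention <= 1.0:
            raise ValueError("allele retention outside [0, 1]")


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # accessions x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray


def compare_core(
    full: GenotypeMatrix, core: CoreSubset, paired: bool = False
) -> ComparisonReport:
    """Compare per-locus diversity of a core subset with the full collection.

    For each of the seven statistics, a two-sided t-test over the
    per-locus values (Welch unequal-variance by default; ``paired=True``
    pairs loci, which are shared between the two sets).  Identical value
    vectors give p = 1.  Allele retention is the fraction of the full
    collection's distinct alleles present in the core.
    """
    if not core.accession_ids:
        raise ValueError("core subset is empty")
    missing = set(core.accession_ids) - set(full.accession_ids)
    if missing:
        raise ValueError(f"core accessions not in collection: {sorted(missing)}")

    sub = full.subset(core.accession_ids)
    full_div = collection_summary(full).drop(index="Mean")
    core_div = collection_summary(sub).drop(index="Mean")

    rows = {}
    for col in STAT_COLUMNS:
        a = full_div[col].to_numpy(dtype=float)
        b = core_div[col].to_numpy(dtype=float)
        if np.array_equal(a, b):
            p = 1.0
        elif paired:
            p = float(stats.ttest_rel(a, b).pvalue)
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows[col] = {"full": float(a.mean()), "core": float(b.mean()), "p_value": p}
    table = pd.DataFrame(rows).T[["full", "core", "p_value"]]
    retention = len(sub.distinct_alleles()) / len(full.distinct_alleles())
    return ComparisonReport(
        table=table,
        allele_retention=retention,
        test="paired" if paired else "welch",
    )


def pcoa(
    distances: np.ndarray | pd.DataFrame,
    n_axes: int = 2,
    ids: list[str] | None = None,
) -> PCoAResult:
    """Principal coordinates analysis of a symmetric distance matrix.

    Classical metric scaling: the Gower-centered squared-distance matrix
    is eigendecomposed; axes are ordered by eigenvalue and coordinates
    are built from positive-eigenvalue axes only.  Negative eigenvalues
    (non-Euclidean distances) are retained in ``eigenvalues``.  Asking
    for more axes than there are positive eigenvalues truncates with a
    warning.
    """
    if isinstance(distances, pd.DataFrame):
        ids = ids or [str(i) for i in distances.index]
        mat = distances.to_numpy(dtype=float)
    else:
        mat = np.asarray(distances, dtype=float)
        ids = ids or [str(i) for i in range(mat.shape[0])]
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")

    dm = DistanceMatrix(mat, ids=ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = _skbio_pcoa(dm, method="eigh", inplace=False)

    eigvals = res.eigvals.to_numpy()
    n_positive = int(np.sum(eigvals > 1e-12))
    if n_axes > n_positive:
        warnings.warn(
            f"requested {n_axes} axes but only {n_positive} positive "
            "eigenvalues; truncating",
            stacklevel=2,
        )
        n_axes = n_positive
    coords = res.samples.iloc[:, :n_axes].copy()
    coords.index = pd.Index(ids, name="accession")
    coords.columns = [f"axis{k + 1}" for k in range(n_axes)]
    return PCoAResult(
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=res.proportion_explained.to_numpy(),
    )


def intersect_methods(subsets: list[CoreSubset]) -> dict:
    """Shared accessions and pairwise overlap counts across method outputs.

    All subsets must come from the same collection.  Returns the overall
    intersection, per-pair overlap counts and the per-method sizes
    (Venn-style bookkeeping).
    """
    if len(subsets) < 2:
        raise ValueError("need at least two subsets to intersect")
    collections = {tuple(s.collection_ids) for s in subsets}
    if len(collections) != 1:
        raise ValueError("subsets come from different collections")
    sets = {s.method: set(s.accession_ids) for s in subsets}
    if len(sets) != len(subsets):
        raise ValueError("duplicate method labels among subsets")
    shared = set.intersection(*sets.values())
    pairwise = {
        (m1, m2): len(sets[m1] & sets[m2])
        for m1, m2 in combinations(sorted(sets), 2)
    }
    return {
        "shared": sorted(shared),
        "n_shared": len(shared),
        "pairwise": pairwise,
        "sizes": {m: len(v) for m, v in sets.items()},
    }
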