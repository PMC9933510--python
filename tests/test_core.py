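"""Core-collection selection: M strategy, annealing, mixed objective."""

import itertools

import numpy as np
import pytest

from conftest import make_matrix
from oracles import (
    exhaustive_best_subset,
    minimum_cover_size,
    subset_allele_count,
    subset_gene_diversity,
)
from ssrcore import (
    AnnealSchedule,
    CoreObjective,
    GenotypeSimConfig,
    anneal_core,
    generate_genotypes,
    greedy_m_core,
    mixed_objective_core,
    mr_distance,
    mr_distance_matrix,
)


class TestMRDistance:
    def test_identity(self):
        a = [("A", "B"), ("C", "C")]
        assert mr_distance(a, list(a)) == 0.0

    def test_maximal_divergence_single_locus(self):
        assert mr_distance([("A", "A")], [("B", "B")]) == pytest.approx(1.0)

    def test_het_vs_hom_half(self):
        assert mr_distance([("A", "B")], [("A", "A")]) == pytest.approx(0.5)

    def test_missing_loci_skipped(self):
        a = [("A", "A"), None, ("C", "C")]
        b = [("B", "B"), ("X", "X"), None]
        assert mr_distance(a, b) == pytest.approx(1.0)  # only locus 1 shared

    def test_no_shared_locus_errors(self):
        with pytest.raises(ValueError, match="no typed locus"):
            mr_distance([None, ("A", "A")], [("B", "B"), None])

    def test_metric_axioms_on_random_genotypes(self):
        """Identity, symmetry and the triangle inequality on complete
        (no-missing) genotype vectors."""
        rng = np.random.default_rng(21)
        alleles = ["A", "B", "C"]
        vecs = [
            [tuple(sorted(rng.choice(alleles, size=2))) for _ in range(5)]
            for _ in range(12)
        ]
        for x, y in itertools.combinations(range(len(vecs)), 2):
            dxy = mr_distance(vecs[x], vecs[y])
            assert dxy == pytest.approx(mr_distance(vecs[y], vecs[x]))
            assert 0.0 <= dxy <= 1.0
            if vecs[x] == vecs[y]:
                assert dxy == 0.0
        for x, y, z in itertools.combinations(range(len(vecs)), 3):
            assert mr_distance(vecs[x], vecs[z]) <= (
                mr_distance(vecs[x], vecs[y]) + mr_distance(vecs[y], vecs[z]) + 1e-12
            )

    def test_matrix_symmetric_zero_diagonal(self, toy6):
        D = mr_distance_matrix(toy6)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)


class TestGreedyMCore:
    def test_single_dominating_accession(self):
        rows = {
            "all": [("A", "B"), ("C", "D")],
            "x": [("A", "A"), ("C", "C")],
            "y": [("B", "B"), ("D", "D")],
        }
        m = make_matrix(rows, ["L1", "L2"])
        core = greedy_m_core(m)
        assert core.accession_ids == ["all"]
        assert core.allele_coverage == 1.0

    def test_full_coverage_always(self, synthetic_160x40):
        matrix, _ = synthetic_160x40
        core = greedy_m_core(matrix)
        assert core.allele_coverage == 1.0
        assert len(core.accession_ids) <= matrix.n_accessions

    def test_greedy_near_optimal_on_toy(self, toy6):
        """Exhaustive set-cover oracle: greedy covers everything and is at
        most one accession larger than the optimum."""
        core = greedy_m_core(toy6)
        assert core.allele_coverage == 1.0
        opt = minimum_cover_size(toy6)
        assert opt == 2
        assert len(core.accession_ids) <= opt + 1

    def test_deterministic(self, toy6):
        a = greedy_m_core(toy6)
        b = greedy_m_core(toy6)
        assert a.accession_ids == b.accession_ids


class TestAnnealCore:
    def test_full_size_is_whole_collection(self, toy6):
        core = anneal_core(toy6, size=6, schedule=AnnealSchedule(seed=0))
        assert core.accession_ids == sorted(toy6.accession_ids)
        assert core.objective_value == len(toy6.distinct_alleles())

    def test_size_out_of_range(self, toy6):
        with pytest.raises(ValueError, match="outside"):
            anneal_core(toy6, size=7)

    @pytest.mark.parametrize(
        "kind,oracle",
        [("allele_count", subset_allele_count),
         ("gene_diversity", subset_gene_diversity)],
    )
    def test_matches_exhaustive_optimum_6_choose_3(self, toy6, kind, oracle):
        """Annealing at default schedule attains the exhaustive-search
        maximum over all C(6,3) subsets, for both criteria."""
        best = exhaustive_best_subset(toy6, 3, oracle)
        core = anneal_core(
            toy6, size=3, objective=CoreObjective(kind=kind),
            schedule=AnnealSchedule(seed=42),
        )
        assert core.objective_value == pytest.approx(best)

    def test_reproducible_under_seed(self, toy6):
        a = anneal_core(toy6, 3, schedule=AnnealSchedule(seed=7))
        b = anneal_core(toy6, 3, schedule=AnnealSchedule(seed=7))
        assert a.accession_ids == b.accession_ids
        assert a.objective_value == b.objective_value

    def test_beats_random_baseline_across_seeds(self):
        """Stochastic dominance: over 20 seeds, the annealed objective is
        never worse than a random subset of the same size."""
        matrix, _ = generate_genotypes(
            GenotypeSimConfig(n_accessions=30, n_loci=8, seed=5)
        )
        rng = np.random.default_rng(0)
        wins = 0
        for seed in range(20):
            core = anneal_core(
                matrix, size=6,
                schedule=AnnealSchedule(steps=30, moves_per_step=30, seed=seed),
            )
            random_ids = list(rng.choice(matrix.accession_ids, size=6, replace=False))
            baseline = subset_allele_count(matrix.subset(random_ids))
            if core.objective_value >= baseline:
                wins += 1
        assert wins == 20

    def test_sampling_ratio_arithmetic(self):
        """Ratios of a 160-accession collection map to the sizes
        16, 24, 32, 40, 48, 64, 80."""
        sizes = [
            round(r * 160) for r in (0.10, 0.15, 0.20, 0.25, 0.30, 0.40, 0.50)
        ]
        assert sizes == [16, 24, 32, 40, 48, 64, 80]


class TestMixedObjectiveCore:
    def test_clone_exclusion_with_pure_mr(self):
        """With weight fully on distance, a clone pair is never both kept."""
        rows = {
            "clone1": [("A", "A"), ("B", "B")],
            "clone2": [("A", "A"), ("B", "B")],
            "other": [("C", "C"), ("D", "D")],
        }
        m = make_matrix(rows, ["L1", "L2"])
        core = mixed_objective_core(
            m, size=2, mr_weight=1.0, sh_weight=0.0,
            schedule=AnnealSchedule(seed=3),
        )
        assert "other" in core.accession_ids

    def test_matches_exhaustive_optimum(self, toy6):
        """Equal-weight mixed criterion attains the exhaustive maximum
        over C(6,3) subsets."""
        D = mr_distance_matrix(toy6)
        idx = {a: i for i, a in enumerate(toy6.accession_ids)}
        full_sh = _shannon(toy6)

        def oracle(sub):
            ids = [idx[a] for a in sub.accession_ids]
            pairs = list(itertools.combinations(ids, 2))
            mean_mr = float(np.mean([D[i, j] for i, j in pairs]))
            return 0.5 * mean_mr + 0.5 * _shannon(sub) / full_sh

        best = exhaustive_best_subset(toy6, 3, oracle)
        core = mixed_objective_core(toy6, size=3, schedule=AnnealSchedule(seed=11))
        assert core.objective_value == pytest.approx(best)

    def test_weights_must_sum_to_one(self, toy6):
        with pytest.raises(ValueError, match="sum to 1"):
            mixed_objective_core(toy6, size=2, mr_weight=0.9, sh_weight=0.9)

    def test_allele_retention_nondecreasing_in_size(self, synthetic_160x40):
        """Sweeping 10-50% sampling on the 160-accession collection, the
        fraction of alleles retained never drops as the core grows."""
        matrix, _ = synthetic_160x40
        retentions = []
        for ratio in (0.10, 0.20, 0.30, 0.50):
            core = anneal_core(
                matrix, size=round(ratio * 160),
                schedule=AnnealSchedule(steps=15, moves_per_step=40, seed=2),
            )
            retentions.append(core.allele_coverage)
        assert retentions == sorted(retentions)


def _shannon(sub):
    total = 0.0
    for loc in sub.locus_ids:
        counts = {}
        for call in sub.locus_calls(loc):
            if call is None:
                continue
            for a in call:
                counts[a] = counts.get(a, 0) + 1
        tot = sum(counts.values())
        for c in counts.values():
            p = c / tot
            total -= p * np.log(p)
    return total


class TestSubsetInvariants:
    def test_subset_na_bounded_by_full(self, synthetic_160x40):
        """Per-locus allele counts in any core never exceed the full
        collection's, and total subset alleles never exceed the total."""
        matrix, _ = synthetic_160x40
        from ssrcore.diversity import collection_summary, total_alleles

        full = collection_summary(matrix)
        core = anneal_core(
            matrix, size=24,
            schedule=AnnealSchedule(steps=10, moves_per_step=40, seed=9),
        )
        sub_table = core.diversity
        for locus in matrix.locus_ids:
            assert sub_table.loc[locus, "na"] <= full.loc[locus, "na"]
        assert total_alleles(sub_table) <= total_alleles(full)
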