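"""Synthetic test beds with known ground truth.

Two generators:

* :func:`generate_assemblies` builds a reference unigene set with planted
  perfect SSRs plus replicate "assemblies" of the same unigenes in which a
  planted repeat may change its repeat number, flanks carry substitution
  noise, and whole unigenes may drop out.  This emulates transcriptome
  assemblies of related varieties sharing homologous unigenes.
* :func:`generate_genotypes` draws a diploid codominant genotype matrix
  from specified per-locus allele-frequency spectra, by default under
  Hardy-Weinberg proportions, with optional direct control of observed
  heterozygosity and of the missing-data rate.

Every run is fully determined by the single integer seed in its config.

Repeat-shift rule (documented because tests recompute its consequences):
a shifted locus changes its repeat count by a delta drawn uniformly from
the feasible subset of {-2, -1, +1, +2} — feasible meaning the new count
stays at or above the detection threshold for that motif length.  A shift
therefore always produces a count different from the reference, so a
planted locus is truth-polymorphic exactly when at least one non-reference
assembly shifted it: P(polymorphic) = 1 - (1 - repeat_shift_prob)^(n_assemblies - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import Genotype, GenotypeMatrix
from .mining import ThresholdSet, find_ssrs

__all__ = [
    "SimulationConfig",
    "GenotypeSimConfig",
    "PlantedSSR",
    "AssemblySet",
    "generate_assemblies",
    "generate_genotypes",
]

_BASES = np.array(list("ACGT"))
_MIN_FLANK = 30  # bp of clean flank kept on each side of a planted repeat


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the assembly-replicate generator."""

    n_unigenes: int = 200
    unigene_length_range: tuple[int, int] = (300, 1500)
    n_planted_ssrs: int = 50
    motif_pool: tuple[str, ...] = ("AG", "AC", "AT", "AAG", "AGG", "AGC", "AAAG")
    repeat_range: dict[int, tuple[int, int]] = field(
        default_factory=lambda: {1: (10, 20), 2: (6, 15), 3: (5, 12),
                                 4: (5, 10), 5: (5, 8), 6: (5, 8)}
    )
    n_assemblies: int = 3
    repeat_shift_prob: float = 0.5
    flank_substitution_rate: float = 0.01
    dropout_prob: float = 0.02
    seed: int = 0
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)

    def __post_init__(self) -> None:
        for name in ("repeat_shift_prob", "flank_substitution_rate", "dropout_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.n_assemblies < 2:
            raise ValueError("need at least two assemblies")
        if self.n_planted_ssrs > self.n_unigenes:
            raise ValueError("more planted SSRs than unigenes (one per unigene)")
        for motif in self.motif_pool:
            lo, _hi = self.repeat_range[len(motif)]
            if lo < self.thresholds[len(motif)]:
                raise ValueError(
                    f"repeat range for {motif!r} starts below the detection "
                    f"threshold {self.thresholds[len(motif)]}"
                )
        max_ssr = max(
            len(m) * self.repeat_range[len(m)][1] for m in self.motif_pool
        )
        if self.unigene_length_range[0] < max_ssr + 2 * _MIN_FLANK:
            raise ValueError(
                f"unigene_length_range minimum {self.unigene_length_range[0]} "
                f"too short to hold a planted SSR of up to {max_ssr} bp plus "
                f"{_MIN_FLANK} bp flanks on each side"
            )


@dataclass(frozen=True)
class PlantedSSR:
    """Truth record for one planted locus."""

    locus_id: str
    unigene_id: str
    motif: str
    ref_start: int  # 1-based inclusive, reference assembly
    ref_end: int
    repeat_counts: dict[str, int | None]  # assembly id -> count (None = dropout)

    @property
    def polymorphic(self) -> bool:
        counts = {c for c in self.repeat_counts.values() if c is not None}
        return len(counts) > 1


@dataclass
class AssemblySet:
    """Assemblies (id -> {unigene id -> sequence}) plus the planted truth."""

    assemblies: dict[str, dict[str, str]]
    truth: list[PlantedSSR]
    reference_id: str
    seed: int

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            row: dict = {
                "locus_id": t.locus_id,
                "unigene_id": t.unigene_id,
                "motif": t.motif,
                "ref_start": t.ref_start,
                "ref_end": t.ref_end,
                "polymorphic": t.polymorphic,
            }
            for asm, count in t.repeat_counts.items():
                row[f"repeats_{asm}"] = count
            rows.append(row)
        return pd.DataFrame(rows)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _clean_background(
    rng: np.random.Generator, length: int, thresholds: ThresholdSet
) -> str:
    """Random sequence free of threshold-passing SSRs (rejection sampling)."""
    for _ in range(200):
        seq = _random_seq(rng, length)
        if not find_ssrs(seq, thresholds=thresholds):
            return seq
    raise RuntimeError(
        f"could not draw an SSR-free background of {length} bp; "
        "thresholds too permissive for this length"
    )


def _build_unigene(
    rng: np.random.Generator,
    length: int,
    motif: str,
    n_repeats: int,
    thresholds: ThresholdSet,
) -> tuple[str, int]:
    """Unigene of `length` bp with exactly one detectable SSR.

    Returns (sequence, 0-based insert offset).  Flanks are screened so the
    planted repeat is the only locus the miner reports and its coordinates
    are exact (the repeat must not extend into the flanks).
    """
    ssr = motif * n_repeats
    flank_total = length - len(ssr)
    for _ in range(200):
        offset = int(rng.integers(_MIN_FLANK, flank_total - _MIN_FLANK + 1))
        up = _clean_background(rng, offset, thresholds)
        down = _clean_background(rng, flank_total - offset, thresholds)
        seq = up + ssr + down
        found = find_ssrs(seq, thresholds=thresholds)
        if (
            len(found) == 1
            and found[0].start == offset + 1
            and found[0].end == offset + len(ssr)
            and found[0].n_repeats == n_repeats
        ):
            return seq, offset
    raise RuntimeError("failed to plant an unambiguous SSR")


def generate_assemblies(config: SimulationConfig) -> AssemblySet:
    """Reference assembly with planted SSRs plus noisy replicate assemblies."""
    rng = np.random.default_rng(config.seed)
    thresholds = config.thresholds
    asm_ids = [f"asm{k}" for k in range(config.n_assemblies)]
    ref_id = asm_ids[0]

    lengths = rng.integers(
        config.unigene_length_range[0],
        config.unigene_length_range[1] + 1,
        size=config.n_unigenes,
    )
    planted_unigenes = rng.choice(
        config.n_unigenes, size=config.n_planted_ssrs, replace=False
    )
    planted_set = set(int(u) for u in planted_unigenes)

    reference: dict[str, str] = {}
    # per planted unigene: (motif, ref repeats, up-flank, down-flank)
    plan: dict[str, tuple[str, int, str, str]] = {}
    truth_pos: dict[str, tuple[int, int]] = {}
    for k in range(config.n_unigenes):
        uid = f"unigene_{k}"
        length = int(lengths[k])
        if k in planted_set:
            motif = str(rng.choice(config.motif_pool))
            lo, hi = config.repeat_range[len(motif)]
            reps = int(rng.integers(lo, hi + 1))
            seq, offset = _build_unigene(rng, length, motif, reps, thresholds)
            reference[uid] = seq
            plan[uid] = (motif, reps, seq[:offset], seq[offset + len(motif) * reps :])
            truth_pos[uid] = (offset + 1, offset + len(motif) * reps)
        else:
            reference[uid] = _clean_background(rng, length, thresholds)

    assemblies: dict[str, dict[str, str]] = {ref_id: reference}
    repeat_counts: dict[str, dict[str, int | None]] = {
        uid: {ref_id: plan[uid][1]} for uid in plan
    }
    for asm in asm_ids[1:]:
        seqs: dict[str, str] = {}
        for k in range(config.n_unigenes):
            uid = f"unigene_{k}"
            if rng.random() < config.dropout_prob:
                if uid in plan:
                    repeat_counts[uid][asm] = None
                continue
            if uid in plan:
                motif, ref_reps, up, down = plan[uid]
                reps = ref_reps
                if rng.random() < config.repeat_shift_prob:
                    reps = _shifted_repeats(
                        rng, ref_reps, thresholds[len(motif)]
                    )
                up_noisy = _substitute(rng, up, config.flank_substitution_rate)
                down_noisy = _substitute(rng, down, config.flank_substitution_rate)
                seqs[uid] = up_noisy + motif * reps + down_noisy
                repeat_counts[uid][asm] = reps
            else:
                seqs[uid] = _substitute(
                    rng, reference[uid], config.flank_substitution_rate
                )
        assemblies[asm] = seqs

    truth = []
    for j, uid in enumerate(sorted(plan, key=lambda u: int(u.split("_")[1]))):
        motif, _reps, _up, _down = plan[uid]
        start, end = truth_pos[uid]
        truth.append(
            PlantedSSR(
                locus_id=f"ssr_{j}",
                unigene_id=uid,
                motif=motif,
                ref_start=start,
                ref_end=end,
                repeat_counts=dict(repeat_counts[uid]),
            )
        )
    return AssemblySet(
        assemblies=assemblies, truth=truth, reference_id=ref_id, seed=config.seed
    )


def _shifted_repeats(
    rng: np.random.Generator, ref_reps: int, min_reps: int
) -> int:
    """Draw the shifted repeat count: uniform over feasible +/-1, +/-2 deltas."""
    feasible = [d for d in (-2, -1, 1, 2) if ref_reps + d >= min_reps]
    return ref_reps + int(rng.choice(feasible))


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per-base substitution to a uniformly chosen different base."""
    if rate == 0.0 or not seq:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for idx in np.flatnonzero(hit):
        others = [b for b in "ACGT" if b != arr[idx]]
        arr[idx] = others[int(rng.integers(3))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# genotype matrices


@dataclass(frozen=True)
class GenotypeSimConfig:
    """Parameters of the genotype-matrix generator.

    ``alleles_per_locus`` may be a fixed integer in [2, 5] or ``None`` to
    draw the allele count of each locus uniformly from 2-5, the range seen
    in diploid SSR panels of narrow-base ornamental collections.
    ``frequency_spectrum`` optionally fixes per-locus allele-frequency
    vectors; when ``None``, spectra are drawn from a flat Dirichlet.
    """

    n_accessions: int = 160
    n_loci: int = 40
    alleles_per_locus: int | None = None
    frequency_spectrum: tuple[tuple[float, ...], ...] | None = None
    target_ho: float | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"missing_rate={self.missing_rate} outside [0, 1]")
        if self.alleles_per_locus is not None and not 2 <= self.alleles_per_locus <= 5:
            raise ValueError("alleles_per_locus must lie in [2, 5]")
        if self.frequency_spectrum is not None:
            if len(self.frequency_spectrum) != self.n_loci:
                raise ValueError("one frequency vector per locus required")
            for vec in self.frequency_spectrum:
                if any(p < 0 for p in vec):
                    raise ValueError("allele frequencies must be nonnegative")
                if abs(sum(vec) - 1.0) > 1e-9:
                    raise ValueError(f"frequency vector sums to {sum(vec)}, not 1")
                if (
                    self.alleles_per_locus is not None
                    and len(vec) != self.alleles_per_locus
                ):
                    raise ValueError(
                        "frequency vector length does not match alleles_per_locus"
                    )


@dataclass
class GenotypeTruth:
    """Ground-truth spectra behind a simulated matrix."""

    frequencies: dict[str, dict[str, float]]  # locus -> allele -> p
    seed: int


def generate_genotypes(
    config: GenotypeSimConfig,
) -> tuple[GenotypeMatrix, GenotypeTruth]:
    """Draw a genotype matrix and return it with its truth frequencies.

    Under the default ``target_ho=None`` genotypes follow Hardy-Weinberg
    proportions at the truth frequencies.  With ``target_ho`` set, each
    call is heterozygous with exactly that probability, alleles then drawn
    from the HWE-conditional heterozygote or homozygote distribution.
    """
    rng = np.random.default_rng(config.seed)
    spectra: list[np.ndarray] = []
    if config.frequency_spectrum is not None:
        spectra = [np.asarray(v, dtype=float) for v in config.frequency_spectrum]
    else:
        for _ in range(config.n_loci):
            k = (
                config.alleles_per_locus
                if config.alleles_per_locus is not None
                else int(rng.integers(2, 6))
            )
            spectra.append(rng.dirichlet(np.ones(k)))

    accession_ids = [f"acc_{i:03d}" for i in range(config.n_accessions)]
    locus_ids = [f"locus_{j:02d}" for j in range(config.n_loci)]
    calls: dict[tuple[str, str], Genotype] = {}
    truth_freqs: dict[str, dict[str, float]] = {}

    for j, locus in enumerate(locus_ids):
        p = spectra[j]
        alleles = [str(a + 1) for a in range(len(p))]
        truth_freqs[locus] = {a: float(pi) for a, pi in zip(alleles, p) if pi > 0}
        draw = _genotype_sampler(p, config.target_ho)
        for acc in accession_ids:
            if rng.random() < config.missing_rate:
                calls[(acc, locus)] = None
            else:
                ia, ib = draw(rng)
                calls[(acc, locus)] = (alleles[ia], alleles[ib])

    matrix = GenotypeMatrix(accession_ids, locus_ids, calls)
    return matrix, GenotypeTruth(frequencies=truth_freqs, seed=config.seed)


def _genotype_sampler(p: np.ndarray, target_ho: float | None):
    """Per-call sampler of unordered allele index pairs."""
    k = len(p)
    if target_ho is None:
        def hwe(rng: np.random.Generator) -> tuple[int, int]:
            a = int(rng.choice(k, p=p))
            b = int(rng.choice(k, p=p))
            return a, b
        return hwe

    het_hwe = 1.0 - float(np.sum(p**2))
    positive = int(np.sum(p > 0))
    if target_ho > 0 and positive < 2:
        raise ValueError(
            "target_ho infeasible: a locus with one segregating allele admits "
            "observed heterozygosity 0 only (feasible range [0, 0])"
        )
    if not 0.0 <= target_ho <= 1.0:
        raise ValueError("target_ho outside the feasible range [0, 1]")

    pairs = [(a, b) for a in range(k) for b in range(a + 1, k)]
    het_w = np.array([2 * p[a] * p[b] for a, b in pairs])
    het_w = het_w / het_w.sum() if het_hwe > 0 else het_w
    hom_w = p**2 / np.sum(p**2)

    def mixed(rng: np.random.Generator) -> tuple[int, int]:
        if rng.random() < target_ho:
            idx = int(rng.choice(len(pairs), p=het_w))
            return pairs[idx]
        a = int(rng.choice(k, p=hom_w))
        return a, a
    return mixed
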