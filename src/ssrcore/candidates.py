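"""Cross-assembly candidate polymorphic SSR discovery.

Given a reference assembly and one or more query assemblies, each
reference SSR's flanking sequences are aligned into every query; where
both flanks match (identity and coverage thresholds), the enclosed query
interval is re-scanned for a repeat of the same canonical motif class.
Candidates are the loci whose repeat counts vary across assemblies
(sample standard deviation > 0) and whose flanks were found in at least
half of the query assemblies (miss rate <= 50%).

Flank matching uses infix edit-distance alignment (edlib): each flank is
located independently in a query sequence; a hit requires, for both
flanks, identity >= ``min_identity`` and query-span coverage >=
``min_coverage``, with the downstream flank starting after the upstream
one ends.  Ties are broken deterministically (lowest total edit distance,
then lowest sequence id, then leftmost).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import edlib

from .mining import SSRLocus, ThresholdSet, find_ssrs, mine_assembly

__all__ = [
    "AlignmentFilter",
    "FlankPair",
    "FlankHit",
    "CandidatePolymorphicSSR",
    "extract_flanks",
    "match_flanks",
    "call_candidates",
]

#: repeat-count floor used when re-detecting inside a matched interval; a
#: query allele may legitimately fall below the mining threshold.
RELAXED_MIN_REPEATS = 3

#: a flank pair is unusable when both flanks are shorter than this.
MIN_USABLE_FLANK = 20


@dataclass(frozen=True)
class AlignmentFilter:
    min_identity: float = 95.0  # percent
    min_coverage: float = 95.0  # percent
    flank_length: int = 100  # bp

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not 0.0 < v <= 100.0:
                raise ValueError(f"{name}={v} outside (0, 100]")
        if self.flank_length <= 0:
            raise ValueError("flank_length must be positive")


@dataclass(frozen=True)
class FlankPair:
    """Up/downstream flanks of a reference SSR (either may be truncated)."""

    up: str
    down: str
    usable: bool


@dataclass(frozen=True)
class FlankHit:
    """Matched flank pair in one query sequence.

    ``interval`` is the 1-based inclusive query span enclosed between the
    two flank matches (the putative SSR allele region).
    """

    sequence_id: str
    interval: tuple[int, int]
    identity_up: float
    identity_down: float
    edit_distance: int


@dataclass(frozen=True)
class CandidatePolymorphicSSR:
    reference_locus: SSRLocus
    flank_up: str
    flank_down: str
    repeat_counts: dict[str, int | None]  # assembly id -> repeats (None = miss)
    sd: float
    miss_rate: float
    annotationless_id: str

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ValueError("miss_rate outside [0, 1]")


def extract_flanks(
    locus: SSRLocus, sequence: str, flank_length: int
) -> FlankPair:
    """Up to `flank_length` bases on each side of the locus.

    Flanks are truncated at sequence ends; the pair is flagged unusable
    when both flanks are shorter than ``MIN_USABLE_FLANK`` (too little
    anchor sequence to place the locus in another assembly).
    """
    if locus.start < 1 or locus.end > len(sequence):
        raise ValueError(
            f"locus {locus.start}-{locus.end} outside sequence of "
            f"length {len(sequence)}"
        )
    up = sequence[max(0, locus.start - 1 - flank_length) : locus.start - 1]
    down = sequence[locus.end : locus.end + flank_length]
    usable = len(up) >= MIN_USABLE_FLANK or len(down) >= MIN_USABLE_FLANK
    return FlankPair(up=up, down=down, usable=usable)


def _locate(flank: str, target: str) -> tuple[int, int, int] | None:
    """Best infix placement of `flank` in `target`.

    Returns (edit_distance, start0, end0_inclusive) of the leftmost
    best-scoring location, or None when the flank is empty.
    """
    if not flank or not target:
        return None
    res = edlib.align(flank, target, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = min(res["locations"], key=lambda loc: (loc[0], loc[1]))
    return res["editDistance"], start, end


def match_flanks(
    flanks: FlankPair,
    query_assembly: Mapping[str, str],
    filt: AlignmentFilter,
) -> FlankHit | None:
    """Best acceptable placement of a flank pair in a query assembly.

    Both flanks must pass the identity and coverage thresholds in the same
    query sequence with the downstream flank beyond the upstream one.
    Returns None when no acceptable hit exists (a "miss").
    """
    if not query_assembly:
        raise ValueError("query assembly is empty")
    best: FlankHit | None = None
    for seq_id in sorted(query_assembly):
        target = query_assembly[seq_id].upper()
        up_loc = _locate(flanks.up, target)
        if up_loc is None:
            continue
        dist_up, up_s, up_e = up_loc
        down_loc = _locate(flanks.down, target[up_e + 1 :])
        if down_loc is None:
            continue
        dist_down, rel_s, rel_e = down_loc
        down_s, down_e = up_e + 1 + rel_s, up_e + 1 + rel_e

        id_up = 100.0 * (1 - dist_up / len(flanks.up))
        id_down = 100.0 * (1 - dist_down / len(flanks.down))
        cov_up = 100.0 * (up_e - up_s + 1) / len(flanks.up)
        cov_down = 100.0 * (down_e - down_s + 1) / len(flanks.down)
        if (
            id_up < filt.min_identity
            or id_down < filt.min_identity
            or cov_up < filt.min_coverage
            or cov_down < filt.min_coverage
        ):
            continue
        hit = FlankHit(
            sequence_id=seq_id,
            interval=(up_e + 2, down_s),  # 1-based inclusive, between flanks
            identity_up=id_up,
            identity_down=id_down,
            edit_distance=dist_up + dist_down,
        )
        if best is None or (hit.edit_distance, hit.sequence_id, hit.interval) < (
            best.edit_distance,
            best.sequence_id,
            best.interval,
        ):
            best = hit
    return best


def _interval_repeats(
    query_seq: str,
    interval: tuple[int, int],
    canonical_class: str,
    thresholds: ThresholdSet,
) -> int | None:
    """Repeat count of the same-class SSR inside a matched interval.

    Re-detection relaxes the repeat floor to ``RELAXED_MIN_REPEATS`` so a
    query allele that shrank below the mining threshold is still counted.
    Returns the repeat count of the longest same-class locus, or None.
    """
    start, end = interval
    if end < start:
        return None
    segment = query_seq[start - 1 : end]
    relaxed = ThresholdSet(
        {
            length: min(thresholds[length], RELAXED_MIN_REPEATS)
            for length in thresholds.motif_lengths()
        }
    )
    loci = [
        l
        for l in find_ssrs(segment, thresholds=relaxed)
        if l.canonical_class == canonical_class
    ]
    if not loci:
        return None
    return max(loci, key=lambda l: (l.length, -l.start)).n_repeats


def call_candidates(
    reference_assembly: Mapping[str, str],
    query_assemblies: Mapping[str, Mapping[str, str]],
    thresholds: ThresholdSet | None = None,
    filt: AlignmentFilter | None = None,
    exclusion_list: set[str] | None = None,
) -> list[CandidatePolymorphicSSR]:
    """Candidate polymorphic SSRs across a reference and query assemblies.

    For each reference SSR (skipping excluded sequence ids and loci with
    unusable flanks): match flanks into every query assembly, re-detect
    the repeat in each matched interval, then keep candidates with sample
    standard deviation of the repeat counts > 0 and miss rate <= 0.5.
    """
    if not query_assemblies:
        raise ValueError("need at least one query assembly (two assemblies total)")
    thresholds = thresholds or ThresholdSet()
    filt = filt or AlignmentFilter()
    exclusion_list = exclusion_list or set()

    ref_loci = [
        l
        for l in mine_assembly(reference_assembly, thresholds)
        if l.sequence_id not in exclusion_list
    ]
    out: list[CandidatePolymorphicSSR] = []
    n_cand = 0
    for locus in ref_loci:
        flanks = extract_flanks(
            locus, reference_assembly[locus.sequence_id], filt.flank_length
        )
        if not flanks.usable:
            continue
        counts: dict[str, int | None] = {"reference": locus.n_repeats}
        n_miss = 0
        for asm_id in sorted(query_assemblies):
            hit = match_flanks(flanks, query_assemblies[asm_id], filt)
            reps = (
                _interval_repeats(
                    query_assemblies[asm_id][hit.sequence_id].upper(),
                    hit.interval,
                    locus.canonical_class,
                    thresholds,
                )
                if hit is not None
                else None
            )
            counts[asm_id] = reps
            if reps is None:
                n_miss += 1
        available = [c for c in counts.values() if c is not None]
        sd = _sample_sd(available)
        miss_rate = n_miss / len(query_assemblies)
        if sd > 0 and miss_rate <= 0.5:
            n_cand += 1
            out.append(
                CandidatePolymorphicSSR(
                    reference_locus=locus,
                    flank_up=flanks.up,
                    flank_down=flanks.down,
                    repeat_counts=counts,
                    sd=sd,
                    miss_rate=miss_rate,
                    annotationless_id=f"cand_{n_cand:04d}",
                )
            )
    return out


def _sample_sd(values: list[int]) -> float:
    """Sample (n-1 denominator) standard deviation; 0 for fewer than 2 values."""
    if len(values) < 2:
        return 0.0
    mean = sum(values) / len(values)
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (len(values) - 1))
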