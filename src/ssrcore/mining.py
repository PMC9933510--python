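"""Perfect microsatellite detection and motif canonicalization.

Detects maximal perfect tandem repeats of 1-6 bp motifs in nucleotide
sequences, using the repeat-count thresholds conventional for EST-SSR
surveys (10 for mononucleotide motifs, 6 for dinucleotide, 5 for tri- to
hexanucleotide), and standardizes motifs into canonical classes that are
invariant under cyclic rotation and reverse complement (e.g. GA, AG, TC
and CT all belong to class ``AG/CT``).

Coordinates are 1-based inclusive throughout, the convention of MISA-style
SSR tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "SSRLocus",
    "ThresholdSet",
    "find_ssrs",
    "canonical_motif",
    "summarize_ssrs",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Minimum repeat counts by motif length: ten for mononucleotides, six for
#: dinucleotides, five for tri- through hexanucleotides.
DEFAULT_MIN_REPEATS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

#: Maximum gap (bp) between neighbouring SSRs grouped as a compound region.
DEFAULT_MAX_INTERRUPTION = 100


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ThresholdSet:
    """Minimum repeat count required to call an SSR, per motif length."""

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )

    def __post_init__(self) -> None:
        for length, count in self.min_repeats.items():
            if length not in range(1, 7):
                raise ValueError(f"motif length {length} outside 1-6")
            if count < 1:
                raise ValueError(f"minimum repeat count {count} must be >= 1")

    def motif_lengths(self) -> list[int]:
        return sorted(self.min_repeats)

    def __getitem__(self, motif_length: int) -> int:
        return self.min_repeats[motif_length]


@dataclass(frozen=True)
class SSRLocus:
    """One perfect microsatellite: motif, repeat count and 1-based span."""

    sequence_id: str
    motif: str
    canonical_class: str
    n_repeats: int
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    compound_group: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.motif) * self.n_repeats:
            raise ValueError(
                f"span {self.start}-{self.end} inconsistent with "
                f"{self.n_repeats} x {self.motif!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _is_reducible(motif: str) -> bool:
    """True if the motif is a whole-number repetition of a shorter motif."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return True
    return False


def canonical_motif(motif: str) -> str:
    """Canonical class label ``X/Y`` for an irreducible 1-6 bp motif.

    X is the lexicographically smallest string among all cyclic rotations
    of the motif and of its reverse complement; Y is the reverse complement
    of X.  The 12 irreducible dinucleotides collapse to 4 classes and the
    60 irreducible trinucleotides to 10.
    """
    motif = motif.upper()
    if not 1 <= len(motif) <= 6:
        raise ValueError(f"motif length {len(motif)} outside 1-6")
    if any(b not in "ACGT" for b in motif):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    if _is_reducible(motif):
        raise ValueError(f"motif {motif!r} is reducible")
    candidates = set()
    for m in (motif, reverse_complement(motif)):
        for i in range(len(m)):
            candidates.add(m[i:] + m[:i])
    x = min(candidates)
    return f"{x}/{reverse_complement(x)}"


def _periodic_runs(seq: str, period: int) -> Iterable[tuple[int, int]]:
    """Yield (start, run_length) of maximal period-`period` stretches.

    `start` is a 0-based index; run_length counts bases, not repeats.  A
    stretch qualifies only if every base is A/C/G/T (N breaks runs) and it
    holds at least two full motif copies.
    """
    n = len(seq)
    i = 0
    while i + 2 * period <= n:
        if any(seq[k] not in "ACGT" for k in range(i, min(i + period, n))):
            i += 1
            continue
        j = i + period
        while j < n and seq[j] == seq[j - period] and seq[j] in "ACGT":
            j += 1
        run = j - i
        if run >= 2 * period:
            yield i, run
            # next maximal run of this period starts past this stretch
            i = j - period + 1
        else:
            i += 1


def find_ssrs(
    sequence: str,
    sequence_id: str = "",
    thresholds: ThresholdSet | None = None,
    max_interruption: int = DEFAULT_MAX_INTERRUPTION,
) -> list[SSRLocus]:
    """All maximal perfect SSRs in `sequence` meeting the thresholds.

    Loci are left- and right-maximal perfect repeats with irreducible
    motifs (an (ATAT)n run is reported with motif AT).  When a region
    supports motifs of several lengths, a locus fully contained inside a
    reported locus is suppressed, preferring the smaller motif when the
    spans coincide.  Loci separated by at most `max_interruption` bases
    share a ``compound_group`` identifier.
    """
    if thresholds is None:
        thresholds = ThresholdSet()
    seq = sequence.upper()
    raw: list[tuple[int, int, str, int]] = []  # start0, end0(exclusive), motif, reps
    for period in thresholds.motif_lengths():
        min_reps = thresholds[period]
        for start, run in _periodic_runs(seq, period):
            motif = seq[start : start + period]
            if _is_reducible(motif):
                continue
            reps = run // period
            if reps >= min_reps:
                raw.append((start, start + reps * period, motif, reps))

    # containment filter: drop loci nested inside another; on identical
    # spans keep the shorter motif
    kept: list[tuple[int, int, str, int]] = []
    raw.sort(key=lambda r: (r[0], -(r[1] - r[0]), len(r[2])))
    for cand in raw:
        s, e, motif, reps = cand
        contained = any(
            ks <= s and e <= ke and (ke - ks > e - s or len(kmotif) < len(motif))
            for ks, ke, kmotif, _ in kept
        )
        if not contained:
            kept.append(cand)

    kept.sort()
    loci = [
        SSRLocus(
            sequence_id=sequence_id,
            motif=motif,
            canonical_class=canonical_motif(motif),
            n_repeats=reps,
            start=s + 1,
            end=e,
        )
        for s, e, motif, reps in kept
    ]
    return _assign_compound_groups(loci, max_interruption)


def _assign_compound_groups(
    loci: list[SSRLocus], max_interruption: int
) -> list[SSRLocus]:
    """Group neighbouring loci whose gap is at most `max_interruption` bp."""
    groups: list[list[int]] = []
    for idx, locus in enumerate(loci):
        if groups and locus.start - loci[groups[-1][-1]].end - 1 <= max_interruption:
            groups[-1].append(idx)
        else:
            groups.append([idx])
    out = list(loci)
    n_groups = 0
    for members in groups:
        if len(members) < 2:
            continue
        n_groups += 1
        gid = f"c{n_groups}"
        for idx in members:
            locus = out[idx]
            out[idx] = SSRLocus(
                sequence_id=locus.sequence_id,
                motif=locus.motif,
                canonical_class=locus.canonical_class,
                n_repeats=locus.n_repeats,
                start=locus.start,
                end=locus.end,
                compound_group=gid,
            )
    return out


def mine_assembly(
    sequences: Mapping[str, str],
    thresholds: ThresholdSet | None = None,
    max_interruption: int = DEFAULT_MAX_INTERRUPTION,
) -> list[SSRLocus]:
    """Run :func:`find_ssrs` over every sequence of an assembly."""
    loci: list[SSRLocus] = []
    for seq_id in sorted(sequences):
        loci.extend(
            find_ssrs(sequences[seq_id], seq_id, thresholds, max_interruption)
        )
    return loci


def summarize_ssrs(loci: list[SSRLocus], assembly_size: int) -> dict:
    """Counts by motif length and canonical class, plus loci-per-kb density.

    ``kb_per_locus`` is assembly size divided by locus count, in kb (one
    SSR "every X kb"); absent when the locus list is empty.
    """
    by_length: dict[int, int] = {}
    by_class: dict[str, int] = {}
    for locus in loci:
        by_length[len(locus.motif)] = by_length.get(len(locus.motif), 0) + 1
        by_class[locus.canonical_class] = by_class.get(locus.canonical_class, 0) + 1
    summary = {
        "n_loci": len(loci),
        "by_motif_length": dict(sorted(by_length.items())),
        "by_class": dict(sorted(by_class.items())),
        "assembly_size_bp": assembly_size,
    }
    if loci:
        summary["kb_per_locus"] = assembly_size / len(loci) / 1000.0
    else:
        summary["kb_per_locus"] = None
    return summary
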