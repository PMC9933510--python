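"""On-disk formats: FASTA assemblies, genotype tables, result TSVs, config.

Conventions: coordinates in tables are 1-based inclusive; genotype tables
are tab-delimited with a header row of locus ids, one row per accession
(`id` then `allele1/allele2` cells, missing as ``NA`` or ``0``); FASTA
sequences are case-folded to uppercase and restricted to A/C/G/T/N.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .candidates import AlignmentFilter, CandidatePolymorphicSSR
from .genotypes import Genotype, GenotypeMatrix
from .mining import SSRLocus, ThresholdSet

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_genotypes",
    "write_genotypes",
    "write_ssr_table",
    "write_candidate_table",
    "PipelineConfig",
    "load_config",
]

_VALID_BASES = set("ACGTN")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> ordered {id: sequence}, validated and uppercased."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate sequence id {record.id!r} in {path}")
        seq = str(record.seq).upper()
        for pos, base in enumerate(seq, start=1):
            if base not in _VALID_BASES:
                raise ValueError(
                    f"invalid character {base!r} at position {pos} of "
                    f"record {record.id!r}"
                )
        sequences[record.id] = seq
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq.upper()), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _parse_call(token: str, row: int, col: str) -> Genotype:
    token = token.strip()
    if token in {"NA", "0", ""}:
        return None
    parts = token.split("/")
    if len(parts) != 2 or not all(parts):
        raise ValueError(
            f"malformed genotype {token!r} at row {row}, locus {col!r} "
            "(expected 'allele1/allele2', 'NA' or '0')"
        )
    a, b = parts
    return (a, b) if a <= b else (b, a)


def read_genotypes(path: str | Path, delimiter: str = "\t") -> GenotypeMatrix:
    """Delimited genotype table -> :class:`GenotypeMatrix`.

    Ragged rows raise with the offending row number (1-based, header = 1).
    """
    with open(path, newline="") as fh:
        reader = csv.reader(
            (line for line in fh if not line.startswith("#")), delimiter=delimiter
        )
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"empty genotype file {path}") from None
        locus_ids = [h.strip() for h in header[1:]]
        accession_ids: list[str] = []
        calls: dict[tuple[str, str], Genotype] = {}
        for row_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"row {row_no} has {len(row) - 1} genotype cells, "
                    f"expected {len(locus_ids)}"
                )
            acc = row[0].strip()
            accession_ids.append(acc)
            for loc, cell in zip(locus_ids, row[1:]):
                calls[(acc, loc)] = _parse_call(cell, row_no, loc)
    return GenotypeMatrix(accession_ids, locus_ids, calls)


def write_genotypes(
    matrix: GenotypeMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["accession"] + matrix.locus_ids)
        for acc in matrix.accession_ids:
            cells = []
            for call in matrix.accession_calls(acc):
                cells.append("NA" if call is None else f"{call[0]}/{call[1]}")
            writer.writerow([acc] + cells)


def write_ssr_table(loci: list[SSRLocus], path: str | Path) -> None:
    """SSR loci as TSV (1-based inclusive coordinates)."""
    rows = [
        {
            "sequence_id": l.sequence_id,
            "start": l.start,
            "end": l.end,
            "motif": l.motif,
            "canonical_class": l.canonical_class,
            "n_repeats": l.n_repeats,
            "compound_group": l.compound_group or ".",
        }
        for l in loci
    ]
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        pd.DataFrame(
            rows,
            columns=[
                "sequence_id", "start", "end", "motif",
                "canonical_class", "n_repeats", "compound_group",
            ],
        ).to_csv(fh, sep="\t", index=False)


def write_candidate_table(
    candidates: list[CandidatePolymorphicSSR], path: str | Path
) -> None:
    """Candidate polymorphic SSRs as TSV (missing counts printed as '.')."""
    assembly_ids: list[str] = []
    for cand in candidates:
        for asm in cand.repeat_counts:
            if asm not in assembly_ids:
                assembly_ids.append(asm)
    rows = []
    for cand in candidates:
        row = {
            "candidate_id": cand.annotationless_id,
            "unigene_id": cand.reference_locus.sequence_id,
            "motif": cand.reference_locus.motif,
            "canonical_class": cand.reference_locus.canonical_class,
            "sd": f"{cand.sd:.4f}",
            "miss_rate": f"{cand.miss_rate:.4f}",
        }
        for asm in assembly_ids:
            count = cand.repeat_counts.get(asm)
            row[f"repeats_{asm}"] = "." if count is None else count
        rows.append(row)
    cols = ["candidate_id", "unigene_id", "motif", "canonical_class"] + [
        f"repeats_{a}" for a in assembly_ids
    ] + ["sd", "miss_rate"]
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        pd.DataFrame(rows, columns=cols).to_csv(fh, sep="\t", index=False)


def write_flank_constructs(
    candidates: list[CandidatePolymorphicSSR], path: str | Path
) -> None:
    """Flank constructs (up + reference repeat + down) as FASTA, for
    external primer-design tools."""
    seqs = {}
    for cand in candidates:
        ref = cand.reference_locus
        seqs[cand.annotationless_id] = (
            cand.flank_up + ref.motif * ref.n_repeats + cand.flank_down
        )
    write_fasta(seqs, path)


# ---------------------------------------------------------------------------
# pipeline configuration

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "stages",
    "simulate",
    "mine",
    "candissr",
    "diversity",
    "core",
    "evaluate",
}
_KNOWN_SUBKEYS = {
    "simulate": {
        "n_unigenes", "unigene_length_range", "n_planted_ssrs", "motif_pool",
        "n_assemblies", "repeat_shift_prob", "flank_substitution_rate",
        "dropout_prob", "n_accessions", "n_loci", "alleles_per_locus",
        "missing_rate", "target_ho",
    },
    "mine": {"fasta", "min_repeats", "max_interruption"},
    "candissr": {
        "reference", "queries", "min_identity", "min_coverage",
        "flank_length", "exclusion",
    },
    "diversity": {"genotypes"},
    "core": {"genotypes", "method", "size", "ratio", "mr_weight", "sh_weight",
             "steps", "cooling_factor"},
    "evaluate": {"genotypes", "core_ids", "paired", "n_axes"},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (flat YAML with per-stage sections)."""

    seed: int = 0
    out_dir: str = "ssrcore_out"
    stages: list[str] = field(default_factory=lambda: ["simulate", "mine"])
    sections: dict[str, dict] = field(default_factory=dict)

    def section(self, name: str) -> dict:
        return dict(self.sections.get(name, {}))

    def thresholds(self) -> ThresholdSet:
        spec = self.section("mine").get("min_repeats")
        if spec is None:
            return ThresholdSet()
        return ThresholdSet({int(k): int(v) for k, v in spec.items()})

    def alignment_filter(self) -> AlignmentFilter:
        sec = self.section("candissr")
        return AlignmentFilter(
            min_identity=float(sec.get("min_identity", 95.0)),
            min_coverage=float(sec.get("min_coverage", 95.0)),
            flank_length=int(sec.get("flank_length", 100)),
        )


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config; unknown keys are errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sections = {}
    for stage, allowed in _KNOWN_SUBKEYS.items():
        sec = raw.get(stage, {})
        if sec is None:
            sec = {}
        if not isinstance(sec, dict):
            raise ValueError(f"config section {stage!r} must be a mapping")
        bad = set(sec) - allowed
        if bad:
            raise ValueError(f"unknown keys in section {stage!r}: {sorted(bad)}")
        sections[stage] = sec
    stages = raw.get("stages", ["simulate", "mine"])
    known_stages = ["simulate", "mine", "candissr", "diversity", "core", "evaluate"]
    for s in stages:
        if s not in known_stages:
            raise ValueError(f"unknown stage {s!r}")
    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "ssrcore_out")),
        stages=list(stages),
        sections=sections,
    )
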