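"""Stage orchestration: simulate -> mine -> candissr -> diversity -> core
-> evaluate, with a machine-readable run manifest.

Each stage reads and writes plain-text artifacts in the output directory;
the manifest records the package version, the seed, stage parameters and
SHA-256 digests of all inputs and primary outputs, so reruns with
identical inputs are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .candidates import call_candidates
from .core import AnnealSchedule, CoreObjective, anneal_core, greedy_m_core, mixed_objective_core
from .diversity import collection_summary, rounded_summary
from .evaluation import compare_core, intersect_methods, pcoa  # noqa: F401  (re-export)
from .io import (
    PipelineConfig,
    read_fasta,
    read_genotypes,
    write_candidate_table,
    write_fasta,
    write_genotypes,
    write_ssr_table,
)
from .mining import mine_assembly
from .simulate import GenotypeSimConfig, SimulationConfig, generate_assemblies, generate_genotypes

log = logging.getLogger("ssrcore")

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _preflight(config: PipelineConfig) -> None:
    """Fail before any compute if a stage lacks its required inputs."""
    produces_assemblies = "simulate" in config.stages
    produces_genotypes = "simulate" in config.stages
    for stage in config.stages:
        sec = config.section(stage)
        if stage == "mine" and not produces_assemblies and not sec.get("fasta"):
            raise ValueError("stage 'mine' needs a 'fasta' input or a prior simulate stage")
        if stage == "candissr" and not produces_assemblies and not (
            sec.get("reference") and sec.get("queries")
        ):
            raise ValueError(
                "stage 'candissr' needs 'reference' and 'queries' inputs "
                "or a prior simulate stage"
            )
        if stage in {"diversity", "core", "evaluate"} and not produces_genotypes and not sec.get("genotypes"):
            raise ValueError(f"stage {stage!r} needs a 'genotypes' input or a prior simulate stage")
    for stage in config.stages:
        sec = config.section(stage)
        for key in ("fasta", "reference", "genotypes", "exclusion", "core_ids"):
            val = sec.get(key)
            if val and not Path(val).exists():
                raise ValueError(f"stage {stage!r}: input path {val!r} does not exist")
        for q in sec.get("queries", []) or []:
            if not Path(q).exists():
                raise ValueError(f"stage 'candissr': query path {q!r} does not exist")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; return the run manifest."""
    _preflight(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {s: config.section(s) for s in config.stages},
        "inputs": {},
        "outputs": {},
    }

    assemblies = None
    reference_id = None
    matrix = None
    genotype_path = None

    for stage in config.stages:
        sec = config.section(stage)
        log.info("stage %s starting", stage)
        try:
            if stage == "simulate":
                sim_keys = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in sec.items()
                    if k in {"n_unigenes", "unigene_length_range", "n_planted_ssrs",
                             "motif_pool", "n_assemblies", "repeat_shift_prob",
                             "flank_substitution_rate", "dropout_prob"}
                }
                aset = generate_assemblies(SimulationConfig(seed=config.seed, **sim_keys))
                assemblies = aset.assemblies
                reference_id = aset.reference_id
                for asm_id, seqs in aset.assemblies.items():
                    p = out_dir / f"{asm_id}.fasta"
                    write_fasta(seqs, p)
                    manifest["outputs"][str(p)] = _sha256(p)
                truth_path = out_dir / "truth_ssrs.tsv"
                aset.truth_table().to_csv(truth_path, sep="\t", index=False)
                manifest["outputs"][str(truth_path)] = _sha256(truth_path)

                gen_keys = {k: v for k, v in sec.items()
                            if k in {"n_accessions", "n_loci", "alleles_per_locus",
                                     "missing_rate", "target_ho"}}
                matrix, truth = generate_genotypes(
                    GenotypeSimConfig(seed=config.seed, **gen_keys)
                )
                genotype_path = out_dir / "genotypes.tsv"
                write_genotypes(matrix, genotype_path)
                manifest["outputs"][str(genotype_path)] = _sha256(genotype_path)
                freq_path = out_dir / "truth_frequencies.json"
                freq_path.write_text(json.dumps(truth.frequencies, indent=1, sort_keys=True))
                manifest["outputs"][str(freq_path)] = _sha256(freq_path)

            elif stage == "mine":
                if sec.get("fasta"):
                    manifest["inputs"][sec["fasta"]] = _sha256(Path(sec["fasta"]))
                    seqs = read_fasta(sec["fasta"])
                else:
                    seqs = assemblies[reference_id]
                loci = mine_assembly(
                    seqs,
                    config.thresholds(),
                    int(sec.get("max_interruption", 100)),
                )
                p = out_dir / "ssr_loci.tsv"
                write_ssr_table(loci, p)
                manifest["outputs"][str(p)] = _sha256(p)

            elif stage == "candissr":
                if sec.get("reference"):
                    manifest["inputs"][sec["reference"]] = _sha256(Path(sec["reference"]))
                    reference = read_fasta(sec["reference"])
                    queries = {}
                    for q in sec["queries"]:
                        manifest["inputs"][q] = _sha256(Path(q))
                        queries[Path(q).stem] = read_fasta(q)
                else:
                    reference = assemblies[reference_id]
                    queries = {k: v for k, v in assemblies.items() if k != reference_id}
                exclusion = set()
                if sec.get("exclusion"):
                    exclusion = set(Path(sec["exclusion"]).read_text().split())
                cands = call_candidates(
                    reference, queries, config.thresholds(),
                    config.alignment_filter(), exclusion,
                )
                p = out_dir / "candidates.tsv"
                write_candidate_table(cands, p)
                manifest["outputs"][str(p)] = _sha256(p)

            elif stage == "diversity":
                matrix = _load_matrix(sec, matrix, manifest)
                summary = rounded_summary(collection_summary(matrix))
                p = out_dir / "diversity.tsv"
                summary.to_csv(p, sep="\t")
                manifest["outputs"][str(p)] = _sha256(p)

            elif stage == "core":
                matrix = _load_matrix(sec, matrix, manifest)
                method = sec.get("method", "mstrategy")
                size = sec.get("size")
                if size is None and sec.get("ratio") is not None:
                    size = max(1, round(float(sec["ratio"]) * matrix.n_accessions))
                schedule = AnnealSchedule(
                    cooling_factor=float(sec.get("cooling_factor", 0.95)),
                    steps=int(sec.get("steps", 200)),
                    seed=config.seed,
                )
                if method == "mstrategy":
                    subset = greedy_m_core(matrix)
                elif method in {"sana", "sagd"}:
                    kind = "allele_count" if method == "sana" else "gene_diversity"
                    subset = anneal_core(matrix, int(size), CoreObjective(kind=kind), schedule)
                elif method == "mixed":
                    subset = mixed_objective_core(
                        matrix, int(size),
                        float(sec.get("mr_weight", 0.5)),
                        float(sec.get("sh_weight", 0.5)),
                        schedule,
                    )
                else:
                    raise ValueError(f"unknown core method {method!r}")
                ids_path = out_dir / f"core_{method}_ids.txt"
                ids_path.write_text("\n".join(subset.accession_ids) + "\n")
                manifest["outputs"][str(ids_path)] = _sha256(ids_path)
                div_path = out_dir / f"core_{method}_diversity.tsv"
                rounded_summary(subset.diversity).to_csv(div_path, sep="\t")
                manifest["outputs"][str(div_path)] = _sha256(div_path)
                manifest.setdefault("core", {})[method] = {
                    "size": len(subset.accession_ids),
                    "sampling_ratio": subset.sampling_ratio,
                    "allele_coverage": subset.allele_coverage,
                }

            elif stage == "evaluate":
                matrix = _load_matrix(sec, matrix, manifest)
                core_ids_path = sec.get("core_ids")
                if core_ids_path:
                    manifest["inputs"][core_ids_path] = _sha256(Path(core_ids_path))
                    core_ids = Path(core_ids_path).read_text().split()
                    from .core import CoreSubset

                    subset = CoreSubset(
                        method="external",
                        accession_ids=sorted(core_ids),
                        collection_ids=list(matrix.accession_ids),
                        sampling_ratio=len(core_ids) / matrix.n_accessions,
                        allele_coverage=0.0,
                        objective_value=0.0,
                    )
                else:
                    subset = greedy_m_core(matrix)
                report = compare_core(matrix, subset, paired=bool(sec.get("paired", False)))
                p = out_dir / "comparison.tsv"
                report.table.to_csv(p, sep="\t")
                manifest["outputs"][str(p)] = _sha256(p)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s done", stage)

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _load_matrix(sec: dict, matrix, manifest: dict):
    if sec.get("genotypes"):
        manifest["inputs"][sec["genotypes"]] = _sha256(Path(sec["genotypes"]))
        return read_genotypes(sec["genotypes"])
    if matrix is None:
        raise ValueError("no genotype matrix available (missing 'genotypes' input)")
    return matrix
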