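"""End-to-end pipeline: simulate/load -> pangenome -> core90 -> supermatrix
-> OGRIs -> signatures -> clade evaluation -> synonym calls.

A YAML config drives every stage; all randomness flows through its single
seed.  Each run writes a manifest recording parameters and SHA-256 hashes of
inputs and artifacts, so reruns with identical config and inputs are
reproducible and tampered inputs are detectable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from . import __version__
from .clade_eval import call_synonyms, evaluate_clades, red_values
from .io import read_json, write_json
from .msa import align_family, concatenate, trim_alignment
from .ogri import pairwise_matrix
from .pangenome import extract_core, mcl_cluster, presence_matrix, score_protein_pairs
from .signature import (
    PhylogroupAssignment,
    assign_phylogroups,
    build_pattern_table,
    count_signatures_per_proposal,
)
from .simulate import SimulationConfig, simulate_dataset, write_dataset, read_dataset

log = logging.getLogger("taxogen")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Serialisable configuration for one pipeline run."""

    outdir: str = "taxogen_run"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    run_msa: bool = True
    run_ogri: bool = True
    run_signatures: bool = True
    run_evaluation: bool = True
    # inputs when not simulating
    dataset_dir: str | None = None
    # stage parameters
    simulation: dict = field(default_factory=dict)
    min_identity: float = 40.0
    min_edge_coverage: float = 0.5
    inflation: float = 5.0
    core_fraction: float = 0.9
    max_gap_fraction: float = 0.5
    prune_fraction: float = 0.2
    fragment_length: int = 1020
    ani_min_identity: float = 30.0
    ani_min_coverage: float = 70.0
    aai_min_coverage: float = 0.7
    support_min: float = 100.0
    synonym_ani_min: float = 96.0
    synonym_dddh_min: float = 70.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns a result dict with the key artifacts and writes everything
    (matrices, tables, manifest) under ``config.outdir``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "params": asdict(config), "inputs": {}}
    results: dict = {}

    # --- stage: dataset ------------------------------------------------
    if config.simulate:
        sim_cfg = SimulationConfig(**{"seed": config.seed, **config.simulation})
        log.info("simulating dataset (%d genomes)", sim_cfg.n_genomes)
        genomes, truth = simulate_dataset(sim_cfg)
        data_dir = out / "dataset"
        write_dataset(genomes, truth, data_dir, overwrite=True)
    else:
        if not config.dataset_dir:
            raise PipelineError("dataset stage: no dataset_dir and simulate=false")
        data_dir = Path(config.dataset_dir)
        genomes, truth = read_dataset(data_dir)
    tree = truth.tree
    if tree is None:
        raise PipelineError("dataset stage: no tree available")
    for p in sorted(data_dir.glob("*")):
        manifest["inputs"][p.name] = _sha256(p)
    results["genomes"], results["truth"] = genomes, truth

    # --- stage: pangenome ----------------------------------------------
    log.info("pangenome: all-vs-all similarity + MCL (inflation %g)", config.inflation)
    graph = score_protein_pairs(
        genomes, min_identity=config.min_identity,
        min_coverage=config.min_edge_coverage,
    )
    families = mcl_cluster(
        graph, inflation=config.inflation, min_identity=config.min_identity
    )
    matrix = presence_matrix(families, sorted(genomes))
    core = extract_core(matrix, fraction=config.core_fraction)
    families.to_tsv(out / "families.tsv")
    matrix.to_tsv(out / "pangenome_matrix.tsv")
    (out / "core_families.txt").write_text("\n".join(core) + "\n")
    results.update(families=families, matrix=matrix, core=core)

    # --- stage: core90 supermatrix --------------------------------------
    if config.run_msa and core:
        log.info("aligning and trimming %d core families", len(core))
        trimmed = []
        for fam in core:
            seqs = {}
            for gid in families.families[fam]:
                g = gid.split("|", 1)[0]
                seqs[g] = genomes[g].proteins[gid]
            if len(seqs) < 2:
                continue
            aln = align_family(seqs, family_id=fam)
            t, _report = trim_alignment(
                aln, config.max_gap_fraction, config.prune_fraction
            )
            trimmed.append(t)
        super_aln = concatenate(trimmed, sorted(genomes))
        super_aln.write(out / "core90.faa", out / "core90.partitions.tsv")
        results["supermatrix"] = super_aln

    # --- stage: OGRIs ----------------------------------------------------
    matrices = {}
    if config.run_ogri:
        recs = [genomes[g] for g in sorted(genomes)]
        log.info("computing OGRI matrices over %d genomes", len(recs))
        matrices["ANI"] = pairwise_matrix(
            "anib", recs, fragment_length=config.fragment_length,
            min_identity=config.ani_min_identity,
            min_coverage=config.ani_min_coverage,
        )
        matrices["AAI"] = pairwise_matrix(
            "aai", recs, min_coverage=config.aai_min_coverage
        )
        matrices["cAAI"] = pairwise_matrix(
            "caai", recs, core_families=core,
            family_map=families.gene_to_family,
            min_coverage=config.aai_min_coverage,
        )
        matrices["dDDH"] = pairwise_matrix(
            "dddh", recs, fragment_length=config.fragment_length
        )
        for name, m in matrices.items():
            m.to_tsv(out / f"{name.lower()}_matrix.tsv")
        results["matrices"] = matrices

    # --- stage: phylogroups + signatures --------------------------------
    assignment = None
    if config.run_signatures:
        clades = truth.clades()
        representatives = {
            label: sorted(members)[0] for label, members in sorted(clades.items())
        }
        assignment = assign_phylogroups(tree, representatives)
        assignment.to_tsv(out / "phylogroups.tsv")
        table = build_pattern_table(matrix, assignment.clades())
        table.to_tsv(out / "pattern_table.tsv")
        sig_counts = count_signatures_per_proposal(matrix, assignment.clades())
        write_json(sig_counts, out / "signature_counts.json")
        results.update(assignment=assignment, pattern_table=table,
                       signature_counts=sig_counts)

    # --- stage: evaluation + synonyms ------------------------------------
    if config.run_evaluation and config.run_ogri and assignment is not None:
        evaluation = evaluate_clades(
            tree, assignment,
            [matrices["AAI"], matrices["cAAI"]],
            support_min=config.support_min,
        )
        synonyms = call_synonyms(
            matrices["ANI"], matrices["dDDH"],
            ani_min=config.synonym_ani_min,
            dddh_min=config.synonym_dddh_min,
        )
        write_json(
            {
                "global_min_intra": evaluation.global_min_intra,
                "synonym_sets": [sorted(s) for s in synonyms.synonym_sets],
                "reds": {
                    label: rep.red for label, rep in evaluation.clades.items()
                },
            },
            out / "evaluation.json",
        )
        results.update(evaluation=evaluation, synonyms=synonyms)

    for p in sorted(out.glob("*")):
        if p.is_file():
            manifest.setdefault("artifacts", {})[p.name] = _sha256(p)
    write_json(manifest, out / "manifest.json")
    results["manifest"] = manifest
    return results


def verify_manifest(outdir: str | Path) -> list[str]:
    """Names of recorded input files whose hash no longer matches."""
    out = Path(outdir)
    manifest = read_json(out / "manifest.json")
    bad = []
    for name, digest in manifest.get("inputs", {}).items():
        p = out / "dataset" / name
        if not p.exists() or _sha256(p) != digest:
            bad.append(name)
    return bad
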