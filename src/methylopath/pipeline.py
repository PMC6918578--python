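"""Pipeline orchestration: validated configuration and report assembly.

A single :class:`PipelineConfig` drives three stages — the thermodynamic
equilibrium report, the pathway comparison and the candidate-sequence
triage — and :func:`run_pipeline` writes their tab-separated reports plus a
Newick tree to an output directory.  Runs are deterministic given the
configuration (including its seed); stages never mutate each other's inputs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import pathways as pw
from . import seqsearch as ss
from . import synthetic as syn
from . import thermo as th
from .model import read_model

logger = logging.getLogger(__name__)


class MediumConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    methanol_m: float = Field(0.5, gt=0, description="methanol, mol/L")
    nad_ratio: float = Field(1.0, gt=0, description="[NAD+]/[NADH]")
    ph: float = Field(7.0, ge=0, le=14)


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid", protected_namespaces=())

    model_path: Optional[str] = None
    model_format: Literal["tabular", "sbml"] = "tabular"
    synthetic: bool = True
    methanol_uptake_cmol: float = Field(6.0, gt=0)
    temperatures_c: list[float] = Field(default_factory=lambda: [28.0, 30.0, 50.0])
    medium: MediumConfig = Field(default_factory=MediumConfig)
    pathways: list[Literal["RuMP", "XuMP", "serine_cycle"]] = Field(
        default_factory=lambda: list(pw.PATHWAY_NAMES)
    )
    objectives: list[Literal["growth", "tag"]] = Field(
        default_factory=lambda: ["growth", "tag"]
    )
    identity_threshold: float = Field(0.9, gt=0, le=1)
    fasta_path: Optional[str] = None
    seed: int = 0
    stages: list[Literal["thermo", "compare", "hps"]] = Field(
        default_factory=lambda: ["thermo", "compare", "hps"]
    )


class ConfigError(ValueError):
    pass


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def run_pipeline(config: PipelineConfig, outdir) -> dict[str, Path]:
    """Execute the configured stages and write their reports.

    Returns a mapping of artifact names to paths.  Raises on any stage
    error; the CLI translates these into nonzero exit codes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if "thermo" in config.stages:
        report = th.equilibrium_report(
            config.temperatures_c,
            methanol_m=config.medium.methanol_m,
            nad_ratio=config.medium.nad_ratio,
        )
        path = outdir / "thermo_report.tsv"
        report.to_csv(path, sep="\t", index=False, float_format="%.6g")
        artifacts["thermo_report"] = path
        logger.info("thermo report: %d temperatures", len(report))

    if "compare" in config.stages:
        if config.model_path:
            model = read_model(config.model_path, format=config.model_format)
        elif config.synthetic:
            model = syn.generate_core_model(syn.CoreModelParams(seed=config.seed))
        else:
            raise ConfigError("compare stage needs model_path or synthetic=true")
        table = pw.compare_pathways(
            model,
            uptake=config.methanol_uptake_cmol,
            objectives=config.objectives,
            pathways=config.pathways,
        )
        path = outdir / "pathway_comparison.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        artifacts["pathway_comparison"] = path
        logger.info("pathway comparison: %d rows", len(table))

    if "hps" in config.stages:
        if config.fasta_path:
            seqs = ss.read_fasta(config.fasta_path)
        else:
            fam, _ = syn.generate_protein_family(
                syn.FamilyParams(seed=config.seed)
            )
            seqs = [ss.ProteinSequence(k, v) for k, v in fam.items()]
        clusters = ss.cluster_by_identity(seqs, threshold=config.identity_threshold)
        cl_path = outdir / "hps_clusters.tsv"
        ss.clusters_to_table(clusters).to_csv(
            cl_path, sep="\t", index=False, float_format="%.6g"
        )
        artifacts["hps_clusters"] = cl_path
        reps = [c.representative for c in clusters]
        if len(reps) >= 2:
            dm = ss.identity_distance_matrix(reps)
            tree = ss.nj_tree(dm)
            nwk_path = outdir / "hps_tree.nwk"
            nwk_path.write_text(ss.write_newick(tree) + "\n")
            artifacts["hps_tree"] = nwk_path
        logger.info("hps triage: %d sequences -> %d clusters", len(seqs), len(clusters))

    return artifacts
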