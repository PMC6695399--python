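"""End-to-end orchestration: config, staging, and report generation.

``run_pipeline`` executes the complete analysis on either a synthetic study
(generated in-process from a seeded configuration) or on external tables:

    mass-correct (exosome) -> floor -> percentile shift (75 mRNA / 99 miRNA)
    -> mRNA Z-score DE -> miRNA fold+paired-t DE per compartment
    -> coverage-filtered target integration -> qPCR confirmation

Identical config + seed gives identical outputs; the seed and every
threshold are echoed into the run metadata.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .datamodel import ConfigError, ExpressionMatrix, GeneIdMap, QpcrDataset, TargetTable
from .diffexpr import DEResult, mirna_de, mrna_de
from .integration import CandidateSet, integrate_candidates
from .normalization import NormalizationSpec, normalize_chips
from .qpcr import QpcrResult, confirm_candidates, quantify
from .synthetic import SyntheticConfig, SyntheticTruth, generate_null_study, generate_study


@dataclass
class InputPaths:
    """External-table mode: paths plus per-file sample metadata specs."""

    mrna_cell: str
    mirna_cell: str
    mirna_exosome: str
    target_table: str
    id_map: str
    sample_meta: dict[str, dict]  # sample name -> group/replicate/compartment/assay
    qpcr: str | None = None
    qpcr_reference: str = "GAPDH"
    target_dialect: str = "two_column"
    geo_dialect: bool = False


@dataclass
class RunConfig:
    """Everything one analysis run needs; exactly one of synthetic/inputs set.

    Every threshold the method defines is a named field with its
    conventional default: 2-fold and q < 0.05 for miRNA DE, |Z| >= 2 for
    mRNA DE, coverage > 0.5 for target prediction, and 1.5-fold with
    p < 0.05 for qPCR confirmation.
    """

    synthetic: SyntheticConfig | None = None
    inputs: InputPaths | None = None
    null_study: bool = False
    seed: int = 0
    z_threshold: float = 2.0
    fold_threshold: float = 2.0
    q_threshold: float = 0.05
    strategy: str = "common_mirna_first"
    min_fraction: float = 0.5
    arm_fallback: bool = False
    qpcr_fold_threshold: float = 1.5
    qpcr_p_threshold: float = 0.05
    mrna_percentile: float = 75.0
    mirna_percentile: float = 99.0
    floor_value: float = 1.0
    mass_correction_factors: dict[str, float] | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigError("exactly one of a synthetic block or input paths must be given")

    @classmethod
    def from_dict(cls, doc: Mapping) -> "RunConfig":
        doc = dict(doc)
        syn = doc.pop("synthetic", None)
        inp = doc.pop("inputs", None)
        if syn is not None:
            syn = SyntheticConfig(**syn)
        if inp is not None:
            inp = InputPaths(**inp)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(synthetic=syn, inputs=inp, **doc)
        if cfg.synthetic is not None and "seed" in doc:
            cfg.synthetic = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(doc)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: v for k, v in d.items() if k not in ("inputs",)}


@dataclass
class PipelineResult:
    """All artifacts of one run, in memory."""

    mrna_de: DEResult
    mirna_cell_de: DEResult
    mirna_exo_de: DEResult
    candidates: CandidateSet
    qpcr_result: QpcrResult | None
    confirmation: pd.DataFrame | None
    truth: SyntheticTruth | None
    written: dict[str, Path] = field(default_factory=dict)


def _load_inputs(inp: InputPaths) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix, TargetTable, GeneIdMap, QpcrDataset | None]:
    reader = io.read_geo_series_matrix if inp.geo_dialect else io.read_expression_table
    spec = inp.sample_meta

    def sub_spec(path: str) -> dict:
        # each file only needs the samples that actually appear in its header
        return spec

    mrna = reader(inp.mrna_cell, sub_spec(inp.mrna_cell))
    mir_cell = reader(inp.mirna_cell, sub_spec(inp.mirna_cell))
    mir_exo = reader(inp.mirna_exosome, sub_spec(inp.mirna_exosome))
    table = io.read_target_table(inp.target_table, inp.target_dialect)
    id_map = io.read_gene_id_map(inp.id_map)
    qpcr = io.read_qpcr_dataset(inp.qpcr, inp.qpcr_reference) if inp.qpcr else None
    return mrna, mir_cell, mir_exo, table, id_map, qpcr


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    When an output directory is configured, writes the DE tables, the
    candidate report (table + cardinality summary + metadata), and the qPCR
    confirmation table.
    """
    truth: SyntheticTruth | None = None
    stage = "load"
    try:
        if config.synthetic is not None:
            syn = dataclasses.replace(config.synthetic, seed=config.seed)
            gen = generate_null_study if config.null_study else generate_study
            mrna, mir_cell, mir_exo, table, id_map, qpcr, truth = gen(syn)
        else:
            mrna, mir_cell, mir_exo, table, id_map, qpcr = _load_inputs(config.inputs)

        stage = "normalization"
        mrna_spec = NormalizationSpec(floor_value=config.floor_value, percentile=config.mrna_percentile)
        mirna_spec = NormalizationSpec(floor_value=config.floor_value, percentile=config.mirna_percentile)
        exo_spec = NormalizationSpec(
            floor_value=config.floor_value,
            percentile=config.mirna_percentile,
            mass_correction_factors=config.mass_correction_factors,
        )
        mrna_n = normalize_chips(mrna, mrna_spec)
        mir_cell_n = normalize_chips(mir_cell, mirna_spec)
        mir_exo_n = normalize_chips(mir_exo, exo_spec)

        stage = "mrna_de"
        mrna_res = mrna_de(mrna_n, z_threshold=config.z_threshold)
        stage = "mirna_de"
        cell_res = mirna_de(mir_cell_n, config.fold_threshold, config.q_threshold)
        exo_res = mirna_de(mir_exo_n, config.fold_threshold, config.q_threshold)

        stage = "integration"
        candidates = integrate_candidates(
            mrna_res,
            cell_res,
            exo_res,
            table,
            id_map,
            strategy=config.strategy,
            min_fraction=config.min_fraction,
            arm_fallback=config.arm_fallback,
        )

        stage = "qpcr"
        qpcr_result = confirmation = None
        if qpcr is not None:
            qpcr_result = quantify(qpcr)
            confirmation = confirm_candidates(
                qpcr_result,
                candidates,
                fold_threshold=config.qpcr_fold_threshold,
                p_threshold=config.qpcr_p_threshold,
            )
    except Exception as err:
        raise type(err)(f"[stage: {stage}] {err}") from err

    result = PipelineResult(
        mrna_de=mrna_res,
        mirna_cell_de=cell_res,
        mirna_exo_de=exo_res,
        candidates=candidates,
        qpcr_result=qpcr_result,
        confirmation=confirmation,
        truth=truth,
    )
    if config.out_dir:
        result.written = write_outputs(result, config)
    return result


def write_outputs(result: PipelineResult, config: RunConfig) -> dict[str, Path]:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_de_table(result.mrna_de, out / "de_mrna.tsv")
    io.write_de_table(result.mirna_cell_de, out / "de_mirna_cell.tsv")
    io.write_de_table(result.mirna_exo_de, out / "de_mirna_exosome.tsv")
    metadata = {
        "seed": config.seed,
        "crossmir_version": __version__,
        "numpy_version": np.__version__,
        "rng": "PCG64",
        "percentile_convention": "linear interpolation between closest ranks",
        "config": config.echo(),
    }
    written = io.write_candidate_report(
        result.candidates,
        {
            "mRNA (cell)": result.mrna_de,
            "miRNA (cell)": result.mirna_cell_de,
            "miRNA (exosome)": result.mirna_exo_de,
        },
        out,
        metadata=metadata,
    )
    written.update(
        de_mrna=out / "de_mrna.tsv",
        de_mirna_cell=out / "de_mirna_cell.tsv",
        de_mirna_exosome=out / "de_mirna_exosome.tsv",
    )
    if result.confirmation is not None:
        io.write_qpcr_table(result.confirmation, out / "qpcr_confirmation.tsv")
        written["qpcr_confirmation"] = out / "qpcr_confirmation.tsv"
    return written


def simulate_to_dir(config: SyntheticConfig, out_dir: str | Path, *, null_study: bool = False) -> dict[str, Path]:
    """Write a synthetic study to disk as plain-text tables plus a manifest.

    The manifest (YAML) records the sample metadata for each expression
    table, the qPCR reference gene, and the full generator configuration, so
    ``run`` on the directory reproduces an inline-synthetic run bit for bit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = generate_null_study if null_study else generate_study
    mrna, mir_cell, mir_exo, table, id_map, qpcr, truth = gen(config)

    io.write_expression_table(mrna, out / "mrna_cell.tsv")
    io.write_expression_table(mir_cell, out / "mirna_cell.tsv")
    io.write_expression_table(mir_exo, out / "mirna_exosome.tsv")
    io.write_target_table(table, out / "targets.tsv")
    io.write_gene_id_map(id_map, out / "id_map.tsv")
    io.write_qpcr_dataset(qpcr, out / "qpcr.tsv")

    sample_meta = {
        s.name: {
            "group": s.group,
            "replicate_index": s.replicate_index,
            "compartment": s.compartment,
            "assay": s.assay,
        }
        for m in (mrna, mir_cell, mir_exo)
        for s in m.samples
    }
    manifest = {
        "sample_meta": sample_meta,
        "qpcr_reference": qpcr.reference_gene,
        "target_dialect": "two_column",
        "synthetic_config": dataclasses.asdict(config),
        "null_study": null_study,
        "truth": {
            "de_genes_up": sorted(truth.de_genes_up),
            "de_genes_down": sorted(truth.de_genes_down),
            "de_mirnas_up": {k: sorted(v) for k, v in truth.de_mirnas_up.items()},
            "de_mirnas_down": {k: sorted(v) for k, v in truth.de_mirnas_down.items()},
            "biomarker_genes_up": sorted(truth.biomarker_genes_up),
            "biomarker_genes_down": sorted(truth.biomarker_genes_down),
            "seed": truth.seed,
            "generator": truth.generator,
        },
    }
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return {
        "manifest": manifest_path,
        "mrna_cell": out / "mrna_cell.tsv",
        "mirna_cell": out / "mirna_cell.tsv",
        "mirna_exosome": out / "mirna_exosome.tsv",
        "targets": out / "targets.tsv",
        "id_map": out / "id_map.tsv",
        "qpcr": out / "qpcr.tsv",
    }


def config_for_simulated_dir(study_dir: str | Path, **overrides) -> RunConfig:
    """Build a RunConfig that runs on a directory written by simulate_to_dir."""
    study = Path(study_dir)
    with open(study / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    inputs = InputPaths(
        mrna_cell=str(study / "mrna_cell.tsv"),
        mirna_cell=str(study / "mirna_cell.tsv"),
        mirna_exosome=str(study / "mirna_exosome.tsv"),
        target_table=str(study / "targets.tsv"),
        id_map=str(study / "id_map.tsv"),
        sample_meta=manifest["sample_meta"],
        qpcr=str(study / "qpcr.tsv"),
        qpcr_reference=manifest["qpcr_reference"],
        target_dialect=manifest.get("target_dialect", "two_column"),
    )
    seed = manifest["synthetic_config"]["seed"]
    return RunConfig(inputs=inputs, seed=seed, **overrides)
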