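"""End-to-end orchestration: (synth |load) -> qc -> sensitivity / de / lr /
batchqc, from one config, with deterministic seeding and a run manifest.

Sub-seeds for every stochastic stage are derived from the master seed by
stable hashing of (stage, stratum, cell type), so per-component results
are reproducible independent of execution order. The manifest records the
package version, the seed, a sha256 hash of the full parameter set and
the status + outputs of every stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._utils import ScshiftError, stable_seed
from .batchqc import batch_mixing_report
from .containers import CountMatrix
from .coordination import lr_interaction_test
from .differential import DEGParams, reversed_genes, wilcoxon_de
from .io_qc import (
    QCParams,
    bundled_lr_pairs,
    filter_cells,
    normalize,
    read_annotation,
    read_count_matrix,
    read_lr_pairs,
    write_annotation,
    write_count_matrix,
)
from .sensitivity import ShiftParams, sensitivity_report
from .synth import SynthConfig, generate_dataset

ALL_STAGES = ("data", "qc", "sensitivity", "de", "lr", "batchqc")


@dataclass
class AnalysisConfig:
    out_dir: str
    seed: int = 0
    # data source: either a synthetic generator config or file paths
    synth: SynthConfig | None = None
    mtx_path: str | None = None
    features_path: str | None = None
    barcodes_path: str | None = None
    annotation_path: str | None = None
    lr_pairs_path: str | None = None  # None -> bundled toy table
    qc: QCParams = field(default_factory=QCParams)
    shift: ShiftParams = field(default_factory=ShiftParams)
    deg: DEGParams = field(default_factory=DEGParams)
    lr_n_permutations: int = 1000
    lr_alpha: float = 0.05
    batch_col: str = "batch"
    batch_n_runs: int = 100
    stratify: tuple[str, ...] = ("tissue", "timepoint")
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ScshiftError(f"unknown stages {sorted(unknown)}; valid: {ALL_STAGES}")
        if self.synth is None and self.mtx_path is None:
            raise ScshiftError("config needs either a synth block or matrix paths")
        if self.synth is not None:
            self.synth = (
                SynthConfig(**self.synth) if isinstance(self.synth, dict) else self.synth
            )
        for name, cls in (("qc", QCParams), ("shift", ShiftParams), ("deg", DEGParams)):
            val = getattr(self, name)
            if isinstance(val, dict):
                setattr(self, name, cls(**val))
        self.stratify = tuple(self.stratify)
        self.stages = tuple(self.stages)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def parameter_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    from . import __version__

    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "stages": {},
    }
    out = lambda name: os.path.join(config.out_dir, name)  # noqa: E731

    def record(stage: str, status: str, outputs: list[str] | None = None) -> None:
        manifest["stages"][stage] = {"status": status, "outputs": outputs or []}

    try:
        # data -------------------------------------------------------------
        if config.synth is not None:
            synth_cfg = dataclasses.replace(
                config.synth, seed=stable_seed(config.seed, "synth")
            )
            counts, annot, truth = generate_dataset(synth_cfg)
            paths = write_count_matrix(counts, out("raw"))
            write_annotation(annot, out("raw/annotation.tsv"))
            record("data", "done", [paths["mtx"], out("raw/annotation.tsv")])
        else:
            counts = read_count_matrix(
                config.mtx_path, config.features_path, config.barcodes_path
            )
            annot = read_annotation(config.annotation_path, cell_ids=counts.cell_ids)
            record("data", "done", [config.mtx_path])

        # qc ---------------------------------------------------------------
        if "qc" in config.stages:
            counts, qc_table = filter_cells(counts, config.qc)
            annot = annot.loc[list(counts.cell_ids)]
            qc_table.to_csv(out("qc_table.tsv"), sep="\t")
            record("qc", "done", [out("qc_table.tsv")])
        else:
            record("qc", "skipped")
        expr = normalize(counts)

        # sensitivity ------------------------------------------------------
        if "sensitivity" in config.stages:
            params = dataclasses.replace(
                config.shift, seed=stable_seed(config.seed, "sensitivity")
            )
            report, _ = sensitivity_report(
                expr, annot, params, stratify=config.stratify
            )
            rounded = report.copy()
            rounded["avg_rank"] = rounded["avg_rank"].round(2)
            report.to_csv(out("sensitivity_full.tsv"), sep="\t", index=False)
            rounded.to_csv(out("sensitivity_ranks.tsv"), sep="\t", index=False)
            record("sensitivity", "done", [out("sensitivity_full.tsv"), out("sensitivity_ranks.tsv")])
        else:
            record("sensitivity", "skipped")

        # de ---------------------------------------------------------------
        if "de" in config.stages:
            tables = []
            reversed_tables = []
            has_treated = (annot["condition"] == "treated").any()
            for t in sorted(annot["cell_type"].unique()):
                sub = annot[annot["cell_type"] == t]
                pert = sub.index[sub["condition"] == "perturbed"]
                ctrl = sub.index[sub["condition"] == "control"]
                if min(len(pert), len(ctrl)) < config.shift.min_cells_per_group:
                    continue
                deg_pc = wilcoxon_de(expr, list(pert), list(ctrl), config.deg)
                deg_pc.insert(0, "cell_type", t)
                tables.append(deg_pc)
                if has_treated:
                    treated = sub.index[sub["condition"] == "treated"]
                    if len(treated) >= config.shift.min_cells_per_group:
                        deg_tp = wilcoxon_de(expr, list(treated), list(pert), config.deg)
                        rev = reversed_genes(
                            deg_pc.drop(columns="cell_type"), deg_tp,
                            alpha=config.deg.alpha_adjusted,
                        )
                        rev.insert(0, "cell_type", t)
                        reversed_tables.append(rev)
            degs = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
            degs.to_csv(out("degs.tsv"), sep="\t", index=False)
            outputs = [out("degs.tsv")]
            if reversed_tables:
                pd.concat(reversed_tables, ignore_index=True).to_csv(
                    out("reversed_genes.tsv"), sep="\t", index=False
                )
                outputs.append(out("reversed_genes.tsv"))
            record("de", "done", outputs)
        else:
            record("de", "skipped")

        # lr ---------------------------------------------------------------
        if "lr" in config.stages:
            if config.lr_pairs_path:
                pairs = read_lr_pairs(config.lr_pairs_path)
            elif config.synth is not None and config.synth.planted_lr:
                # synthetic runs test their own planted pairs
                pairs = pd.DataFrame(
                    [(p.ligand, p.receptor) for p in config.synth.planted_lr],
                    columns=["ligand", "receptor"],
                )
            else:
                pairs = bundled_lr_pairs()
            lr = lr_interaction_test(
                expr,
                annot,
                pairs,
                n_permutations=config.lr_n_permutations,
                alpha=config.lr_alpha,
                seed=stable_seed(config.seed, "lr"),
            )
            lr.ordered_counts.to_csv(out("lr_counts_ordered.tsv"), sep="\t")
            lr.symmetric_counts.to_csv(out("lr_counts_symmetric.tsv"), sep="\t")
            lr.detail.to_csv(out("lr_detail.tsv"), sep="\t", index=False)
            record("lr", "done", [out("lr_counts_ordered.tsv"), out("lr_counts_symmetric.tsv"), out("lr_detail.tsv")])
        else:
            record("lr", "skipped")

        # batchqc ----------------------------------------------------------
        if "batchqc" in config.stages:
            bq = batch_mixing_report(
                expr,
                annot,
                batch_col=config.batch_col,
                n_runs=config.batch_n_runs,
                seed=stable_seed(config.seed, "batchqc"),
            )
            bq.to_csv(out("batchqc.tsv"), sep="\t", index=False)
            record("batchqc", "done", [out("batchqc.tsv")])
        else:
            record("batchqc", "skipped")
    except Exception as exc:
        stage = next(
            (s for s in ALL_STAGES if s not in manifest["stages"]), "unknown"
        )
        record(stage, f"failed: {exc}")
        _write_manifest(manifest, config.out_dir)
        raise ScshiftError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_manifest(manifest, config.out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: str) -> None:
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
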