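"""Synthetic droplet scRNA-seq generator with planted ground truth.

Emulates the statistical structure the downstream analyses assume: several
cell types with negative-binomial UMI counts, a two-condition design
(control vs perturbed) with per-cell-type perturbation magnitudes
(fraction of DE genes x log fold-change effect), mitochondrial genes with
a tunable expected UMI fraction, multiple batches with an optional
additive batch effect in log-mean space, and optionally planted
ligand-receptor co-expression between chosen cell-type pairs.

Counts for gene g in cell c are NB(mu, r) with
``mu = mu_g * exp(delta) * lib_c`` where mu_g is a log-normal per-gene
baseline mean, ``delta`` sums the condition / batch / ligand-receptor
log-fold-change offsets (natural log) that apply to that gene and cell,
``lib_c`` is a log-normal per-cell library-size factor and ``r`` is a
shared inverse-dispersion. Identical config + seed gives bit-identical
output.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._utils import ScshiftError
from .containers import CountMatrix, validate_annotation
from .io_qc import write_annotation, write_count_matrix


@dataclass
class PerturbationEffect:
    """Per-cell-type perturbation: a random ``fraction_de`` of genes shift
    by ``log_fc`` (natural log) in perturbed cells; ``up_fraction`` of the
    shifted genes go up, the rest down. Effect size = fraction_de * |log_fc|.
    """

    fraction_de: float = 0.0
    log_fc: float = 0.0
    up_fraction: float = 0.5


@dataclass
class PlantedLR:
    """A ligand-receptor pair boosted in a directed cluster pair:
    ligand expression up in all cells of ``type_a``, receptor up in
    ``type_b`` (both conditions), by ``boost_log_fc`` natural-log units.
    """

    ligand: str
    receptor: str
    type_a: str
    type_b: str
    boost_log_fc: float = 2.0


@dataclass
class SynthConfig:
    n_cell_types: int = 3
    cells_per_type_per_condition: int | dict = 150
    n_genes: int = 500
    gene_mean_log_mean: float = -1.0
    gene_mean_log_sd: float = 1.0
    nb_dispersion: float = 2.0
    lib_size_sigma: float = 0.3
    effects: dict = field(default_factory=dict)  # cell_type -> PerturbationEffect
    mito_fraction_target: float = 0.05
    n_mito_genes: int = 10
    n_batches: int = 2
    batch_effect_log_fc: float = 0.0
    batch_gene_fraction: float = 0.10
    planted_lr: list = field(default_factory=list)
    lr_base_mean: float | None = 1.0
    tissue: str = "tissue"
    timepoint: str = "t0"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 1 or self.n_genes < 1:
            raise ValueError("n_cell_types and n_genes must be positive")
        if not (0 <= self.mito_fraction_target < 1):
            raise ValueError("mito_fraction_target must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        fixed = {}
        for name, eff in self.effects.items():
            if isinstance(eff, tuple):
                eff = PerturbationEffect(*eff)
            elif isinstance(eff, dict):
                eff = PerturbationEffect(**eff)
            if not (0 <= eff.fraction_de <= 1):
                raise ValueError("fraction_de must be in [0, 1]")
            fixed[name] = eff
        self.effects = fixed
        self.planted_lr = [
            PlantedLR(**p) if isinstance(p, dict) else p for p in self.planted_lr
        ]

    @property
    def cell_types(self) -> list[str]:
        return [f"type{i}" for i in range(self.n_cell_types)]

    def cells_of(self, cell_type: str) -> int:
        if isinstance(self.cells_per_type_per_condition, dict):
            return int(self.cells_per_type_per_condition[cell_type])
        return int(self.cells_per_type_per_condition)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset, for parameter-recovery checks."""

    effect_sizes: dict  # cell_type -> fraction_de * |log_fc|
    de_genes: dict  # cell_type -> list of shifted gene ids
    de_signs: dict  # cell_type -> {gene: +1/-1}
    planted_lr: list  # PlantedLR records
    batch_genes: dict  # batch -> list of shifted gene ids

    def to_json(self) -> str:
        payload = asdict(self)
        payload["planted_lr"] = [asdict(p) for p in self.planted_lr]
        return json.dumps(payload, indent=1, sort_keys=True)


def _gene_universe(config: SynthConfig) -> np.ndarray:
    width = max(4, len(str(config.n_genes)))
    regular = [f"gene{i:0{width}d}" for i in range(config.n_genes - config.n_mito_genes)]
    mito = [f"mt-gene{i}" for i in range(config.n_mito_genes)]
    return np.array(regular + mito, dtype=object)


def generate_dataset(
    config: SynthConfig,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Draw a full dataset; returns (counts, annotation, truth)."""
    rng = np.random.default_rng(config.seed)
    gene_ids = _gene_universe(config)
    n_genes = len(gene_ids)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    is_mito = np.array([g.startswith("mt-") for g in gene_ids])

    base_mean = rng.lognormal(
        config.gene_mean_log_mean, config.gene_mean_log_sd, size=n_genes
    )
    if is_mito.any() and config.mito_fraction_target > 0:
        # tune mito means so E[mito UMIs] / E[total UMIs] hits the target
        non_mito_total = base_mean[~is_mito].sum()
        target = config.mito_fraction_target
        base_mean[is_mito] = (target / (1 - target)) * non_mito_total / is_mito.sum()

    for pair in config.planted_lr:
        for g in (pair.ligand, pair.receptor):
            if g not in gene_pos:
                raise ScshiftError(f"planted ligand-receptor gene {g!r} not in gene universe")
        for t in (pair.type_a, pair.type_b):
            if t not in config.cell_types:
                raise ScshiftError(f"planted ligand-receptor cell type {t!r} unknown")
        if config.lr_base_mean is not None:
            base_mean[gene_pos[pair.ligand]] = config.lr_base_mean
            base_mean[gene_pos[pair.receptor]] = config.lr_base_mean

    # per-batch gene subsets carrying the batch effect
    batch_names = [f"batch{b}" for b in range(config.n_batches)]
    n_batch_genes = int(round(config.batch_gene_fraction * n_genes))
    batch_genes: dict[str, list[str]] = {}
    batch_offsets = np.zeros((config.n_batches, n_genes))
    for b, bname in enumerate(batch_names):
        idx = rng.choice(n_genes, size=n_batch_genes, replace=False)
        batch_genes[bname] = [gene_ids[i] for i in sorted(idx)]
        if b > 0:  # batch0 is the reference batch
            batch_offsets[b, idx] = config.batch_effect_log_fc

    # per-type condition effects
    de_genes: dict[str, list[str]] = {}
    de_signs: dict[str, dict[str, int]] = {}
    effect_sizes: dict[str, float] = {}
    cond_offsets = {t: np.zeros(n_genes) for t in config.cell_types}
    candidates = np.flatnonzero(~is_mito)
    for t in config.cell_types:
        eff = config.effects.get(t, PerturbationEffect())
        n_de = int(round(eff.fraction_de * len(candidates)))
        idx = rng.choice(candidates, size=n_de, replace=False)
        signs = np.where(rng.random(n_de) < eff.up_fraction, 1.0, -1.0)
        cond_offsets[t][idx] = signs * abs(eff.log_fc)
        de_genes[t] = [gene_ids[i] for i in idx]
        de_signs[t] = {gene_ids[i]: int(s) for i, s in zip(idx, signs)}
        effect_sizes[t] = eff.fraction_de * abs(eff.log_fc)

    lr_offsets = {t: np.zeros(n_genes) for t in config.cell_types}
    for pair in config.planted_lr:
        lr_offsets[pair.type_a][gene_pos[pair.ligand]] += pair.boost_log_fc
        lr_offsets[pair.type_b][gene_pos[pair.receptor]] += pair.boost_log_fc

    blocks, cell_ids, annot_rows = [], [], []
    r = config.nb_dispersion
    for t in config.cell_types:
        n_cells = config.cells_of(t)
        for cond in ("control", "perturbed"):
            batches = rng.integers(config.n_batches, size=n_cells)
            lib = rng.lognormal(0.0, config.lib_size_sigma, size=n_cells)
            log_mu = np.log(base_mean)[:, None] + lr_offsets[t][:, None]
            log_mu = log_mu + batch_offsets[batches].T
            if cond == "perturbed":
                log_mu = log_mu + cond_offsets[t][:, None]
            mu = np.exp(log_mu) * lib[None, :]
            p = r / (r + mu)
            blocks.append(rng.negative_binomial(r, p))
            for j in range(n_cells):
                cid = f"{t}_{cond}_{j}"
                cell_ids.append(cid)
                annot_rows.append(
                    {
                        "cell_id": cid,
                        "sample_id": f"{cond}_{batch_names[batches[j]]}",
                        "tissue": config.tissue,
                        "timepoint": config.timepoint,
                        "condition": cond,
                        "batch": batch_names[batches[j]],
                        "cell_type": t,
                    }
                )

    counts = CountMatrix(
        sp.csr_matrix(np.concatenate(blocks, axis=1)),
        gene_ids,
        np.array(cell_ids, dtype=object),
    )
    annot = validate_annotation(pd.DataFrame(annot_rows), cell_ids=counts.cell_ids)
    truth = SyntheticTruth(effect_sizes, de_genes, de_signs, list(config.planted_lr), batch_genes)
    return counts, annot, truth


def planted_lr_dataset(
    config: SynthConfig,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Ligand-receptor-focused draw: condition effects are switched off so
    everything except the planted pairs is exchangeable across clusters."""
    if config.n_cell_types < 2:
        raise ScshiftError("planted_lr_dataset needs at least 2 cell types")
    quiet = SynthConfig(**{**asdict(config), "effects": {}})
    return generate_dataset(quiet)


def write_dataset(
    counts: CountMatrix, annot: pd.DataFrame, truth: SyntheticTruth, out_dir: str
) -> dict[str, str]:
    """Write MTX triplet + annotation TSV + truth JSON into ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    paths = write_count_matrix(counts, out_dir)
    paths["annotation"] = os.path.join(out_dir, "annotation.tsv")
    write_annotation(annot, paths["annotation"])
    paths["truth"] = os.path.join(out_dir, "truth.json")
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())
    return paths
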