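"""Synthetic multi-dataset scRNA-seq generator with known subtype and batch
structure.

The generative model is deliberately the simplest one that exercises every
stage of the pipeline: per-gene baseline log-means drawn once; each subtype
adds a fixed log-shift to its own marker genes; each dataset adds gene-wise
Gaussian batch offsets; cells draw a library size from a log-normal and
counts from a negative binomial (gamma-Poisson) around the cell's expected
expression. Subtypes can be removed from chosen datasets to emulate the
partial subtype overlap that makes multi-study integration hard. It is a
testbed, not a biological claim: no dropout curves fit to real data, no
doublets, no ambient RNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .datatypes import ExpressionDataset


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic multi-batch benchmark.

    Defaults describe six datasets of 300 cells over five subtypes with 25
    markers each (~1 natural-log-unit upshift), moderate gene-wise batch
    shifts (sd 0.3 log-units), and two subtypes each absent from one dataset.
    """

    n_genes: int = 1000
    n_subtypes: int = 5
    n_datasets: int = 6
    cells_per_dataset: int = 300
    marker_genes_per_subtype: int = 25
    marker_shift: float = 1.0
    batch_shift_sd: float = 0.3
    library_size_mean: float = 2500.0
    library_size_sigma: float = 0.3
    nb_dispersion: float = 0.1
    samples_per_dataset: int = 2
    missing_subtype_map: dict[int, list[int]] = field(
        default_factory=lambda: {1: [4], 4: [0]})
    seed: int = 42
    model_seed: int = 42

    def __post_init__(self):
        for name in ("n_genes", "n_subtypes", "n_datasets", "cells_per_dataset",
                     "marker_genes_per_subtype", "samples_per_dataset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.marker_shift < 0:
            raise ValueError("marker_shift must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.marker_genes_per_subtype * self.n_subtypes > self.n_genes:
            raise ValueError("more marker genes requested than genes available")


def generate_synthetic_atlas_inputs(
    cfg: SimulationConfig,
) -> tuple[list[ExpressionDataset], pd.DataFrame]:
    """Generate per-dataset counts plus a truth table.

    Returns ``(datasets, truth)`` where ``truth`` has one row per cell with
    its dataset, sample and true subtype. Marker genes of subtype ``s`` are
    genes ``s*m .. (s+1)*m - 1`` (``m = marker_genes_per_subtype``).

    The gene-level model (baseline log-means) depends only on ``model_seed``;
    ``seed`` drives all cell-level sampling (batch offsets, subtype draws,
    library sizes, counts). Two configs sharing ``model_seed`` therefore
    describe the same generative universe, so a query simulated with a fresh
    ``seed`` is new data from the same population — what a held-out
    experiment would look like.
    """
    model_rng = np.random.default_rng(cfg.model_seed)
    rng = np.random.default_rng(cfg.seed)
    g, s = cfg.n_genes, cfg.n_subtypes
    base = model_rng.normal(0.0, 1.2, size=g)

    subtype_logmean = np.tile(base, (s, 1))
    marker_sets = []
    for k in range(s):
        markers = np.arange(k * cfg.marker_genes_per_subtype,
                            (k + 1) * cfg.marker_genes_per_subtype)
        subtype_logmean[k, markers] += cfg.marker_shift
        marker_sets.append(markers)

    datasets, truth_rows = [], []
    for d in range(cfg.n_datasets):
        batch_offset = rng.normal(0.0, cfg.batch_shift_sd, size=g)
        present = [k for k in range(s)
                   if k not in cfg.missing_subtype_map.get(d, [])]
        subtype_of_cell = rng.choice(present, size=cfg.cells_per_dataset)
        sample_of_cell = rng.integers(cfg.samples_per_dataset,
                                      size=cfg.cells_per_dataset)
        lib = rng.lognormal(np.log(cfg.library_size_mean),
                            cfg.library_size_sigma, size=cfg.cells_per_dataset)
        counts = np.empty((g, cfg.cells_per_dataset), dtype=np.int64)
        for c in range(cfg.cells_per_dataset):
            logmu = subtype_logmean[subtype_of_cell[c]] + batch_offset
            p = np.exp(logmu)
            p /= p.sum()
            mu = lib[c] * p
            if cfg.nb_dispersion > 0:   # gamma-Poisson = negative binomial
                r = 1.0 / cfg.nb_dispersion
                lam = rng.gamma(shape=r, scale=mu / r)
            else:
                lam = mu
            counts[:, c] = rng.poisson(lam)
        cell_ids = [f"d{d}_c{c}" for c in range(cfg.cells_per_dataset)]
        meta = pd.DataFrame({
            "dataset_id": f"dataset{d}",
            "sample_id": [f"dataset{d}_s{x}" for x in sample_of_cell],
            "true_subtype": [f"S{k}" for k in subtype_of_cell],
        }, index=cell_ids)
        datasets.append(ExpressionDataset(
            gene_ids=[f"g{i}" for i in range(g)],
            cell_ids=cell_ids,
            counts=sparse.csr_matrix(counts),
            cell_meta=meta,
        ))
        truth_rows.append(meta)
    truth = pd.concat(truth_rows)
    truth.index.name = "cell_id"
    return datasets, truth


def marker_genes_of(cfg: SimulationConfig, subtype: int) -> list[str]:
    m = cfg.marker_genes_per_subtype
    return [f"g{i}" for i in range(subtype * m, (subtype + 1) * m)]
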