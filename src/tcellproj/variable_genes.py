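"""Variable-gene selection and the cross-dataset consensus ranking.

Per dataset, genes are ranked by standardized variance: the observed variance
of the log-normalized values divided by the value of a loess mean-variance
trend at that gene's mean (a variance-stabilized dispersion). Cycling,
mitochondrial, ribosomal and non-coding genes, and genes detected in fewer
than 0.1% or more than 90% of cells, are excluded before ranking. The
consensus over datasets keeps the genes found variable in the most datasets,
breaking ties toward genes supported by the largest datasets, then by the best
within-list rank, then lexicographically.
"""

from __future__ import annotations

import re
import warnings
from importlib import resources

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datatypes import ExpressionDataset

# Symbol patterns for the default exclusion categories (mouse conventions);
# the cycling list ships as an editable packaged file.
MITO_PATTERN = re.compile(r"^mt-", re.IGNORECASE)
RIBO_PATTERN = re.compile(r"^(Rps|Rpl|Mrps|Mrpl)", re.IGNORECASE)
NONCODING_PATTERN = re.compile(r"(^Gm\d+$)|(Rik$)|(^A[A-Z]\d{6}$)")


def default_exclusion_list() -> set[str]:
    text = resources.files("tcellproj.data").joinpath("cycling_genes.txt").read_text()
    return {line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")}


def is_excluded(gene: str, extra: set[str]) -> bool:
    return (
        gene in extra
        or MITO_PATTERN.search(gene) is not None
        or RIBO_PATTERN.search(gene) is not None
        or NONCODING_PATTERN.search(gene) is not None
    )


def standardized_variance(ds: ExpressionDataset) -> np.ndarray:
    """Dispersion statistic: per-gene variance over a loess mean-variance trend."""
    norm = ds.normalized
    if norm is None:
        raise ValueError("normalized layer required")
    mean = np.asarray(norm.mean(axis=1)).ravel()
    sq = norm.copy()
    sq.data **= 2
    var = np.asarray(sq.mean(axis=1)).ravel() - mean**2
    var = np.maximum(var, 0.0)
    expressed = mean > 0
    disp = np.zeros_like(mean)
    if expressed.sum() >= 10:
        lm, lv = np.log10(mean[expressed]), np.log10(var[expressed] + 1e-12)
        trend = lowess(lv, lm, frac=0.3, return_sorted=False)
        disp[expressed] = var[expressed] / np.maximum(10.0**trend, 1e-12)
    else:  # too few genes for a trend; fall back to raw dispersion
        disp[expressed] = var[expressed] / np.maximum(mean[expressed], 1e-12)
    return disp


def select_variable_genes(
    ds: ExpressionDataset,
    n: int = 600,
    exclude: set[str] | None = None,
    min_frac: float = 0.001,
    max_frac: float = 0.90,
) -> list[str]:
    """Top ``n`` variable genes, ordered by decreasing standardized variance."""
    if exclude is None:
        exclude = default_exclusion_list()
    norm = ds.normalized
    if norm is None:
        raise ValueError("normalized layer required")
    det_frac = np.asarray((norm > 0).mean(axis=1)).ravel()
    disp = standardized_variance(ds)
    eligible = np.array([
        (min_frac <= det_frac[i] <= max_frac) and not is_excluded(g, exclude)
        for i, g in enumerate(ds.gene_ids)
    ])
    order = np.argsort(-disp, kind="stable")
    ranked = [ds.gene_ids[i] for i in order if eligible[i]]
    if len(ranked) < n:
        warnings.warn(f"only {len(ranked)} eligible genes (requested {n})")
    return ranked[:n]


def consensus_variable_genes(
    lists: list[list[str]],
    dataset_sizes: list[int] | None = None,
    n: int = 800,
) -> list[str]:
    """Merge per-dataset variable-gene lists into one integration gene set.

    Rank key: (number of lists containing the gene, desc) then (total cell
    count of the supporting datasets, desc) then (best within-list rank, asc)
    then lexicographic.
    """
    if len(lists) < 2:
        raise ValueError("need at least two variable-gene lists")
    if dataset_sizes is None:
        dataset_sizes = [1] * len(lists)
    stats: dict[str, list] = {}
    for li, (genes, size) in enumerate(zip(lists, dataset_sizes)):
        for rank, g in enumerate(genes):
            s = stats.setdefault(g, [0, 0, len(genes)])
            s[0] += 1
            s[1] += size
            s[2] = min(s[2], rank)
    ranked = sorted(stats, key=lambda g: (-stats[g][0], -stats[g][1], stats[g][2], g))
    return ranked[:n]
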