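"""Query/atlas pre-processing: log-normalization, T-cell purity filtering,
human-to-mouse ortholog mapping, and per-cell signature scoring.

Normalization follows the standard library-size formula for UMI counts:
``ln(1 + scale_factor * x / S)`` where ``x`` is the count of one gene in one
cell and ``S`` is that cell's total count. The T-cell filter is a transparent
marker-score classifier: a cell is kept as a T cell when its mean
log-expression over T-cell markers exceeds its mean over lineage-excluding
genes by more than a threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .datatypes import ExpressionDataset

log = logging.getLogger(__name__)

# Default marker panels (mouse symbols).
T_CELL_MARKERS = ["Cd2", "Cd3d", "Cd3e", "Cd3g", "Cd4", "Cd8a", "Cd8b1"]
NON_T_BLACKLIST = ["Spi1", "Fcer1g", "Csf1r", "Cd19"]


def normalize_counts(ds: ExpressionDataset, scale_factor: float = 10_000.0) -> ExpressionDataset:
    """Return a copy with the ``normalized`` layer filled in.

    Cells with zero total counts are dropped (with a logged count). If the
    input already carries a normalized layer, or its counts look already
    log-scaled (non-integer, small dynamic range), it is passed through
    unchanged with a warning.
    """
    if ds.normalized is not None:
        warnings.warn("dataset already normalized; passing through unchanged")
        return ds
    counts = ds.counts
    data = counts.data
    if data.size and (not np.allclose(data, np.round(data))) and data.max() < 50:
        warnings.warn(
            "counts look already log-normalized (non-integer, small range); "
            "passing through unchanged"
        )
        out = ds.copy()
        out.normalized = out.counts.copy()
        return out
    if data.size and data.min() < 0:
        raise ValueError("negative counts")

    totals = ds.cell_totals()
    keep = totals > 0
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("dropping %d cells with zero total counts before normalization", n_drop)
        ds = ds.subset_cells(keep)
        totals = totals[keep]

    norm = ds.counts.tocsc(copy=True).astype(float)
    # column scaling then log1p; operates on nonzeros only so sparsity is kept
    inv = scale_factor / totals
    norm.data *= np.repeat(inv, np.diff(norm.indptr))
    np.log1p(norm.data, out=norm.data)
    out = ds.copy()
    out.normalized = norm.tocsr()
    return out


@dataclass
class TCellFilterReport:
    n_t: int
    n_non_t: int
    n_unknown: int
    scores: pd.Series


def filter_t_cells(
    ds: ExpressionDataset,
    t_markers: list[str] | None = None,
    blacklist: list[str] | None = None,
    enable: bool = True,
    threshold: float = 0.0,
) -> tuple[ExpressionDataset, TCellFilterReport]:
    """Remove cells not enriched in T-cell markers.

    Each cell is scored ``s = mean(normalized over t_markers present) -
    mean(normalized over blacklist present)``. Cells are labeled ``T`` when
    ``s > threshold`` and at least one T marker is detected, ``Non-T`` when the
    blacklist mean exceeds the marker mean, and ``unknown`` otherwise; only
    ``T`` cells are kept. ``enable=False`` returns the input unchanged.
    """
    t_markers = T_CELL_MARKERS if t_markers is None else t_markers
    blacklist = NON_T_BLACKLIST if blacklist is None else blacklist
    if not enable:
        return ds, TCellFilterReport(ds.n_cells, 0, 0, pd.Series(dtype=float))
    if ds.normalized is None:
        raise ValueError("normalized layer required; run normalize_counts first")
    gi = ds.gene_index()
    t_idx = [gi[g] for g in t_markers if g in gi]
    b_idx = [gi[g] for g in blacklist if g in gi]
    if not t_idx:
        raise ValueError(
            "none of the T-cell marker genes found in the gene space "
            "(wrong species or empty panel?)"
        )
    norm = ds.normalized
    t_mat = norm[t_idx].toarray()
    t_mean = t_mat.mean(axis=0)
    t_detected = (t_mat > 0).any(axis=0)
    b_mean = norm[b_idx].toarray().mean(axis=0) if b_idx else np.zeros(ds.n_cells)
    score = t_mean - b_mean
    is_t = (score > threshold) & t_detected
    is_non_t = (~is_t) & (b_mean > t_mean)
    kept = ds.subset_cells(is_t)
    report = TCellFilterReport(
        n_t=int(is_t.sum()),
        n_non_t=int(is_non_t.sum()),
        n_unknown=int((~is_t & ~is_non_t).sum()),
        scores=pd.Series(score, index=ds.cell_ids),
    )
    log.info("T-cell filter: kept %d T, removed %d Non-T, %d unknown",
             report.n_t, report.n_non_t, report.n_unknown)
    return kept, report


def map_orthologs(ds: ExpressionDataset, table: pd.DataFrame) -> ExpressionDataset:
    """Translate a human dataset into mouse gene space via an ortholog table.

    ``table`` has columns (human, mouse). Human genes without an ortholog are
    dropped. One-to-many mappings prefer the pair whose upper-cased mouse
    symbol equals the human symbol; remaining ambiguity is resolved by
    lexicographic order of the mouse symbol (logged). Several human genes
    mapping to one mouse gene have their counts summed.
    """
    if ds.species != "human":
        raise ValueError("map_orthologs expects a human dataset")
    gi = ds.gene_index()
    pairs = table[table["human"].isin(gi)]
    if pairs.empty:
        raise ValueError("no overlap between dataset genes and the ortholog table")

    chosen: dict[str, str] = {}
    n_ambiguous = 0
    for human, grp in pairs.groupby("human", sort=False):
        cands = sorted(set(grp["mouse"]))
        exact = [m for m in cands if m.upper() == human.upper()]
        if exact:
            chosen[human] = exact[0]
        else:
            if len(cands) > 1:
                n_ambiguous += 1
            chosen[human] = cands[0]
    if n_ambiguous:
        log.info("%d ambiguous ortholog mappings resolved lexicographically", n_ambiguous)

    # group human rows by target mouse gene (sum on collision), deterministic order
    mouse_to_rows: dict[str, list[int]] = {}
    for human in sorted(chosen):
        mouse_to_rows.setdefault(chosen[human], []).append(gi[human])
    mouse_genes = sorted(mouse_to_rows)
    rows = []
    for m in mouse_genes:
        idx = mouse_to_rows[m]
        block = ds.counts[idx]
        rows.append(block.sum(axis=0) if len(idx) > 1 else block)
    counts = sparse.vstack([sparse.csr_matrix(r) for r in rows], format="csr")
    return ExpressionDataset(
        gene_ids=mouse_genes,
        cell_ids=ds.cell_ids,
        counts=counts,
        cell_meta=ds.cell_meta,
        species="mouse",
    )


def score_signature(
    ds: ExpressionDataset,
    signature: list[str],
    n_bins: int = 25,
    n_controls: int = 100,
    control: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell signature score with expression-bin-matched control subtraction.

    The score is the mean normalized expression over the signature genes
    present, minus (when ``control=True``) the mean over a random control pool
    drawn from the same expression-level bins (``n_bins`` bins over mean
    expression, ``n_controls`` controls per signature gene, fixed ``seed``).
    """
    if ds.normalized is None:
        raise ValueError("normalized layer required")
    gi = ds.gene_index()
    present = [g for g in signature if g in gi]
    if not present:
        raise ValueError("no signature gene present in the dataset")
    if len(present) < 0.5 * len(signature):
        warnings.warn(
            f"only {len(present)}/{len(signature)} signature genes present"
        )
    norm = ds.normalized
    sig_idx = np.array([gi[g] for g in present])
    sig_score = np.asarray(norm[sig_idx].mean(axis=0)).ravel()
    if not control:
        return sig_score

    gene_means = np.asarray(norm.mean(axis=1)).ravel()
    order = np.argsort(gene_means, kind="stable")
    # equal-occupancy bins over the expression-sorted gene list
    bin_of = np.empty(len(gene_means), dtype=int)
    bin_of[order] = np.minimum(
        (np.arange(len(gene_means)) * n_bins) // max(len(gene_means), 1), n_bins - 1
    )
    rng = np.random.default_rng(seed)
    ctrl_idx: list[np.ndarray] = []
    for g in sig_idx:
        pool = np.flatnonzero(bin_of == bin_of[g])
        ctrl_idx.append(rng.choice(pool, size=n_controls, replace=True))
    ctrl_idx = np.unique(np.concatenate(ctrl_idx))
    ctrl_score = np.asarray(norm[ctrl_idx].mean(axis=0)).ravel()
    return sig_score - ctrl_score
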