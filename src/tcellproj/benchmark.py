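"""Cross-validated projection benchmark.

Each fold removes half of the samples of one dataset (all of them when the
dataset has a single sample), removes those cells from the reference, and
projects them back, comparing projected coordinates with the cells' original
positions in the reference map and transferred labels with their reference
annotation.

Two holdout protocols are provided. The default, ``mode="drop"``, keeps the
atlas's frozen coordinate spaces and removes the held-out cells from the
reference side (anchoring and the neighbor vote see only retained cells), so
projected and original coordinates live in the same frame and the
within-radius fractions measure projection displacement directly.
``mode="rebuild"`` re-runs the whole atlas construction without the held-out
cells and aligns the rebuilt PCA/UMAP spaces to the full atlas by similarity
Procrustes on the shared cells; this additionally measures the stability of
map construction itself, which at small atlas sizes dominates the radius
metrics. In either protocol reduced-reference cells keep their full-atlas
subtype annotation.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .atlas import AtlasBuilder
from .datatypes import ExpressionDataset
from .projection import project

log = logging.getLogger(__name__)

DEFAULT_RADII = {"umap": 1.0, "pca": 5.0}


def projection_distance_metrics(
    projected: np.ndarray,
    original_coords: np.ndarray,
    radii: list[float],
    cell_ids: list[str] | None = None,
    original_ids: list[str] | None = None,
) -> dict[float, float]:
    """Fraction of cells whose displacement is within each radius."""
    projected = np.asarray(projected, dtype=float)
    original = np.asarray(original_coords, dtype=float)
    if cell_ids is not None and original_ids is not None:
        pos = {c: i for i, c in enumerate(original_ids)}
        missing = [c for c in cell_ids if c not in pos]
        if missing:
            raise ValueError(f"unmatched cells: {missing[:5]}"
                             + ("..." if len(missing) > 5 else ""))
        original = original[[pos[c] for c in cell_ids]]
    if projected.shape != original.shape:
        raise ValueError("matched coordinate sets must have equal shapes")
    disp = np.linalg.norm(projected - original, axis=1)
    return {float(r): float((disp <= r).mean()) for r in radii}


def procrustes_transform(source: np.ndarray, target: np.ndarray):
    """Similarity (rotation + scale + translation) mapping source -> target.

    Fit by orthogonal Procrustes on matched rows; returns a callable applying
    the transform to new points in the source frame.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    a, b = src - mu_s, tgt - mu_t
    u, s, vt = np.linalg.svd(a.T @ b)
    rot = u @ vt
    denom = (a**2).sum()
    scale = s.sum() / denom if denom > 0 else 1.0

    def apply(points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - mu_s) @ rot * scale + mu_t

    return apply


def default_holdout_folds(datasets: list[ExpressionDataset], seed: int = 0):
    """One fold per dataset: half its samples (all, if single-sample)."""
    rng = np.random.default_rng(seed)
    folds = []
    for i, ds in enumerate(datasets):
        samples = sorted(ds.cell_meta["sample_id"].unique())
        if len(samples) == 1:
            held = samples
        else:
            n_hold = len(samples) // 2
            held = sorted(rng.choice(samples, size=n_hold, replace=False))
        folds.append({"dataset": i, "held_samples": list(held)})
    return folds


def subset_reference(atlas, keep_idx: np.ndarray):
    """Reduced reference: frozen spaces untouched, reference cells subset."""
    from dataclasses import replace

    keep_idx = np.asarray(keep_idx, dtype=int)
    return replace(
        atlas,
        integrated=atlas.integrated[:, keep_idx],
        pca_embeddings=atlas.pca_embeddings[keep_idx],
        umap_embeddings=atlas.umap_embeddings[keep_idx],
        ica_embeddings=atlas.ica_embeddings[keep_idx],
        labels=atlas.labels.iloc[keep_idx],
        cell_meta=None if atlas.cell_meta is None else atlas.cell_meta.iloc[keep_idx],
        subtype_order=list(atlas.subtype_order),
    )


def crossvalidate_projection(
    datasets: list[ExpressionDataset],
    builder: AtlasBuilder,
    holdout: list[dict] | None = None,
    radii: dict[str, float] | None = None,
    k: int = 20,
    seed: int = 0,
    labels: pd.Series | None = None,
    mode: str = "drop",
) -> pd.DataFrame:
    """Run the half-sample holdout benchmark (see module docstring).

    ``labels`` optionally replaces the full atlas's per-cell annotation (e.g.,
    functional-cluster names derived from marker signatures) before accuracy
    is measured. Returns a per-fold table plus a pooled row (cell-weighted
    means) with columns ``frac_within_r_umap``, ``frac_within_r_pca`` and
    ``accuracy``.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    if mode not in ("drop", "rebuild"):
        raise ValueError("mode must be 'drop' or 'rebuild'")
    radii = radii or DEFAULT_RADII
    holdout = holdout or default_holdout_folds(datasets, seed=seed)

    full_atlas = builder.fit(datasets).atlas_
    if labels is not None:
        full_atlas.labels = labels.loc[full_atlas.labels.index]
        full_atlas.subtype_order = sorted(set(full_atlas.labels))
    full_ids = list(full_atlas.labels.index)
    full_pos = {c: i for i, c in enumerate(full_ids)}

    rows = []
    for fold in holdout:
        d, held = fold["dataset"], set(fold["held_samples"])
        held_mask = datasets[d].cell_meta["sample_id"].isin(held).values
        held_cells = datasets[d].subset_cells(held_mask)
        held_ids = set(held_cells.cell_ids)
        reduced = [ds if i != d else ds.subset_cells(~held_mask)
                   for i, ds in enumerate(datasets)]
        reduced = [ds for ds in reduced if ds.n_cells > 0]
        if len(reduced) < 2:
            warnings.warn(f"fold {d}: fewer than two datasets remain; skipped")
            continue

        if mode == "drop":
            keep = np.array([i for i, c in enumerate(full_ids) if c not in held_ids])
            red_atlas = subset_reference(full_atlas, keep)
            to_full_pca = to_full_umap = lambda x: x
        else:
            fold_builder = dc_replace_builder(builder)
            red_atlas = fold_builder.fit(reduced).atlas_
            red_ids = list(red_atlas.labels.index)
            # reduced-atlas cells keep their full-atlas annotation
            red_atlas.labels = full_atlas.labels.loc[red_ids]
            red_atlas.subtype_order = full_atlas.subtype_order
            shared_idx_full = np.array([full_pos[c] for c in red_ids])
            to_full_pca = procrustes_transform(
                red_atlas.pca_embeddings, full_atlas.pca_embeddings[shared_idx_full])
            to_full_umap = procrustes_transform(
                red_atlas.umap_embeddings, full_atlas.umap_embeddings[shared_idx_full])

        res = project(held_cells, red_atlas, filter=False, k=k, space="pca")
        proj_ids = res.query.cell_ids

        m_umap = projection_distance_metrics(
            to_full_umap(res.umap_coords), full_atlas.umap_embeddings,
            [radii["umap"]], proj_ids, full_ids)[radii["umap"]]
        m_pca = projection_distance_metrics(
            to_full_pca(res.pca_coords), full_atlas.pca_embeddings,
            [radii["pca"]], proj_ids, full_ids)[radii["pca"]]
        truth = full_atlas.labels.loc[proj_ids]
        acc = float((res.predicted_label.loc[proj_ids].values ==
                     truth.values).mean())
        rows.append({
            "fold": d, "n_cells": len(proj_ids),
            "frac_within_r_umap": m_umap, "frac_within_r_pca": m_pca,
            "accuracy": acc,
        })
        log.info("fold %d: umap %.3f, pca %.3f, acc %.3f", d, m_umap, m_pca, acc)

    df = pd.DataFrame(rows)
    w = df["n_cells"] / df["n_cells"].sum()
    pooled = {
        "fold": "pooled", "n_cells": int(df["n_cells"].sum()),
        "frac_within_r_umap": float((df["frac_within_r_umap"] * w).sum()),
        "frac_within_r_pca": float((df["frac_within_r_pca"] * w).sum()),
        "accuracy": float((df["accuracy"] * w).sum()),
    }
    return pd.concat([df, pd.DataFrame([pooled])], ignore_index=True)


def dc_replace_builder(builder: AtlasBuilder) -> AtlasBuilder:
    """Fresh builder with identical parameters (sklearn clone semantics)."""
    return AtlasBuilder(**builder.get_params())
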