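"""Projection of query datasets into a frozen reference atlas.

The reference is never modified: queries are batch-corrected *toward* the
atlas (anchor-based, atlas as the reference side), then passed through the
atlas's stored centering/scaling, PCA rotation, UMAP transform and ICA
rotation. Subtypes are transferred by a majority vote of the k nearest
annotated reference cells (PCA space by default).
"""

from __future__ import annotations

import logging
import warnings
from importlib import resources

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .anchors import _correct_query, _dense_on_genes, find_anchors_dense
from .datatypes import ExpressionDataset, ProjectionResult, ReferenceAtlas
from .io import read_ortholog_table
from .preprocess import filter_t_cells, map_orthologs, normalize_counts

log = logging.getLogger(__name__)

MIN_INTERSECTION_GENES = 100


def align_query(
    query: ExpressionDataset,
    atlas: ReferenceAtlas,
    k_anchor: int = 5,
    anchor_threshold: float = 0.8,
    threshold_mode: str = "absolute",
) -> tuple[np.ndarray, dict]:
    """Batch-correct a normalized query toward the atlas.

    Returns ``(corrected, info)`` where ``corrected`` is a genes x cells
    matrix on the **full** atlas gene space (atlas genes missing from the
    query are zero-filled) and only the query was modified. Falls back to
    direct (uncorrected) values with a warning when no anchor survives
    filtering.
    """
    if query.normalized is None:
        raise ValueError("query must be normalized (run normalize_counts)")
    qgenes = set(query.gene_ids)
    shared = [g for g in atlas.var_genes if g in qgenes]
    if len(shared) < MIN_INTERSECTION_GENES:
        raise ValueError(
            f"only {len(shared)} genes shared between query and atlas "
            f"(< {MIN_INTERSECTION_GENES}); wrong species? consider ortho mode"
        )
    n_missing = len(atlas.var_genes) - len(shared)
    if n_missing > 0.25 * len(atlas.var_genes):
        warnings.warn(
            f"{n_missing}/{len(atlas.var_genes)} atlas genes missing from the "
            "query will be zero-filled; projection may be biased"
        )
    gidx = {g: i for i, g in enumerate(atlas.var_genes)}
    shared_idx = [gidx[g] for g in shared]

    ref_x = atlas.integrated[shared_idx].T          # atlas cells x shared genes
    qry_x = _dense_on_genes(query, shared)          # query cells x shared genes

    anchors = find_anchors_dense(
        ref_x, qry_x, k_anchor=k_anchor, batch_ids=("atlas", "query")
    ).filtered(anchor_threshold, threshold_mode)
    info = {"n_shared_genes": len(shared), "n_zero_filled": n_missing,
            "n_anchors": len(anchors)}
    if len(anchors):
        corrected_shared = _correct_query(ref_x, qry_x, anchors.pairs)
    else:
        warnings.warn(
            "no anchors survived filtering between query and atlas; "
            "falling back to DIRECT projection (no batch correction)"
        )
        info["direct_fallback"] = True
        corrected_shared = qry_x

    corrected = np.zeros((len(atlas.var_genes), query.n_cells))
    corrected[shared_idx] = corrected_shared.T
    if n_missing:
        log.info("zero-filled %d atlas genes absent from the query", n_missing)
    return corrected, info


def embed_query(
    corrected: np.ndarray, atlas: ReferenceAtlas
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply the frozen atlas reductions to a genes x cells corrected matrix."""
    if corrected.shape[0] != len(atlas.var_genes):
        raise ValueError(
            f"corrected matrix has {corrected.shape[0]} genes; atlas expects "
            f"{len(atlas.var_genes)}"
        )
    z = atlas.standardize(corrected)                 # cells x genes
    pca = z @ atlas.pca_rotation
    umap_coords = np.asarray(atlas.umap_model.transform(pca), dtype=float)
    ica = z @ atlas.ica_rotation
    return pca, umap_coords, ica


def classify_cells(
    coords: np.ndarray,
    atlas: ReferenceAtlas,
    k: int = 20,
    space: str = "pca",
    min_conf: float = 0.0,
) -> tuple[pd.Series, pd.Series]:
    """kNN majority-vote label transfer from the annotated reference cells.

    Ties are broken toward the candidate subtype with the smaller mean
    neighbor distance, then by the atlas subtype order. Cells whose modal
    fraction falls below ``min_conf`` are labeled ``"unassigned"``.
    """
    if k > atlas.n_cells:
        raise ValueError(f"k={k} exceeds the reference size {atlas.n_cells}")
    ref = atlas.pca_embeddings if space == "pca" else atlas.umap_embeddings
    if space not in ("pca", "umap"):
        raise ValueError("space must be 'pca' or 'umap'")
    coords = np.asarray(coords, dtype=float)
    labels_ref = np.asarray(atlas.labels.values)
    dist, idx = NearestNeighbors(n_neighbors=k).fit(ref).kneighbors(coords)
    order = {s: r for r, s in enumerate(atlas.subtype_order)}
    out_labels, out_conf = [], []
    for row_idx, row_dist in zip(idx, dist):
        votes: dict[str, list] = {}
        for j, d in zip(row_idx, row_dist):
            votes.setdefault(labels_ref[j], []).append(d)
        best = sorted(
            votes.items(),
            key=lambda kv: (-len(kv[1]), float(np.mean(kv[1])),
                            order.get(kv[0], len(order))),
        )[0]
        conf = len(best[1]) / k
        out_labels.append(best[0] if conf >= min_conf else "unassigned")
        out_conf.append(conf)
    return pd.Series(out_labels), pd.Series(out_conf)


def project(
    query: ExpressionDataset,
    atlas: ReferenceAtlas,
    direct: bool = False,
    ortho: bool = False,
    filter: bool = True,
    k: int = 20,
    space: str = "pca",
    ortholog_table: pd.DataFrame | None = None,
    anchor_threshold: float = 0.8,
    threshold_mode: str = "absolute",
) -> ProjectionResult:
    """Full projection pipeline.

    normalize -> [ortholog map] -> [T-cell filter] -> [align unless direct]
    -> embed -> classify. Every stage records cell counts in the result log.
    """
    runlog: dict = {"n_input_cells": query.n_cells}
    if ortho:
        if query.species != "human":
            raise ValueError("ortho mode requires a human query")
        table = ortholog_table
        if table is None:
            with resources.as_file(
                resources.files("tcellproj.data").joinpath("orthologs_human_mouse.tsv")
            ) as p:
                table = read_ortholog_table(p)
        query = map_orthologs(query, table)
        runlog["n_genes_after_ortho"] = query.n_genes
    if query.normalized is None:
        query = normalize_counts(query)
    if filter:
        query, report = filter_t_cells(query)
        runlog["t_filter"] = {"kept": report.n_t, "non_t": report.n_non_t,
                              "unknown": report.n_unknown}
    runlog["n_cells_projected"] = query.n_cells

    if direct:
        corrected = np.zeros((len(atlas.var_genes), query.n_cells))
        gidx = {g: i for i, g in enumerate(atlas.var_genes)}
        shared = [g for g in atlas.var_genes if g in set(query.gene_ids)]
        corrected[[gidx[g] for g in shared]] = _dense_on_genes(query, shared).T
        runlog["mode"] = "direct"
    else:
        corrected, info = align_query(
            query, atlas, anchor_threshold=anchor_threshold,
            threshold_mode=threshold_mode)
        runlog["mode"] = "aligned"
        runlog.update(info)

    pca, umap_coords, ica = embed_query(corrected, atlas)
    labels, conf = classify_cells(pca if space == "pca" else umap_coords,
                                  atlas, k=k, space=space)
    labels.index = query.cell_ids
    conf.index = query.cell_ids
    # result carries the corrected values in the normalized layer; the counts
    # layer is the original raw counts restricted to the atlas gene space
    raw = query.subset_genes(list(atlas.var_genes), fill_missing=True)
    out_query = ExpressionDataset(
        gene_ids=list(atlas.var_genes),
        cell_ids=query.cell_ids,
        counts=raw.counts,
        normalized=sparse.csr_matrix(corrected),
        cell_meta=query.cell_meta,
        species=atlas.species,
    )
    return ProjectionResult(
        query=out_query,
        pca_coords=pca,
        umap_coords=umap_coords,
        ica_coords=ica,
        predicted_label=labels,
        label_confidence=conf,
        log=runlog,
    )


class AtlasProjector(BaseEstimator):
    """scikit-learn-style interface over :func:`project`.

    ``fit`` binds the (frozen) atlas; ``transform`` returns the PCA
    coordinates of a query; ``predict`` returns transferred subtype labels;
    ``project`` returns the full :class:`ProjectionResult`.
    """

    def __init__(
        self,
        atlas: ReferenceAtlas | None = None,
        direct: bool = False,
        ortho: bool = False,
        filter: bool = True,
        k: int = 20,
        space: str = "pca",
        anchor_threshold: float = 0.8,
        threshold_mode: str = "absolute",
    ):
        self.atlas = atlas
        self.direct = direct
        self.ortho = ortho
        self.filter = filter
        self.k = k
        self.space = space
        self.anchor_threshold = anchor_threshold
        self.threshold_mode = threshold_mode

    def fit(self, X=None, y=None) -> "AtlasProjector":
        if self.atlas is None:
            raise ValueError("an atlas must be supplied")
        self.atlas_ = self.atlas
        return self

    def project(self, query: ExpressionDataset) -> ProjectionResult:
        if not hasattr(self, "atlas_"):
            self.fit()
        return project(
            query, self.atlas_, direct=self.direct, ortho=self.ortho,
            filter=self.filter, k=self.k, space=self.space,
            anchor_threshold=self.anchor_threshold,
            threshold_mode=self.threshold_mode)

    def transform(self, query: ExpressionDataset) -> np.ndarray:
        return self.project(query).pca_coords

    def predict(self, query: ExpressionDataset) -> np.ndarray:
        return np.asarray(self.project(query).predicted_label.values)
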