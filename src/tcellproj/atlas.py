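"""Reference-atlas construction.

``fit_reference`` freezes the coordinate system: genes are centered (and
optionally unit-scaled), a PCA rotation is computed by SVD, a UMAP transform
is fitted on the PCA embeddings (with a deterministic 2-PC initialisation so
that rebuilt atlases share a stable global layout), and 50 independent
components are extracted with whitened fixed-point ICA (deflation). ICA
components are sign-normalized so each component's largest-|loading| gene has
a positive loading. ``cluster_snn`` runs shared-nearest-neighbor Louvain
clustering on a chosen embedding to define the functional clusters that label
transfer uses. ``AtlasBuilder`` is the scikit-learn-style estimator that runs
the whole pipeline (variable genes -> anchors -> integration -> reductions ->
clustering) on a list of datasets.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator
from sklearn.decomposition import FastICA
from sklearn.neighbors import NearestNeighbors

from .anchors import integrate_datasets
from .datatypes import ExpressionDataset, ReferenceAtlas, SignatureSet
from .preprocess import normalize_counts
from .variable_genes import consensus_variable_genes, select_variable_genes

log = logging.getLogger(__name__)


@dataclass
class ClusterConfig:
    """SNN-clustering preset. TIL-style default: resolution 0.6 on the UMAP
    embedding with k=20; an LCMV-style preset would use 0.4 on PCA."""

    resolution: float = 0.6
    k_param: int = 20
    reduction: str = "umap"

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.k_param < 2:
            raise ValueError("k_param must be >= 2")
        if self.reduction not in ("umap", "pca"):
            raise ValueError("reduction must be 'umap' or 'pca'")


TIL_PRESET = ClusterConfig(resolution=0.6, k_param=20, reduction="umap")
LCMV_PRESET = ClusterConfig(resolution=0.4, k_param=20, reduction="pca")


def _fit_pca(z: np.ndarray, n_pc: int):
    """SVD PCA of a centered cells x genes matrix; deterministic sign."""
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    rot = vt[:n_pc].T  # genes x n_pc
    # sign convention: largest-|loading| gene positive per component
    for k in range(rot.shape[1]):
        g = np.argmax(np.abs(rot[:, k]))
        if rot[g, k] < 0:
            rot[:, k] *= -1
    return rot, z @ rot


def fit_reference(
    integrated: np.ndarray,
    var_genes: list[str],
    n_pc: int = 50,
    n_ica: int = 50,
    seed: int = 0,
    scale_genes: bool = True,
    umap_n_neighbors: int = 30,
    umap_min_dist: float = 0.3,
    cell_ids: list[str] | None = None,
    cell_meta: pd.DataFrame | None = None,
    species: str = "mouse",
) -> ReferenceAtlas:
    """Fit the frozen reductions on an integrated genes x cells matrix."""
    import umap  # deferred: numba compilation is expensive at import time

    integrated = np.asarray(integrated, dtype=float)
    n_genes, n_cells = integrated.shape
    if n_pc > min(n_genes, n_cells):
        raise ValueError(f"n_pc={n_pc} exceeds min(genes, cells)={min(n_genes, n_cells)}")
    n_ica = min(n_ica, n_genes, n_cells)

    center = integrated.mean(axis=1)
    if scale_genes:
        scale = integrated.std(axis=1)
        scale[scale == 0] = 1.0
    else:
        scale = np.ones(n_genes)
    z = ((integrated - center[:, None]) / scale[:, None]).T  # cells x genes

    pca_rotation, pca_embeddings = _fit_pca(z, n_pc)

    init = pca_embeddings[:, :2].copy()
    init *= 10.0 / max(np.abs(init).max(), 1e-12)
    model = umap.UMAP(
        n_neighbors=min(umap_n_neighbors, n_cells - 1),
        min_dist=umap_min_dist,
        init=init,
        random_state=seed,
        n_components=2,
    )
    umap_embeddings = model.fit_transform(pca_embeddings)

    ica = FastICA(
        n_components=n_ica, algorithm="deflation", whiten="unit-variance",
        random_state=seed, max_iter=1000, tol=1e-4,
    )
    ica_embeddings = ica.fit_transform(z)
    ica_rotation = ica.components_.T  # valid because z is gene-centered
    for k in range(n_ica):  # sign-normalize: top-|loading| gene positive
        g = np.argmax(np.abs(ica_rotation[:, k]))
        if ica_rotation[g, k] < 0:
            ica_rotation[:, k] *= -1
            ica_embeddings[:, k] *= -1

    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(n_cells)]
    labels = pd.Series(["unannotated"] * n_cells, index=cell_ids, name="label")
    return ReferenceAtlas(
        var_genes=list(var_genes),
        integrated=integrated,
        center=center,
        scale=scale,
        pca_rotation=pca_rotation,
        pca_embeddings=pca_embeddings,
        umap_model=model,
        umap_embeddings=np.asarray(umap_embeddings, dtype=float),
        ica_rotation=ica_rotation,
        ica_embeddings=ica_embeddings,
        labels=labels,
        species=species,
        cell_meta=cell_meta,
    )


def snn_graph(embedding: np.ndarray, k: int, prune: float = 1 / 15) -> sparse.csr_matrix:
    """Shared-nearest-neighbor graph: Jaccard overlap of kNN sets, pruned."""
    n = embedding.shape[0]
    if k >= n:
        raise ValueError(f"k_param={k} must be below the cell count {n}")
    nbr = NearestNeighbors(n_neighbors=k).fit(embedding).kneighbors(
        embedding, return_distance=False)
    sets = [set(row) | {i} for i, row in enumerate(nbr)]
    rows, cols, vals = [], [], []
    # candidate edges: pairs sharing at least one neighbor list membership
    inv: dict[int, list[int]] = {}
    for i, s in enumerate(sets):
        for j in s:
            inv.setdefault(j, []).append(i)
    seen = set()
    for members in inv.values():
        for a in members:
            for b in members:
                if a < b and (a, b) not in seen:
                    seen.add((a, b))
                    inter = len(sets[a] & sets[b])
                    jac = inter / (len(sets[a] | sets[b]))
                    if jac >= prune:
                        rows.append(a)
                        cols.append(b)
                        vals.append(jac)
    m = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
    return (m + m.T).tocsr()


def cluster_snn(
    atlas_or_embedding,
    config: ClusterConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """SNN + Louvain clustering; cluster ids 0..C-1 ordered by decreasing size."""
    config = config or TIL_PRESET
    if isinstance(atlas_or_embedding, ReferenceAtlas):
        emb = (atlas_or_embedding.umap_embeddings if config.reduction == "umap"
               else atlas_or_embedding.pca_embeddings)
    else:
        emb = np.asarray(atlas_or_embedding, dtype=float)
    g = snn_graph(emb, config.k_param)
    coo = sparse.triu(g).tocoo()
    graph = igraph.Graph(
        n=emb.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    igraph.set_random_number_generator(random.Random(seed))
    part = graph.community_multilevel(weights="weight", resolution=config.resolution)
    raw = np.asarray(part.membership)
    # relabel by decreasing cluster size, ties by first occurrence
    sizes = pd.Series(raw).value_counts()
    mapping = {old: new for new, old in enumerate(sizes.index)}
    return np.array([mapping[c] for c in raw])


def annotate_clusters(
    atlas: ReferenceAtlas, signatures: SignatureSet | dict[str, list[str]]
) -> pd.Series:
    """Map unsupervised clusters onto user-supplied marker signatures.

    Each cluster is assigned the signature whose genes have the highest mean
    integrated expression over the cluster's cells — the programmatic form of
    annotating functional clusters from a marker panel. Returns the new
    per-cell label series; assign it to ``atlas.labels`` (and set
    ``atlas.subtype_order``) to adopt it.
    """
    sigs = signatures.signatures if isinstance(signatures, SignatureSet) else signatures
    gi = {g: i for i, g in enumerate(atlas.var_genes)}
    labels = atlas.labels
    mapping: dict[str, str] = {}
    for c in sorted(set(labels)):
        mask = labels.values == c
        scores = {}
        for name, genes in sigs.items():
            idx = [gi[g] for g in genes if g in gi]
            if idx:
                scores[name] = float(atlas.integrated[idx][:, mask].mean())
        if not scores:
            raise ValueError("no signature gene present in the atlas gene space")
        mapping[c] = max(sorted(scores), key=lambda s: scores[s])
    return labels.map(mapping)


def annotate_ica(
    atlas: ReferenceAtlas, signatures: SignatureSet, top: int = 3
) -> pd.DataFrame:
    """Score every (component, signature) pair by |sum of gene loadings|.

    Returns the top scoring signatures per component as a long table
    (component, rank, signature, score). Signatures with no gene in the atlas
    space are skipped with a warning.
    """
    import warnings

    gi = {g: i for i, g in enumerate(atlas.var_genes)}
    rows = []
    for name, genes in signatures.items():
        idx = [gi[g] for g in genes if g in gi]
        if not idx:
            warnings.warn(f"signature {name!r} has no gene in the atlas space; skipped")
            continue
        scores = np.abs(atlas.ica_rotation[idx].sum(axis=0))
        for comp in range(atlas.n_ica):
            rows.append((comp, name, scores[comp]))
    df = pd.DataFrame(rows, columns=["component", "signature", "score"])
    out = []
    for comp, grp in df.groupby("component"):
        best = grp.sort_values(["score", "signature"], ascending=[False, True]).head(top)
        for rank, (_, r) in enumerate(best.iterrows(), start=1):
            out.append((comp, rank, r["signature"], r["score"]))
    return pd.DataFrame(out, columns=["component", "rank", "signature", "score"])


class AtlasBuilder(BaseEstimator):
    """Build a :class:`ReferenceAtlas` from multiple count datasets.

    Follows the scikit-learn estimator protocol: all configuration lives in
    ``__init__`` (see ``get_params``/``set_params``), ``fit`` consumes a list
    of :class:`ExpressionDataset` and exposes the result as fitted attributes
    (``atlas_``, ``var_genes_``, ``labels_``).

    Parameters
    ----------
    n_var_genes : variable genes selected per dataset (600).
    n_consensus : consensus integration genes across datasets (800).
    n_pc, n_ica : number of principal / independent components (50 each).
    anchor_threshold, threshold_mode : anchor score filter (0.8, absolute)
        or quantile when ``threshold_mode='percentile'``.
    cluster_config : SNN/Louvain preset for the functional clusters.
    random_state : seed for UMAP, ICA and clustering.
    """

    def __init__(
        self,
        n_var_genes: int = 600,
        n_consensus: int = 800,
        n_pc: int = 50,
        n_ica: int = 50,
        k_anchor: int = 5,
        anchor_threshold: float = 0.8,
        threshold_mode: str = "absolute",
        scale_genes: bool = True,
        umap_n_neighbors: int = 30,
        umap_min_dist: float = 0.3,
        cluster_config: ClusterConfig | None = None,
        species: str = "mouse",
        random_state: int = 0,
    ):
        self.n_var_genes = n_var_genes
        self.n_consensus = n_consensus
        self.n_pc = n_pc
        self.n_ica = n_ica
        self.k_anchor = k_anchor
        self.anchor_threshold = anchor_threshold
        self.threshold_mode = threshold_mode
        self.scale_genes = scale_genes
        self.umap_n_neighbors = umap_n_neighbors
        self.umap_min_dist = umap_min_dist
        self.cluster_config = cluster_config
        self.species = species
        self.random_state = random_state

    def fit(self, datasets: list[ExpressionDataset], y=None) -> "AtlasBuilder":
        datasets = [
            ds if ds.normalized is not None else normalize_counts(ds)
            for ds in datasets
        ]
        lists = [
            select_variable_genes(ds, n=self.n_var_genes) for ds in datasets
        ]
        sizes = [ds.n_cells for ds in datasets]
        self.var_genes_ = consensus_variable_genes(lists, sizes, n=self.n_consensus)

        integrated, batch_of_cell, cell_ids = integrate_datasets(
            datasets,
            self.var_genes_,
            k_anchor=self.k_anchor,
            score_threshold=self.anchor_threshold,
            threshold_mode=self.threshold_mode,
        )
        meta = pd.concat([ds.cell_meta for ds in datasets]).loc[cell_ids]
        meta["batch"] = batch_of_cell
        atlas = fit_reference(
            integrated,
            self.var_genes_,
            n_pc=min(self.n_pc, len(self.var_genes_), integrated.shape[1]),
            n_ica=self.n_ica,
            seed=self.random_state,
            scale_genes=self.scale_genes,
            umap_n_neighbors=self.umap_n_neighbors,
            umap_min_dist=self.umap_min_dist,
            cell_ids=cell_ids,
            cell_meta=meta,
            species=self.species,
        )
        clusters = cluster_snn(
            atlas, self.cluster_config or TIL_PRESET, seed=self.random_state)
        atlas.labels = pd.Series(
            [f"C{c}" for c in clusters], index=cell_ids, name="label")
        atlas.subtype_order = [f"C{c}" for c in sorted(set(clusters))]
        self.labels_ = atlas.labels
        self.atlas_ = atlas
        return self

    def fit_atlas(self, datasets: list[ExpressionDataset]) -> ReferenceAtlas:
        return self.fit(datasets).atlas_
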