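"""Core in-memory containers.

All expression matrices are stored **gene-major** (genes x cells). Every public
API in the package states its orientation explicitly; the 10x convention of
genes-as-rows is preserved end to end to avoid silent transpositions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd
from scipy import sparse


def _as_spmatrix(m) -> sparse.csr_matrix:
    if sparse.issparse(m):
        return m.tocsr()
    return sparse.csr_matrix(np.asarray(m, dtype=float))


@dataclass
class ExpressionDataset:
    """A gene x cell expression dataset with per-cell metadata.

    Parameters
    ----------
    gene_ids : ordered, duplicate-free gene identifiers (rows).
    cell_ids : ordered, duplicate-free cell barcodes (columns).
    counts : non-negative matrix, shape ``(n_genes, n_cells)``; sparse-friendly.
    normalized : optional matrix of log-normalized values, same shape/order.
    cell_meta : per-cell table indexed by ``cell_ids`` (sample_id, dataset_id,
        condition, clonotype_id are the conventional columns).
    species : ``"mouse"`` or ``"human"``.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sparse.spmatrix
    normalized: sparse.spmatrix | None = None
    cell_meta: pd.DataFrame | None = None
    species: str = "mouse"

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell_ids")
        self.counts = _as_spmatrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.gene_ids)} genes, {len(self.cell_ids)} cells)"
            )
        if self.counts.nnz and self.counts.min() < 0:
            raise ValueError("negative values in counts")
        if self.normalized is not None:
            self.normalized = _as_spmatrix(self.normalized)
            if self.normalized.shape != self.counts.shape:
                raise ValueError("normalized layer shape differs from counts")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            self.cell_meta = self.cell_meta.copy()
            if not set(self.cell_ids) <= set(self.cell_meta.index):
                raise ValueError("cell_meta rows must be keyed by cell_ids")
            self.cell_meta = self.cell_meta.loc[self.cell_ids]
        if self.species not in ("mouse", "human"):
            raise ValueError(f"unknown species {self.species!r}")

    # -- convenience -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def cell_totals(self) -> np.ndarray:
        """Per-cell total counts (the S of the normalization formula)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_cells(self, mask_or_ids) -> "ExpressionDataset":
        if isinstance(mask_or_ids, (list, pd.Index)):
            idx = [self.cell_ids.index(c) for c in mask_or_ids]
        else:
            mask = np.asarray(mask_or_ids)
            idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        idx = np.asarray(idx, dtype=int)
        cells = [self.cell_ids[i] for i in idx]
        return ExpressionDataset(
            gene_ids=self.gene_ids,
            cell_ids=cells,
            counts=self.counts[:, idx],
            normalized=None if self.normalized is None else self.normalized[:, idx],
            cell_meta=self.cell_meta.iloc[idx],
            species=self.species,
        )

    def subset_genes(self, genes: list[str], fill_missing: bool = False) -> "ExpressionDataset":
        """Restrict to ``genes`` (in that order); optionally zero-fill absent ones."""
        gi = self.gene_index()
        if fill_missing:
            rows = []
            n = self.n_cells
            for g in genes:
                if g in gi:
                    rows.append(self.counts[gi[g]])
                else:
                    rows.append(sparse.csr_matrix((1, n)))
            counts = sparse.vstack(rows, format="csr")
            norm = None
            if self.normalized is not None:
                rows = [
                    self.normalized[gi[g]] if g in gi else sparse.csr_matrix((1, n))
                    for g in genes
                ]
                norm = sparse.vstack(rows, format="csr")
        else:
            genes = [g for g in genes if g in gi]
            idx = [gi[g] for g in genes]
            counts = self.counts[idx]
            norm = None if self.normalized is None else self.normalized[idx]
        return ExpressionDataset(
            gene_ids=genes,
            cell_ids=self.cell_ids,
            counts=counts,
            normalized=norm,
            cell_meta=self.cell_meta,
            species=self.species,
        )

    def copy(self) -> "ExpressionDataset":
        return replace(
            self,
            gene_ids=list(self.gene_ids),
            cell_ids=list(self.cell_ids),
            counts=self.counts.copy(),
            normalized=None if self.normalized is None else self.normalized.copy(),
            cell_meta=self.cell_meta.copy(),
        )


@dataclass
class SignatureSet:
    """Named gene lists (e.g., mSigDB hallmark or canonical-pathway sets)."""

    signatures: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.signatures.items():
            if not genes:
                raise ValueError(f"signature {name!r} has an empty gene list")

    def __getitem__(self, name: str) -> list[str]:
        return self.signatures[name]

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures)

    def items(self):
        return self.signatures.items()


@dataclass
class AnchorSet:
    """Scored cross-batch cell pairs used for batch correction.

    ``pairs`` rows are ``(index_in_batch_a, index_in_batch_b, score)`` with the
    score in [0, 1]; filtering retains pairs at or above ``score_threshold``
    (absolute mode) or above the corresponding score quantile (percentile mode).
    """

    pairs: np.ndarray  # (n, 3): a_idx, b_idx, score
    batch_ids: tuple[str, str]
    score_threshold: float = 0.8

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=float).reshape(-1, 3)
        if self.pairs.size and (
            self.pairs[:, 2].min() < -1e-12 or self.pairs[:, 2].max() > 1 + 1e-12
        ):
            raise ValueError("anchor scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def scores(self) -> np.ndarray:
        return self.pairs[:, 2]

    def filtered(self, threshold: float | None = None, mode: str = "absolute") -> "AnchorSet":
        thr = self.score_threshold if threshold is None else threshold
        if mode == "percentile":
            cut = np.quantile(self.scores, thr) if len(self) else 0.0
        elif mode == "absolute":
            cut = thr
        else:
            raise ValueError("mode must be 'absolute' or 'percentile'")
        keep = self.scores >= cut
        return AnchorSet(self.pairs[keep], self.batch_ids, score_threshold=thr)


@dataclass
class ReferenceAtlas:
    """A frozen, integrated reference map of T-cell states.

    The integrated matrix lives on the consensus variable genes; the PCA/ICA
    rotations and the fitted UMAP transform are computed once and never touched
    by projection, so that any number of query datasets can be compared on the
    same coordinate system.
    """

    var_genes: list[str]
    integrated: np.ndarray               # genes x cells
    center: np.ndarray                   # per-gene mean
    scale: np.ndarray                    # per-gene sd (1.0 where degenerate)
    pca_rotation: np.ndarray             # genes x n_pc
    pca_embeddings: np.ndarray           # cells x n_pc
    umap_model: Any                      # fitted umap.UMAP (transform-capable)
    umap_embeddings: np.ndarray          # cells x 2
    ica_rotation: np.ndarray             # genes x n_ica (50 by default)
    ica_embeddings: np.ndarray           # cells x n_ica
    labels: pd.Series                    # per-cell subtype, indexed by cell id
    species: str = "mouse"
    subtype_order: list[str] | None = None
    subtype_palette: dict[str, str] | None = None
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self):
        n_genes = len(self.var_genes)
        n_cells = self.integrated.shape[1]
        if self.integrated.shape[0] != n_genes:
            raise ValueError("integrated matrix must be var_genes x cells")
        for name in ("center", "scale"):
            v = np.asarray(getattr(self, name), dtype=float).ravel()
            if v.shape[0] != n_genes:
                raise ValueError(f"{name} length != number of var_genes")
            setattr(self, name, v)
        if self.pca_rotation.shape[0] != n_genes:
            raise ValueError("pca_rotation rows must match var_genes")
        if self.pca_embeddings.shape != (n_cells, self.pca_rotation.shape[1]):
            raise ValueError("pca_embeddings shape mismatch")
        if self.ica_rotation.shape[0] != n_genes:
            raise ValueError("ica_rotation rows must match var_genes")
        if len(self.labels) != n_cells:
            raise ValueError("labels must cover every reference cell")
        if self.subtype_order is None:
            self.subtype_order = sorted(pd.unique(self.labels))

    @property
    def n_cells(self) -> int:
        return self.integrated.shape[1]

    @property
    def n_pc(self) -> int:
        return self.pca_rotation.shape[1]

    @property
    def n_ica(self) -> int:
        return self.ica_rotation.shape[1]

    def standardize(self, matrix: np.ndarray) -> np.ndarray:
        """Apply the atlas centering/scaling to a genes x cells matrix."""
        z = (np.asarray(matrix, dtype=float) - self.center[:, None]) / self.scale[:, None]
        return z.T  # cells x genes

    def checksum(self) -> str:
        """Digest of all frozen numeric state; projection must never change it."""
        h = hashlib.sha256()
        for arr in (
            self.integrated,
            self.center,
            self.scale,
            self.pca_rotation,
            self.pca_embeddings,
            self.umap_embeddings,
            self.ica_rotation,
            self.ica_embeddings,
        ):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(",".join(self.var_genes).encode())
        h.update(",".join(map(str, self.labels)).encode())
        return h.hexdigest()


@dataclass
class ProjectionResult:
    """A query dataset embedded in the frozen atlas spaces, with predictions."""

    query: ExpressionDataset              # corrected values on the atlas gene space
    pca_coords: np.ndarray                # cells x n_pc
    umap_coords: np.ndarray               # cells x 2
    ica_coords: np.ndarray                # cells x n_ica
    predicted_label: pd.Series | None = None
    label_confidence: pd.Series | None = None
    log: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.query.n_cells
        for name in ("pca_coords", "umap_coords", "ica_coords"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} row count != query cell count")
        if self.label_confidence is not None:
            c = np.asarray(self.label_confidence, dtype=float)
            if c.size and (c.min() < 0 or c.max() > 1):
                raise ValueError("confidence must lie in [0, 1]")
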