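"""Readers and writers: 10x-style MTX triplets, dense CSV/TSV, GMT signature
collections, ortholog tables, and the versioned atlas bundle."""

from __future__ import annotations

import json
import logging
import pickle
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datatypes import ExpressionDataset, ReferenceAtlas, SignatureSet

log = logging.getLogger(__name__)

ATLAS_BUNDLE_VERSION = "tcellproj-atlas-1"


class FormatError(ValueError):
    """A file does not conform to its expected on-disk format."""


def _dedupe(names: list[str]) -> list[str]:
    """Disambiguate duplicate symbols by suffixing .1, .2, ... in file order."""
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}.{seen[n]}")
        else:
            seen[n] = 0
            out.append(n)
    return out


def _read_sidecar(path: Path, kind: str) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing {kind} file: {path}")
    df = pd.read_csv(path, sep="\t", header=None)
    # features.tsv may carry (id, symbol, type); prefer the symbol column
    col = 1 if (kind == "genes" and df.shape[1] > 1) else 0
    return df.iloc[:, col].astype(str).tolist()


def read_counts(path, format: str = "mtx10x", species: str = "mouse") -> ExpressionDataset:
    """Load a genes x cells count matrix.

    ``mtx10x`` expects a directory with ``matrix.mtx``, a gene list
    (``features.tsv`` or ``genes.tsv``) and ``barcodes.tsv``. ``csv``/``tsv``
    expect a dense table whose first column holds gene ids and whose header row
    holds cell ids. Cells with zero total counts are retained but flagged in
    ``cell_meta["zero_count"]``.
    """
    path = Path(path)
    if format == "mtx10x":
        if not path.is_dir():
            raise FormatError(f"mtx10x expects a directory, got {path}")
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise FormatError(f"missing matrix file: {mtx}")
        genes_file = path / "features.tsv"
        if not genes_file.exists():
            genes_file = path / "genes.tsv"
        genes = _dedupe(_read_sidecar(genes_file, "genes"))
        barcodes = _read_sidecar(path / "barcodes.tsv", "barcodes")
        counts = sparse.csr_matrix(spio.mmread(str(mtx)))
        if counts.shape != (len(genes), len(barcodes)):
            raise FormatError(
                f"matrix shape {counts.shape} inconsistent with "
                f"{len(genes)} genes x {len(barcodes)} barcodes"
            )
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
            mat = df.apply(pd.to_numeric, errors="raise")
        except (ValueError, TypeError) as e:
            raise FormatError(f"non-numeric entry in {path}: {e}") from e
        genes = _dedupe([str(g) for g in df.index])
        barcodes = [str(c) for c in df.columns]
        counts = sparse.csr_matrix(mat.to_numpy(dtype=float))
    else:
        raise ValueError(f"unknown format {format!r}")

    ds = ExpressionDataset(gene_ids=genes, cell_ids=_dedupe(barcodes), counts=counts,
                           species=species)
    totals = ds.cell_totals()
    ds.cell_meta["zero_count"] = totals == 0
    n_zero = int((totals == 0).sum())
    if n_zero:
        log.warning("%d cells with zero total counts flagged (kept)", n_zero)
    return ds


def write_counts_mtx(ds: ExpressionDataset, path) -> None:
    """Write a dataset as matrix.mtx + features.tsv + barcodes.tsv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(path / "matrix.mtx"), sparse.coo_matrix(ds.counts))
    (path / "features.tsv").write_text("\n".join(ds.gene_ids) + "\n")
    (path / "barcodes.tsv").write_text("\n".join(ds.cell_ids) + "\n")


def read_gmt(path) -> SignatureSet:
    """Parse a tab-delimited GMT file (name, description, genes...)."""
    sigs: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {ln}: expected >=3 tab-separated fields")
            name = fields[0]
            genes = [g for g in fields[2:] if g.strip()]
            sigs[name] = genes
    return SignatureSet(sigs)


def read_ortholog_table(path) -> pd.DataFrame:
    """Two-column TSV of (human_symbol, mouse_symbol); '#' lines are comments."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["human", "mouse"], dtype=str)
    return df.dropna()


# ---------------------------------------------------------------------------
# Atlas bundle: a directory of .npy arrays, a pickled UMAP model, and a JSON
# manifest carrying the version tag plus a UMAP probe set used to verify the
# transform after reload.
# ---------------------------------------------------------------------------

_ARRAYS = (
    "integrated", "center", "scale", "pca_rotation", "pca_embeddings",
    "umap_embeddings", "ica_rotation", "ica_embeddings",
)


def save_atlas(atlas: ReferenceAtlas, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name in _ARRAYS:
        np.save(path / f"{name}.npy", np.asarray(getattr(atlas, name)))
    with open(path / "umap_model.pkl", "wb") as fh:
        pickle.dump(atlas.umap_model, fh)
    labels = atlas.labels
    pd.DataFrame({"cell_id": labels.index, "label": labels.values}).to_csv(
        path / "labels.tsv", sep="\t", index=False
    )
    if atlas.cell_meta is not None:
        atlas.cell_meta.to_csv(path / "cell_meta.tsv", sep="\t")
    # probe set: a handful of reference PCA rows and their UMAP images
    rng = np.random.default_rng(0)
    n_probe = min(20, atlas.pca_embeddings.shape[0])
    probe_idx = rng.choice(atlas.pca_embeddings.shape[0], size=n_probe, replace=False)
    probe_in = atlas.pca_embeddings[probe_idx]
    probe_out = atlas.umap_model.transform(probe_in)
    manifest = {
        "version": ATLAS_BUNDLE_VERSION,
        "species": atlas.species,
        "var_genes": atlas.var_genes,
        "subtype_order": atlas.subtype_order,
        "subtype_palette": atlas.subtype_palette,
        "umap_probe_in": probe_in.tolist(),
        "umap_probe_out": probe_out.tolist(),
    }
    (path / "manifest.json").write_text(json.dumps(manifest))


def load_atlas(path) -> ReferenceAtlas:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest.get("version") != ATLAS_BUNDLE_VERSION:
        raise FormatError(
            f"incompatible atlas bundle version {manifest.get('version')!r}; "
            f"expected {ATLAS_BUNDLE_VERSION!r}"
        )
    arrays = {name: np.load(path / f"{name}.npy") for name in _ARRAYS}
    with open(path / "umap_model.pkl", "rb") as fh:
        umap_model = pickle.load(fh)
    lab = pd.read_csv(path / "labels.tsv", sep="\t", dtype={"cell_id": str})
    labels = pd.Series(lab["label"].values, index=lab["cell_id"].values, name="label")
    meta_path = path / "cell_meta.tsv"
    cell_meta = pd.read_csv(meta_path, sep="\t", index_col=0) if meta_path.exists() else None
    atlas = ReferenceAtlas(
        var_genes=list(manifest["var_genes"]),
        umap_model=umap_model,
        labels=labels,
        species=manifest["species"],
        subtype_order=manifest.get("subtype_order"),
        subtype_palette=manifest.get("subtype_palette"),
        cell_meta=cell_meta,
        **arrays,
    )
    probe_in = np.asarray(manifest["umap_probe_in"])
    probe_out = np.asarray(manifest["umap_probe_out"])
    if probe_in.size:
        got = umap_model.transform(probe_in)
        err = np.max(np.abs(got - probe_out))
        if err > 1e-6:
            raise FormatError(
                f"reloaded UMAP transform deviates from stored probe outputs "
                f"(max abs err {err:.2e} > 1e-6)"
            )
    return atlas
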