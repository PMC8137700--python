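"""Clonotype-level analyses: Morisita repertoire overlap between subtypes and
clonotype enrichment in chosen subtypes.

Clonotype identifiers are opaque strings (e.g., concatenated CDR3s); the
package consumes pre-called clonotypes and performs no V(D)J parsing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ClonotypeTable:
    """Rows of (cell_id, clonotype_id, subtype_label[, sample_id])."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"cell_id", "clonotype_id", "subtype_label"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if self.table["cell_id"].duplicated().any():
            raise ValueError("duplicate cell_ids in clonotype table")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_projection(cls, clonotypes: pd.DataFrame, labels: pd.Series) -> "ClonotypeTable":
        """Join a (cell_id, clonotype_id[, sample_id]) table with predicted labels."""
        df = clonotypes.copy()
        df["subtype_label"] = df["cell_id"].map(labels)
        return cls(df.dropna(subset=["subtype_label"]))

    def subtype_counts(self, subtype: str) -> dict[str, int]:
        sub = self.table[self.table["subtype_label"] == subtype]
        return dict(Counter(sub["clonotype_id"]))


def morisita_index(counts_a: dict[str, int], counts_b: dict[str, int]) -> float:
    """Morisita-Horn overlap of two clonotype repertoires.

    ``C = 2 sum(x_i y_i) / [(sum(x_i^2)/X^2 + sum(y_i^2)/Y^2) * X * Y]`` with
    X, Y the repertoire totals. 1 for identical relative abundances, 0 for
    disjoint supports; symmetric.
    """
    if not counts_a or not counts_b:
        raise ValueError("empty repertoire")
    xa = np.array(list(counts_a.values()), dtype=float)
    xb = np.array(list(counts_b.values()), dtype=float)
    if (xa < 0).any() or (xb < 0).any():
        raise ValueError("negative clonotype counts")
    x_tot, y_tot = xa.sum(), xb.sum()
    if x_tot <= 0 or y_tot <= 0:
        raise ValueError("repertoire total must be positive")
    shared = set(counts_a) & set(counts_b)
    cross = sum(counts_a[c] * counts_b[c] for c in shared)
    denom = ((xa**2).sum() / x_tot**2 + (xb**2).sum() / y_tot**2) * x_tot * y_tot
    return float(2.0 * cross / denom)


def subtype_overlap_matrix(
    table: ClonotypeTable,
    downsample: int = 500,
    seed: int = 0,
    min_cells: int = 10,
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Morisita overlap between subtypes' clonotype repertoires.

    Each subtype is uniformly down-sampled to at most ``downsample`` cells
    (fixed seed) before counting clonotypes; subtypes with fewer than
    ``min_cells`` cells are excluded and reported. Diagonal is 1.
    """
    df = table.table
    rng = np.random.default_rng(seed)
    subtypes = sorted(df["subtype_label"].unique())
    kept, excluded, counts = [], [], {}
    for s in subtypes:
        # sort by cell id so the draw is invariant to input row order
        sub = df[df["subtype_label"] == s].sort_values("cell_id")
        if len(sub) < min_cells:
            excluded.append(s)
            continue
        if len(sub) > downsample:
            idx = rng.choice(len(sub), size=downsample, replace=False)
            sub = sub.iloc[np.sort(idx)]
        kept.append(s)
        counts[s] = dict(Counter(sub["clonotype_id"]))
    if len(kept) < 2:
        raise ValueError("need at least two subtypes with enough cells")
    mat = pd.DataFrame(np.eye(len(kept)), index=kept, columns=kept)
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            v = morisita_index(counts[a], counts[b])
            mat.loc[a, b] = mat.loc[b, a] = v
    return mat, excluded


def enriched_clonotypes(
    table: ClonotypeTable,
    target_subtypes: set[str] | None = None,
    min_frac: float = 0.5,
    min_cells: int = 2,
) -> pd.DataFrame:
    """Clonotypes with at least ``min_frac`` of their cells in the target
    subtypes (default Tex/Tpex: the tumor-reactive compartments), considering
    only clonotypes of size >= ``min_cells``; sorted by clone size descending.
    """
    df = table.table
    if target_subtypes is None:
        target_subtypes = {"Tex", "Tpex"}
    known = set(df["subtype_label"].unique()) | {"unassigned"}
    unknown = set(target_subtypes) - known
    if unknown and unknown == set(target_subtypes):
        # every requested subtype absent from the table: almost surely a typo
        raise ValueError(f"unknown target subtypes: {sorted(unknown)}")
    rows = []
    for clone, grp in df.groupby("clonotype_id"):
        size = len(grp)
        if size < min_cells:
            continue
        in_target = int(grp["subtype_label"].isin(target_subtypes).sum())
        frac = in_target / size
        if frac >= min_frac:
            per_subtype = grp["subtype_label"].value_counts().to_dict()
            rows.append((clone, size, in_target, frac, per_subtype))
    out = pd.DataFrame(
        rows, columns=["clonotype_id", "size", "n_in_target", "frac_in_target",
                       "per_subtype_counts"])
    return out.sort_values(["size", "clonotype_id"],
                           ascending=[False, True]).reset_index(drop=True)
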