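"""Downstream comparison machinery.

Composition tables and fold changes between conditions; discriminant ICA
dimensions (two-sample KS or Welch t per component, Bonferroni-corrected by
the number of components); discriminant genes (per-gene Wilcoxon rank-sum
with Benjamini-Hochberg adjustment); a cross-study marker-consensus
meta-analysis with a row-scaled, Ward-clustered profile matrix; and per-gene
max-rescaled marker profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionDataset, ProjectionResult, ReferenceAtlas


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def subtype_composition(
    labels_by_condition: dict[str, pd.Series | list],
    subtypes: list[str] | None = None,
) -> pd.DataFrame:
    """Counts and fractions of each subtype per condition.

    Zero-count subtypes are reported explicitly; fractions sum to 1 within
    each condition.
    """
    if subtypes is None:
        subtypes = sorted({s for lab in labels_by_condition.values() for s in lab})
    rows = []
    for cond, labels in labels_by_condition.items():
        labels = pd.Series(list(labels))
        if labels.empty:
            raise ValueError(f"condition {cond!r} has no cells")
        counts = labels.value_counts()
        total = len(labels)
        for s in subtypes:
            c = int(counts.get(s, 0))
            rows.append((s, cond, c, c / total))
    return pd.DataFrame(rows, columns=["subtype", "condition", "count", "fraction"])


def composition_fold_change(
    case: pd.Series | list,
    control: pd.Series | list,
    min_cells: int = 50,
) -> pd.DataFrame:
    """Per-subtype fraction fold change (case / control).

    Subtypes with fewer than ``min_cells`` cells in both conditions combined
    are omitted with a reason; a zero control fraction with nonzero case
    fraction is flagged as ``+inf`` rather than failing.
    """
    comp = subtype_composition({"case": case, "control": control})
    wide_n = comp.pivot(index="subtype", columns="condition", values="count")
    wide_f = comp.pivot(index="subtype", columns="condition", values="fraction")
    rows = []
    for s in wide_n.index:
        total = int(wide_n.loc[s].sum())
        fc_case, fc_ctrl = wide_f.loc[s, "case"], wide_f.loc[s, "control"]
        if total < min_cells:
            rows.append((s, total, np.nan, f"omitted: {total} < {min_cells} cells"))
        elif fc_ctrl == 0:
            rows.append((s, total, np.inf if fc_case > 0 else np.nan,
                         "control fraction is zero"))
        else:
            rows.append((s, total, fc_case / fc_ctrl, ""))
    return pd.DataFrame(rows, columns=["subtype", "n_cells", "fold_change", "note"])


# ---------------------------------------------------------------------------
# discriminant ICA dimensions
# ---------------------------------------------------------------------------

def _ica_coords(obj, subset: str | None) -> np.ndarray:
    if isinstance(obj, ProjectionResult):
        coords = obj.ica_coords
        if subset is not None:
            if obj.predicted_label is None:
                raise ValueError("subset requested but no predicted labels")
            mask = np.asarray(obj.predicted_label.values) == subset
            coords = coords[mask]
        return coords
    if isinstance(obj, ReferenceAtlas):
        coords = obj.ica_embeddings
        if subset is not None:
            coords = coords[np.asarray(obj.labels.values) == subset]
        return coords
    return np.asarray(obj, dtype=float)


def find_discriminant_dimensions(
    query,
    baseline,
    test: str = "ks",
    subset: str | None = None,
    n_tests: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank ICA dimensions by how strongly the query deviates from baseline.

    ``query``/``baseline`` may be :class:`ProjectionResult`,
    :class:`ReferenceAtlas` or plain (cells x dims) arrays. Per dimension a
    two-sample KS (or Welch t) test is run; p values are multiplied by the
    number of dimensions (Bonferroni; 50 for the default atlas, and kept at
    the full dimension count even when a subtype subset is analysed). The
    table is sorted by the test statistic, descending.
    """
    q = _ica_coords(query, subset)
    b = _ica_coords(baseline, subset)
    if q.shape[0] < 10:
        raise ValueError(f"query side has only {q.shape[0]} cells (< 10)")
    if b.shape[0] < 10:
        raise ValueError(f"baseline side has only {b.shape[0]} cells (< 10)")
    if q.shape[1] != b.shape[1]:
        raise ValueError("query and baseline dimension counts differ")
    ndim = q.shape[1]
    factor = ndim if n_tests is None else n_tests
    rows = []
    for d in range(ndim):
        if test == "ks":
            res = stats.ks_2samp(q[:, d], b[:, d])
        elif test == "t":
            res = stats.ttest_ind(q[:, d], b[:, d], equal_var=False)
        else:
            raise ValueError("test must be 'ks' or 't'")
        stat = abs(float(res.statistic))
        p = float(res.pvalue)
        rows.append((d, stat, p, min(1.0, factor * p)))
    df = pd.DataFrame(rows, columns=["dimension", "statistic", "p", "p_corrected"])
    df["significant"] = df["p_corrected"] < alpha
    return df.sort_values("statistic", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# discriminant genes
# ---------------------------------------------------------------------------

def find_discriminant_genes(
    cond_a: ExpressionDataset,
    cond_b: ExpressionDataset,
    subtype: str | None = None,
    labels_a: pd.Series | None = None,
    labels_b: pd.Series | None = None,
    min_cells: int = 25,
    min_logfc: float = 0.25,
    min_detect_frac: float = 0.10,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression between two conditions.

    Both sides are first restricted to cells predicted as ``subtype`` (when
    labels are provided). The log fold change is the natural-log ratio of mean
    ``expm1``-backtransformed expression with pseudocount 1; positive logFC
    means higher in ``cond_a``. Genes are filtered to |logFC| > ``min_logfc``
    and detection in at least ``min_detect_frac`` of either side, then BH
    adjusted and sorted by adjusted p.
    """
    def _matrix(ds, labels):
        if ds.normalized is None:
            raise ValueError("normalized layer required for DE")
        if subtype is not None and labels is not None:
            ds = ds.subset_cells(np.asarray(labels.loc[ds.cell_ids].values) == subtype)
        return ds

    a = _matrix(cond_a, labels_a)
    b = _matrix(cond_b, labels_b)
    if a.n_cells < min_cells or b.n_cells < min_cells:
        raise ValueError(
            f"need >= {min_cells} cells per side (got {a.n_cells} vs {b.n_cells})"
        )
    genes = [g for g in a.gene_ids if g in set(b.gene_ids)]
    xa = a.subset_genes(genes).normalized.toarray()
    xb = b.subset_genes(genes).normalized.toarray()

    mean_a = np.expm1(xa).mean(axis=1)
    mean_b = np.expm1(xb).mean(axis=1)
    logfc = np.log(mean_a + 1) - np.log(mean_b + 1)
    det_a = (xa > 0).mean(axis=1)
    det_b = (xb > 0).mean(axis=1)
    keep = (np.abs(logfc) > min_logfc) & ((det_a >= min_detect_frac) |
                                          (det_b >= min_detect_frac))
    idx = np.flatnonzero(keep)
    pvals = np.ones(len(idx))
    for k, gi in enumerate(idx):
        ra, rb = xa[gi], xb[gi]
        if np.all(ra == ra[0]) and np.all(rb == rb[0]) and ra[0] == rb[0]:
            continue
        pvals[k] = stats.mannwhitneyu(ra, rb, alternative="two-sided").pvalue
    padj = multipletests(pvals, method="fdr_bh")[1] if len(idx) else np.array([])
    df = pd.DataFrame({
        "gene": [genes[i] for i in idx],
        "logFC": logfc[idx],
        "p": pvals,
        "p_adj": padj,
        "detect_frac_a": det_a[idx],
        "detect_frac_b": det_b[idx],
    })
    return df.sort_values(["p_adj", "p"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# cross-study marker consensus
# ---------------------------------------------------------------------------

def marker_consensus(
    de_tables: list[dict],
    atlas_var_genes: list[str],
    integrated_means: pd.DataFrame | None = None,
    min_studies: int = 4,
    max_per_subtype: int = 25,
    min_cells: int = 50,
    alpha: float = 0.05,
    n_col_clusters: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.Series | None]:
    """Cross-study conserved marker panel and clustered profile matrix.

    ``de_tables`` entries are dicts with keys ``study``, ``subtype``,
    ``n_cells`` and ``table`` (a DE table with ``gene``/``p_adj``/``logFC``).
    Only combinations with at least ``min_cells`` cells enter. A gene joins
    the panel when upregulated (padj < alpha, logFC > 0) in at least
    ``min_studies`` studies for some subtype; it is attributed to the subtype
    with the most supporting studies, capped at ``max_per_subtype`` genes per
    subtype (by study support, then mean adjusted p), and intersected with the
    atlas variable genes. ``integrated_means`` (genes x "study|subtype"
    columns) yields the row-z-scored, Ward-clustered profile matrix; the
    column cluster assignment at the ``n_col_clusters`` cut is returned for
    conservation assessment.
    """
    entries = sorted(
        (e for e in de_tables if e.get("n_cells", min_cells) >= min_cells),
        key=lambda e: (str(e["study"]), str(e["subtype"])),
    )
    support: dict[tuple[str, str], set] = {}
    pvals: dict[tuple[str, str], list] = {}
    for e in entries:
        t = e["table"]
        up = t[(t["p_adj"] < alpha) & (t["logFC"] > 0)]
        for _, r in up.iterrows():
            key = (r["gene"], str(e["subtype"]))
            support.setdefault(key, set()).add(str(e["study"]))
            pvals.setdefault(key, []).append(float(r["p_adj"]))

    # attribute each gene to the subtype with maximal study support
    best: dict[str, tuple[str, int, float]] = {}
    for (gene, subtype), studies in support.items():
        n, mp = len(studies), float(np.mean(pvals[(gene, subtype)]))
        cur = best.get(gene)
        if cur is None or (n, -mp) > (cur[1], -cur[2]):
            best[gene] = (subtype, n, mp)
    var_set = set(atlas_var_genes)
    candidates = [
        (g, s, n, mp) for g, (s, n, mp) in best.items()
        if n >= min_studies and g in var_set
    ]
    panel_rows = []
    for subtype in sorted({s for _, s, _, _ in candidates}):
        subs = [c for c in candidates if c[1] == subtype]
        subs.sort(key=lambda c: (-c[2], c[3], c[0]))
        panel_rows.extend(subs[:max_per_subtype])
    if not panel_rows:
        raise ValueError(
            f"empty marker panel (thresholds: min_studies={min_studies}, "
            f"min_cells={min_cells}, alpha={alpha}; {len(entries)} eligible "
            f"study-subtype tables, {len(best)} supported genes)"
        )
    panel = pd.DataFrame(panel_rows,
                         columns=["gene", "subtype", "n_studies", "mean_p_adj"])
    panel = panel.sort_values(["subtype", "n_studies", "gene"],
                              ascending=[True, False, True]).reset_index(drop=True)

    if integrated_means is None:
        return panel, None, None
    genes = [g for g in panel["gene"] if g in integrated_means.index]
    prof = integrated_means.loc[genes].astype(float)
    z = prof.sub(prof.mean(axis=1), axis=0)
    sd = prof.std(axis=1).replace(0, 1.0)
    z = z.div(sd, axis=0)
    row_link = linkage(pdist(z.values), method="ward")
    col_link = linkage(pdist(z.values.T), method="ward")
    row_order = pd.Index(z.index)[_leaf_order(row_link)]
    col_order = pd.Index(z.columns)[_leaf_order(col_link)]
    profile = z.loc[row_order, col_order]
    if n_col_clusters is None:
        n_col_clusters = panel["subtype"].nunique()
    col_clusters = pd.Series(
        fcluster(col_link, t=n_col_clusters, criterion="maxclust"),
        index=z.columns,
    ).loc[col_order]
    return panel, profile, col_clusters


def _leaf_order(link) -> list[int]:
    from scipy.cluster.hierarchy import leaves_list

    return list(leaves_list(link))


def plot_marker_heatmap(profile: pd.DataFrame, path, col_clusters: pd.Series | None = None):
    """Write a marker-consensus profile matrix as a heatmap (PNG/SVG by
    extension) with the underlying matrix saved alongside as TSV."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * profile.shape[1]), max(4, 0.12 * profile.shape[0])))
    im = ax.imshow(profile.values, aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(profile.shape[1]))
    ax.set_xticklabels(profile.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(profile.shape[0]))
    ax.set_yticklabels(profile.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="row z-score")
    if col_clusters is not None:
        for x, c in enumerate(col_clusters.loc[profile.columns]):
            ax.text(x, -1.0, str(c), ha="center", fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    profile.to_csv(str(path).rsplit(".", 1)[0] + ".tsv", sep="\t")


def normalized_marker_profile(
    avg_expression: pd.DataFrame, subtypes: list[str] | None = None
) -> pd.DataFrame:
    """Rescale each gene row by its maximum over the selected subtypes.

    All-zero rows stay zero (no NaN).
    """
    df = avg_expression if subtypes is None else avg_expression[subtypes]
    df = df.astype(float)
    if (df.values < 0).any():
        raise ValueError("average expression must be non-negative")
    mx = df.max(axis=1)
    mx[mx == 0] = 1.0
    return df.div(mx, axis=0)
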