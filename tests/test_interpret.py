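import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tcellproj.interpret import (
    composition_fold_change,
    find_discriminant_dimensions,
    find_discriminant_genes,
    marker_consensus,
    normalized_marker_profile,
    subtype_composition,
)
from tcellproj.preprocess import normalize_counts

from conftest import make_dataset


class TestComposition:
    def test_fractions(self):
        t = subtype_composition({"ctrl": ["Tex"] * 90 + ["Tpex"] * 10})
        f = t.set_index("subtype")["fraction"]
        assert f["Tex"] == 0.9 and f["Tpex"] == 0.1

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(list("ABCD"), 500)
        t = subtype_composition({"x": labels})
        assert abs(t["fraction"].sum() - 1.0) < 1e-12

    def test_absent_subtype_reported_as_zero(self):
        t = subtype_composition({"x": ["Tex"] * 5}, subtypes=["Tex", "Treg"])
        assert t[t.subtype == "Treg"]["count"].iloc[0] == 0

    def test_empty_condition_raises(self):
        with pytest.raises(ValueError, match="no cells"):
            subtype_composition({"x": []})


class TestFoldChange:
    def test_simple_ratio(self):
        case = ["A"] * 50 + ["B"] * 50
        ctrl = ["A"] * 20 + ["B"] * 80
        fc = composition_fold_change(case, ctrl).set_index("subtype")
        assert np.isclose(fc.loc["A", "fold_change"], 2.5)

    def test_small_subtype_omitted(self):
        case = ["A"] * 100 + ["B"] * 15
        ctrl = ["A"] * 100 + ["B"] * 15
        fc = composition_fold_change(case, ctrl).set_index("subtype")
        assert np.isnan(fc.loc["B", "fold_change"])
        assert "omitted" in fc.loc["B", "note"]

    def test_identical_conditions_give_unity(self):
        labels = ["A"] * 60 + ["B"] * 40
        fc = composition_fold_change(labels, list(labels)).set_index("subtype")
        assert np.allclose(fc["fold_change"], 1.0)

    def test_zero_control_flagged_inf(self):
        case = ["A"] * 30 + ["B"] * 70
        ctrl = ["B"] * 100
        fc = composition_fold_change(case, ctrl, min_cells=20).set_index("subtype")
        assert np.isinf(fc.loc["A", "fold_change"])


class TestDiscriminantDimensions:
    def test_identical_sides_give_zero_statistic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 50))
        t = find_discriminant_dimensions(x, x)
        assert (t["statistic"] == 0).all()
        assert (t["p_corrected"] == 1.0).all()

    def test_null_split_rarely_flags(self):
        """Random halves of the same pool: zero flagged dimensions in >=95%
        of 100 seeded repetitions (x50 Bonferroni at alpha 0.05)."""
        rng = np.random.default_rng(1)
        clean = 0
        for _ in range(100):
            pool = rng.normal(size=(1000, 50))
            idx = rng.permutation(1000)
            t = find_discriminant_dimensions(pool[idx[:500]], pool[idx[500:]])
            clean += int(t["significant"].sum() == 0)
        assert clean >= 95

    def test_shifted_dimension_ranks_first_with_closed_form_D(self):
        """One dimension shifted by 3 sd: KS D equals 2*Phi(1.5)-1 = 0.8664
        within +-0.05 and that dimension tops the ranking."""
        from scipy.stats import norm

        rng = np.random.default_rng(2)
        q = rng.normal(size=(500, 50))
        b = rng.normal(size=(500, 50))
        q[:, 13] += 3.0
        t = find_discriminant_dimensions(q, b)
        assert int(t.iloc[0]["dimension"]) == 13
        expect = 2 * norm.cdf(1.5) - 1
        assert abs(t.iloc[0]["statistic"] - expect) <= 0.05

    def test_statistic_symmetric_in_sides(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(100, 10))
        b = rng.normal(1.0, 1, size=(120, 10))
        ta = find_discriminant_dimensions(a, b).set_index("dimension")
        tb = find_discriminant_dimensions(b, a).set_index("dimension")
        assert np.allclose(ta["statistic"], tb.loc[ta.index, "statistic"])

    def test_bonferroni_caps_at_one_and_is_monotone(self):
        rng = np.random.default_rng(4)
        t = find_discriminant_dimensions(
            rng.normal(size=(50, 20)), rng.normal(size=(50, 20)))
        assert (t["p_corrected"] <= 1.0).all()
        s = t.sort_values("p")
        assert (np.diff(s["p_corrected"].values) >= -1e-12).all()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(factor=st.integers(1, 200), p=st.floats(1e-12, 1.0))
    def test_correction_formula_bounds(self, factor, p):
        assert min(1.0, factor * p) <= 1.0
        assert min(1.0, factor * p) >= p or factor < 1

    def test_small_side_raises(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="query"):
            find_discriminant_dimensions(
                rng.normal(size=(5, 50)), rng.normal(size=(100, 50)))

    def test_welch_t_variant(self):
        rng = np.random.default_rng(6)
        q = rng.normal(size=(200, 10))
        q[:, 2] += 2.0
        t = find_discriminant_dimensions(q, rng.normal(size=(200, 10)), test="t")
        assert int(t.iloc[0]["dimension"]) == 2


class TestDiscriminantGenes:
    def _pair(self, shift_gene=None, n=200, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.poisson(3.0, size=(50, n)).astype(float)
        b = rng.poisson(3.0, size=(50, n)).astype(float)
        if shift_gene is not None:
            a[shift_gene] = rng.poisson(3.0 * np.e**2, size=n)
        return (normalize_counts(make_dataset(a)),
                normalize_counts(make_dataset(b)))

    def test_spiked_gene_ranks_first(self):
        a, b = self._pair(shift_gene=7)
        t = find_discriminant_genes(a, b)
        assert t.iloc[0]["gene"] == "g7"
        assert t.iloc[0]["p_adj"] < 1e-6
        assert t.iloc[0]["logFC"] > 0  # higher in cond_a by convention

    def test_identical_groups_yield_no_hits(self):
        hits = 0
        for seed in range(10):
            a, b = self._pair(seed=seed)
            t = find_discriminant_genes(a, b)
            hits += int((t["p_adj"] < 0.05).any())
        assert hits <= 1  # no gene passes BH 0.05 in >=9/10 null resamplings

    def test_too_few_cells_raises(self):
        a, b = self._pair(n=10)
        with pytest.raises(ValueError, match="cells"):
            find_discriminant_genes(a, b)

    def test_subtype_restriction(self, atlas):
        rng = np.random.default_rng(1)
        a = normalize_counts(make_dataset(rng.poisson(3.0, size=(20, 100))))
        labels = pd.Series(["S0"] * 50 + ["S1"] * 50, index=a.cell_ids)
        t = find_discriminant_genes(a, a, subtype="S0",
                                    labels_a=labels, labels_b=labels)
        assert (t["logFC"] == 0).all() if len(t) else True


class TestMarkerConsensus:
    @staticmethod
    def _table(genes, p=1e-4):
        return pd.DataFrame({"gene": genes, "p_adj": p, "logFC": 1.0})

    def test_attribution_to_max_support_subtype(self):
        entries = []
        for s in range(5):
            entries.append({"study": f"st{s}", "subtype": "Treg",
                            "n_cells": 100, "table": self._table(["Foxp3"])})
        for s in range(3):
            entries.append({"study": f"st{s}", "subtype": "Tex",
                            "n_cells": 100, "table": self._table(["Foxp3"])})
        panel, _, _ = marker_consensus(entries, ["Foxp3"])
        assert panel.set_index("gene").loc["Foxp3", "subtype"] == "Treg"

    def test_three_study_gene_excluded(self):
        entries = [
            {"study": f"st{s}", "subtype": "Tex", "n_cells": 100,
             "table": self._table(["Pdcd1", "Weak"] if s < 3 else ["Pdcd1"])}
            for s in range(4)
        ]
        panel, _, _ = marker_consensus(entries, ["Pdcd1", "Weak"])
        assert "Weak" not in set(panel["gene"])

    def test_low_cell_combinations_ignored(self):
        entries = [
            {"study": f"st{s}", "subtype": "Tex", "n_cells": 10,
             "table": self._table(["Pdcd1"])}
            for s in range(6)
        ]
        with pytest.raises(ValueError, match="empty marker panel"):
            marker_consensus(entries, ["Pdcd1"])

    def test_order_invariance(self):
        entries = [
            {"study": f"st{s}", "subtype": t, "n_cells": 100,
             "table": self._table([f"gene{t}{i}" for i in range(4)])}
            for s in range(5) for t in ("A", "B")
        ]
        p1, _, _ = marker_consensus(entries, [f"gene{t}{i}" for t in "AB"
                                              for i in range(4)])
        p2, _, _ = marker_consensus(entries[::-1], [f"gene{t}{i}" for t in "AB"
                                                    for i in range(4)])
        assert p1.equals(p2)

    def test_planted_structure_clusters_by_subtype(self):
        """Six studies x three subtypes with subtype-specific markers: the
        profile columns cluster perfectly by subtype (ARI = 1 at C=3)."""
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        subtypes = ["Tex", "Treg", "EM"]
        genes = {t: [f"{t}_g{i}" for i in range(6)] for t in subtypes}
        all_genes = [g for t in subtypes for g in genes[t]]
        entries = [
            {"study": f"st{s}", "subtype": t, "n_cells": 100,
             "table": self._table(genes[t])}
            for s in range(6) for t in subtypes
        ]
        cols, col_subtype = [], []
        means = {}
        for s in range(6):
            for t in subtypes:
                col = f"st{s}|{t}"
                cols.append(col)
                col_subtype.append(t)
                means[col] = [
                    3.0 + rng.normal(0, 0.1) if g in genes[t]
                    else 0.5 + rng.normal(0, 0.1)
                    for g in all_genes
                ]
        mat = pd.DataFrame(means, index=all_genes)
        panel, profile, col_clusters = marker_consensus(
            entries, all_genes, integrated_means=mat, n_col_clusters=3)
        truth = [col_subtype[cols.index(c)] for c in col_clusters.index]
        assert adjusted_rand_score(truth, col_clusters.values) == 1.0
        # rows are z-scored
        assert np.allclose(profile.mean(axis=1), 0.0, atol=1e-9)


class TestNormalizedMarkerProfile:
    def test_row_rescaling(self):
        df = pd.DataFrame([[2, 4, 1, 0]], index=["g"], columns=list("ABCD"))
        out = normalized_marker_profile(df)
        assert list(out.loc["g"]) == [0.5, 1.0, 0.25, 0.0]

    def test_nonzero_rows_peak_at_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.random((20, 4)) + 0.01)
        out = normalized_marker_profile(df)
        assert np.allclose(out.max(axis=1), 1.0)

    def test_all_zero_row_stays_zero(self):
        df = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]])
        out = normalized_marker_profile(df)
        assert (out.iloc[0] == 0).all()
        assert not out.isna().any().any()
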