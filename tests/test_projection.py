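import numpy as np
import pandas as pd
import pytest

from tcellproj.projection import (
    AtlasProjector,
    align_query,
    classify_cells,
    embed_query,
    project,
)

from conftest import make_dataset


class TestEmbedQuery:
    def test_reference_profile_maps_to_stored_coords(self, atlas):
        sub = atlas.integrated[:, :25]
        pca, umap_c, ica = embed_query(sub, atlas)
        assert np.allclose(pca, atlas.pca_embeddings[:25], atol=1e-6)
        assert np.allclose(ica, atlas.ica_embeddings[:25], atol=1e-6)

    def test_zero_profile_is_finite(self, atlas):
        pca, umap_c, ica = embed_query(np.zeros((len(atlas.var_genes), 3)), atlas)
        expect = (-atlas.center / atlas.scale) @ atlas.pca_rotation
        assert np.allclose(pca, expect[None, :], atol=1e-8)
        assert np.isfinite(umap_c).all() and np.isfinite(ica).all()

    def test_deterministic(self, atlas):
        q = atlas.integrated[:, 40:60] + 0.05
        a = embed_query(q, atlas)
        b = embed_query(q, atlas)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_gene_space_mismatch_raises(self, atlas):
        with pytest.raises(ValueError, match="genes"):
            embed_query(np.zeros((7, 3)), atlas)


class TestClassifyCells:
    def test_coincident_cell_k1(self, atlas):
        labels, conf = classify_cells(atlas.pca_embeddings[:5], atlas, k=1)
        assert list(labels) == list(atlas.labels.iloc[:5])
        assert (conf == 1.0).all()

    def test_majority_vote_fraction(self):
        """Three neighbors voting (Tex, Tex, Tpex) give Tex at 2/3."""
        import dataclasses

        from conftest import make_dataset  # noqa: F401

        # minimal synthetic reference: 3 cells at distinct positions
        ref = np.array([[0.0, 0], [0.1, 0], [4.0, 0]])
        labels = pd.Series(["Tex", "Tex", "Tpex"], index=["a", "b", "c"])

        class Tiny:
            pca_embeddings = ref
            umap_embeddings = ref
            subtype_order = ["Tex", "Tpex"]
            n_cells = 3
        tiny = Tiny()
        tiny.labels = labels
        got, conf = classify_cells(np.array([[0.05, 0]]), tiny, k=3)
        assert got.iloc[0] == "Tex"
        assert np.isclose(conf.iloc[0], 2 / 3)

    def test_k_exceeding_reference_raises(self, atlas):
        with pytest.raises(ValueError, match="reference"):
            classify_cells(atlas.pca_embeddings[:2], atlas, k=atlas.n_cells + 1)

    def test_generative_query_recovers_subtype(self):
        """Query cells drawn from one subtype's generative distribution in a
        well-separated reference are assigned that subtype for >=95% of
        cells (n=500)."""
        rng = np.random.default_rng(0)
        centers = rng.normal(0, 8, size=(5, 10))  # well-separated clusters

        class Ref:
            pca_embeddings = np.vstack([
                c + rng.normal(0, 1, size=(200, 10)) for c in centers])
            umap_embeddings = pca_embeddings[:, :2]
            subtype_order = [f"S{k}" for k in range(5)]
            n_cells = 1000
        ref = Ref()
        ref.labels = pd.Series(np.repeat(ref.subtype_order, 200))
        query = centers[2] + rng.normal(0, 1, size=(500, 10))
        labels, conf = classify_cells(query, ref, k=20)
        assert (labels.values == "S2").mean() >= 0.95


class TestAlignAndProject:
    def test_reference_immutable_under_projection(self, atlas, sim_datasets):
        before = atlas.checksum()
        project(sim_datasets[1], atlas, filter=False)
        assert atlas.checksum() == before

    def test_self_subsample_needs_little_correction(self, atlas):
        """Aligning a query drawn from the atlas's own integrated profiles
        produces corrections that are small compared with the corrections
        applied to a genuinely batch-shifted version of the same cells, and
        carry no appreciable systematic component relative to that shift."""
        from tcellproj.datatypes import ExpressionDataset
        from scipy import sparse

        rng = np.random.default_rng(0)
        idx = rng.choice(atlas.n_cells, 300, replace=False)
        sub = atlas.integrated[:, idx]

        def _align(mat):
            q = ExpressionDataset(
                gene_ids=list(atlas.var_genes),
                cell_ids=[f"q{i}" for i in range(mat.shape[1])],
                counts=sparse.csr_matrix(np.zeros_like(mat)),
                normalized=sparse.csr_matrix(mat),
            )
            corrected, _ = align_query(q, atlas)
            return corrected - mat

        shift = rng.normal(0, 0.5, size=len(atlas.var_genes))
        corr_self = _align(sub)
        corr_shifted = _align(sub + shift[:, None])
        # the shifted query needs corrections on the scale of the shift;
        # the self query must need far less, with near-zero net component
        assert np.abs(corr_self).mean() < 0.5 * np.abs(corr_shifted).mean()
        assert np.abs(corr_self.mean(axis=1)).mean() < 0.3 * np.abs(shift).mean()

    def test_missing_genes_zero_filled(self, atlas, sim_datasets):
        drop = set(atlas.var_genes[:10])
        q = sim_datasets[2].subset_genes(
            [g for g in sim_datasets[2].gene_ids if g not in drop])
        res = project(q, atlas, filter=False)
        gidx = {g: i for i, g in enumerate(atlas.var_genes)}
        rows = [gidx[g] for g in drop]
        assert np.abs(res.query.normalized[rows].toarray()).max() == 0.0

    def test_small_intersection_raises(self, atlas):
        q = make_dataset(np.ones((5, 30)), genes=[f"only{i}" for i in range(5)])
        from tcellproj.preprocess import normalize_counts

        with pytest.raises(ValueError, match="shared"):
            align_query(normalize_counts(q), atlas)

    def test_direct_mode_tiny_query(self, atlas, sim_datasets):
        tiny = sim_datasets[0].subset_cells(np.arange(20))
        res = project(tiny, atlas, direct=True, filter=False)
        assert res.query.n_cells == 20
        assert res.log["mode"] == "direct"

    def test_ortho_mode_rejects_mouse_query(self, atlas, sim_datasets):
        with pytest.raises(ValueError, match="human"):
            project(sim_datasets[0], atlas, ortho=True)

    def test_cell_count_conserved_without_filter(self, atlas, sim_datasets):
        res = project(sim_datasets[3], atlas, filter=False)
        assert res.query.n_cells == sim_datasets[3].n_cells

    def test_permutation_stability(self, atlas, sim_datasets):
        """Permuting query cells permutes outputs identically."""
        q = sim_datasets[4].subset_cells(np.arange(120))
        rng = np.random.default_rng(1)
        perm = rng.permutation(120)
        res_a = project(q, atlas, filter=False, direct=True)
        res_b = project(q.subset_cells(perm), atlas, filter=False, direct=True)
        assert np.allclose(res_b.pca_coords, res_a.pca_coords[perm], atol=1e-9)
        assert list(res_b.predicted_label.values) == [
            res_a.predicted_label.values[i] for i in perm]

    def test_self_projection_reproduces_labels(self, atlas, sim_datasets):
        """Projecting the atlas's own source datasets reproduces the stored
        subtype labels for >=90% of cells (analog of cross-validated
        classification accuracy on real atlases)."""
        hits = total = 0
        for ds in sim_datasets:
            res = project(ds, atlas, filter=False)
            own = atlas.labels.loc[res.query.cell_ids]
            hits += int((res.predicted_label.values == own.values).sum())
            total += res.query.n_cells
        assert hits / total >= 0.90


class TestAtlasProjectorEstimator:
    def test_sklearn_params_roundtrip(self, atlas):
        p = AtlasProjector(atlas=atlas, k=10)
        params = p.get_params()
        assert params["k"] == 10
        p.set_params(k=25)
        assert p.k == 25

    def test_transform_and_predict_shapes(self, atlas, sim_datasets):
        tiny = sim_datasets[0].subset_cells(np.arange(40))
        p = AtlasProjector(atlas=atlas, direct=True, filter=False).fit()
        coords = p.transform(tiny)
        labels = p.predict(tiny)
        assert coords.shape == (40, atlas.n_pc)
        assert set(labels) <= set(atlas.subtype_order)
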