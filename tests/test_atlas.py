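import numpy as np
import pytest

from tcellproj.atlas import (
    ClusterConfig,
    annotate_ica,
    cluster_snn,
    fit_reference,
)
from tcellproj.datatypes import SignatureSet


class TestFitReference:
    def test_center_scale_rotation_reproduces_embeddings(self, atlas):
        z = atlas.standardize(atlas.integrated)
        rec = z @ atlas.pca_rotation
        rel = np.abs(rec - atlas.pca_embeddings).max() / np.abs(
            atlas.pca_embeddings).max()
        assert rel < 1e-6

    def test_pca_embeddings_centered(self, atlas):
        assert np.abs(atlas.pca_embeddings.mean(axis=0)).max() < 1e-8

    def test_ica_rotation_reproduces_embeddings(self, atlas):
        z = atlas.standardize(atlas.integrated)
        rec = z @ atlas.ica_rotation
        assert np.allclose(rec, atlas.ica_embeddings, atol=1e-8)

    def test_ica_has_requested_components(self, atlas):
        assert atlas.ica_rotation.shape[1] == 50
        assert atlas.ica_embeddings.shape[1] == 50

    def test_ica_sign_convention(self, atlas):
        top = np.abs(atlas.ica_rotation).argmax(axis=0)
        signs = atlas.ica_rotation[top, np.arange(atlas.n_ica)]
        assert (signs > 0).all()

    def test_umap_self_transform_close(self, atlas):
        got = atlas.umap_model.transform(atlas.pca_embeddings)
        d = np.linalg.norm(got - atlas.umap_embeddings, axis=1)
        assert (d <= 0.5).mean() >= 0.95

    def test_ica_recovers_planted_gene_programs(self):
        """Five independent sparse gene programs mixed linearly are recovered
        up to permutation and sign with mean |corr| > 0.9."""
        rng = np.random.default_rng(0)
        n_cells, n_genes, k = 800, 150, 5
        sources = rng.laplace(size=(n_cells, k))
        mixing = np.zeros((n_genes, k))
        for j in range(k):
            mixing[j * 20:(j + 1) * 20, j] = rng.normal(1.5, 0.3, 20)
        x = mixing @ sources.T + rng.normal(0, 0.3, (n_genes, n_cells))
        ref = fit_reference(x, [f"g{i}" for i in range(n_genes)],
                            n_pc=20, n_ica=10, seed=0)
        corr = np.corrcoef(np.hstack([sources, ref.ica_embeddings]).T)[:k, k:]
        assert np.abs(corr).max(axis=1).mean() > 0.9

    def test_n_pc_larger_than_data_raises(self):
        x = np.random.default_rng(0).normal(size=(10, 30))
        with pytest.raises(ValueError, match="n_pc"):
            fit_reference(x, [f"g{i}" for i in range(10)], n_pc=20)

    def test_build_reproducible(self, sim_datasets):
        """Identical seeds and inputs give bit-identical frozen matrices."""
        from tcellproj.atlas import AtlasBuilder

        a = AtlasBuilder(random_state=0).fit(sim_datasets[:3]).atlas_
        b = AtlasBuilder(random_state=0).fit(sim_datasets[:3]).atlas_
        assert np.array_equal(a.pca_rotation, b.pca_rotation)
        assert np.array_equal(a.ica_rotation, b.ica_rotation)
        assert np.array_equal(a.umap_embeddings, b.umap_embeddings)
        assert (a.labels.values == b.labels.values).all()


class TestClusterSnn:
    def test_two_separated_blobs_give_two_clusters(self):
        rng = np.random.default_rng(0)
        emb = np.vstack([
            rng.normal(0, 1, size=(300, 2)),
            rng.normal(10, 1, size=(300, 2)),   # 10 sigma apart
        ])
        labels = cluster_snn(emb, ClusterConfig(resolution=0.1, k_param=20,
                                                reduction="pca"), seed=0)
        assert len(set(labels)) == 2
        # blob membership respected
        assert len(set(labels[:300])) == 1 and len(set(labels[300:])) == 1

    def test_same_seed_same_labels(self):
        rng = np.random.default_rng(1)
        emb = rng.normal(size=(200, 2))
        cfg = ClusterConfig(resolution=0.6, k_param=15, reduction="pca")
        a = cluster_snn(emb, cfg, seed=3)
        b = cluster_snn(emb, cfg, seed=3)
        assert np.array_equal(a, b)

    def test_cluster_ids_ordered_by_size(self):
        rng = np.random.default_rng(2)
        emb = np.vstack([rng.normal(0, 1, (400, 2)), rng.normal(12, 1, (100, 2))])
        labels = cluster_snn(emb, ClusterConfig(resolution=0.1, k_param=15,
                                                reduction="pca"), seed=0)
        sizes = np.bincount(labels)
        assert (np.diff(sizes) <= 0).all()

    def test_k_exceeding_cells_raises(self):
        emb = np.zeros((10, 2))
        with pytest.raises(ValueError, match="k_param"):
            cluster_snn(emb, ClusterConfig(resolution=0.5, k_param=10,
                                           reduction="pca"))

    @pytest.mark.parametrize("bad", [
        {"resolution": 0.0}, {"resolution": -1.0}, {"k_param": 1},
        {"reduction": "tsne"},
    ])
    def test_config_validation(self, bad):
        kwargs = {"resolution": 0.6, "k_param": 20, "reduction": "umap"}
        kwargs.update(bad)
        with pytest.raises(ValueError):
            ClusterConfig(**kwargs)

    def test_til_preset_accepted_verbatim(self, atlas):
        cfg = ClusterConfig(resolution=0.6, k_param=20, reduction="umap")
        labels = cluster_snn(atlas, cfg, seed=0)
        assert len(labels) == atlas.n_cells


class TestAnnotateIca:
    def _atlas_with_loadings(self, atlas, loadings):
        import dataclasses

        rot = atlas.ica_rotation.copy()
        return dataclasses.replace(atlas, ica_rotation=rot), rot

    def test_hand_computed_score(self, atlas):
        # loadings g1: 2.0, g2: -1.0 on component 0 -> |2 - 1| = 1.0
        import dataclasses

        rot = np.zeros_like(atlas.ica_rotation)
        rot[0, 0], rot[1, 0] = 2.0, -1.0
        rot[2, 1] = 5.0  # keep other components nonzero somewhere
        a = dataclasses.replace(atlas, ica_rotation=rot)
        sigs = SignatureSet({"SIG": [atlas.var_genes[0], atlas.var_genes[1]]})
        table = annotate_ica(a, sigs)
        score = table[(table.component == 0) & (table.signature == "SIG")]
        assert np.isclose(score["score"].iloc[0], 1.0)

    def test_sign_flip_invariant(self, atlas):
        import dataclasses

        sigs = SignatureSet({"SIG": atlas.var_genes[:5]})
        t1 = annotate_ica(atlas, sigs)
        flipped = dataclasses.replace(atlas, ica_rotation=-atlas.ica_rotation)
        t2 = annotate_ica(flipped, sigs)
        assert np.allclose(t1["score"].values, t2["score"].values)

    def test_disjoint_signature_skipped(self, atlas):
        sigs = SignatureSet({"GOOD": atlas.var_genes[:3], "ALIEN": ["ZZZ9"]})
        with pytest.warns(UserWarning, match="ALIEN"):
            table = annotate_ica(atlas, sigs)
        assert set(table["signature"]) == {"GOOD"}

    def test_top_three_retained(self, atlas):
        sigs = SignatureSet(
            {f"S{i}": atlas.var_genes[i:i + 4] for i in range(6)})
        table = annotate_ica(atlas, sigs, top=3)
        assert table.groupby("component").size().max() <= 3
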