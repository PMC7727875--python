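import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from tpscore.io_formats import CountMatrix, GeneSet, ValidationError
from tpscore.manifold import (
    EmbedConfig,
    GeneSetSkip,
    compute_size_factors,
    embed_autoencoder,
    embed_classic,
    filter_low_genes,
    preprocess_expression,
    subset_counts,
)


def _counts(mat, genes=None, cells=None):
    mat = np.asarray(mat)
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    cells = cells or [f"c{j}" for j in range(mat.shape[1])]
    return CountMatrix(genes, cells, sp.csr_matrix(mat))


class TestSizeFactors:
    def test_equal_totals_give_unit_factors(self):
        cm = _counts([[2, 2, 2], [3, 3, 3]])
        np.testing.assert_allclose(compute_size_factors(cm).s, 1.0)

    def test_formula_by_hand(self):
        # totals (100, 200, 400) -> s = (0.5, 1.0, 2.0)
        cm = _counts([[100, 200, 400]])
        np.testing.assert_allclose(compute_size_factors(cm).s, [0.5, 1.0, 2.0])

    def test_median_is_one(self):
        rng = np.random.default_rng(0)
        cm = _counts(rng.poisson(5, (10, 7)) + 1)
        assert abs(np.median(compute_size_factors(cm).s) - 1.0) < 1e-9

    def test_zero_total_cell_named(self):
        cm = _counts([[1, 0], [2, 0]], cells=["ok", "empty"])
        with pytest.raises(ValidationError, match="empty"):
            compute_size_factors(cm)

    def test_transcriptome_wide_contract(self):
        """Factors computed on the full matrix are unchanged by later gene subsetting."""
        rng = np.random.default_rng(1)
        cm = _counts(rng.poisson(5, (20, 6)) + 1)
        before = compute_size_factors(cm).s.copy()
        subset_counts(cm, GeneSet("s", "", cm.gene_ids[:5]), min_overlap=2)
        np.testing.assert_array_equal(compute_size_factors(cm).s, before)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=2, max_value=50))
    def test_scaling_invariance(self, k):
        rng = np.random.default_rng(3)
        mat = rng.poisson(4, (6, 5)) + 1
        s1 = compute_size_factors(_counts(mat)).s
        s2 = compute_size_factors(_counts(mat * k)).s
        np.testing.assert_allclose(s1, s2)


class TestFilterLowGenes:
    def test_paper_threshold(self):
        cm = _counts([[1, 1, 0], [1, 1, 1], [2, 2, 1]])  # row sums 2, 3, 5
        out = filter_low_genes(cm, min_total=3)
        assert out.gene_ids == ["g1", "g2"]

    def test_zero_threshold_is_identity(self, tiny_counts):
        out = filter_low_genes(tiny_counts, min_total=0)
        np.testing.assert_array_equal(out.dense(), tiny_counts.dense())

    def test_row_sums_0_3_5(self):
        cm = _counts([[0, 0], [1, 2], [2, 3]])
        assert filter_low_genes(cm, min_total=3).n_genes == 2

    def test_all_removed_errors(self):
        cm = _counts([[1, 0], [0, 1]])
        with pytest.raises(ValidationError):
            filter_low_genes(cm, min_total=10)


class TestSubsetCounts:
    def test_intersection(self):
        cm = _counts(np.eye(3, dtype=int), genes=["A", "B", "C"])
        sub = subset_counts(cm, GeneSet("s", "", ["A", "B", "Z"]), min_overlap=2)
        assert sub.gene_ids == ["A", "B"]

    def test_disjoint_set_skips(self):
        cm = _counts(np.eye(2, dtype=int), genes=["A", "B"])
        with pytest.raises(GeneSetSkip):
            subset_counts(cm, GeneSet("s", "", ["X", "Y"]), min_overlap=1)

    def test_full_overlap_is_identity(self, tiny_counts):
        sub = subset_counts(
            tiny_counts, GeneSet("s", "", list(tiny_counts.gene_ids)), min_overlap=3
        )
        np.testing.assert_array_equal(sub.dense(), tiny_counts.dense())

    def test_matrix_row_order_preserved(self):
        cm = _counts(np.arange(8).reshape(4, 2), genes=["D", "A", "C", "B"])
        sub = subset_counts(cm, GeneSet("s", "", ["A", "B", "D"]), min_overlap=2)
        assert sub.gene_ids == ["D", "A", "B"]


@pytest.fixture(scope="module")
def sim_subset(small_sim_module):
    sim = small_sim_module
    sf = compute_size_factors(sim.counts)
    de_genes = [g for g, f in zip(sim.counts.gene_ids, sim.de_flags) if f]
    sub = subset_counts(sim.counts, GeneSet("de", "", de_genes), min_overlap=5)
    return sub, sf


@pytest.fixture(scope="module")
def small_sim_module():
    from tpscore.simulate import SimParams, simulate_counts

    return simulate_counts(
        SimParams(n_genes=120, n_cells=300, de_prob=0.25, de_factor_scale=1.0, seed=7)
    )


class TestEmbedClassic:
    def test_pca_matches_svd_oracle(self, sim_subset):
        sub, sf = sim_subset
        X = preprocess_expression(sub, sf)
        emb = embed_classic(sub, sf, EmbedConfig(method="pca", seed=0))
        Xc = X - X.mean(0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        oracle = U[:, :2] * S[:2]
        for j in range(2):  # per-axis sign freedom
            assert min(
                np.abs(emb.coords[:, j] - oracle[:, j]).max(),
                np.abs(emb.coords[:, j] + oracle[:, j]).max(),
            ) < 1e-8

    def test_rank1_second_component_degenerate(self):
        # one expression pattern scaled across cells -> rank-1 preprocessed matrix
        cells = np.arange(1, 9)
        mat = np.outer([1, 2, 4, 8], cells)
        cm = _counts(mat)
        sf = compute_size_factors(cm)
        emb = embed_classic(cm, sf, EmbedConfig(method="pca", bottleneck_dim=2))
        v = emb.coords.var(axis=0)
        assert v[1] < 1e-10 * max(v[0], 1e-30)

    def test_pca_too_many_components_errors(self, sim_subset):
        sub, sf = sim_subset
        with pytest.raises(ValidationError, match="bottleneck_dim"):
            hl = (512, 500, 512)
            embed_classic(sub, sf, EmbedConfig(method="pca", bottleneck_dim=500, hidden_layers=hl))

    def test_tsne_deterministic_with_seed(self, sim_subset):
        sub, sf = sim_subset
        cfg = EmbedConfig(method="tsne", seed=5)
        a = embed_classic(sub, sf, cfg).coords
        b = embed_classic(sub, sf, cfg).coords
        np.testing.assert_array_equal(a, b)

    def test_umap_deterministic_with_seed(self, sim_subset):
        sub, sf = sim_subset
        cfg = EmbedConfig(method="umap", seed=5)
        a = embed_classic(sub, sf, cfg).coords
        b = embed_classic(sub, sf, cfg).coords
        np.testing.assert_array_equal(a, b)

    def test_pca_invariant_to_gene_permutation(self, sim_subset):
        sub, sf = sim_subset
        perm = np.random.default_rng(0).permutation(sub.n_genes)
        shuffled = sub.select_genes(perm)
        a = embed_classic(sub, sf, EmbedConfig(method="pca")).coords
        b = embed_classic(shuffled, sf, EmbedConfig(method="pca")).coords
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestEmbedAutoencoder:
    def test_default_two_coordinates(self, sim_subset):
        sub, sf = sim_subset
        cfg = EmbedConfig(epochs=3, patience=2, seed=0)
        emb = embed_autoencoder(sub, sf, cfg)
        assert emb.coords.shape == (sub.n_cells, 2)
        assert np.all(np.isfinite(emb.coords))

    def test_deterministic_for_fixed_seed(self, sim_subset):
        sub, sf = sim_subset
        cfg = EmbedConfig(epochs=3, patience=2, seed=9)
        a = embed_autoencoder(sub, sf, cfg).coords
        b = embed_autoencoder(sub, sf, cfg).coords
        np.testing.assert_array_equal(a, b)

    def test_invariant_to_gene_permutation_at_fixed_seed(self, sim_subset):
        sub, sf = sim_subset
        perm = np.random.default_rng(1).permutation(sub.n_genes)
        cfg = EmbedConfig(epochs=3, patience=2, seed=9)
        a = embed_autoencoder(sub, sf, cfg).coords
        b = embed_autoencoder(sub.select_genes(perm), sf, cfg).coords
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("hl", [(4, 2, 4), (8, 4, 8), (16, 8, 16)])
    def test_benchmark_architectures(self, sim_subset, hl):
        sub, sf = sim_subset
        cfg = EmbedConfig(hidden_layers=hl, bottleneck_dim=hl[1], epochs=2, patience=2)
        emb = embed_autoencoder(sub, sf, cfg)
        assert emb.coords.shape[1] == hl[1]


class TestEmbedConfig:
    def test_middle_layer_must_match_bottleneck(self):
        with pytest.raises(ValidationError):
            EmbedConfig(bottleneck_dim=4, hidden_layers=(64, 2, 64))

    def test_bottleneck_minimum(self):
        with pytest.raises(ValidationError):
            EmbedConfig(bottleneck_dim=1, hidden_layers=(4, 1, 4))


def test_all_backends_recover_strong_signal(small_sim_module):
    """With clearly separated simulated groups, every backend's embedding
    supports classification well above the 0.5 random baseline."""
    from tpscore.relevance import relevance_score
    from tpscore.manifold import embed

    sim = small_sim_module
    sf = compute_size_factors(sim.counts)
    de_genes = [g for g, f in zip(sim.counts.gene_ids, sim.de_flags) if f]
    sub = subset_counts(sim.counts, GeneSet("de", "", de_genes), min_overlap=5)
    for method in ("autoencoder", "pca", "tsne", "umap"):
        cfg = EmbedConfig(method=method, epochs=60, patience=10, seed=2)
        emb = embed(sub, sf, cfg)
        score = relevance_score(emb, sim.group, n_trees=100, seed=2)
        assert score >= 0.5 + 0.2, f"{method} relevance {score:.3f} too low"
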