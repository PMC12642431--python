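"""Iterative stability clustering: splits, stability, rescue, hybrids."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from psn_atlas.cluster import (
    ClusterParams,
    call_hybrids,
    gradient_positions,
    iterate_clustering,
    rescue_rare,
    select_hvgs,
    two_way_split,
)
from psn_atlas.exceptions import ConfigurationError, InputError
from psn_atlas.pipeline import atlas_subtype_labels
from psn_atlas.sim.atlas import (
    AtlasSimConfig,
    HybridSpec,
    PopulationSpec,
    SharedProgramSpec,
    simulate_atlas,
)

FAST = ClusterParams(n_hvg=50, n_resamples=20, n_perm=99, alpha=0.05, n_pc_perm=10, seed=0)


def gaussian_blobs(sizes, sep, n_feat=30, seed=0, sd=1.0):
    """AnnData with TPM-like positive values: blobs along the first axis."""
    rng = np.random.default_rng(seed)
    rows = []
    for k, n in enumerate(sizes):
        mu = np.zeros(n_feat)
        mu[: n_feat // 2] = k * sep
        rows.append(rng.normal(mu, sd, size=(n, n_feat)))
    X = np.exp2(np.concatenate(rows)) - 0.5
    X = np.clip(X, 0, None)
    obs = pd.DataFrame(
        {"blob": np.repeat(np.arange(len(sizes)), sizes)},
        index=[f"c{i}" for i in range(sum(sizes))],
    )
    return ad.AnnData(X=X, obs=obs)


class TestHVGSelection:
    def test_exactly_the_variable_genes(self):
        rng = np.random.default_rng(0)
        X = np.ones((20, 30))
        X[:, :5] = rng.uniform(0, 100, size=(20, 5))
        m = ad.AnnData(X=X, var=pd.DataFrame(index=[f"G{i}" for i in range(30)]))
        assert set(select_hvgs(m, 5)) == {f"G{i}" for i in range(5)}

    def test_error_when_too_few_variable(self):
        m = ad.AnnData(X=np.ones((10, 10)))
        with pytest.raises(InputError):
            select_hvgs(m, 5)

    def test_independent_of_cell_order(self, kept_atlas, rng):
        h1 = select_hvgs(kept_atlas, 200)
        perm = rng.permutation(kept_atlas.n_obs)
        h2 = select_hvgs(kept_atlas[perm].copy(), 200)
        assert h1 == h2

    def test_planted_markers_are_highly_variable(self):
        pops = [
            PopulationSpec("A", 15, [f"MkA_{i}" for i in range(10)]),
            PopulationSpec("B", 15, [f"MkB_{i}" for i in range(10)]),
        ]
        adata = simulate_atlas(
            AtlasSimConfig(populations=pops, n_genes=300, n_contaminated=0, n_lowdepth=0, n_lowgenes=0)
        )
        hvgs = set(select_hvgs(adata, 100))
        markers = {g for p in pops for g in p.marker_genes}
        assert markers <= hvgs


class TestTwoWaySplit:
    def test_well_separated_blobs_split_perfectly(self):
        m = gaussian_blobs([20, 20], sep=10.0)
        node = two_way_split(np.arange(40), m, FAST)
        assert node.separation_p < 0.05
        assert node.stability is not None and np.all(node.stability == 1.0)
        lab = node.labels
        assert len(set(lab[:20])) == 1 and len(set(lab[20:])) == 1 and lab[0] != lab[-1]

    def test_single_blob_rarely_significant(self):
        hits = 0
        for seed in range(100):
            m = gaussian_blobs([40], sep=0.0, seed=seed)
            p = ClusterParams(n_hvg=20, n_resamples=20, n_perm=199, alpha=0.01, n_pc_perm=5, seed=seed)
            node = two_way_split(np.arange(40), m, p)
            if node.separation_p < p.alpha:
                hits += 1
        assert hits <= 5  # separation_p >= alpha in >= 95% of seeds

    def test_small_group_terminates_recursion(self):
        m = gaussian_blobs([20, 3], sep=10.0)
        node = two_way_split(np.arange(23), m, FAST)
        assert node.is_leaf  # putative child below min_size

    def test_too_few_cells_is_leaf_not_error(self):
        m = gaussian_blobs([6], sep=0.0)
        node = two_way_split(np.arange(6), m, FAST)
        assert node.is_leaf and node.children is None

    def test_identical_cells_leaf_with_p_one(self):
        m = ad.AnnData(X=np.ones((20, 10)) * 5)
        node = two_way_split(np.arange(20), m, FAST)
        assert node.is_leaf and node.separation_p == 1.0

    def test_stability_equals_resample_recount(self):
        # brute-force recount of agreements on a small instance
        m = gaussian_blobs([15, 12], sep=4.0, seed=3)
        p = ClusterParams(n_hvg=20, n_resamples=25, n_perm=99, alpha=0.05, n_pc_perm=5, seed=3)
        node = two_way_split(np.arange(27), m, p)
        recount = (node.resample_assignments == node.labels[None, :]).sum(axis=0) / 25
        assert np.allclose(node.stability, recount)

    def test_dropped_cells_monotone_in_stability_cutoff(self, kept_atlas):
        import numpy.random as npr

        dropped = {}
        for cutoff in (0.8, 0.95):
            p = ClusterParams(seed=0, stability_cutoff=cutoff, n_perm=99, alpha=0.05)
            node = two_way_split(
                np.asarray(kept_atlas.obs_names),
                kept_atlas,
                p,
                rng=np.random.default_rng(7),
            )
            dropped[cutoff] = set(map(str, node.dropped_cells))
        assert dropped[0.8] <= dropped[0.95]


class TestIterateClustering:
    def test_empty_matrix_rejected(self):
        with pytest.raises(InputError):
            iterate_clustering(ad.AnnData(X=np.zeros((0, 5))), FAST)

    def test_single_population_single_leaf(self):
        m = gaussian_blobs([30], sep=0.0)
        tree = iterate_clustering(m, FAST)
        assert len(tree.leaves) == 1
        assert len(tree.leaves[0].cell_ids) == 30

    def test_conservation_all_cells_accounted(self, kept_atlas, atlas_tree):
        leaf_cells = [c for leaf in atlas_tree.leaves for c in leaf.cell_ids]
        dropped = atlas_tree.dropped()
        assert len(leaf_cells) + len(dropped) == kept_atlas.n_obs
        assert set(map(str, leaf_cells)) | set(dropped) == set(map(str, kept_atlas.obs_names))

    def test_fixed_seed_reproducible(self, kept_atlas, atlas_tree):
        tree2 = iterate_clustering(kept_atlas, ClusterParams(seed=0))
        a1 = atlas_tree.assignments()
        a2 = tree2.assignments()
        assert a1.sort_index().equals(a2.sort_index())

    def test_recovers_planted_populations(self, kept_atlas, atlas_tree):
        from sklearn.metrics import adjusted_rand_score

        labels = atlas_tree.assignments().reindex(kept_atlas.obs_names)
        keep = labels != "dropped"
        ari = adjusted_rand_score(kept_atlas.obs.truth_label[keep], labels[keep])
        assert len(atlas_tree.leaves) == 8
        assert ari >= 0.9

    def test_hierarchical_first_split_separates_super_groups(self):
        pops = [
            PopulationSpec(n, 12, [f"Mk{n}_{i}" for i in range(10)]) for n in "ABCD"
        ]
        programs = [
            SharedProgramSpec("s1", ["A", "B"], 25, 5.5),
            SharedProgramSpec("s2", ["C", "D"], 25, 5.5),
        ]
        adata = simulate_atlas(
            AtlasSimConfig(populations=pops, shared_programs=programs, n_genes=400,
                           n_contaminated=0, n_lowdepth=0, n_lowgenes=0, seed=1)
        )
        tree = iterate_clustering(adata, ClusterParams(seed=1, n_perm=99, alpha=0.05, n_hvg=200))
        root = tree.root
        assert not root.is_leaf
        side = {}
        for k, child in enumerate(root.children):
            for lbl in adata.obs.truth_label.loc[child.cell_ids].unique():
                side[lbl] = k
        assert side["A"] == side["B"] and side["C"] == side["D"] and side["A"] != side["C"]


class TestRescueRare:
    def test_planted_outlier_pair_rescued(self):
        m = gaussian_blobs([60, 2], sep=12.0, seed=5)
        tree = iterate_clustering(m, FAST)  # 62 cells: 2-cell group can't be a leaf
        assert len(tree.leaves) == 1
        tree2 = rescue_rare(tree, m, FAST)
        rares = [l for l in tree2.leaves if l.leaf_label.startswith("R")]
        assert len(rares) == 1
        assert set(map(str, rares[0].cell_ids)) == {"c60", "c61"}

    def test_homogeneous_leaf_unchanged(self):
        m = gaussian_blobs([40], sep=0.0, seed=6)
        tree = iterate_clustering(m, FAST)
        tree2 = rescue_rare(tree, m, FAST)
        assert len(tree2.leaves) == len(tree.leaves)

    def test_default_atlas_yields_nine_discrete_clusters(self, kept_atlas, atlas_tree):
        tree2 = rescue_rare(atlas_tree, kept_atlas, atlas_tree.params)
        assert len(tree2.leaves) == 9
        rare = [l for l in tree2.leaves if l.leaf_label.startswith("R")][0]
        assert list(kept_atlas.obs.truth_label.loc[rare.cell_ids].unique()) == ["PSN9"]


def bridge_config(n_hybrid=50, seed=0):
    pops = [
        PopulationSpec("A", 25, [f"MkA_{i}" for i in range(10)], marker_mean=2.5),
        PopulationSpec("B", 25, [f"MkB_{i}" for i in range(10)], marker_mean=2.5),
    ]
    return AtlasSimConfig(
        populations=pops,
        hybrids=[HybridSpec("A", "B", n_cells=n_hybrid, lambda_range=(0.2, 0.8))],
        n_genes=400,
        n_contaminated=0,
        n_lowdepth=0,
        n_lowgenes=0,
        seed=seed,
    )


class TestHybrids:
    def test_runs_guard(self, kept_atlas, atlas_tree):
        with pytest.raises(ConfigurationError):
            call_hybrids(atlas_tree, kept_atlas, atlas_tree.params, n_subset_runs=5)

    def test_gradient_recovers_mixing_weight(self):
        adata = simulate_atlas(bridge_config())
        truth = adata.obs.truth_label
        hyb = adata.obs_names[(truth == "PSN-H").to_numpy()]
        assert len(hyb) == 50
        hvgs = select_hvgs(adata, 200)
        grad = gradient_positions(
            adata,
            hvgs,
            hyb,
            adata.obs_names[(truth == "A").to_numpy()],
            adata.obs_names[(truth == "B").to_numpy()],
        )
        lam = adata.obs.hybrid_lambda.loc[hyb].to_numpy()
        mae = np.abs(grad - (1 - lam)).mean()
        assert mae <= 0.15

    def test_gradient_endpoint(self):
        cfg = bridge_config(n_hybrid=5)
        cfg.hybrids[0].lambda_range = (0.0, 0.0)  # pure parent B replicas
        adata = simulate_atlas(cfg)
        truth = adata.obs.truth_label
        hvgs = select_hvgs(adata, 200)
        grad = gradient_positions(
            adata,
            hvgs,
            adata.obs_names[(truth == "PSN-H").to_numpy()],
            adata.obs_names[(truth == "A").to_numpy()],
            adata.obs_names[(truth == "B").to_numpy()],
        )
        assert np.all(grad > 0.8)

    def test_pure_parents_rarely_flip(self):
        adata = simulate_atlas(bridge_config(n_hybrid=10, seed=2))
        params = ClusterParams(seed=2, n_perm=199, n_hvg=200)
        tree = iterate_clustering(adata, params)
        calls = call_hybrids(tree, adata, params)
        called = {c.cell_id for c in calls}
        pure = set(map(str, adata.obs_names[(adata.obs.truth_label != "PSN-H").to_numpy()]))
        assert len(called & pure) <= 0.1 * len(pure)


def test_end_to_end_ten_subtype_classes(kept_atlas):
    labels, tree, calls = atlas_subtype_labels(kept_atlas, ClusterParams(seed=0))
    classes = sorted(labels[labels != "dropped"].unique())
    assert len(classes) == 10
    assert "hybrid" in classes and any(c.startswith("R") for c in classes)
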