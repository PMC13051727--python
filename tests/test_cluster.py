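"""Hierarchical clustergrams, k-means partitions, k selection, ordering."""

import numpy as np
import pytest

from scqflow import (
    KMeansSubpopulations,
    hierarchical_clustergram,
    kmeans_partition,
    select_k,
    subgroup_order,
)
from scqflow.synthetic import generate_ct
from scqflow import pooled_median_normalize, subset_expression

from conftest import make_expression
from oracles import complete_linkage_heights, kmeans_wcss_exhaustive


def test_three_point_complete_linkage_by_hand():
    # collinear points 0, 1, 2: first merge at distance 1, then complete
    # linkage takes the max pairwise distance, so the root sits at 2
    e = make_expression([[0.0], [1.0], [2.0]])
    d = hierarchical_clustergram(e)
    heights = d.merges[:, 2]
    assert heights[0] == pytest.approx(1.0)
    assert heights[1] == pytest.approx(2.0)


def test_duplicated_cells_merge_at_height_zero():
    e = make_expression([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
    d = hierarchical_clustergram(e)
    assert d.merges[0, 2] == 0.0


def test_merge_heights_match_brute_force_oracle():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(10, 3))
    d = hierarchical_clustergram(make_expression(X))
    np.testing.assert_allclose(
        np.sort(d.merges[:, 2]), np.sort(complete_linkage_heights(X)), rtol=1e-10
    )


def test_gene_axis_and_too_few_items():
    e = make_expression(np.arange(6.0).reshape(2, 3))
    assert hierarchical_clustergram(e, axis="genes").n_leaves == 3
    with pytest.raises(ValueError):
        hierarchical_clustergram(make_expression([[1.0, 2.0]]), axis="cells")


def test_kmeans_recovers_separated_clouds():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 0.5, size=(20, 2))
    b = rng.normal(10, 0.5, size=(20, 2))
    e = make_expression(np.vstack([a, b]))
    model = kmeans_partition(e, k=2, seed=1)
    labels = model.assignment
    assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
    assert labels[0] != labels[20]


def test_k1_wcss_is_total_sum_of_squares():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(15, 4))
    e = make_expression(X)
    model = kmeans_partition(e, k=1, seed=0)
    tss = np.sum((X - X.mean(axis=0)) ** 2)
    assert model.wcss == pytest.approx(tss, rel=1e-9)


@pytest.mark.parametrize("k", [2, 3])
def test_wcss_matches_exhaustive_partition_minimum(k):
    rng = np.random.default_rng(7 + k)
    X = rng.normal(size=(8, 2))
    model = kmeans_partition(make_expression(X), k=k, seed=0, n_init=50)
    assert model.wcss == pytest.approx(kmeans_wcss_exhaustive(X, k), rel=1e-9)


def test_cluster_model_internal_consistency():
    m, _ = generate_ct(seed=2)
    e = pooled_median_normalize(m)
    model = kmeans_partition(e, k=4, seed=2)
    assert set(model.assignment) == {1, 2, 3, 4}
    assert model.sizes.min() > 0
    # centroids are member means; wcss is the recomputed squared distance sum
    recomputed = 0.0
    for c in range(1, 5):
        members = e.expr[model.assignment == c]
        np.testing.assert_allclose(members.mean(axis=0), model.centroids[c - 1], atol=1e-9)
        recomputed += np.sum((members - model.centroids[c - 1]) ** 2)
    assert model.wcss == pytest.approx(recomputed, rel=1e-9)


def test_wcss_non_increasing_in_n_init():
    m, _ = generate_ct(seed=4)
    e = pooled_median_normalize(m)
    w1 = kmeans_partition(e, k=5, seed=3, n_init=1).wcss
    w10 = kmeans_partition(e, k=5, seed=3, n_init=10).wcss
    assert w10 <= w1 + 1e-9


def test_kmeans_reproducible_and_k_bounds():
    e = make_expression(np.random.default_rng(5).normal(size=(12, 3)))
    a = kmeans_partition(e, k=3, seed=9)
    b = kmeans_partition(e, k=3, seed=9)
    np.testing.assert_array_equal(a.assignment, b.assignment)
    with pytest.raises(ValueError):
        kmeans_partition(e, k=13, seed=0)
    with pytest.raises(ValueError):
        KMeansSubpopulations(n_clusters=2).fit(np.array([[np.nan, 1.0]]))


def test_select_k_finds_planted_four_clusters():
    m, _ = generate_ct(seed=6)
    e = pooled_median_normalize(m)
    wt = subset_expression(e, e.group_mask("WT"))
    k, diag = select_k(wt, range(2, 7), seed=6, n_init=20)
    assert k == 4
    assert set(diag.columns) == {"k", "wcss", "silhouette"}


def test_select_k_flags_homogeneous_cloud():
    rng = np.random.default_rng(8)
    e = make_expression(rng.normal(size=(60, 10)))
    with pytest.warns(UserWarning, match="no cluster structure"):
        k, diag = select_k(e, range(2, 6), seed=0, n_init=10)
    assert diag.attrs["no_structure"]
    assert diag["silhouette"].max() < 0.25


def test_select_k_degenerate_identical_cells():
    e = make_expression(np.ones((10, 3)))
    with pytest.warns(UserWarning, match="identical"):
        k, diag = select_k(e, range(2, 4), seed=0)
    assert k == 1 and diag.empty


def test_select_k_invariant_under_cell_duplication():
    rng = np.random.default_rng(10)
    centers = np.array([[0, 0], [8, 0], [0, 8]], dtype=float)
    X = np.vstack([rng.normal(c, 1.0, size=(15, 2)) for c in centers])
    k1, _ = select_k(make_expression(X), range(2, 6), seed=1, n_init=10)
    k2, _ = select_k(make_expression(np.vstack([X, X])), range(2, 6), seed=1, n_init=10)
    assert k1 == k2 == 3


def test_subgroup_order_is_contiguous_permutation():
    m, _ = generate_ct(seed=9)
    e = pooled_median_normalize(m)
    model = kmeans_partition(e, k=4, seed=9)
    order = subgroup_order(e, model)
    assert sorted(order) == list(range(e.n_cells))
    # cells of one cluster occupy a contiguous block
    labels_in_order = model.assignment[order]
    changes = np.sum(labels_in_order[1:] != labels_in_order[:-1])
    assert changes == model.k - 1


def test_subgroup_order_singleton_clusters():
    e = make_expression(np.diag([1.0, 2.0, 3.0]))
    model = kmeans_partition(e, k=3, seed=0)
    order = subgroup_order(e, model)
    assert sorted(order) == [0, 1, 2]
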