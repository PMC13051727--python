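"""K-S differential testing, Bonferroni control, seed-gene export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scqflow import (
    cluster_vs_rest,
    export_seed_genes,
    group_vs_group,
    kmeans_partition,
    ks_two_sample,
)
from scqflow.differential import read_seed_genes

from conftest import make_expression
from oracles import ks_d_ecdf_sweep


def test_ks_identical_samples():
    d, p = ks_two_sample([1.0, 2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0, 5.0])
    assert d == 0.0 and p == pytest.approx(1.0)


def test_ks_disjoint_supports():
    with pytest.warns(UserWarning, match="little power"):
        d, _ = ks_two_sample([1, 2, 3], [4, 5, 6])
    assert d == 1.0


def test_ks_interleaved_hand_value():
    with pytest.warns(UserWarning):
        d, _ = ks_two_sample([1, 3, 5, 7], [2, 4, 6, 8])
    assert d == pytest.approx(0.25)


def test_ks_empty_sample_rejected():
    with pytest.raises(ValueError):
        ks_two_sample([], [1.0])


@settings(max_examples=60, deadline=None)
@given(
    x=st.lists(st.floats(-10, 10, allow_nan=False), min_size=5, max_size=25),
    y=st.lists(st.floats(-10, 10, allow_nan=False), min_size=5, max_size=25),
)
def test_ks_d_matches_ecdf_sweep_oracle(x, y):
    d, p = ks_two_sample(x, y)
    assert d == pytest.approx(ks_d_ecdf_sweep(x, y), abs=1e-12)
    assert 0.0 <= d <= 1.0 and 0.0 < p <= 1.0


def _planted_matrix(seed=0, n_cells=384, n_genes=96, cluster_size=30, shift=4.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 1.0, size=(n_cells, n_genes))
    X[:cluster_size, 0] += shift  # marker gene in the focal cluster
    return X


def _planted_model(X, cluster_size=30):
    from scqflow import ClusterModel

    n = X.shape[0]
    assignment = np.where(np.arange(n) < cluster_size, 1, 2)
    centroids = np.vstack(
        [X[:cluster_size].mean(axis=0), X[cluster_size:].mean(axis=0)]
    )
    return ClusterModel(
        k=2,
        assignment=assignment,
        centroids=centroids,
        wcss=0.0,
        seed=0,
        n_init=1,
        genes=[f"g{j}" for j in range(X.shape[1])],
        bound=5.0,
    )


def test_planted_marker_significant_after_bonferroni():
    # a +4 log2 shift in a 30-cell cluster vs the 354 remaining cells
    X = _planted_matrix(seed=1)
    r = cluster_vs_rest(make_expression(X), _planted_model(X), 1)
    row = r.table.set_index("gene").loc["g0"]
    assert row["significant"] and row["direction"] == 1
    assert r.m == 96 and (r.table["p_bonf"] >= r.table["p_raw"]).all()


def test_alpha_zero_nothing_significant():
    e = make_expression(_planted_matrix(seed=2))
    model = kmeans_partition(e, k=2, seed=2)
    r = cluster_vs_rest(e, model, 1, alpha=0.0)
    assert r.n_significant == 0


def test_cluster_covering_all_cells_rejected():
    e = make_expression(np.random.default_rng(3).normal(size=(10, 4)))
    model = kmeans_partition(e, k=1, seed=0)
    with pytest.raises(ValueError, match="covers all cells"):
        cluster_vs_rest(e, model, 1)


def test_multiplicity_genes_x_clusters():
    e = make_expression(_planted_matrix(seed=4, n_genes=10))
    model = kmeans_partition(e, k=2, seed=4)
    r = cluster_vs_rest(e, model, 1, multiplicity="genes_x_clusters")
    assert r.m == 20


def test_identical_groups_nothing_significant():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(60, 20))
    groups = ["WT"] * 30 + ["eKO"] * 30
    X = np.vstack([X[:30], X[:30]])  # literally identical group blocks
    r = group_vs_group(make_expression(X, groups=groups))
    assert r.n_significant == 0
    assert (r.table["ks_D"] == 0).all()


def test_group_swap_flips_direction_only():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(60, 8))
    X[:30, 0] += 3
    ga = ["A"] * 30 + ["B"] * 30
    gb = ["B"] * 30 + ["A"] * 30
    ra = group_vs_group(make_expression(X, groups=ga))
    rb = group_vs_group(make_expression(X, groups=gb))
    np.testing.assert_allclose(ra.table["p_raw"], rb.table["p_raw"])
    np.testing.assert_array_equal(
        ra.table["direction"].to_numpy(), -rb.table["direction"].to_numpy()
    )


def test_more_than_two_groups_rejected():
    e = make_expression(np.zeros((6, 2)), groups=["A", "A", "B", "B", "C", "C"])
    with pytest.raises(ValueError, match="pairwise"):
        group_vs_group(e)


def test_floor_ties_keep_statistics_in_range():
    rng = np.random.default_rng(7)
    X = np.full((80, 5), -5.0)  # heavy flooring
    X[:40] += rng.random(size=(40, 5)) * 0.5
    r = group_vs_group(make_expression(X, groups=["A"] * 40 + ["B"] * 40))
    assert (r.table["ks_D"] <= 1.0).all()
    assert ((r.table["p_raw"] > 0) & (r.table["p_raw"] <= 1)).all()


def test_seed_gene_export_round_trip(tmp_path):
    X = _planted_matrix(seed=8, n_genes=12)
    r = cluster_vs_rest(make_expression(X), _planted_model(X), 1)
    path = tmp_path / "seed.csv"
    export_seed_genes(r, path)
    back = read_seed_genes(path)
    assert set(back["gene"]) == set(r.significant_genes)
    assert len(back) == r.n_significant


def test_seed_gene_export_empty(tmp_path):
    e = make_expression(np.random.default_rng(9).normal(size=(40, 6)))
    model = kmeans_partition(e, k=2, seed=9)
    r = cluster_vs_rest(e, model, 1, alpha=0.0)
    path = tmp_path / "none.csv"
    export_seed_genes(r, path)
    back = pd.read_csv(path)
    assert len(back) == 0 and list(back.columns) == ["gene", "ks_D", "p_bonf", "direction"]
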