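import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from wingmorph.shape_stats import (
    allometry_r2,
    crossval_reclassify,
    cva,
    mahalanobis_with_permutation,
    upgma_tree,
)


def three_group_data(rng, n=15, p=4, sep=2.0):
    means = np.zeros((3, p))
    means[0, 0] = -sep
    means[1, 0] = sep
    means[2, 1] = sep
    x = np.vstack([rng.standard_normal((n, p)) + means[g] for g in range(3)])
    labels = np.repeat(["A", "B", "C"], n)
    return x, labels


def test_cva_three_groups_two_dfs_sum_100(rng):
    x, labels = three_group_data(rng)
    res = cva(x, labels)
    assert res.df_scores.shape[1] == 2
    assert res.df_contributions.sum() == pytest.approx(100.0)
    # DF scores have identity pooled within-group covariance
    groups, p = res.groups, res.df_scores.shape[1]
    w = np.zeros((p, p))
    for g in groups:
        xg = res.df_scores[res.labels == g]
        w += (xg.shape[0] - 1) * np.cov(xg, rowvar=False)
    w /= len(res.labels) - len(groups)
    np.testing.assert_allclose(w, np.eye(p), atol=1e-8)


def test_cva_null_separation_small(rng):
    n = 200
    x = rng.standard_normal((2 * n, 5))
    labels = np.repeat(["A", "B"], n)
    res = cva(x, labels)
    gap = abs(res.group_means.loc["A", "DF1"] - res.group_means.loc["B", "DF1"])
    assert gap < 3 / np.sqrt(n) * 3  # standardized scores, null separation


def test_cva_collinear_means_df1_dominates(rng):
    # two clusters of 3 groups with collinear means
    p = 4
    x, labels = [], []
    for g, mu in enumerate([0.0, 0.2, 5.0]):
        pts = rng.standard_normal((30, p)) * 0.3
        pts[:, 0] += mu
        x.append(pts)
        labels += [f"G{g}"] * 30
    res = cva(np.vstack(x), np.array(labels))
    assert res.df_contributions[0] > 99.0


def test_mahalanobis_univariate_closed_form(rng):
    # two large univariate groups, means 0 and 1, pooled variance ~1
    n = 20000
    x = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)])[:, None]
    labels = np.repeat(["A", "B"], n)
    res = mahalanobis_with_permutation(x, labels, n_perm=10, seed=0)
    assert res.distances.loc["A", "B"] == pytest.approx(1.0, abs=0.05)


def test_mahalanobis_matches_direct_formula(rng):
    x, labels = three_group_data(rng, n=10, p=4)
    res = mahalanobis_with_permutation(x, labels, n_perm=10, seed=0)
    for g1, g2 in [("A", "B"), ("A", "C"), ("B", "C")]:
        x1, x2 = x[labels == g1], x[labels == g2]
        n1, n2 = len(x1), len(x2)
        s = ((n1 - 1) * np.cov(x1.T) + (n2 - 1) * np.cov(x2.T)) / (n1 + n2 - 2)
        diff = x1.mean(0) - x2.mean(0)
        d = np.sqrt(diff @ np.linalg.inv(s) @ diff)
        assert res.distances.loc[g1, g2] == pytest.approx(d, rel=1e-10)


def test_mahalanobis_and_cva_invariant_to_linear_maps(rng):
    """Distances and DF contributions are unchanged by any well-conditioned
    invertible linear transform of the features."""
    x, labels = three_group_data(rng, n=20, p=4)
    a = rng.standard_normal((4, 4)) + 4 * np.eye(4)
    y = x @ a.T + rng.standard_normal(4)
    d1 = mahalanobis_with_permutation(x, labels, n_perm=5, seed=0).distances
    d2 = mahalanobis_with_permutation(y, labels, n_perm=5, seed=0).distances
    np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-6)
    c1 = cva(x, labels).df_contributions
    c2 = cva(y, labels).df_contributions
    np.testing.assert_allclose(c1, c2, atol=1e-6)


def test_singular_features_reduced_automatically(rng):
    # p > n forces the 99%-variance PC reduction path
    x, labels = three_group_data(rng, n=8, p=4)
    wide = np.hstack([x, x @ rng.standard_normal((4, 40))])
    res = mahalanobis_with_permutation(wide, labels, n_perm=5, seed=0)
    assert np.isfinite(res.distances.to_numpy()).all()
    cls = crossval_reclassify(wide, labels)
    assert 0 <= cls.total_accuracy <= 1


def test_reclassify_separated_and_consistent(rng):
    x, labels = three_group_data(rng, n=20, p=4, sep=8.0)
    res = crossval_reclassify(x, labels)
    assert res.total_accuracy == 1.0
    c = res.confusion.to_numpy()
    assert res.total_accuracy == pytest.approx(np.trace(c) / c.sum())
    assert (res.confusion.sum(axis=1) == 20).all()


def test_allometry_perfect_and_null(rng):
    x, labels = three_group_data(rng, n=30, p=4)
    res = cva(x, labels)
    # DF1 exactly linear in a fabricated size variable -> r2 = 1
    cs = 2.0 * res.df_scores[:, 0] + 5.0
    allo = allometry_r2(res, cs)
    assert allo.r2 == pytest.approx(1.0)
    # independent size -> r2 near zero
    cs_null = rng.normal(1.5, 0.1, len(cs))
    allo0 = allometry_r2(res, cs_null)
    assert allo0.r2 < 0.1
    with pytest.raises(ValueError):
        allometry_r2(res, np.ones(len(cs)))


def test_upgma_hand_case():
    d = pd.DataFrame(
        [[0, 2, 6], [2, 0, 6], [6, 6, 0]], index=list("ABC"), columns=list("ABC"), dtype=float
    )
    tree = upgma_tree(d)
    np.testing.assert_allclose(tree.merge_heights(), [1.0, 3.0])
    assert frozenset({"A", "B"}) in tree.clades()
    nwk = tree.to_newick()
    assert nwk.count("(") == 2 and nwk.endswith(";")


def test_upgma_ultrametric_round_trip():
    """On an ultrametric input the cophenetic distances reproduce the input."""
    d = pd.DataFrame(
        [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]],
        index=list("ABCD"), columns=list("ABCD"), dtype=float,
    )
    tree = upgma_tree(d)
    np.testing.assert_allclose(tree.cophenetic().to_numpy(), d.to_numpy(), atol=1e-12)


def test_upgma_newick_branch_lengths_parse():
    dendropy = pytest.importorskip("dendropy")
    d = pd.DataFrame(
        [[0, 2, 6], [2, 0, 6], [6, 6, 0]], index=list("ABC"), columns=list("ABC"), dtype=float
    )
    nwk = upgma_tree(d).to_newick()
    t = dendropy.Tree.get(data=nwk, schema="newick")
    leaf_depths = {
        lf.taxon.label: lf.distance_from_root() for lf in t.leaf_node_iter()
    }
    # ultrametric: all leaves equidistant from the root
    vals = list(leaf_depths.values())
    assert max(vals) - min(vals) < 1e-9
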