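import numpy as np
import pandas as pd
import pytest

from wingmorph.barcode import (
    K2PSaturationError,
    bootstrap_support,
    group_distance_summary,
    k2p_distance,
    k2p_matrix,
    nj_tree,
)
from wingmorph.datatypes import SequenceSet
from wingmorph.simulate import SequenceSimConfig, simulate_k2p_sequences


def test_k2p_identical_zero():
    d, n = k2p_distance("ACGTACGT", "ACGTACGT")
    assert d == 0.0 and n == 8


def test_k2p_transitions_closed_form():
    """10 transitions in 100 sites: d = -1/2 ln(0.8)."""
    a = "A" * 100
    b = "G" * 10 + "A" * 90
    d, n = k2p_distance(a, b)
    assert n == 100
    assert d == pytest.approx(-0.5 * np.log(0.8))


def test_k2p_transversions_closed_form():
    # 10 transversions in 100 sites: d = -1/2 ln(1-Q) - 1/4 ln(1-2Q)
    a = "A" * 100
    b = "C" * 10 + "A" * 90
    d, _ = k2p_distance(a, b)
    assert d == pytest.approx(-0.5 * np.log(0.9) - 0.25 * np.log(0.8))


def test_k2p_pairwise_deletion():
    a = "ACGTACGTAC" + "N-"
    b = "ACGTACGTAT" + "AC"
    d_full, n_full = k2p_distance(a, b)
    d_clean, n_clean = k2p_distance(a[:10], b[:10])
    assert d_full == d_clean and n_full == n_clean == 10


def test_k2p_matches_site_counting_oracle(rng):
    """Random pairs: distance equals the closed form computed from an
    independent per-site count."""
    bases = np.array(list("ACGT"))
    for _ in range(20):
        a = bases[rng.integers(0, 4, 200)]
        b = a.copy()
        idx = rng.choice(200, 30, replace=False)
        b[idx] = bases[rng.integers(0, 4, 30)]
        sa, sb = "".join(a), "".join(b)
        ts = sum(
            1 for x, y in zip(sa, sb)
            if x != y and {x, y} in ({"A", "G"}, {"C", "T"})
        )
        tv = sum(1 for x, y in zip(sa, sb) if x != y) - ts
        p, q = ts / 200, tv / 200
        expected = -0.5 * np.log(1 - 2 * p - q) - 0.25 * np.log(1 - 2 * q)
        assert k2p_distance(sa, sb)[0] == pytest.approx(expected, abs=1e-12)


def test_k2p_saturation_error():
    a = "A" * 40
    b = "G" * 40
    with pytest.raises(K2PSaturationError):
        k2p_distance(a, b)


def test_nj_three_taxa_closed_form():
    d = pd.DataFrame(
        [[0, 5, 9], [5, 0, 10], [9, 10, 0]], index=list("ABC"), columns=list("ABC"), dtype=float
    )
    tree = nj_tree(d)
    # a = (dAB + dAC - dBC)/2 = 2, b = 3, c = 7
    lens = dict(zip((c.name for c in tree.root.children), tree.root.lengths))
    assert lens["A"] == pytest.approx(2.0)
    assert lens["B"] == pytest.approx(3.0)
    assert lens["C"] == pytest.approx(7.0)


def test_nj_recovers_additive_matrix_exactly(rng):
    """A matrix generated from a known 6-taxon tree is recovered exactly
    (path-length distances equal the input), cross-checked against the
    scikit-bio NJ implementation."""
    skbio = pytest.importorskip("skbio")
    labels = list("ABCDEF")
    # fixed 6-taxon additive matrix from tree ((A:1,B:2):1,(C:3,(D:1,E:1):2):1,F:4)
    tree_paths = {
        ("A", "B"): 3, ("A", "C"): 6, ("A", "D"): 6, ("A", "E"): 6, ("A", "F"): 6,
        ("B", "C"): 7, ("B", "D"): 7, ("B", "E"): 7, ("B", "F"): 7,
        ("C", "D"): 6, ("C", "E"): 6, ("C", "F"): 8,
        ("D", "E"): 2, ("D", "F"): 8, ("E", "F"): 8,
    }
    d = pd.DataFrame(0.0, index=labels, columns=labels)
    for (a, b), v in tree_paths.items():
        d.loc[a, b] = d.loc[b, a] = float(v)
    tree = nj_tree(d)
    paths = tree.path_lengths()
    np.testing.assert_allclose(paths.loc[labels, labels].to_numpy(), d.to_numpy(), atol=1e-10)
    # independent oracle: scikit-bio NJ produces the same bipartitions
    sk_dm = skbio.DistanceMatrix(d.to_numpy(), ids=labels)
    sk_tree = skbio.tree.nj(sk_dm)
    sk_splits = set()
    for node in sk_tree.non_tips():
        names = frozenset(t.name for t in node.tips())
        if 1 < len(names) < len(labels) - 1:
            sk_splits.add(names if "A" not in names else frozenset(labels) - names)
    assert tree.bipartitions() == sk_splits


def test_nj_identical_rows_zero_cherry():
    labels = list("ABCD")
    d = pd.DataFrame(
        [[0, 0, 4, 4], [0, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
        index=labels, columns=labels, dtype=float,
    )
    tree = nj_tree(d)
    paths = tree.path_lengths()
    assert paths.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)


def test_nj_on_ultrametric_matches_upgma_topology():
    from wingmorph.shape_stats import upgma_tree
    labels = list("ABCD")
    d = pd.DataFrame(
        [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]],
        index=labels, columns=labels, dtype=float,
    )
    nj_clades = {c for c in nj_tree(d).bipartitions()}
    up = upgma_tree(d)
    up_clades = {c for c in up.clades() if 1 < len(c) < 3}
    assert up_clades <= {frozenset(labels) - c for c in nj_clades} | nj_clades


def test_group_summary_single_substitution():
    """Two groups of identical sequences, one transition apart: within = 0,
    between = K2P(P=0.01) = -1/2 ln(0.98)."""
    seq = "ACGT" * 25
    other = "G" + seq[1:]  # A->G transition at site 1
    ss = SequenceSet(
        records=[
            ("a1", "X", seq), ("a2", "X", seq),
            ("b1", "Y", other), ("b2", "Y", other),
        ]
    )
    s = group_distance_summary(ss, n_boot=50, seed=0)
    assert s.within["X"][0] == 0.0
    expected = -0.5 * np.log(1 - 0.02)
    assert s.between[("X", "Y")][0] == pytest.approx(expected)
    assert s.barcode_gap == pytest.approx(expected)


def test_group_summary_identical_sequences_gap_zero():
    seq = "ACGT" * 25
    ss = SequenceSet(records=[(f"s{i}", "XY"[i % 2], seq) for i in range(6)])
    s = group_distance_summary(ss, n_boot=10, seed=0)
    assert s.barcode_gap == 0.0


def test_group_summary_singleton_absent():
    seq = "ACGT" * 25
    ss = SequenceSet(records=[("a1", "X", seq), ("a2", "X", seq), ("b1", "Y", seq)])
    s = group_distance_summary(ss, n_boot=10, seed=0)
    assert s.within["Y"] is None


def test_bootstrap_high_signal_support(rng):
    cfg = SequenceSimConfig(
        group_sizes=(4, 4),
        group_names=("A", "B"),
        length=1000,
        within_group_divergence=(0.001, 0.001),
        between_group_divergence=0.2,
        seed=21,
    )
    ss = simulate_k2p_sequences(cfg)
    tree = bootstrap_support(ss, n_reps=100, seed=5)
    supports = []

    def collect(node):
        if node.children is None:
            return
        if node.support is not None:
            supports.append(node.support)
        for c in node.children:
            collect(c)

    collect(tree.root)
    assert supports and max(supports) > 95.0
    assert all(0 <= s <= 100 for s in supports)


def test_bootstrap_deterministic(rng):
    cfg = SequenceSimConfig(group_sizes=(3, 3), group_names=("A", "B"),
                            within_group_divergence=(0.005, 0.005),
                            between_group_divergence=0.05, seed=8)
    ss = simulate_k2p_sequences(cfg)
    t1 = bootstrap_support(ss, n_reps=50, seed=9)
    t2 = bootstrap_support(ss, n_reps=50, seed=9)
    assert t1.to_newick() == t2.to_newick()


def test_outgroup_rooting():
    cfg = SequenceSimConfig(
        group_sizes=(3, 3, 1),
        group_names=("A", "B", "Out"),
        length=800,
        within_group_divergence=(0.002, 0.002, 0.0),
        between_group_divergence={("A", "B"): 0.03, ("A", "Out"): 0.2, ("B", "Out"): 0.2},
        seed=31,
    )
    ss = simulate_k2p_sequences(cfg)
    tree = nj_tree(k2p_matrix(ss), outgroup="Out_001")
    assert len(tree.root.children) == 2
    sides = [c.leaves() for c in tree.root.children]
    assert frozenset(["Out_001"]) in sides
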