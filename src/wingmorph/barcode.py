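"""Cox1 barcode analysis: K2P distances, population summaries, NJ trees.

Pairwise distances use the Kimura 2-parameter correction, which handles
transitions and transversions separately:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

with P and Q the transition and transversion proportions over comparable
sites (pairwise deletion of gap/N columns, MEGA's distance default).
Within- and between-population means, their site-bootstrap standard errors
and the barcode gap summarise the matrix; trees come from Saitou–Nei
neighbor joining with optional outgroup rooting and bipartition bootstrap
support, exported as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import logging

import numpy as np
import pandas as pd

from .datatypes import SequenceSet

logger = logging.getLogger("wingmorph")

__all__ = [
    "k2p_distance",
    "k2p_matrix",
    "group_distance_summary",
    "nj_tree",
    "bootstrap_support",
    "K2PSaturationError",
    "GroupDistanceSummary",
    "NJTree",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


class K2PSaturationError(ValueError):
    pass


def _site_counts(seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """(comparable sites, transitions, transversions) under pairwise deletion."""
    n = ts = tv = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in _VALID or y not in _VALID:
            continue  # gaps, N and other ambiguity codes are excluded pairwise
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    return n, ts, tv


def k2p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """K2P distance and the number of comparable sites."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned (equal length)")
    n, ts, tv = _site_counts(seq_a, seq_b)
    if n == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    p, q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise K2PSaturationError(f"K2P saturated (P={p:.3f}, Q={q:.3f})")
    return float(-0.5 * np.log(w1) - 0.25 * np.log(w2)), n


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("AGCT"):  # A,G purines first: family = code >> 1
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _encode(seqset: SequenceSet) -> np.ndarray:
    rows = [
        _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        for _, _, seq in seqset.records
    ]
    return np.stack(rows)


def k2p_matrix_from_codes(codes: np.ndarray, ids: list[str]) -> pd.DataFrame:
    n = codes.shape[0]
    out = np.zeros((n, n))
    valid = codes != 255
    fam = codes >> 1
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        comp = both.sum(axis=1)
        diff = (codes[i] != codes[i + 1:]) & both
        ts = (diff & (fam[i] == fam[i + 1:])).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        if np.any(comp == 0):
            raise ValueError("no comparable sites after pairwise deletion")
        p, q = ts / comp, tv / comp
        w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
        if np.any(w1 <= 0) or np.any(w2 <= 0):
            raise K2PSaturationError("K2P saturated for at least one pair")
        d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
        out[i, i + 1:] = d
        out[i + 1:, i] = d
    return pd.DataFrame(out, index=ids, columns=ids)


def k2p_matrix(seqset: SequenceSet) -> pd.DataFrame:
    """Symmetric matrix of K2P distances over an aligned SequenceSet
    (pairwise deletion of gap/ambiguous columns)."""
    if not seqset.check_aligned():
        raise ValueError("sequence set is not aligned")
    return k2p_matrix_from_codes(_encode(seqset), seqset.ids())


@dataclass
class GroupDistanceSummary:
    within: dict[str, tuple[float, float] | None]        # mean, SE; None for singletons
    between: dict[tuple[str, str], tuple[float, float]]
    barcode_gap: float          # min between mean - max within mean (proportion)
    barcode_gap_percent: float
    group_gap: dict[str, float]  # per group: min between(g,.) - within(g)


def _pair_means(matrix: pd.DataFrame, members: dict[str, list[str]]):
    within = {}
    for g, ids in members.items():
        pairs = [matrix.loc[a, b] for a, b in combinations(ids, 2)]
        within[g] = float(np.mean(pairs)) if pairs else None
    between = {}
    for g1, g2 in combinations(members, 2):
        vals = [matrix.loc[a, b] for a in members[g1] for b in members[g2]]
        between[(g1, g2)] = float(np.mean(vals))
    return within, between


def group_distance_summary(
    seqset: SequenceSet,
    n_boot: int = 500,
    seed: int = 0,
) -> GroupDistanceSummary:
    """Within/between-population mean K2P distances with site-bootstrap SEs.

    Standard errors resample alignment columns with replacement (MEGA's
    approach).  Singleton groups have no within-group mean and are reported
    as absent.  The barcode gap is min(between means) - max(within means);
    ``group_gap`` gives the per-population version (its smallest
    between-group mean minus its own within-group mean).
    """
    if not seqset.check_aligned():
        raise ValueError("sequence set is not aligned")
    pops = seqset.populations()
    members: dict[str, list[str]] = {}
    for sid, pop in pops.items():
        members.setdefault(pop, []).append(sid)
    matrix = k2p_matrix(seqset)
    within_mean, between_mean = _pair_means(matrix, members)

    codes = _encode(seqset)
    rng = np.random.default_rng(seed)
    boot_within = {g: [] for g in members}
    boot_between = {p: [] for p in between_mean}
    ncols = codes.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, ncols, size=ncols)
        try:
            bm = k2p_matrix_from_codes(codes[:, cols], seqset.ids())
        except (K2PSaturationError, ValueError):
            continue
        w, b = _pair_means(bm, members)
        for g in members:
            if w[g] is not None:
                boot_within[g].append(w[g])
        for p in between_mean:
            boot_between[p].append(b[p])

    within = {
        g: (within_mean[g], float(np.std(boot_within[g], ddof=1))) if within_mean[g] is not None else None
        for g in members
    }
    between = {p: (between_mean[p], float(np.std(boot_between[p], ddof=1))) for p in between_mean}

    finite_within = [v for v in within_mean.values() if v is not None]
    gap = min(between_mean.values()) - max(finite_within) if finite_within else float("nan")
    group_gap = {}
    for g in members:
        if within_mean[g] is None:
            continue
        bvals = [m for p, m in between_mean.items() if g in p]
        group_gap[g] = float(min(bvals) - within_mean[g])
    return GroupDistanceSummary(within, between, float(gap), float(gap) * 100.0, group_gap)


@dataclass
class _Node:
    name: str | None = None
    children: list = None
    lengths: list = None
    support: float | None = None

    def leaves(self) -> frozenset:
        if self.children is None:
            return frozenset([self.name])
        out = frozenset()
        for c in self.children:
            out |= c.leaves()
        return out


@dataclass
class NJTree:
    root: _Node
    ids: list[str]

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each named by the side not containing the first id."""
        all_leaves = self.root.leaves()
        anchor = self.ids[0]
        splits = set()

        def walk(node):
            if node.children is None:
                return
            for child in node.children:
                ls = child.leaves()
                if 1 < len(ls) < len(all_leaves) - 1:
                    side = all_leaves - ls if anchor in ls else ls
                    splits.add(side)
                walk(child)

        walk(self.root)
        return splits

    def path_lengths(self) -> pd.DataFrame:
        """Leaf-to-leaf distances along the tree."""
        dists: dict[str, dict[str, float]] = {}

        def walk(node, depth, acc):
            if node.children is None:
                acc.append((node.name, depth))
                return
            for child, ln in zip(node.children, node.lengths):
                walk(child, depth + ln, acc)

        def all_pairs(node):
            if node.children is None:
                return
            sub = []
            for child, ln in zip(node.children, node.lengths):
                acc = []
                walk(child, ln, acc)
                sub.append(acc)
            for i, j in combinations(range(len(sub)), 2):
                for name_a, da in sub[i]:
                    for name_b, db in sub[j]:
                        dists.setdefault(name_a, {})[name_b] = da + db
                        dists.setdefault(name_b, {})[name_a] = da + db
            for child in node.children:
                all_pairs(child)

        all_pairs(self.root)
        out = pd.DataFrame(0.0, index=self.ids, columns=self.ids)
        for a in self.ids:
            for b in self.ids:
                if a != b:
                    out.loc[a, b] = dists[a][b]
        return out

    def to_newick(self) -> str:
        def fmt(node):
            if node.children is None:
                return node.name
            inner = ",".join(
                f"{fmt(c)}:{ln:.10g}" for c, ln in zip(node.children, node.lengths)
            )
            label = "" if node.support is None else f"{node.support:.0f}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"


def nj_tree(matrix: pd.DataFrame, outgroup: str | None = None) -> NJTree:
    """Saitou–Nei neighbor joining on the Q-criterion.

    Negative branch lengths are clamped to zero with the deficit moved to the
    sister branch (standard display practice).  The unrooted tree is returned
    with a trifurcating root, or rooted on the outgroup branch when given.
    """
    ids = list(matrix.index)
    if len(ids) < 3:
        raise ValueError("need at least 3 taxa")
    d = matrix.to_numpy().astype(float).copy()
    if not np.all(np.isfinite(d)):
        bad = [(ids[i], ids[j]) for i, j in zip(*np.where(~np.isfinite(d))) if i < j]
        raise ValueError(f"undefined distances for pairs: {bad}")
    nodes = [_Node(name=i) for i in ids]
    active = list(range(len(ids)))

    while len(active) > 3:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(q), q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        dij = sub[i_loc, j_loc]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (n - 2))
        lj = dij - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        gi, gj = active[i_loc], active[j_loc]
        new = _Node(children=[nodes[gi], nodes[gj]], lengths=[li, lj])
        # distances from the new node to every remaining taxon
        new_row = 0.5 * (d[gi] + d[gj] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        nodes.append(new)
        active = [a for a in active if a not in (gi, gj)] + [len(nodes) - 1]

    a, b, c = active
    # final three branches from the three-point formulas
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    lens = [max(x, 0.0) for x in (la, lb, lc)]
    root = _Node(children=[nodes[a], nodes[b], nodes[c]], lengths=lens)
    tree = NJTree(root=root, ids=ids)
    if outgroup is not None:
        tree = _root_on(tree, outgroup)
    return tree


def _root_on(tree: NJTree, outgroup: str) -> NJTree:
    """Re-root on the midpoint of the outgroup's terminal branch."""
    if outgroup not in tree.ids:
        raise ValueError(f"outgroup {outgroup!r} not among taxa")

    def detach(node, parent_children, parent_lengths):
        for idx, child in enumerate(node.children or []):
            if child.children is None and child.name == outgroup:
                ln = node.lengths[idx]
                rest_children = [c for k, c in enumerate(node.children) if k != idx]
                rest_lengths = [l for k, l in enumerate(node.lengths) if k != idx]
                ingroup = _Node(children=rest_children, lengths=rest_lengths)
                if len(rest_children) == 1:
                    ingroup = rest_children[0]
                    half = rest_lengths[0]
                else:
                    half = 0.0
                new_root = _Node(
                    children=[child, ingroup], lengths=[ln / 2.0, ln / 2.0 + half]
                )
                return NJTree(root=new_root, ids=tree.ids)
            if child.children is not None:
                res = detach(child, node.children, node.lengths)
                if res is not None:
                    return res
        return None

    res = detach(tree.root, None, None)
    if res is None:  # outgroup hangs directly off the trifurcating root
        raise ValueError(f"could not root on {outgroup!r}")
    return res


def bootstrap_support(
    seqset: SequenceSet,
    n_reps: int = 1000,
    seed: int = 0,
    outgroup: str | None = None,
) -> NJTree:
    """NJ tree with bipartition bootstrap support (percent of replicates).

    Alignment columns are resampled with replacement; replicates whose K2P
    matrix saturates are skipped and counted (warning if > 5% skipped).
    """
    if not seqset.check_aligned():
        raise ValueError("sequence set is not aligned")
    base_matrix = k2p_matrix(seqset)
    tree = nj_tree(base_matrix, outgroup=outgroup)
    ids = seqset.ids()
    codes = _encode(seqset)
    ncols = codes.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    used = skipped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        try:
            bt = nj_tree(k2p_matrix_from_codes(codes[:, cols], ids))
        except (K2PSaturationError, ValueError):
            skipped += 1
            continue
        used += 1
        reps = bt.bipartitions()
        for bp in counts:
            if bp in reps:
                counts[bp] += 1
    if skipped > 0.05 * n_reps:
        logger.warning("%d/%d bootstrap replicates skipped (saturation)", skipped, n_reps)

    def annotate(node):
        if node.children is None:
            return
        for child in node.children:
            ls = child.leaves()
            all_leaves = tree.root.leaves()
            if 1 < len(ls) < len(all_leaves) - 1:
                side = all_leaves - ls if ids[0] in ls else ls
                if side in counts and used:
                    child.support = 100.0 * counts[side] / used
            annotate(child)

    annotate(tree.root)
    return tree
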