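"""Between-population shape statistics.

Shape variables (relative-warp scores for landmarks, NEF vectors for
outlines) are compared by canonical variate analysis (discriminant factors
maximizing between- to pooled-within-group variance), pairwise Mahalanobis
distances with permutation significance, leave-one-out validated
reclassification, an allometry summary (r² of DF1 regressed on centroid
size), and a UPGMA dendrogram of the Mahalanobis matrix.

When the pooled within-group covariance is singular — routine at n ≈ 20
wings per site — features are first projected onto the principal components
covering 99% of total variance; Mahalanobis distances are invariant to this
kind of invertible linear reduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .size_stats import ClassificationResult, _confusion_result

logger = logging.getLogger("wingmorph")

__all__ = [
    "cva",
    "mahalanobis_with_permutation",
    "crossval_reclassify",
    "allometry_r2",
    "upgma_tree",
    "DiscriminantResult",
    "MahalanobisMatrix",
    "AllometryResult",
    "UPGMATree",
]


def _group_stats(x: np.ndarray, labels: np.ndarray) -> tuple[list, dict, np.ndarray]:
    groups = list(dict.fromkeys(labels))
    means = {g: x[labels == g].mean(axis=0) for g in groups}
    n, p = x.shape
    w = np.zeros((p, p))
    for g in groups:
        xg = x[labels == g]
        if xg.shape[0] > 1:
            w += (xg.shape[0] - 1) * np.cov(xg, rowvar=False)
    w /= n - len(groups)
    return groups, means, w


def _reduce_if_singular(x: np.ndarray, max_dim: int, var_kept: float = 0.99) -> np.ndarray:
    """Project onto principal components covering ``var_kept`` of variance,
    but only when the relevant pooled covariance (whose rank is bounded by
    ``max_dim``) would otherwise be singular; full-rank inputs below the
    bound pass through untouched (Mahalanobis quantities are invariant to
    the reduction either way)."""
    n, p = x.shape
    xc = x - x.mean(axis=0)
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    ev = s**2
    if ev.sum() == 0:
        raise ValueError("constant feature matrix")
    rank = int(np.sum(s > s[0] * 1e-9))
    if p < max_dim and rank == p:
        return x
    frac = np.cumsum(ev) / ev.sum()
    keep = int(np.searchsorted(frac, var_kept) + 1)
    keep = max(1, min(keep, max_dim - 1, rank))
    logger.info("reducing %d features to %d PCs (99%% variance / rank limit)", p, keep)
    return xc @ vt[:keep].T


@dataclass
class DiscriminantResult:
    df_scores: np.ndarray            # (n, n_df)
    df_contributions: np.ndarray     # percent of between-group variation, sums to 100
    group_means: pd.DataFrame        # group x DF centroids
    groups: list[str]
    labels: np.ndarray


def cva(features: np.ndarray, labels) -> DiscriminantResult:
    """Canonical variate analysis of a specimen x variable matrix.

    Axes v solve B v = λ W v (B between-group, W pooled within-group
    covariance) and are scaled so DF scores have identity pooled
    within-group covariance.  At most min(g - 1, p) factors exist and their
    contributions sum to 100%.
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    g_count = len(set(labels.tolist()))
    x = _reduce_if_singular(x, x.shape[0] - g_count)
    groups, means, w = _group_stats(x, labels)
    g, (n, p) = len(groups), x.shape
    if g < 2:
        raise ValueError("need at least 2 groups")
    grand = x.mean(axis=0)
    b = np.zeros((p, p))
    for gr in groups:
        ng = np.sum(labels == gr)
        dev = (means[gr] - grand)[:, None]
        b += ng * (dev @ dev.T)
    b /= n - 1
    # whiten by W, then symmetric eigenproblem
    evals_w, evecs_w = np.linalg.eigh(w)
    if evals_w.min() <= 0:
        raise np.linalg.LinAlgError("pooled covariance not positive definite after reduction")
    w_inv_half = evecs_w @ np.diag(evals_w**-0.5) @ evecs_w.T
    m = w_inv_half @ b @ w_inv_half
    lam, u = np.linalg.eigh(m)
    order = np.argsort(lam)[::-1]
    n_df = min(g - 1, p)
    lam = np.clip(lam[order][:n_df], 0, None)
    v = (w_inv_half @ u[:, order][:, :n_df])  # v' W v = I
    scores = (x - grand) @ v
    contrib = 100.0 * lam / lam.sum() if lam.sum() > 0 else np.zeros(n_df)
    gmeans = pd.DataFrame(
        {f"DF{i + 1}": [scores[labels == gr, i].mean() for gr in groups] for i in range(n_df)},
        index=groups,
    )
    return DiscriminantResult(scores, contrib, gmeans, groups, labels)


def _mahalanobis_pair(x1: np.ndarray, x2: np.ndarray) -> float:
    n1, n2 = x1.shape[0], x2.shape[0]
    s = ((n1 - 1) * np.cov(x1, rowvar=False) + (n2 - 1) * np.cov(x2, rowvar=False)) / (n1 + n2 - 2)
    s = np.atleast_2d(s)
    diff = x1.mean(axis=0) - x2.mean(axis=0)
    d2 = float(diff @ np.linalg.solve(s, diff))
    return float(np.sqrt(max(d2, 0.0)))


@dataclass
class MahalanobisMatrix:
    distances: pd.DataFrame
    p_values: pd.DataFrame
    n_permutations: int
    seed: int

    def condensed(self) -> np.ndarray:
        return squareform(self.distances.to_numpy(), checks=False)


def mahalanobis_with_permutation(
    features: np.ndarray,
    labels,
    n_perm: int = 1000,
    seed: int = 0,
) -> MahalanobisMatrix:
    """Pairwise Mahalanobis distances between group means under the pooled
    within-group covariance, with per-pair permutation p-values (add-one
    convention, labels shuffled within the pair)."""
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    groups = list(dict.fromkeys(labels))
    # pairwise pooled covariances only see the two groups' samples
    sizes = [int(np.sum(labels == g)) for g in groups]
    s1, s2 = sorted(sizes)[:2]
    x = _reduce_if_singular(x, s1 + s2 - 2)
    dmat = pd.DataFrame(0.0, index=groups, columns=groups)
    pmat = pd.DataFrame(np.nan, index=groups, columns=groups)
    for pair_idx, (g1, g2) in enumerate(combinations(groups, 2)):
        x1, x2 = x[labels == g1], x[labels == g2]
        obs = _mahalanobis_pair(x1, x2)
        pooled = np.vstack([x1, x2])
        n1 = x1.shape[0]
        rng = np.random.default_rng([seed, pair_idx])
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled.shape[0])
            d = _mahalanobis_pair(pooled[perm[:n1]], pooled[perm[n1:]])
            if d >= obs - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        dmat.loc[g1, g2] = dmat.loc[g2, g1] = obs
        pmat.loc[g1, g2] = pmat.loc[g2, g1] = p
    return MahalanobisMatrix(dmat, pmat, n_perm, seed)


def crossval_reclassify(features: np.ndarray, labels) -> ClassificationResult:
    """Leave-one-out reclassification by nearest group mean in Mahalanobis
    distance, refitting means and pooled covariance per fold."""
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    groups = list(dict.fromkeys(labels))
    # per fold one training sample is removed
    x = _reduce_if_singular(x, x.shape[0] - 1 - len(groups))
    n = x.shape[0]
    truth, assigned = [], []
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        xt, lt = x[mask], labels[mask]
        gs, means, w = _group_stats(xt, lt)
        try:
            w_inv = np.linalg.inv(w)
        except np.linalg.LinAlgError:
            evals, evecs = np.linalg.eigh(w)
            keep = evals > evals.max() * 1e-9
            logger.info("fold %d: singular pooled covariance, using %d PCs", i, keep.sum())
            w_inv = evecs[:, keep] @ np.diag(1.0 / evals[keep]) @ evecs[:, keep].T
        d2 = {g: float((x[i] - means[g]) @ w_inv @ (x[i] - means[g])) for g in gs}
        truth.append(labels[i])
        assigned.append(min(d2, key=d2.get))
    return _confusion_result(truth, assigned, groups, method="mahalanobis_shape")


@dataclass
class AllometryResult:
    r2: float
    slope: float
    intercept: float
    per_df_r2: list[float]


def allometry_r2(df_result: DiscriminantResult, cs: np.ndarray, n_dfs: int = 2) -> AllometryResult:
    """Allometric effect: OLS regression of each discriminant factor on
    centroid size, summarised by the determination coefficient r²."""
    cs = np.asarray(cs, dtype=float)
    if np.ptp(cs) == 0:
        raise ValueError("constant centroid size: allometry regression undefined")
    per_df = []
    first = None
    for i in range(min(n_dfs, df_result.df_scores.shape[1])):
        res = stats.linregress(cs, df_result.df_scores[:, i])
        per_df.append(float(res.rvalue**2))
        if i == 0:
            first = res
    return AllometryResult(
        r2=per_df[0],
        slope=float(first.slope),
        intercept=float(first.intercept),
        per_df_r2=per_df,
    )


@dataclass
class UPGMATree:
    linkage: np.ndarray
    labels: list[str]

    def merge_heights(self) -> np.ndarray:
        """Ultrametric node heights (half the merge distance)."""
        return self.linkage[:, 2] / 2.0

    def cophenetic(self) -> pd.DataFrame:
        coph = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(coph, index=self.labels, columns=self.labels)

    def clades(self) -> list[frozenset]:
        """Leaf set of every internal node, in merge order."""
        n = len(self.labels)
        sets: dict[int, frozenset] = {i: frozenset([self.labels[i]]) for i in range(n)}
        out = []
        for j, (a, b, _, _) in enumerate(self.linkage):
            sets[n + j] = sets[int(a)] | sets[int(b)]
            out.append(sets[n + j])
        return out

    def to_newick(self) -> str:
        n = len(self.labels)
        depth: dict[int, float] = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: self.labels[i] for i in range(n)}
        for j, (a, b, dist, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            h = dist / 2.0
            la, lb = h - depth[a], h - depth[b]
            node[n + j] = f"({node[a]}:{la:.10g},{node[b]}:{lb:.10g})"
            depth[n + j] = h
        return node[n + len(self.linkage) - 1] + ";"


def upgma_tree(distances: MahalanobisMatrix | pd.DataFrame) -> UPGMATree:
    """Average-linkage (UPGMA) dendrogram of a distance matrix.

    Labels are sorted before clustering so tied merges resolve to the
    lexicographically first pair, making the tree deterministic.
    """
    dmat = distances.distances if isinstance(distances, MahalanobisMatrix) else distances
    labels = sorted(dmat.index)
    d = dmat.loc[labels, labels].to_numpy()
    link = hierarchy.average(squareform(d, checks=False))
    return UPGMATree(link, labels)
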