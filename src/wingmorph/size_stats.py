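"""Group comparisons of wing size and maximum-likelihood size classification.

Global size (centroid size for landmarks, first-ellipse semi-major axis for
outlines) is compared across populations with a one-way ANOVA and pairwise
permutation tests on the absolute difference of group means (1000 runs by
default, Bonferroni-corrected).  A leave-one-out "validated reclassification"
assigns each wing to the population whose Gaussian size density (fitted on
the training folds) it maximizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("wingmorph")

__all__ = ["pairwise_size_tests", "ml_size_classify", "SizeTestResult", "ClassificationResult"]


@dataclass
class SizeTestResult:
    anova_F: float
    anova_p: float
    pairwise_p: pd.DataFrame      # symmetric, NaN diagonal
    significant: pd.DataFrame     # at the Bonferroni-adjusted threshold
    bonferroni_alpha: float
    n_permutations: int
    seed: int


def pairwise_size_tests(
    cs_by_group: dict[str, np.ndarray],
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> SizeTestResult:
    """Permutation tests of |mean CS difference| for every population pair.

    p = (#{permuted statistic >= observed} + 1) / (n_perm + 1), the add-one
    convention, so p is never exactly zero.  Each pair draws from an RNG
    seeded by (seed, pair index) so results do not depend on pair order.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in cs_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    labels = list(groups)
    n_pairs = len(labels) * (len(labels) - 1) // 2
    bonf = alpha / n_pairs
    pmat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for pair_idx, (g1, g2) in enumerate(combinations(labels, 2)):
        x, y = groups[g1], groups[g2]
        if np.ptp(np.concatenate([x, y])) == 0:
            logger.warning("constant size in pair (%s, %s); p = 1", g1, g2)
            pmat.loc[g1, g2] = pmat.loc[g2, g1] = 1.0
            continue
        obs = abs(x.mean() - y.mean())
        pooled = np.concatenate([x, y])
        rng = np.random.default_rng([seed, pair_idx])
        # vectorised label permutation: permute columns of a (n_perm, n) index grid
        idx = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
        perm = pooled[idx]
        stat = np.abs(perm[:, : x.size].mean(axis=1) - perm[:, x.size:].mean(axis=1))
        p = (np.sum(stat >= obs - 1e-12) + 1) / (n_perm + 1)
        pmat.loc[g1, g2] = pmat.loc[g2, g1] = p
    f, p_anova = stats.f_oneway(*groups.values())
    return SizeTestResult(
        anova_F=float(f),
        anova_p=float(p_anova),
        pairwise_p=pmat,
        significant=pmat < bonf,
        bonferroni_alpha=bonf,
        n_permutations=n_perm,
        seed=seed,
    )


@dataclass
class ClassificationResult:
    confusion: pd.DataFrame       # true (rows) x assigned (columns) counts
    per_group_accuracy: dict[str, float]
    total_accuracy: float
    method: str
    validation: str = "leave_one_out"


def _confusion_result(truth: list[str], assigned: list[str], labels: list[str], method: str) -> ClassificationResult:
    conf = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for t, a in zip(truth, assigned):
        conf.loc[t, a] += 1
    per_group = {
        g: float(conf.loc[g, g] / conf.loc[g].sum()) if conf.loc[g].sum() else float("nan")
        for g in labels
    }
    total = float(np.trace(conf.to_numpy()) / conf.to_numpy().sum())
    return ClassificationResult(conf, per_group, total, method=method)


def ml_size_classify(cs_by_group: dict[str, np.ndarray]) -> ClassificationResult:
    """Leave-one-out maximum-likelihood classification on size alone.

    Per fold, each group's training sizes are summarised by a Normal(mean, sd)
    with its own sd; the held-out wing goes to the group with the highest
    density.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in cs_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if v.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 observations")
    labels = list(groups)
    truth: list[str] = []
    assigned: list[str] = []
    for g in labels:
        values = groups[g]
        for i in range(values.size):
            held = values[i]
            best, best_ll = None, -np.inf
            skip = False
            for h in labels:
                train = np.delete(groups[h], i) if h == g else groups[h]
                mu, sd = train.mean(), train.std(ddof=1)
                if sd == 0:
                    logger.warning("zero training variance in group %s; fold skipped", h)
                    skip = True
                    break
                ll = stats.norm.logpdf(held, loc=mu, scale=sd)
                if ll > best_ll:
                    best, best_ll = h, ll
            if not skip:
                truth.append(g)
                assigned.append(best)
    return _confusion_result(truth, assigned, labels, method="ml_size")
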