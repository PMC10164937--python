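"""Machine-learning classification of populations from shape features.

PCA exploration, the deterministic Kennard–Stone representative split,
PLS-DA (partial least squares regression onto one-hot class indicators,
prediction by nearest class centroid in latent space) with the component
count tuned by cross-validated balanced error rate (BER), and per-class
one-vs-rest ROC AUC with a Mann–Whitney rank p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "pca_summary",
    "kennard_stone_split",
    "fit_plsda",
    "auc_per_class",
    "PLSDAModel",
    "AUCReport",
]


def pca_summary(features: np.ndarray, n_axes: int | None = None):
    """Scores and explained-variance fractions of a (centered) feature matrix."""
    x = np.asarray(features, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need n >= 3 specimens")
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    ev = s**2
    if ev.sum() == 0:
        raise ValueError("constant feature matrix")
    frac = ev / ev.sum()
    if n_axes is None:
        n_axes = len(s)
    scores = u[:, :n_axes] * s[:n_axes]
    return scores, frac[:n_axes]


def kennard_stone_split(features: np.ndarray, train_fraction: float) -> tuple[list[int], list[int]]:
    """Deterministic Kennard–Stone max-min selection of a training subset.

    Features are standardized; the first two training points are the most
    distant pair, and each subsequent point maximizes its minimum Euclidean
    distance to the points already selected.  Ties break on the lower index.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    x = np.asarray(features, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need n >= 3")
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - x.mean(axis=0)) / sd
    n_train = max(2, int(round(train_fraction * n)))
    d = cdist(xs, xs)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    selected = [min(i, j), max(i, j)]
    min_d = np.minimum(d[selected[0]], d[selected[1]])
    while len(selected) < n_train:
        min_d[selected] = -np.inf
        nxt = int(np.argmax(min_d))
        selected.append(nxt)
        min_d = np.minimum(min_d, d[nxt])
    test = [i for i in range(n) if i not in set(selected)]
    return selected, test


@dataclass
class PLSDAModel:
    n_components: int
    classes: list[str]
    tuning_curve: pd.DataFrame      # columns: n_components, ber, ber_se
    chosen_by: str = "min_BER_1SE"
    x_mean: np.ndarray = field(default=None, repr=False)
    x_std: np.ndarray = field(default=None, repr=False)
    pls: PLSRegression = field(default=None, repr=False)
    centroids: np.ndarray = field(default=None, repr=False)  # (g, n_components)

    def transform(self, features: np.ndarray) -> np.ndarray:
        xs = (np.asarray(features, float) - self.x_mean) / self.x_std
        return self.pls.transform(xs)

    def decision_scores(self, features: np.ndarray) -> pd.DataFrame:
        """Per-class score = negative distance to the class centroid in latent
        space (monotone in the assignment rule)."""
        t = self.transform(features)
        d = cdist(t, self.centroids)
        return pd.DataFrame(-d, columns=self.classes)

    def predict(self, features: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(features).to_numpy()
        return np.asarray(self.classes)[np.argmax(scores, axis=1)]


def _one_hot(labels: np.ndarray, classes: list[str]) -> np.ndarray:
    return np.column_stack([(labels == c).astype(float) for c in classes])


def _fit_single(x: np.ndarray, labels: np.ndarray, classes: list[str], ncomp: int):
    mean, std = x.mean(axis=0), x.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    xs = (x - mean) / std
    pls = PLSRegression(n_components=ncomp, scale=False)
    pls.fit(xs, _one_hot(labels, classes))
    t = pls.transform(xs)
    centroids = np.stack([t[labels == c].mean(axis=0) for c in classes])
    return mean, std, pls, centroids


def _ber(truth: np.ndarray, pred: np.ndarray, classes: list[str]) -> float:
    errs = []
    for c in classes:
        mask = truth == c
        if mask.any():
            errs.append(float(np.mean(pred[mask] != c)))
    return float(np.mean(errs))


def fit_plsda(
    features: np.ndarray,
    labels,
    max_components: int = 10,
    cv_folds: int = 5,
    seed: int = 0,
) -> PLSDAModel:
    """Tune and fit a PLS-DA classifier.

    For each candidate component count the stratified-CV balanced error rate
    (mean over classes of the class-wise error) is estimated; the chosen
    count is the smallest one within one standard error of the minimum BER.
    The final model is refit on all provided data.
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = min(np.sum(labels == c) for c in classes)
    if counts < cv_folds:
        raise ValueError(f"smallest class has {counts} members; cannot stratify {cv_folds} folds")
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    max_components = min(max_components, rank)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(x, labels))
    rows = []
    for ncomp in range(1, max_components + 1):
        fold_bers = []
        for tr, te in folds:
            mean, std, pls, cents = _fit_single(x[tr], labels[tr], classes, ncomp)
            t = pls.transform((x[te] - mean) / std)
            pred = np.asarray(classes)[np.argmin(cdist(t, cents), axis=1)]
            fold_bers.append(_ber(labels[te], pred, classes))
        fold_bers = np.asarray(fold_bers)
        rows.append(
            {
                "n_components": ncomp,
                "ber": float(fold_bers.mean()),
                "ber_se": float(fold_bers.std(ddof=1) / np.sqrt(len(fold_bers))),
            }
        )
    curve = pd.DataFrame(rows)
    best = curve["ber"].min()
    thresh = best + curve.loc[curve["ber"].idxmin(), "ber_se"]
    chosen = int(curve.loc[curve["ber"] <= thresh, "n_components"].iloc[0])
    mean, std, pls, cents = _fit_single(x, labels, classes, chosen)
    return PLSDAModel(
        n_components=chosen,
        classes=classes,
        tuning_curve=curve,
        x_mean=mean,
        x_std=std,
        pls=pls,
        centroids=cents,
    )


@dataclass
class AUCReport:
    per_class_auc: dict[str, float]
    per_class_p: dict[str, float]
    n_components_used: int
    evaluation: str  # e.g. "training" or "held_out"


def auc_per_class(
    model: PLSDAModel,
    features: np.ndarray,
    labels,
    evaluation: str = "held_out",
) -> AUCReport:
    """One-vs-rest ROC AUC per class from the model's decision scores.

    The p-value is the one-sided Mann–Whitney rank test of the class's
    scores against the rest, the rank statistic underlying the AUC.
    """
    labels = np.asarray(labels)
    scores = model.decision_scores(features)
    aucs: dict[str, float] = {}
    ps: dict[str, float] = {}
    for c in model.classes:
        mask = labels == c
        if not mask.any():
            aucs[c] = float("nan")
            ps[c] = float("nan")
            continue
        s = scores[c].to_numpy()
        aucs[c] = float(roc_auc_score(mask.astype(int), s))
        res = stats.mannwhitneyu(s[mask], s[~mask], alternative="greater")
        ps[c] = float(res.pvalue)
    return AUCReport(aucs, ps, model.n_components, evaluation)
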