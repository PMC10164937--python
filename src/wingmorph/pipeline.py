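"""End-to-end analysis drivers tying the stages together.

``analyze_landmarks`` runs GPA -> relative warps -> size and shape
statistics -> PLS-DA on a landmark Dataset; ``analyze_outlines`` does the
same from NEF feature vectors with the first-ellipse semi-major axis as the
size variable; ``analyze_barcode`` summarises a sequence set and builds the
bootstrapped NJ tree.
"""

from __future__ import annotations

import numpy as np

from . import barcode as bc
from . import efa, gpa, plsda, shape_stats, size_stats
from .datatypes import Dataset, SequenceSet, split_by_group

__all__ = ["analyze_landmarks", "analyze_outlines", "analyze_barcode"]


def _shape_analyses(features: np.ndarray, labels, cs: np.ndarray, n_perm: int, seed: int) -> dict:
    out: dict = {}
    out["size_tests"] = size_stats.pairwise_size_tests(
        split_by_group(cs, labels), n_perm=n_perm, seed=seed
    )
    out["size_classification"] = size_stats.ml_size_classify(split_by_group(cs, labels))
    disc = shape_stats.cva(features, labels)
    out["cva"] = disc
    out["allometry"] = shape_stats.allometry_r2(disc, cs)
    out["mahalanobis"] = shape_stats.mahalanobis_with_permutation(
        features, labels, n_perm=n_perm, seed=seed
    )
    out["reclassification"] = shape_stats.crossval_reclassify(features, labels)
    out["dendrogram"] = shape_stats.upgma_tree(out["mahalanobis"])
    min_class = min(np.sum(np.asarray(labels) == g) for g in set(labels))
    folds = int(min(5, min_class))
    model = plsda.fit_plsda(features, labels, max_components=10, cv_folds=folds, seed=seed)
    out["plsda"] = model
    out["auc"] = plsda.auc_per_class(model, features, labels, evaluation="training")
    out["pca_variance"] = plsda.pca_summary(features)[1]
    return out


def analyze_landmarks(dataset: Dataset, n_perm: int = 1000, seed: int = 0) -> dict:
    res = gpa.gpa_align(dataset)
    warps = gpa.relative_warps(res)
    out = _shape_analyses(warps.scores, np.asarray(res.labels), res.cs, n_perm, seed)
    out["procrustes"] = res
    out["warps"] = warps
    return out


def analyze_outlines(
    dataset: Dataset,
    harmonics: int = efa.DEFAULT_HARMONICS,
    resample_to: int = 128,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    features, sizes, labels = [], [], []
    for contour in dataset.configurations:
        rs = efa.resample_contour(contour, resample_to)
        coeffs = efa.efa_decompose(rs, H=harmonics, normalize=True)
        features.append(efa.nef_feature_vector(coeffs))
        sizes.append(efa.outline_size_measures(rs).semi_major_1)
        labels.append(contour.specimen.population)
    out = _shape_analyses(
        np.asarray(features), np.asarray(labels), np.asarray(sizes), n_perm, seed
    )
    out["sizes"] = np.asarray(sizes)
    return out


def analyze_barcode(
    seqset: SequenceSet,
    n_boot: int = 1000,
    seed: int = 0,
    outgroup: str | None = None,
) -> dict:
    if not seqset.check_aligned():
        raise ValueError("sequences must be aligned")
    matrix = bc.k2p_matrix(seqset)
    summary = bc.group_distance_summary(seqset, n_boot=min(n_boot, 500), seed=seed)
    tree = bc.bootstrap_support(seqset, n_reps=n_boot, seed=seed, outgroup=outgroup)
    return {"k2p_matrix": matrix, "summary": summary, "tree": tree}
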