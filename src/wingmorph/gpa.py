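"""Generalized Procrustes analysis for landmark configurations.

Size is the centroid size CS = sqrt(sum of squared landmark distances to the
centroid), the standard isometric size estimator.  Shape is extracted by
generalized least-squares superimposition: every configuration is translated
to the origin, scaled to unit CS and rotated (rotation only — wings are all
right wings, so reflections are disallowed) to a consensus that is refined
iteratively.  "Relative warps" are the principal components of the aligned
coordinates and serve as the shape variables for all downstream statistics;
with no bending-energy weighting the score space is isometric to Procrustes
residual space.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from .datatypes import Dataset, LandmarkConfiguration

logger = logging.getLogger("wingmorph")

__all__ = ["centroid_size", "gpa_align", "relative_warps", "ProcrustesResult", "ShapeScores"]


class DegenerateConfigurationError(ValueError):
    pass


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size in the units of the input coordinates (mm here).

    Square root of the summed squared distances of the k landmarks to their
    centroid.  Translation-invariant; scales linearly with the configuration.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0.0:
        raise DegenerateConfigurationError("all landmarks coincide (centroid size 0)")
    return cs


def _center_scale(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    return centered / np.sqrt((centered**2).sum())


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rotation (det = +1, no reflection) taking source onto target.

    Kabsch solution via SVD of the cross-covariance, with the smallest
    singular direction flipped when the unconstrained optimum is a reflection.
    """
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


@dataclass
class ProcrustesResult:
    aligned: np.ndarray        # (n, k, 2), each unit centroid size
    consensus: np.ndarray      # (k, 2) mean shape, unit centroid size
    cs: np.ndarray             # (n,) centroid sizes in mm
    residuals: np.ndarray      # (n, k, 2) aligned - consensus(mean of aligned)
    iterations: int
    converged: bool
    specimen_ids: list[str] | None = None
    labels: list[str] | None = None


def gpa_align(
    dataset: Dataset | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Iterative GLS Procrustes superimposition.

    Each round rotates every (centred, unit-CS) configuration onto the current
    consensus, recomputes the consensus as the arithmetic mean and rescales it
    to unit CS; iteration stops when the consensus RMS change falls below
    ``tol``.  The total Procrustes sum of squares is non-increasing across
    rounds.
    """
    if isinstance(dataset, Dataset):
        coords = dataset.coordinate_array()
        ids = [c.specimen.id for c in dataset.configurations]
        labels = dataset.labels()
    else:
        coords = np.asarray(dataset, dtype=float)
        ids = labels = None
    n = coords.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")

    cs = np.array([centroid_size(c) for c in coords])
    shapes = np.stack([_center_scale(c) for c in coords])

    consensus = shapes[0].copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        aligned = np.stack([s @ optimal_rotation(s, consensus) for s in shapes])
        new_consensus = aligned.mean(axis=0)
        new_consensus = new_consensus / np.sqrt((new_consensus**2).sum())
        change = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        shapes = aligned
        if change < tol:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge in %d iterations", max_iter)

    mean_aligned = shapes.mean(axis=0)
    residuals = shapes - mean_aligned
    return ProcrustesResult(
        aligned=shapes,
        consensus=consensus,
        cs=cs,
        residuals=residuals,
        iterations=it,
        converged=converged,
        specimen_ids=ids,
        labels=labels,
    )


@dataclass
class ShapeScores:
    scores: np.ndarray              # (n, n_axes)
    explained_variance: np.ndarray  # (n_axes,), fractions of total
    n_axes: int
    labels: list[str] | None = None


def relative_warps(result: ProcrustesResult, n_axes: int | None = None) -> ShapeScores:
    """Principal components of the aligned coordinates (flattened to n x 2k).

    With all axes retained the scores are an isometric re-coordinatisation of
    the Procrustes residuals, so inter-specimen distances are preserved.
    """
    n, k, _ = result.aligned.shape
    x = result.aligned.reshape(n, 2 * k)
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    ev = s**2
    total = ev.sum()
    rank = int(np.sum(s > s[0] * 1e-12)) if total > 0 else 0
    if n_axes is None:
        n_axes = rank
    elif n_axes > rank:
        logger.warning("requested %d axes but rank is %d; truncating", n_axes, rank)
        n_axes = rank
    scores = u[:, :n_axes] * s[:n_axes]
    frac = ev / total if total > 0 else np.zeros_like(ev)
    return ShapeScores(
        scores=scores,
        explained_variance=frac[:n_axes],
        n_axes=n_axes,
        labels=result.labels,
    )
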