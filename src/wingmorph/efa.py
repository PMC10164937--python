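"""Elliptic Fourier analysis of closed wing-cell outlines.

A closed contour is parameterized by arc length and its x(t), y(t) series
decomposed into harmonic ellipses (Kuhl–Giardina formulation for polygonal
chains).  Normalized coefficients (NEF) remove translation, rotation, scale
and starting point: the first harmonic is rotated so its semi-major axis lies
along +x with the starting point on it (a1 = semi-major > 0, b1 = c1 = 0),
and all coefficients are divided by the semi-major length.  Size travels
out-of-band as :class:`OutlineSize` — square-root area, perimeter, and the
semi-major axis of the first ellipse, the latter serving as the outline
centroid-size analogue downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from .datatypes import OutlineContour

logger = logging.getLogger("wingmorph")

__all__ = [
    "resample_contour",
    "efa_decompose",
    "outline_size_measures",
    "reconstruct_contour",
    "nef_feature_vector",
    "EFACoefficients",
    "OutlineSize",
    "DEFAULT_HARMONICS",
]

# chosen so cumulative harmonic power >= 99% on synthetic wing-cell contours
DEFAULT_HARMONICS = 7


class AliasingError(ValueError):
    pass


def shoelace_area(points: np.ndarray) -> float:
    """Signed polygon area; positive for counter-clockwise traversal."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def perimeter(points: np.ndarray) -> float:
    closed = np.vstack([points, points[:1]])
    return float(np.sqrt((np.diff(closed, axis=0) ** 2).sum(axis=1)).sum())


def _as_points(contour: OutlineContour | np.ndarray) -> np.ndarray:
    if isinstance(contour, OutlineContour):
        return contour.points
    return np.asarray(contour, dtype=float)


def resample_contour(contour: OutlineContour | np.ndarray, m: int) -> OutlineContour | np.ndarray:
    """Resample to m points equally spaced by arc length, counter-clockwise.

    The first point is preserved (it anchors the first named landmark); a
    clockwise input is reversed before resampling.
    """
    pts = _as_points(contour)
    if m < 8:
        raise ValueError("need m >= 8 resampled points")
    if shoelace_area(pts) < 0:
        pts = np.vstack([pts[:1], pts[1:][::-1]])
    closed = np.vstack([pts, pts[:1]])
    seg = np.sqrt((np.diff(closed, axis=0) ** 2).sum(axis=1))
    total = seg.sum()
    if total == 0:
        raise ValueError("zero-length contour")
    t = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, m, endpoint=False)
    x = np.interp(targets, t, closed[:, 0])
    y = np.interp(targets, t, closed[:, 1])
    out = np.column_stack([x, y])
    if isinstance(contour, OutlineContour):
        return OutlineContour(contour.specimen, out, contour.anchor_landmarks, contour.outline_set)
    return out


@dataclass
class EFACoefficients:
    harmonics: np.ndarray       # (H, 4) rows (a_n, b_n, c_n, d_n)
    H: int
    normalized: bool
    dc: tuple[float, float]     # (A0, C0)
    scale: float = 1.0          # semi-major of harmonic 1 divided out when normalized

    @property
    def first_ellipse_axes(self) -> tuple[float, float]:
        """(semi-major, semi-minor) of the first harmonic ellipse."""
        m = self.harmonics[0].reshape(2, 2)
        s = np.linalg.svd(m, compute_uv=False)
        return float(s[0]), float(s[1])


def _raw_efa(points: np.ndarray, H: int) -> tuple[np.ndarray, tuple[float, float]]:
    closed = np.vstack([points, points[:1]])
    d = np.diff(closed, axis=0)
    dt = np.sqrt((d**2).sum(axis=1))
    keep = dt > 0
    d, dt = d[keep], dt[keep]
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    n = np.arange(1, H + 1)[:, None]
    phi = 2.0 * np.pi * t / T
    cos_d = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
    sin_d = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    coef = T / (2.0 * (n.ravel() ** 2) * np.pi**2)
    vx, vy = d[:, 0] / dt, d[:, 1] / dt
    a = coef * (cos_d @ vx)
    b = coef * (sin_d @ vx)
    c = coef * (cos_d @ vy)
    dd = coef * (sin_d @ vy)
    # DC term: mean of the piecewise-linear x(t), y(t) over one period
    seg_mean = 0.5 * (closed[:-1][keep] + closed[1:][keep])
    a0 = float((seg_mean[:, 0] * dt).sum() / T)
    c0 = float((seg_mean[:, 1] * dt).sum() / T)
    return np.column_stack([a, b, c, dd]), (a0, c0)


def _phase_shift(harm: np.ndarray, theta: float) -> np.ndarray:
    """Shift the starting point by parameter angle theta."""
    out = np.empty_like(harm)
    for i in range(harm.shape[0]):
        nth = (i + 1) * theta
        rot = np.array([[np.cos(nth), -np.sin(nth)], [np.sin(nth), np.cos(nth)]])
        out[i] = (harm[i].reshape(2, 2) @ rot).ravel()
    return out


def _spatial_rotate(harm: np.ndarray, psi: float) -> np.ndarray:
    rot = np.array([[np.cos(psi), np.sin(psi)], [-np.sin(psi), np.cos(psi)]])
    out = np.empty_like(harm)
    for i in range(harm.shape[0]):
        out[i] = (rot @ harm[i].reshape(2, 2)).ravel()
    return out


def _normalize(harm: np.ndarray) -> tuple[np.ndarray, float]:
    a1, b1, c1, d1 = harm[0]
    theta0 = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1), a1**2 + c1**2 - b1**2 - d1**2)
    candidates = []
    for j in range(4):
        theta = theta0 + j * np.pi / 2.0
        shifted = _phase_shift(harm, theta)
        major_sq = shifted[0, 0] ** 2 + shifted[0, 2] ** 2
        candidates.append((major_sq, shifted))
    best = max(c[0] for c in candidates)
    # keep the starting-point solutions on the semi-major axis (theta ambiguity
    # of pi remains); break the tie deterministically by the coefficient vector
    finalists = []
    for major_sq, shifted in candidates:
        if major_sq < best * (1.0 - 1e-9):
            continue
        psi = np.arctan2(shifted[0, 2], shifted[0, 0])
        rotated = _spatial_rotate(shifted, psi)
        finalists.append(rotated)
    norm = max(finalists, key=lambda h: tuple(np.round(h.ravel(), 9)))
    scale = norm[0, 0]  # semi-major of first ellipse
    return norm / scale, float(scale)


def efa_decompose(
    contour: OutlineContour | np.ndarray,
    H: int = DEFAULT_HARMONICS,
    normalize: bool = True,
) -> EFACoefficients:
    """Elliptic Fourier coefficients of a resampled closed contour."""
    pts = _as_points(contour)
    if H < 1:
        raise ValueError("need H >= 1 harmonics")
    if H > pts.shape[0] / 2:
        raise AliasingError(f"H={H} exceeds Nyquist limit m/2={pts.shape[0] / 2:g}")
    harm, dc = _raw_efa(pts, H)
    if not normalize:
        return EFACoefficients(harm, H, False, dc)
    norm, scale = _normalize(harm)
    return EFACoefficients(norm, H, True, dc, scale=scale)


@dataclass
class OutlineSize:
    sqrt_area: float
    perimeter: float
    semi_major_1: float


def outline_size_measures(
    contour: OutlineContour | np.ndarray,
    coeffs: EFACoefficients | None = None,
) -> OutlineSize:
    """The three outline size variables (all in mm).

    ``semi_major_1`` comes from the un-normalized first-harmonic ellipse and is
    the value downstream size statistics consume as the outline's centroid
    size.
    """
    pts = _as_points(contour)
    area = shoelace_area(pts)
    if area < 0:
        logger.warning("clockwise or self-intersecting contour; using |area|")
        area = abs(area)
    if coeffs is None or coeffs.normalized:
        coeffs = efa_decompose(pts, H=1, normalize=False)
    semi_major = coeffs.first_ellipse_axes[0] * (coeffs.scale if coeffs.normalized else 1.0)
    return OutlineSize(
        sqrt_area=float(np.sqrt(area)),
        perimeter=perimeter(pts),
        semi_major_1=float(semi_major),
    )


def reconstruct_contour(coeffs: EFACoefficients, m: int = 256) -> np.ndarray:
    """Inverse Fourier synthesis at m evenly spaced parameter values."""
    t = np.linspace(0.0, 2.0 * np.pi, m, endpoint=False)
    x = np.full(m, coeffs.dc[0] if not coeffs.normalized else 0.0)
    y = np.full(m, coeffs.dc[1] if not coeffs.normalized else 0.0)
    for i in range(coeffs.H):
        a, b, c, d = coeffs.harmonics[i]
        n = i + 1
        x = x + a * np.cos(n * t) + b * np.sin(n * t)
        y = y + c * np.cos(n * t) + d * np.sin(n * t)
    return np.column_stack([x, y])


def nef_feature_vector(coeffs: EFACoefficients) -> np.ndarray:
    """Flattened NEF shape features, omitting the three coefficients fixed by
    normalization (a1, b1, c1)."""
    if not coeffs.normalized:
        raise ValueError("feature vector requires normalized coefficients")
    flat = coeffs.harmonics.ravel()
    return flat[3:]  # drop a1 (=1), b1 (=0), c1 (=0); keep d1 onward
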