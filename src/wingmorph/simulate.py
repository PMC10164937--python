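"""Synthetic wing and sequence generators.

These generators emulate the statistical structure of a three-population
biting-midge wing study: three sites of ~20 wings each, distinct population
mean shapes (two sites shape-similar, one divergent), population size
differences (the second site's wings largest, the first's smallest), a
controllable allometric component, i.i.d. Gaussian landmark noise, and Cox1
sequence sets diverged under the Kimura 2-parameter substitution model.

Every generated quantity is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .datatypes import Dataset, LandmarkConfiguration, OutlineContour, SequenceSet, Specimen
from .gpa import centroid_size

__all__ = [
    "SyntheticConfig",
    "SequenceSimConfig",
    "simulate_landmark_dataset",
    "simulate_outline_dataset",
    "simulate_k2p_sequences",
    "ellipse_contour",
    "allometric_slope_for_r2",
    "base_wing_template",
    "ConfigError",
]


class ConfigError(ValueError):
    pass


def base_wing_template(k: int = 11) -> np.ndarray:
    """An elongate wing-like arrangement of k landmarks, centred, unit CS."""
    if k == 11:
        pts = np.array(
            [
                [0.05, 0.50], [0.30, 0.72], [0.60, 0.80], [0.90, 0.70],
                [1.00, 0.50], [0.88, 0.32], [0.65, 0.22], [0.42, 0.20],
                [0.25, 0.28], [0.12, 0.36], [0.45, 0.50],
            ]
        )
    else:  # points on a 2:1 ellipse
        t = np.linspace(0, 2 * np.pi, k, endpoint=False)
        pts = np.column_stack([np.cos(t), 0.5 * np.sin(t)])
    pts = pts - pts.mean(axis=0)
    return pts / centroid_size(pts)


def _similarity_complement_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis of flattened-shape directions orthogonal to the
    similarity transforms (x/y translation, rotation, scaling) at the
    template, so displacement fields are pure shape changes."""
    k = template.shape[0]
    flat = template.ravel()
    trans_x = np.tile([1.0, 0.0], k)
    trans_y = np.tile([0.0, 1.0], k)
    scale = flat.copy()
    rot = np.column_stack([-template[:, 1], template[:, 0]]).ravel()
    sim = np.stack([trans_x, trans_y, scale, rot])
    q, _ = np.linalg.qr(sim.T)
    proj = np.eye(2 * k) - q @ q.T
    return proj


def _default_fields(template: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two orthonormal shape-displacement fields plus the allometric field.

    Field A displaces the wing margin landmarks (shared by the two
    shape-similar populations); field B — also the allometric direction — is
    the divergent population's displacement.
    """
    k = template.shape[0]
    rng = np.random.default_rng(20230424)
    proj = _similarity_complement_basis(template)
    raw_a = proj @ rng.standard_normal(2 * k)
    raw_b = proj @ rng.standard_normal(2 * k)
    a = raw_a / np.linalg.norm(raw_a)
    b = raw_b - (raw_b @ a) * a
    b = b / np.linalg.norm(b)
    return a.reshape(k, 2), b.reshape(k, 2), b.reshape(k, 2)


@dataclass
class SyntheticConfig:
    """Study conditions for the landmark and outline generators.

    Defaults mirror the sampled design: three populations of 20/22/23
    wings, landmark centroid sizes Normal(1.363, 0.074), Normal(1.887,
    0.096) and Normal(1.6, 0.08) mm — the second population largest, the
    first smallest — with the second population's mean shape divergent
    from the other two.
    """

    n_per_group: tuple[int, ...] = (20, 22, 23)
    group_names: tuple[str, ...] = ("Corsica", "Moselle", "Var")
    k: int = 11
    group_cs_mean: tuple[float, ...] = (1.363, 1.887, 1.6)
    group_cs_sd: tuple[float, ...] = (0.074, 0.096, 0.08)
    shape_divergence: tuple[float, ...] = (0.012, 0.035, 0.018)
    allometric_slope: float = 0.04      # shape units per mm of CS deviation
    noise_sd: float = 0.006             # isotropic landmark noise, shape units
    outline_points: int = 100
    outline_axis_ratio: float = 0.55    # semi-minor / semi-major of cell template
    seed: int = 0
    group_templates: list | None = None       # per-group (k, 2) unit-CS templates
    allometric_direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        g = len(self.n_per_group)
        if len(self.group_names) != g or len(self.group_cs_mean) != g or len(self.group_cs_sd) != g:
            raise ConfigError("per-group settings must all have the same length")
        if len(self.shape_divergence) != g:
            raise ConfigError("shape_divergence must have one entry per group")
        if any(n < 3 for n in self.n_per_group):
            raise ConfigError("need n >= 3 per group")
        if any(s < 0 for s in self.group_cs_sd) or self.noise_sd < 0:
            raise ConfigError("standard deviations must be >= 0")

    def n_groups(self) -> int:
        return len(self.n_per_group)


def _resolve_templates(config: SyntheticConfig):
    base = base_wing_template(config.k)
    if np.allclose(base, base[0]):
        raise ConfigError("degenerate template: all points identical")
    field_a, field_b, allo = _default_fields(base)
    if config.allometric_direction is not None:
        allo = np.asarray(config.allometric_direction, float)
        allo = allo / np.linalg.norm(allo)
    if config.group_templates is not None:
        templates = [np.asarray(t, float) for t in config.group_templates]
        for t in templates:
            if np.allclose(t, t[0]):
                raise ConfigError("degenerate template: all points identical")
        return templates, allo
    # groups 1 and 3 displace along the shared field A, group 2 along B
    templates = []
    for gi, mag in enumerate(config.shape_divergence):
        direction = field_b if gi == 1 else field_a
        t = base + mag * direction
        t = t - t.mean(axis=0)
        templates.append(t / centroid_size(t))
    return templates, allo


def simulate_landmark_dataset(config: SyntheticConfig) -> Dataset:
    """Generate a landmark Dataset under the configured study conditions.

    Each wing is its population's unit-CS template plus an allometric
    displacement proportional to (CS - population mean CS) plus isotropic
    Gaussian landmark noise, scaled to a Normal centroid size and randomly
    rotated and translated.
    """
    templates, allo = _resolve_templates(config)
    rng = np.random.default_rng(config.seed)
    configs = []
    for gi, name in enumerate(config.group_names):
        for i in range(config.n_per_group[gi]):
            cs = rng.normal(config.group_cs_mean[gi], config.group_cs_sd[gi])
            shape = (
                templates[gi]
                + config.allometric_slope * (cs - config.group_cs_mean[gi]) * allo
                + config.noise_sd * rng.standard_normal((config.k, 2))
            )
            shape = shape - shape.mean(axis=0)
            shape = shape / centroid_size(shape) * cs
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
            coords = shape @ rot.T + rng.uniform(-5, 5, size=2)
            configs.append(
                LandmarkConfiguration(Specimen(f"{name}_{i + 1:03d}", name), coords)
            )
    ds = Dataset.from_configurations(configs)
    ds.validate()
    return ds


def ellipse_contour(a: float, b: float, m: int = 100, center=(0.0, 0.0)) -> np.ndarray:
    """Counter-clockwise ellipse with semi-axes (a, b), m points."""
    t = np.linspace(0, 2 * np.pi, m, endpoint=False)
    return np.column_stack([center[0] + a * np.cos(t), center[1] + b * np.sin(t)])


def _radial_template(config: SyntheticConfig, gi: int) -> np.ndarray:
    """Per-group radial profile r(phi) of the cell outline, unit semi-major.

    A polar ellipse carries a third-harmonic bulge whose phase is shared by
    groups 1 and 3 and shifted for group 2, with amplitude shape_divergence.
    """
    m = config.outline_points
    phi = np.linspace(0, 2 * np.pi, m, endpoint=False)
    ar = config.outline_axis_ratio
    r = ar / np.sqrt((ar * np.cos(phi)) ** 2 + np.sin(phi) ** 2)
    phase = 0.4 if gi == 1 else 2.2 + 0.15 * gi
    r = r * (1.0 + config.shape_divergence[gi] * np.cos(3 * phi + phase))
    return r


def simulate_outline_dataset(config: SyntheticConfig, max_retries: int = 10) -> Dataset:
    """Generate closed wing-cell contours as a Dataset of OutlineContour.

    Contours are star-shaped radial curves (so they cannot self-intersect
    while the radius stays positive); low-frequency radial noise perturbs
    each wing and the curve is scaled so that the drawn size value is its
    approximate semi-major axis, then randomly rotated and translated.
    """
    rng = np.random.default_rng(config.seed)
    m = config.outline_points
    phi = np.linspace(0, 2 * np.pi, m, endpoint=False)
    configs = []
    for gi, name in enumerate(config.group_names):
        base_r = _radial_template(config, gi)
        for i in range(config.n_per_group[gi]):
            size = rng.normal(config.group_cs_mean[gi], config.group_cs_sd[gi])
            for attempt in range(max_retries):
                noise = np.zeros(m)
                for h in range(2, 6):
                    amp = config.noise_sd * rng.standard_normal(2)
                    noise += amp[0] * np.cos(h * phi) + amp[1] * np.sin(h * phi)
                r = base_r * (1.0 + noise)
                if r.min() > 0.05:
                    break
            else:
                raise ConfigError("could not generate a positive-radius contour")
            pts = np.column_stack([r * np.cos(phi), r * np.sin(phi)]) * size
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
            pts = pts @ rot.T + rng.uniform(-2, 2, size=2)
            configs.append(
                OutlineContour(
                    Specimen(f"{name}_{i + 1:03d}", name),
                    pts,
                    outline_set="custom",
                )
            )
    ds = Dataset.from_configurations(configs)
    ds.validate()
    return ds


def allometric_slope_for_r2(
    target_r2: float,
    config: SyntheticConfig,
) -> tuple[float, list[np.ndarray]]:
    """Slope and aligned group templates giving an expected DF1-on-CS r².

    Constructs all group mean shapes displaced along the allometric
    direction by slope * (group mean CS - grand mean CS), so the shape
    projection onto that axis is exactly linear in CS with residual variance
    noise_sd².  Returns (slope, group_templates) to plug into the config.
    """
    if not 0 < target_r2 < 1:
        raise ConfigError("target_r2 must be in (0, 1)")
    n = np.asarray(config.n_per_group, float)
    mu = np.asarray(config.group_cs_mean, float)
    sd = np.asarray(config.group_cs_sd, float)
    w = n / n.sum()
    grand = float(w @ mu)
    var_cs = float(w @ (sd**2) + w @ ((mu - grand) ** 2))
    slope = (config.noise_sd / np.sqrt(var_cs)) * np.sqrt(target_r2 / (1 - target_r2))
    base = base_wing_template(config.k)
    _, _, allo = _default_fields(base)
    templates = []
    for g in range(len(mu)):
        t = base + slope * (mu[g] - grand) * allo
        templates.append(t)
    return float(slope), templates


@dataclass
class SequenceSimConfig:
    """Study conditions for the K2P sequence generator.

    ``within_group_divergence`` and ``between_group_divergence`` are expected
    pairwise K2P distances; between may be a scalar (all pairs) or a mapping
    of group-name pairs.
    """

    group_sizes: tuple[int, ...] = (13, 10, 10)
    group_names: tuple[str, ...] = ("Corsica", "Moselle", "Var")
    length: int = 401
    within_group_divergence: tuple[float, ...] = (0.020, 0.001, 0.014)
    between_group_divergence: float | dict = 0.022
    transition_transversion_ratio: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ConfigError("length must be >= 1")
        if any(w < 0 for w in self.within_group_divergence):
            raise ConfigError("divergences must be >= 0")
        if len(self.group_sizes) != len(self.group_names):
            raise ConfigError("group_sizes and group_names must match")

    def between(self, g1: str, g2: str) -> float:
        if isinstance(self.between_group_divergence, dict):
            key = (g1, g2) if (g1, g2) in self.between_group_divergence else (g2, g1)
            return float(self.between_group_divergence[key])
        return float(self.between_group_divergence)


_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _k2p_site_probs(d: float, ratio: float) -> tuple[float, float]:
    """Per-site transition (P) and transversion (Q) probabilities after
    evolving an expected distance d with transition/transversion ratio R."""
    at = d * ratio / (ratio + 1.0)
    bt = d / (2.0 * (ratio + 1.0))
    p = 0.25 - 0.5 * np.exp(-2.0 * (at + bt)) + 0.25 * np.exp(-4.0 * bt)
    q = 0.5 - 0.5 * np.exp(-4.0 * bt)
    return float(p), float(q)


def _evolve(seq: np.ndarray, d: float, ratio: float, rng: np.random.Generator) -> np.ndarray:
    if d == 0:
        return seq.copy()
    p, q = _k2p_site_probs(d, ratio)
    if 1.0 - 2.0 * p - q <= 0 or 1.0 - 2.0 * q <= 0:
        raise ConfigError(f"divergence {d} beyond K2P saturation")
    u = rng.random(seq.size)
    out = seq.copy()
    ts_mask = u < p
    tv_mask = (u >= p) & (u < p + q)
    for i in np.where(ts_mask)[0]:
        out[i] = _TRANSITION[out[i]]
    pick = rng.integers(0, 2, size=tv_mask.sum())
    for j, i in enumerate(np.where(tv_mask)[0]):
        out[i] = _TRANSVERSIONS[out[i]][pick[j]]
    return out


def simulate_k2p_sequences(config: SequenceSimConfig) -> SequenceSet:
    """Sequence sets whose expected pairwise K2P distances match the config.

    A star phylogeny: per-group ancestors at branch lengths solved from the
    three-point formulas on the between-group targets (minus the within
    contribution), tips at within/2 from their ancestor.  Substitutions are
    i.i.d. per site with the configured transition/transversion ratio.
    """
    names = list(config.group_names)
    w = dict(zip(names, config.within_group_divergence))
    # corrected between-target net of tip branches
    bp = {}
    for g1, g2 in combinations(names, 2):
        bp[(g1, g2)] = config.between(g1, g2) - 0.5 * (w[g1] + w[g2])
    branch = {}
    if len(names) == 2:
        g1, g2 = names
        branch[g1] = branch[g2] = bp[(g1, g2)] / 2.0
    else:
        for g in names:
            others = [h for h in names if h != g]
            total = 0.0
            for h in others:
                total += bp.get((g, h), bp.get((h, g)))
            rest = bp.get((others[0], others[1]), bp.get((others[1], others[0])))
            branch[g] = 0.5 * (total - rest) if len(others) == 2 else total / len(others)
    for g, b in branch.items():
        if b < -1e-12:
            raise ConfigError(
                f"between-group divergence too small relative to within for group {g!r}"
            )
        branch[g] = max(b, 0.0)
    rng = np.random.default_rng(config.seed)
    root = _BASES[rng.integers(0, 4, size=config.length)]
    records = []
    ratio = config.transition_transversion_ratio
    for gi, name in enumerate(names):
        ancestor = _evolve(root, branch[name], ratio, rng)
        for i in range(config.group_sizes[gi]):
            tip = _evolve(ancestor, w[name] / 2.0, ratio, rng)
            records.append((f"{name}_{i + 1:03d}", name, "".join(tip)))
    out = SequenceSet(records=records)
    out.check_aligned()
    return out
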