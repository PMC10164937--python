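# Methods

This note documents the statistical machinery, the synthetic study
conditions, the numerical conventions, and the design choices that were
genuinely open.

## Landmark shape and size

**Centroid size.** CS = √Σᵢ‖xᵢ − x̄‖² over the k = 11 landmarks, in mm.
It is the standard isometric size estimator: translation- and
rotation-invariant, linear in scale.

**Generalized Procrustes analysis.** Configurations are centred, scaled to
unit CS and rotated to a consensus by the least-squares (Kabsch) rotation;
the consensus is recomputed as the arithmetic mean, rescaled to unit CS
(fixing the scale gauge), and iteration continues until the consensus RMS
change falls below 1e-10 (max 100 rounds, `converged` flagged otherwise).
Two conventions matter:

- *Reflections are disallowed* (rotation determinant constrained to +1).
  All wings in the emulated design are right wings; a mirror-image
  configuration should register as genuinely different.
- *No tangent-space projection.* Conspecific wing variation is small, so
  aligned coordinates are used directly; this is an approximation of order
  (Procrustes distance)², negligible here.

**Relative warps** are the principal components of the aligned coordinate
matrix (n × 2k, mean-centred), with no bending-energy weighting (α = 0).
With α = 0 the score space is exactly isometric to Procrustes residual
space (verified by a test), so downstream Mahalanobis statistics are
identical whether computed on residuals or on warp scores; partial warps
are never materialized.

## Outline shape and size

Closed wing-cell contours are resampled to equal arc-length spacing
(counter-clockwise, first point preserved as the anchor landmark) and
decomposed into elliptic Fourier harmonics using the Kuhl–Giardina
polygonal-chain formulation. Normalization (NEF) removes translation (DC
term dropped), starting point and rotation (the first-harmonic ellipse is
rotated so its semi-major axis lies along +x with the start point on it:
a₁ > 0, b₁ = c₁ = 0) and scale (division by the semi-major length). The
π ambiguity of the starting-point phase is resolved deterministically by
taking the candidate with the lexicographically largest rounded coefficient
vector; for near-circular first harmonics this choice is arbitrary but
stable. The downstream shape feature vector is the flattened normalized
coefficients of harmonics 1..H minus the three coefficients fixed by
normalization.

*Harmonic count.* Default H = 7, chosen so cumulative harmonic power
exceeds 99% on the synthetic wing-cell contours; configurable.

*Parameterization caveat.* Under arc-length parameterization the first
harmonic of a non-circular ellipse is **not** the geometric ellipse: a 2:1
ellipse yields first-harmonic semi-axes (1.8284, 1.0730), confirmed against
an independent dense quadrature oracle. Only for circles do the two
coincide. Similarly, the Fourier coefficients are the exact series of the
piecewise-linear contour, so reconstruction truncated at the Nyquist count
retains a ~1/n² tail (relative RMSE ≈ 5e-5 at H = m/2) rather than being
machine-exact.

*Outline size.* Three measures are computed — √(shoelace area), perimeter,
and the semi-major axis of the un-normalized first harmonic. The semi-major
axis serves as the outline CS in all downstream size statistics; the other
two are reported alongside.

## Size statistics

Pairwise population differences in CS use a permutation test on the
absolute difference of group means (default 1000 runs), with the add-one
convention p = (#{permuted ≥ observed} + 1)/(n_perm + 1) so p is never 0,
and Bonferroni correction α = 0.05 / #pairs. Permutations for each pair are
seeded by (seed, pair index), making results independent of pair order. A
one-way ANOVA (scipy) summarises the global difference. The choice of the
mean-difference statistic (rather than a studentized one) matches the
one-dimensional CS comparison; the add-one test is exact at level c/(n+1).

Size-based classification is leave-one-out maximum likelihood: per fold
each population's training CS is summarised by Normal(mean, sd) with its own
sd (not pooled), and the held-out wing is assigned to the density-maximizing
population. Leave-one-out is the natural "validated reclassification" scheme
at n ≈ 20 per group.

## Shape statistics

**Canonical variate analysis.** Axes solve Bv = λWv (B between-group, W
pooled within-group covariance, whitening + symmetric eigendecomposition)
and are scaled so DF scores have identity pooled within-group covariance.
With g groups there are min(g−1, p) factors and their contributions (λ
fractions) sum to 100%.

**Singularity policy.** NEF vectors (and occasionally warp scores) can
exceed the rank the relevant pooled covariance supports — routine at
n ≈ 20 wings per site. Features are then projected onto the principal
components covering 99% of variance, further capped by the rank bound of
the consumer: n − g for CVA, the smallest pair's n₁+n₂−2 for pairwise
Mahalanobis, n − 1 − g for leave-one-out folds. Full-rank inputs below the
bound pass through untouched; Mahalanobis quantities are invariant to this
reduction (tested under random invertible feature maps).

**Mahalanobis distances** between group means use the pair-pooled
within-group covariance; p-values permute labels within the pair and
recompute the distance (add-one convention, 1000 permutations by default).
Leave-one-out reclassification refits group means and the pooled covariance
per fold and assigns by nearest Mahalanobis distance.

**Allometry** is the r² of the OLS regression of DF1 (optionally DF2) on
CS. It is quantified but *not* removed by default; an explicit
size-correction (residual shape) mode is deliberately out of the default
path since the emulated analyses report residual size influence rather than
correcting for it.

**Dendrograms** are UPGMA (average linkage) on the population Mahalanobis
matrix via scipy; labels are sorted before clustering so ties merge
lexicographically-first, and Newick export writes ultrametric branch
lengths (node height = merge distance / 2).

## PLS-DA

Features are standardized and regressed onto one-hot class indicators with
sklearn's PLS; prediction assigns the nearest class centroid in latent
space (equivalent to the max-score rule for these models). The component
count is tuned by stratified 5-fold cross-validated balanced error rate
(mean over classes of the class-wise error); the chosen count is the
smallest within one standard error of the minimum BER, a standard
parsimony tie-break. Per-class one-vs-rest AUC is computed from the model's
decision scores, with a one-sided Mann–Whitney rank p-value (the rank
statistic underlying the AUC); the report labels whether evaluation used
training or held-out data. The Kennard–Stone split (deterministic max-min
selection on standardized Euclidean distances) is provided for
representative train/test partitioning.

## Barcode analysis

K2P distances use pairwise deletion of gap/ambiguous sites (ambiguity codes
other than ACGT are treated as missing), matching the common
distance-analysis default of MEGA-style tools. Within- and
between-population means are averaged over all pairs; standard errors come
from a seeded site bootstrap (500 replicates by default). The barcode gap is
reported globally (min between-mean − max within-mean) and per population
(its smallest between-mean minus its own within-mean). Neighbor joining is
the Saitou–Nei Q-criterion algorithm; negative branch lengths are clamped
to zero with the deficit transferred to the sister branch; trees are
unrooted (trifurcating root) unless an outgroup is given, in which case the
root is placed at the midpoint of the outgroup's terminal branch.
Bipartition bootstrap support resamples alignment columns, rebuilds
K2P + NJ per replicate, and reports the percentage of replicates containing
each original bipartition; saturated replicates are skipped and counted.
Tree building is intentionally NJ-only; likelihood phylogenetics is out of
scope.

## Synthetic study conditions

`SyntheticConfig` defaults define the emulated design and are not tuning
knobs:

- three populations ("Corsica", "Moselle", "Var") of 20/22/23 wings;
- landmark CS drawn from Normal(1.363, 0.074), Normal(1.887, 0.096) and
  Normal(1.6, 0.08) mm — the second population largest, the first smallest;
- 11 landmarks; per-population mean shapes are a shared wing-like template
  displaced along fixed orthonormal shape fields (orthogonalized against
  the similarity transforms so displacements are pure shape):
  populations 1 and 3 share a displacement direction (magnitudes
  0.012/0.018), population 2 diverges along its own direction (0.035),
  making the "1 with 3, apart from 2" dendrogram topology a recoverable
  ground truth;
- allometry is a linear shape displacement along one fixed direction,
  slope × (CS − population mean CS); the default slope 0.04/mm, with
  population 2's divergence direction equal to the allometric direction,
  puts the DF1-on-CS r² in the strong-allometry regime the landmark
  analyses report. `allometric_slope_for_r2` constructs slope + templates
  for an exact expected r² (used by the parameter-recovery tests);
- isotropic Gaussian landmark noise, sd 0.006 shape units — a free
  parameter with no empirical anchor (digitization error is never
  reported); chosen so shape classification is good but imperfect,
  mirroring published reclassification scores;
- outlines are star-shaped radial curves (polar ellipse, axis ratio 0.55,
  with a population-specific third-harmonic bulge), perturbed by
  low-frequency radial noise — star-shapedness guarantees simple closed
  curves while the radius stays positive (bounded retries otherwise);
- sequences evolve on a star phylogeny under per-site K2P substitution
  (transition/transversion ratio 2.0 by default, no rate heterogeneity —
  the distance analysis assumes none): per-population ancestors at branch
  lengths solved from the between-population targets by the three-point
  formulas, tips at within/2. Expected pairwise K2P distances equal the
  configured targets (verified by a 200-replicate recovery test). Defaults:
  401 bp, within 0.020/0.001/0.014, between 0.022.

What the generators do **not** emulate: digitization artifacts with
spatial structure, measurement covariance between neighbouring landmarks,
left/right asymmetry, sexual dimorphism, indels, rate heterogeneity or
coalescent population structure. Passing tests therefore demonstrate that
the *pipeline* recovers known truth under its stated model, not that real
wings satisfy that model.

## Problem sizes and tolerances

Statistical calibration tests use 2000 null replicates for the permutation
test's type-I error (199 permutations per replicate — the add-one test is
exact at level 10/200 = 0.05, so the reduced count affects granularity
only), 200–500 samples for chance-level classifier checks (tolerance
±0.07), and 30 replicates for the ≥95% recovery checks (pass bar 29/30).
The molecular recovery test averages 10 replicate sequence sets; the
acceptance script averages 20 (within one set all pairwise distances share
ancestral substitutions, so single-set summaries are noisy while replicate
means are unbiased — verified over 150 replicates). Geometric identities
are asserted at 1e-9..1e-6 depending on discretization; NEF invariance at
1e-6 requires ≥512 resampled points.

## Known limitations

- Outline anchors are positional conventions, not verified homologies;
  `anchor_landmarks` is metadata.
- The EFA normalization's lexicographic tie-break can switch branches for
  contours whose first harmonic is nearly circular.
- The NJ implementation is O(n³) and intended for tens of taxa.
- PLS-DA AUCs evaluated on training data (as the default report does at
  these sample sizes) are optimistic; the report carries an explicit
  `evaluation` field.
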