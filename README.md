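# wingmorph

Wing geometric morphometrics and mtDNA barcoding for discriminating insect
populations — built around the kind of study design used for biting-midge
(*Culicoides*) surveillance: three field populations, ~20 female wings each,
11 anatomical landmarks plus two closed wing-cell outlines per wing, and a
set of Cox1 barcode sequences per population.

The package answers two questions. **Do the populations differ in wing size
and shape, and which wing descriptor separates them best?** Size is the
centroid size CS = √Σᵢ‖xᵢ − x̄‖² for landmarks, or the semi-major axis of
the first Fourier ellipse for outlines; shape comes from generalized
Procrustes analysis (GPA) of landmarks or normalized elliptic Fourier
coefficients (NEF) of outlines. Sizes are compared by one-way ANOVA and
pairwise permutation tests with Bonferroni correction, and by a leave-one-out
maximum-likelihood classifier. Shapes are compared by canonical variate
analysis (discriminant factors DF1, DF2), pairwise Mahalanobis distances
D = [(m₁−m₂)ᵀ S⁻¹ (m₁−m₂)]^½ with permutation p-values, leave-one-out
validated reclassification, an allometry summary (r² of DF1 regressed on
CS), UPGMA dendrograms, and a PLS-DA classifier tuned by cross-validated
balanced error rate with per-class ROC AUC. **Do the same populations
diverge genetically?** Kimura 2-parameter distances
d = −½ln(1−2P−Q) − ¼ln(1−2Q), within/between-population summaries with the
barcode gap, and bootstrapped neighbor-joining trees.

Because wing-coordinate data from such studies are rarely deposited, the
package ships first-class synthetic generators (`wingmorph.simulate`) that
emulate the study conditions — population-specific mean shapes, size
differences, a controllable allometric component, Gaussian landmark noise,
and K2P-diverged sequence sets — so every stage is testable end to end.

## Worked example

```python
from wingmorph.simulate import SyntheticConfig, simulate_landmark_dataset
from wingmorph import pipeline

ds = simulate_landmark_dataset(SyntheticConfig(seed=1))   # 3 populations, 65 wings
res = pipeline.analyze_landmarks(ds, n_perm=1000, seed=1)

print(res["size_tests"].pairwise_p.round(4))
print(f"size LOO accuracy: {res['size_classification'].total_accuracy:.1%}")
print(f"shape LOO accuracy: {res['reclassification'].total_accuracy:.1%}")
print(f"allometry r2 (DF1 ~ CS): {res['allometry'].r2:.3f}")
print(res["mahalanobis"].distances.round(2))
print(res["dendrogram"].to_newick())
```

prints

```
         Corsica  Moselle    Var
Corsica      NaN    0.001  0.001
Moselle    0.001      NaN  0.001
Var        0.001    0.001    NaN
size LOO accuracy: 95.4%
shape LOO accuracy: 67.7%
allometry r2 (DF1 ~ CS): 0.572
         Corsica  Moselle   Var
Corsica     0.00     8.42  2.39
Moselle     8.42     0.00  5.91
Var         2.39     5.91  0.00
(Moselle:3.58434936,(Corsica:1.19335572,Var:1.19335572):2.39099364);
```

All three pairwise size differences are significant at the minimum
attainable permutation p (1/1001, printed 0.001). Wing size alone
reclassifies 95% of wings; Procrustes shape reclassifies 68%, with the
largest Mahalanobis distance between the divergent population (Moselle) and
the others — and the dendrogram accordingly joins Corsica with Var before
Moselle. The allometry r² means 57% of DF1 variance is shared with size.

The same interface exists for outlines (`pipeline.analyze_outlines`, fed by
`simulate_outline_dataset`) and barcodes (`pipeline.analyze_barcode`, fed by
`simulate_k2p_sequences` or any aligned FASTA).

A thin CLI wraps these drivers:

```sh
wingmorph simulate --kind landmarks --seed 1 --out data/
wingmorph run --config run.yaml
wingmorph barcode --fasta cox1.fasta --out results/ --bootstrap 1000 --seed 1
```

Every subcommand writes a `run_manifest.json` with its parameters and seed.

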