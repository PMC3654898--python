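# Methods

## The model

`amylpot` models short aggregating peptides at the level of single-residue,
single-position statistics. The unit of analysis is the hexapeptide:
six-residue peptides are the standard experimental vehicle for growing
amyloid fibrils, and the two experimental classes — fibril formers
("amyloid") and homologous peptides that only form amorphous β-aggregates
("non-amyloid") — can differ by a single substitution, so the discriminating
signal is positional, not compositional alone.

For a labeled class of hexapeptides the derivation chain is:

1. **Positional composition.** `Comp(i,j) = 100 · n(i,j) / N(j)` — the
   percentage of class peptides carrying residue `i` at position `j`
   (`j = 1..6` from the amino terminus). `N(j)` equals the number of
   peptides for every `j`.
2. **Propensity.** `Propen(i,j) = Comp(i,j) / Comp_glob(i)`, normalizing by
   the bundled background composition of globular proteins (percent units on
   both sides, so the ratio is dimensionless). The identity
   `Σ_i Propen(i,j)·Comp_glob(i) = 100` holds at every position for any
   dataset and is property-tested.
3. **Statistical potential.** `φ(i,j) = −RT · ln Propen(i,j)` in kcal/mol.
   Negative energies mark residues favored at a position.

A hexapeptide `k` is scored under a class matrix by the position-additive
total `φ_tot(k) = Σ_j φ(r_j, j)`, and discriminated by the differential

    Δφ(k) = φ_tot(k | amyloid) − φ_tot(k | non-amyloid),

with `Δφ < 0` calling the peptide an amyloid former. A tie (`Δφ = 0`,
which occurs e.g. when both matrices are identical) is deliberately called
non-amyloid: the rule's favorable direction is reserved for strictly
negative differentials. The same scorer slides a six-residue window along
full-length protein sequences to flag candidate aggregation-prone regions;
windows are reported individually (0-based half-open starts, plus 1-based
display coordinates) with no merging or smoothing of overlapping windows —
the model defines none.

## Parameters that matter

- **RT = 0.6 kcal/mol** (≈300 K), configurable. The published preference
  thresholds — propensity ≥ 1.2 "preferred", ≤ 0.8 "avoided" — map under
  this value to energies ≤ −0.109 and ≥ +0.134 kcal/mol, and the bundled
  matrices are consistent with exactly these cutoffs (e.g. Tyr at amyloid
  position 6, −0.112, is preferred while Phe at position 1, −0.060, is
  not). 0.6 is the unique round value with this property.
- **Preference thresholds 1.2 / 0.8** (dimensionless propensities),
  configurable via `PreferenceThresholds`. The published "avoided" lists
  are subsets of what the ≤ 0.8 rule yields (the listing criterion for the
  published tables is not stated), so tests assert one-directional
  containment only.
- **Zero-count cells.** `ln 0` is undefined; residues never observed at a
  position carry potential exactly 0.000 with an `observed=False` flag so
  they are distinguishable from true propensity-1 cells. When a potential
  matrix is read from a file (including the bundled ones) a cell that is
  exactly 0.000 is taken as unobserved — the printed matrices carry no
  flags, and some zero cells may in truth be propensity-1; this ambiguity
  is inherent to the 3-decimal published format. No pseudo-count is applied
  by default (matching the published matrices); `pseudo > 0` is available
  for derivations from small samples and marks every cell observed.
- **Normalization mode.** Only background-composition normalization is
  implemented and tested; normalizing by a set's own overall composition or
  by β-strand propensity are alternatives the method's authors considered
  and rejected, and this package follows the chosen mode.
- **Energy-differential distributions** default to bin width 0.2 kcal/mol
  on a grid anchored at 0, so the conventional cutoff −0.2 kcal/mol is a
  bin edge; the cutoff comparison is inclusive (`≤`), keeping edge values
  in the favorable tail. Both are configurable.
- **Property scales.** Totals are sums of six per-residue values. The
  bundled retention-time hydrophobicity coefficients define the total
  hydrophobicity `H_T`. Class summaries report sample standard deviation
  (ddof = 1). The shipped scale file also carries an isoelectric-point
  scale (Zimmerman, external literature values) and
  `long_range_energy_synthetic`, a synthetic stand-in for a long-range
  non-bonded contact-energy scale whose published values are not bundled;
  it exists so the three-property feature vector is complete, and no test
  or result depends on its specific values. Placeholder rows for a wider
  49-property compilation are included for users to fill in; placeholders
  are listed but unusable until complete.
- **Random forest**: 100 trees, unlimited depth, √p features per split,
  majority vote, deterministic given a seed. The default feature vector is
  the 12 per-position energies under both matrices plus the three property
  totals (15 features); 12-feature energy-only and 6-feature Δ-energy
  modes are options. Cross-validation is stratified k-fold (k = 5, 10, 20
  in the standard protocol) with metrics computed from confusion counts
  pooled across folds, the convention of the workbench tools this harness
  mirrors; per-fold counts are also reported.

## The synthetic generator

The published 139/168 peptide compilation is assembled from other studies'
supplements and is not redistributable here, so the package generates
synthetic datasets with known class-conditional position biases. The
generator inverts the derivation chain: residue `i` appears at position `j`
of class `c` with probability proportional to
`Comp_glob(i) · exp(−φ_c(i,j) / (RT·τ))`, renormalized per position.
Positions are sampled independently — the scoring model is strictly
position-additive, with residue-pair terms out of scope — and `τ = 1`
reproduces the bundled matrices' bias strength while large `τ` recovers the
background composition. Unobserved cells sample at background weight
(`exp(0) = 1`), consistent with the zero-handling convention above.
Default class sizes are 139/168, the sizes of the experimental
compilations; the evaluation experiments below use larger sizes chosen for
statistical resolution.

What the generator does *not* emulate: the single-substitution homology
structure of the real compilations (real non-amyloid peptides are mutants
of amyloid parents, so the real classes are far more entangled than
position-independent sampling produces), residue-pair correlations, and
experimental label noise (peptides mislabeled non-amyloid for kinetic
reasons). Passing synthetic benchmarks therefore demonstrates correctness
of the machinery, not real-data accuracy.

## Identifiability and the recovery experiment

Position probabilities normalize, so potentials are identifiable only up to
a per-position additive constant: sampling from a matrix `φ` and re-deriving
converges not to `φ` but to `φ(i,j) + RT·ln(W_j/100)` where `W_j` is the
position's Boltzmann weight sum. For matrices derived from real counts
`W_j = 100` exactly and the distinction vanishes, but the bundled amyloid
block has many unobserved cells re-entering at background weight, making
the offset material (up to ~0.3 kcal/mol at some positions).
`recovery_experiment` therefore measures per-cell deviations against this
large-sample limit; with 5,000 peptides per class, cells with expected
count ≥ 50 are recovered to well under 0.1 kcal/mol mean absolute deviation
(per-cell sampling error is ≈ RT/√count). Cells below the expected-count
bar are reported as high-variance rather than judged.

The same normalization offset explains a subtlety of the discriminator:
the Δφ sign rule is the exact equal-prior maximum-likelihood classifier of
the generative model *when its matrices are derived from data* (the per-
position normalizers then cancel algebraically, cell for cell, against the
empirical class probabilities — the package's likelihood-ratio reference
classifier uses the same zero-count convention, background probability, so
the identity is exact and is asserted call-for-call on held-out samples).
With the bundled matrices as published, the per-class normalizer sums
differ and the sign rule's threshold is shifted slightly off the Bayes
point; the random forest, which learns its threshold from data, can
therefore sit between the published rule's accuracy and the Bayes rate
depending on the sample drawn.

## Evaluation problem sizes

The shipped experiments use 5,000 peptides per class for derivation-
recovery and the sign-rule/likelihood identity (10,000 held-out peptides),
and 500 per class for 10-fold cross-validation — sizes at which per-cell
expected counts clear the reliability bar and accuracy estimates resolve to
about one percentage point, while the full test suite and the acceptance
script each run in well under a minute.

## Known limitations

- The published headline rates (89% amyloid recall, 54% non-amyloid, the
  82.7/81.3/83.9 cross-validation figures, class-average `H_T` 251.1/217.6)
  depend on the original experimental compilation and are not reproducible
  from the bundled constants alone. Users who reconstruct that compilation
  from the original supplements can check them directly:
  `classify_dataset` with the bundled matrices should identify ≈123 of the
  139 amyloid peptides. This is documented as an external-data check only.
- Scores are position-additive; cooperative or pair effects between
  positions are not modeled.
- The scanner reports raw windows; aggregating overlapping windows into
  merged aggregation-prone intervals is left to the user.
- The strict 20-letter alphabet rejects ambiguity codes rather than
  imputing them; sequences containing B/Z/X/U must be cleaned upstream.
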