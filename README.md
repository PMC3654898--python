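# amylpot

Position-specific statistical energy potentials for telling apart
hexapeptides that form **amyloid fibrils** from close homologues that only
form **amorphous β-aggregates**.

Short 5–9 residue segments (aggregation-prone regions, APRs) drive amyloid
formation in proteins, and six-residue peptides are the standard
experimental system for studying them: a single substitution can switch a
fibril former into a non-former. `amylpot` is for computational biologists
and protein engineers who want to (a) derive position-specific potentials
from their own labeled hexapeptide sets, (b) score peptides and scan
protein sequences with the bundled published potential matrices, and
(c) benchmark statistical and machine-learning discriminators on data with
known structure.

## The model

For a class of labeled hexapeptides, the composition of residue *i* at
position *j* (percent, *j* = 1..6) is normalized by the background
composition of globular proteins to give a propensity, then
Boltzmann-inverted into an energy:

    Propen(i,j) = Comp(i,j) / Comp_glob(i)
    φ(i,j)      = −RT · ln Propen(i,j)        (RT = 0.6 kcal/mol)

A peptide *k* is scored by the position sum φ_tot(k) = Σ_j φ(r_j, j) under
both the amyloid-derived and non-amyloid-derived matrix, and classified by
the differential

    Δφ(k) = φ_tot(k | amyloid) − φ_tot(k | non-amyloid)

with Δφ < 0 predicting fibril formation. Residues with propensity ≥ 1.2
are "preferred" at a position, ≤ 0.8 "avoided". Per-residue property
totals (e.g. total hydrophobicity H_T, the sum of retention-time
hydrophobicity coefficients) and a cross-validated random-forest harness
(12 position energies + 3 property totals as features) round out the
toolkit. Both published 20×6 potential matrices, the globular background
composition and the hydrophobicity coefficients ship with the package.
See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

```python
import amylpot as ap

amy = ap.load_amyloid_potentials()
non = ap.load_non_amyloid_potentials()

for seq in ("STVIIE", "VQIVYK"):
    s = ap.score_peptide(seq, amy, non)
    print(seq, f"{s.phi_amyloid:.3f} {s.phi_nonamyloid:.3f} "
               f"{s.delta_phi:.3f} {s.call.value} "
               f"H_T={ap.total_hydrophobicity(seq):.2f}")
```

prints

```
STVIIE -6.975 -5.269 -1.706 amyloid H_T=209.95
VQIVYK 2.290 1.668 0.622 non_amyloid H_T=215.14
```

STVIIE (the de novo designed fibril-forming parent peptide) scores 6.975
kcal/mol *below* zero under the amyloid statistics and Δφ = −1.706
kcal/mol, a confident amyloid call; VQIVYK (a fibril-forming segment of
tau) happens to score positive here, Δφ = +0.622, illustrating that the
sign rule is a statistical discriminator, not an oracle. H_T is each
peptide's total hydrophobicity; fibril formers are on average the more
hydrophobic class.

The same operations are available from the shell:

```sh
amylpot score --in peptides.tsv            # Δφ discriminator
amylpot scan --fasta protein.fa            # 6-mer window scan for APRs
amylpot derive --in peptides.tsv --label amyloid --out matrix.tsv
amylpot prefs --matrix matrix.tsv          # preferred/avoided residues
amylpot properties --in peptides.tsv       # class H_T summary
amylpot crossval --in peptides.tsv --folds 10 --seed 17
amylpot simulate --n 500 --tau 1.0 --seed 42 --out synth.tsv
```

Dataset files are two-column TSV (`sequence<TAB>label`, labels `amyloid` /
`non_amyloid`) or FASTA with `>id|label` headers.

Because the experimental compilation behind the published matrices is
assembled from other studies' supplements, it does not ship here; the
`simulate` module generates labeled datasets with the same class-
conditional position biases (temperature factor τ controls class overlap)
so every pipeline stage can be exercised and benchmarked end to end. Users
who reconstruct the original 139/168 compilation can check the published
recall directly: `classify_dataset` with the bundled matrices should
identify about 123 of the 139 fibril formers.

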