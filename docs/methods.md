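# Methods

## Overview

`neo3dgenome` prioritizes candidate neoantigens — MHC class I 9-mer
epitopes arising from somatic mutations — by combining a conventional
peptide-MHC binding score with information about *where the peptide's DNA
locus sits in the folded 3D genome*. The working hypothesis is that the
DNA origins of immunogenic (T-cell-activating) epitopes are not randomly
placed: immuno-positive loci tend to co-locate in nuclear space, so a
candidate whose locus sits in a neighborhood rich in known immuno-positive
loci deserves a boost.

The pipeline has five stages:

1. **Binning** — the genome is partitioned into fixed 500 kb bins; each
   bin is one bead of a coarse-grained polymer and one row/column of the
   Hi-C contact matrix.
2. **Compartment degree** — per chromosome, the contact matrix is
   normalized to observed/expected, correlated (Pearson), and the first
   principal eigenvector of the correlation matrix is taken as a per-bin
   chromatin-activity score ("compartment degree", the standard A/B
   compartment statistic).
3. **Polymer reconstruction** — each chromosome is a bead-on-string
   chain (23 chains for a human bin table). Beads receive nuclear-radius
   targets decreasing in compartment degree (active chromatin sits
   nearer the nuclear center), and an ensemble of conformations is
   optimized from random starts under bond + radial quadratic restraints
   (300 replicas by default).
4. **Epitope curation and placement** — assay-level records are
   restricted to human MHC-I 9-mers; per-(peptide, allele) groups pool
   assay outcomes into a positive rate, labeled immuno-positive if the
   rate is strictly above 0.8 and immuno-negative if strictly below 0.2
   (boundaries and intermediates dropped); labeled peptides are placed
   on the genome via a peptide → (chromosome, position) mapping table.
5. **Scoring** — a target peptide's KNN score is the positive fraction
   among its k = 10 nearest *same-chromosome* training epitopes, with
   nearness measured by replica-averaged 3D bead distance. The final
   prioritization score is `baseline − knn` where the baseline is the
   external pMHC score rescaled to [0, 1], lower = stronger binder;
   candidates are ranked ascending.

## Model and assumptions

**Contact matrix.** Symmetric, non-negative, raw or pre-normalized
counts; no balancing is applied (none is assumed by the downstream
steps). Coordinates are 0-based with half-open 500 kb bins; the last bin
of a chromosome may be short but is still one bead.

**Compartment degree.** The O/E step divides each entry by the mean
observed count at its genomic offset (diagonal included; zero-coverage
offsets stay 0). Bins with zero marginal count are masked out of the
correlation and later filled by nearest-valid-neighbor interpolation so
every bead gets a radial target. The eigenvector sign is arbitrary; it
is oriented against a user-supplied track (e.g. gene density) when
given, else so that the larger compartment (more bins) is negative. The
degree is mean-centered over valid bins and scaled to unit maximum
absolute value. Whether the underlying quantity should be the raw
eigenvector or a transform of it is genuinely open; the raw eigenvector
is the one computation that is standard across the field.

**Polymer objective.** The bias potential is

```
E = bond_k · Σ_bonds (d_ij − L)²  +  radial_k · Σ_i (|r_i| − t_i)²
```

with bond length L = 1 model unit, bond_k = radial_k = 1, confinement
radius R = 10, and radial targets linear in the genome-wide *rank* of
the compartment degree between r_min = 0.2 R and r_max = 0.95 R (most
active bead nearest the center). Rank mapping (rather than a linear map
of the degree values) makes the targets robust to the eigenvector's
heavy tails. No excluded-volume term is included: the two stated
restraint families fully determine the statistic the scorer uses
(pairwise distances within a chromosome), and adding force-field detail
the data cannot constrain would only add parameters.

**Optimization.** Annealed gradient descent: per iteration a random kick
with linearly decaying amplitude (initial σ = 0.1) is tried and kept
only if it lowers the energy, then a gradient step with backtracking
line search (halve until decrease, grow 10 % after success). The energy
trace is therefore monotone non-increasing by construction, and a run
terminates at the iteration budget (default 5000) or when the relative
energy improvement drops below 1e-6. Starting conformations are
confined random walks with exact unit steps (out-of-bounds steps
rejected and redrawn). Replica r of an ensemble uses seed
`base_seed + r`; everything downstream of a seed is bit-reproducible.

Degenerate inputs: a constant compartment profile maps all radial
targets to the midpoint with a warning; a non-finite energy or gradient
aborts with the replica's seed in the error; an all-zero chromosome is
rejected before the compartment step.

**KNN score.** Only same-chromosome neighbors vote, because chromosome
territories make inter-chromosomal model distances systematically larger
and incomparable. Distances are averaged over replicas *per pair* —
never over coordinates, since each replica's global orientation is an
arbitrary isometry (the score is provably invariant under per-replica
rotations/reflections). Ties are broken deterministically by
(distance, genome-wide bin index, peptide string). The "majority vote"
is exposed as the continuous positive-vote fraction, which the
subtraction and the ROC analysis both require; fewer than k available
neighbors → all are used; zero → the global training positive rate with
a neighbor count of 0 so callers can detect the fallback.

**Score combination.** `combined = baseline − knn` requires the baseline
in [0, 1] with *lower = stronger predicted binder* (the orientation that
makes the subtraction reward both strong binding and a positive spatial
neighborhood). This orientation contract is enforced with a validation
error pointing at `rescale_baseline`, which offers fractional-rank
rescaling (orientation-preserving or inverting) and a log-IC50 map for
affinity-scale input. Which output scale of an external predictor a
user feeds in is their responsibility; the rank mode makes any monotone
scale acceptable.

## Statistics

**Pair contact-frequency comparisons.** Within a chromosome, all
unordered pos-pos and neg-neg pairs contribute their Hi-C contact
frequency; genome-wide, pos-pos / neg-neg / pos-neg pairs on *different*
chromosomes are compared. Because pairs sharing an epitope are strongly
dependent, a two-sample rank test that assumes independent observations
is badly calibrated on this design — measured on null (label-permuted)
data, Mann-Whitney U never reaches p < 0.06 at 12+12 epitopes per
chromosome, i.e. it is drastically conservative. The default test is
therefore an exact **epitope-label permutation test**: the statistic is
the difference of group mean CFs, and the null distribution is built by
permuting immunogenicity labels among the located epitopes and
recomputing the pair groups (999 permutations by default, add-one
p-value). Mann-Whitney remains available (`test="mannwhitney"`) for
comparability; at genome-wide pair counts its p-values are also inflated
by the quadratic growth of dependent pairs and should be read as
ordering evidence, not calibrated error rates. No multiple-testing
correction is applied across chromosomes by default.

**Evaluation.** Leave-one-out cross-validation: each epitope is scored
with itself excluded from the training set. ROC and precision-recall
curves (and AUC / average-precision areas) are computed on negated
scores so that the lower-is-better prioritization orientation maps onto
the usual higher-is-positive convention; AUC ties receive half credit
(the statistic equals the concordant-pair Mann-Whitney formulation,
asserted against a brute-force pair-counting oracle in the tests).
Bootstrap 95 % confidence intervals (1000 resamples over peptides,
seeded, resamples without both classes redrawn) qualify comparisons
between the combined and baseline-only rankings.

## Synthetic data: what it emulates, and what it does not

The generators produce the statistical structure the pipeline consumes,
with planted ground truth:

- **Hi-C**: expected intra-chromosomal counts decay as
  `|i−j|^(−α)` (α = 1 by default), multiplied by a checkerboard factor
  (default 3) when two bins share a planted A/B label and divided by it
  otherwise; inter-chromosomal counts are a flat level with the same
  compartment factor; Poisson sampling around the expectation
  (negative-binomial behind a flag). This reproduces distance decay and
  plaid compartment correlation — it does not emulate TADs, loops,
  coverage biases, translocations, or balancing artifacts.
- **Epitopes**: unique random 9-mers placed uniformly (null) or with
  positives concentrated in a chosen bin set at a leak rate (default
  10 %). Peptide sequences deliberately carry no signal: the method
  uses only loci and labels, and the fixtures mirror that.
- **Baseline scores**: a binormal model calibrated so the expected AUC
  equals a target (default 0.70) — negatives N(0,1), positives
  N(−μ,1), μ = √2 · Φ⁻¹(AUC) — then rank-rescaled to [0, 1],
  lower = positive-leaning.

Default study conditions for the end-to-end simulation: 4 chromosomes ×
25 bins at 500 kb, 5-bin checkerboard blocks at strength 3, 50 positive
and 190 negative epitopes (positive prevalence ≈ 0.21, matching the
composition of curated human T-cell assay collections), baseline AUC
0.70, 8 replicas at 600 iterations. These sizes keep a full multi-seed
study on one CPU in tens of seconds while leaving every planted effect
recoverable; the reconstruction quality saturates well below the
300-replica production default because the toy genome is small.

Passing tests on these fixtures show that each stage recovers exactly
the structure it is designed to detect, at effect sizes chosen to be
realistic for the assay; they do not show that real Hi-C and real
curated epitopes carry that structure — that is the scientific claim
the method exists to test on real data.

## Known limitations and numerical notes

- Subtracting the KNN vote has an inherent cost under the no-signal
  null: adding an uninformative score of variance p(1−p)/k to a
  calibrated baseline *lowers* AUC by ≈ 0.02 at k = 10 and prevalence
  0.2 (measured both in the idealized independent-noise model and in
  the full pipeline). The combined score is therefore only expected to
  help when spatial clustering of positives is real.
- The permutation test's add-one p-value is slightly conservative at
  small permutation counts; the observed null rejection rate at
  α = 0.05 with 199–999 permutations stays within the binomial band.
- The polymer restraint set is infeasible when adjacent beads' radial
  targets differ by more than the bond length (e.g. a hard checkerboard
  profile produces target jumps of several bond lengths at block
  boundaries); the optimizer then converges to a compromise with
  nonzero energy. Constraint-satisfaction diagnostics should use
  smoothly varying profiles, where the optimum is exact.
- Optimization is a local method; different seeds reach different
  (mirror-equivalent or genuinely distinct) optima. All downstream
  statistics use only within-chromosome distances averaged over
  replicas, which is insensitive to the arbitrary global orientation of
  each replica.
- `O(n²)` dense matrices throughout: the genome-wide human matrix at
  500 kb (~6200 bins) is ~300 MB as float64, fine on a workstation;
  finer resolutions would need a sparse backend, which is out of scope.
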