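# neo3dgenome

Neoantigen prioritization from 3D genome structure.

When a tumor carries many somatic mutations, hundreds of candidate
neoantigens — mutated 9-mer peptides potentially presented by MHC class
I — compete for a short validation list. Standard prioritization scores
each peptide by predicted peptide-MHC binding alone. `neo3dgenome` adds
an orthogonal signal: **where the peptide's DNA locus sits in the folded
genome**. Immuno-positive epitope loci are not placed randomly in
nuclear space; if a candidate's locus lies in a 3D neighborhood rich in
known immuno-positive loci, its priority rises.

The package is for computational immunologists and genome-biology
groups who have (a) a Hi-C contact matrix, (b) a curated table of
T-cell assay outcomes, (c) peptide-to-genome mappings, and (d) scores
from a binding predictor such as NetMHCpan, and want a reproducible,
tested implementation of the whole chain — including synthetic-data
generators that make every stage testable without external downloads.

## Method

1. **Bin** the genome at 500 kb; each bin is a bead and a Hi-C
   row/column.
2. **Compartment degree** per chromosome: observed/expected
   normalization → Pearson correlation → first principal eigenvector
   (the standard A/B compartment statistic), used as per-bin chromatin
   activity.
3. **Polymer reconstruction**: one bead-on-string chain per chromosome;
   each bead gets a nuclear-radius target decreasing in compartment
   degree (active chromatin near the center); an ensemble of replicas
   (default 300) is optimized from random starts under the bias
   potential

   ```
   E = k_bond Σ (d_ij − L)² + k_rad Σ (‖r_i‖ − t_i)²
   ```

4. **Curate epitopes**: human MHC-I 9-mers; per-(peptide, allele)
   positive rate over assays; label positive if rate > 0.8, negative if
   rate < 0.2, drop the rest; place each peptide on the genome from a
   mapping table.
5. **Score**: for target peptide *p*,
   `knn(p)` = positive fraction among the k = 10 nearest
   same-chromosome training loci (replica-averaged Euclidean bead
   distance), and the final score is

   ```
   score(p) = baseline(p) − knn(p)
   ```

   with `baseline` in [0, 1], lower = stronger predicted binder.
   Candidates are ranked ascending; leave-one-out ROC/PR compares the
   combined ranking against baseline-only.

Scientific details, assumptions, and limitations: [docs/methods.md](docs/methods.md).

## Worked example

Run a fully synthetic, seeded end-to-end study with planted structure
(clustered immuno-positive loci, checkerboard Hi-C, a baseline predictor
calibrated to AUC 0.70):

```bash
$ neo3dgenome simulate --seed 1 --out sim_out
combined  AUC 0.793  AUPR 0.531
baseline  AUC 0.740  AUPR 0.433
delta AUC (combined - baseline): +0.053
```

Reading the numbers: the baseline-only leave-one-out ranking realizes
AUC 0.740 on this draw (its generator target is 0.70); adding the
3D-genome KNN vote lifts the AUC to 0.793 and the area under the
precision-recall curve from 0.433 to 0.531 — the spatial clustering of
positive loci planted by the generator is recovered by the combined
score. With `--spatial-mode uniform` (no planted clustering) the lift
disappears. `sim_out/` contains the per-peptide LOOCV table
(`loocv.tsv`), the AUC/AUPR report with bootstrap confidence intervals
(`report.json`), and the study configuration (`config.json`).

On real inputs, the equivalent run is:

```bash
neo3dgenome predict \
  --hic hesc_500kb.txt --chrom-sizes hg19.chrom.sizes \
  --epitopes iedb_assays.tsv --mapping peptide_loci.tsv \
  --baseline netmhcpan_scores.tsv \
  --k 10 --replicas 300 --seed 1 --out results/
```

which writes the curated epitope table, the conformation ensemble (XYZ +
JSON sidecar), the ranked `predictions.tsv` (lowest combined score =
highest predicted immunogenicity), and `report.json`.

The same machinery is available as a library: `ContactMatrix`,
`compartment_degree`, `generate_ensemble`, `knn_score`, `loocv_scores`,
and a scikit-learn estimator `Genome3DNNClassifier` (features: bin
index + baseline score) that composes with sklearn model selection.

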