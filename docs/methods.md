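# Methods

## Model and procedure

`xisig` frames sex-differential methylation detection as per-gene binary
classification rather than per-CpG hypothesis testing. The unit of analysis
is the *gene methylation signal*: for one gene and one sample, the vector of
β values of the gene's CpGs ordered by physical chromosomal coordinate
(1-based, strand-ignored; ordering uses the coordinate only). Stacking one
vector per sample gives an n_samples × n_CpG pattern matrix. Because
n_samples ≪ n_CpG in the intended designs, PCA is performed on the
samples × samples Pearson cross-correlation kernel of the zero-mean,
unit-norm patterns; its eigenvalues equal the squared singular values of the
normalized pattern matrix, so the EVD and SVD routes agree (property-tested
to 1e−8).

The supervised rule is deliberately minimal: project onto the two leading
PCA features and assign a held-out sample to the nearest class centroid
(Euclidean). Held-out patterns are projected by the kernel-extension
formula p_c = (r·v_c)/√λ_c, where r is the vector of correlations between
the normalized test pattern and the normalized training patterns; for a
training pattern this reproduces its in-sample projection √λ_c·v_c exactly,
so the rule is self-consistent. Components with λ ≤ 1e−9 contribute 0.

Cross-validation is exhaustive, not sampled: every choice of t training
samples per class, crossed with every remaining sample tested singly. For
two classes of n_A and n_B samples this yields
C(n_A,t)·C(n_B,t)·((n_A−t)+(n_B−t)) evaluations — 2400 for 6 vs 6 at t = 3.
All predictions are pooled into a single confusion matrix (micro
aggregation; per-split MCC is undefined for single-sample test sets) and
summarized by one Matthews correlation coefficient. The positive class is
*female* by fixed convention (MCC is invariant to the choice; reports need a
stable one). Genes with pooled MCC strictly above the threshold (default
0.995) are *sex_differential*; the remainder are *variable*. The threshold
is a fixed configuration value, not auto-detected from the histogram.

Alongside the MCC, each gene carries two spectrum summaries of the
full-data kernel: λ₂/λ₁ (small when one direction dominates) and λ₁/Σλ.
Both definitions are plausible readings of an "eigenvalue ratio" ranking
and they order genes differently, so the report carries both columns
(`pca_ratio`, `pca_ratio_l1frac`) and ranking takes the mode as a
parameter; the default scoring mode is λ₂/λ₁, whose values lie in [0, 1].
A boolean `separable` flag records whether the *unsupervised* top-2
projections already split the sexes with zero error (nearest-true-class
centroid, no cross-validation); it is reported but gates nothing.

## Tunable parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `min_cpg` | 3 | CpGs | with 2 CpGs every zero-mean pattern is ±(x,−x), all correlations are ±1 and the kernel is uninformative; 3 is the smallest informative size |
| `train_per_class` | 3 | samples | half of each class in the reference 6 vs 6 design |
| `mcc_threshold` | 0.995 | — | strict inequality; sits inside the empty band of the bimodal MCC distribution the method produces on Xi-structured data |
| `region_mode` | `all` | — | `promoter` restricts to {TSS1500, TSS200, 5UTR, 1stExon}, the conventional 450k promoter group; whole-gene signals separate the sexes far better than promoter-only ones |
| `hist_bin_width` | 0.05 | MCC | fine enough to resolve the empty band below the top bin |
| `missing_token` | `NA` | — | GEO exports vary; configurable |

Missing β values are handled by dropping the CpG column across all samples
(complete-case), never the sample, so the class design — and with it the
split enumeration — stays intact. Probes mapped to k genes contribute to
all k signals; genes annotated on two chromosomes are kept as separate
(gene, chromosome) records; duplicate coordinates within a gene keep the
first probe by id, with a warning.

## Synthetic data: what it emulates and what it does not

The generator plants the geometry that makes sex classifiable from
methylation signals:

* **CpG architecture** — each gene gets a per-CpG mean profile
  `baseline ± profile_spread` (default 0.05 ± 0.15) shared by all samples:
  the island/shore/body heterogeneity that gives real within-sex patterns
  high mutual correlation. Profiles are *stratified* uniform (a permuted,
  equally spaced grid), so every gene realizes the nominal architecture
  variance; iid draws would leave a random fraction of genes uninformative,
  which emulates nothing biological.
* **Xi hemimethylation** — at inactivated genes, female means are
  `male + Δ·w_j` with a per-CpG gain `w_j ∈ [0, 2]`, mean 1 (so the mean
  female − male difference equals the configured effect Δ), *anti-correlated*
  with the active-X level plus stratified jitter (± 0.3): CpGs unmethylated
  on the active X gain the most on the inactive copy, CpGs already
  methylated have little headroom. The per-CpG variation of the gain is
  load-bearing: a constant shift Δ would be removed exactly by the
  zero-mean normalization and no correlation-based classifier could see it.
  The anti-correlation partially mirror-images the female signal, which is
  the feature the kernel detects; designs with gains independent of the
  architecture leave the detectability of individual genes to chance (a
  gain profile that happens to align with the architecture only rescales
  the pattern) and were rejected in simulation.
* **Nulls** — escape and autosomal genes use identical male/female means;
  at Δ = 0 all categories collapse to the same generative law.
* **Noise and labels** — truncated Gaussian noise on the β scale
  (σ default 0.05, clipped to [0, 1]); term/preterm gestation labels
  assigned orthogonally to sex with no simulated effect.

Not emulated: probe cross-reactivity and SNP artifacts, chip/batch
effects, cell-type mixture, beta-binomial intensity noise, correlated
noise along the gene, skewed sex ratios, and the heavy-tailed β
distributions of real arrays. Passing the recovery tests therefore shows
the estimator and its cross-validation machinery are correct under the
stated generative model — not that real cohorts of this size will yield
the same gene counts.

Determinism: one `numpy` generator seeded from the config drives all
draws in a fixed order; the same config yields byte-identical files.

## Numerical choices

* Zero-variance (flat) patterns normalize to the zero vector and are
  flagged degenerate; their kernel rows are 0 off-diagonal, 1 on the
  diagonal. A gene whose every pattern is flat scores MCC 0 and is flagged.
* Eigenvector signs follow a fixed convention (largest-magnitude entry
  positive, first index on ties) so heatmap exports are reproducible;
  classification itself is sign-invariant.
* Kernel entries are symmetrized and clipped to [−1, 1]; eigenvalues below
  1e−9 are treated as zero.
* MCC with a zero denominator factor returns 0 (random-predictor
  convention, logged).
* Classification distance ties (≤ 1e−12) go to the label that sorts first
  and are counted per gene and logged; a flat test pattern projects to the
  origin and resolves by this rule when the centroids are mirror-symmetric.
* Ranking ties on the eigenvalue ratio break by gene symbol ascending,
  logged.
* Floats are written with 10 significant digits; reports sort descending by
  the chosen ratio with a stable mergesort.

## Problem sizes

The bundled example cohort is 12 samples (6 female / 6 male, balanced
term/preterm) × 200 genes (110 inactivated incl. a PGK1-like positive
control, 40 escape incl. the 16 known escape-list symbols, 50 autosomal),
scored at 2400 splits per gene in ≈ 10 s on one CPU. The parameter-recovery
check uses 6 vs 6 with 50 inactivated + 50 escape genes of 8 CpGs at
Δ = 0.4, σ = 0.05; the effect-monotonicity check uses 10 genes ×
Δ ∈ {0, 0.1, 0.2, 0.3, 0.4} × 3 seeds. Exhaustive enumeration grows as
C(n,t)², so genome-scale runs at larger n should reduce `train_per_class`
or parallelize per gene (out of scope here).

## Known limitations

* The discovery-scale results of the motivating study design (hundreds of
  X-linked genes from a 12-infant array cohort, a single autosomal hit)
  require the original undeposited data and the vendor manifest; they are
  out of reach offline and are replaced here by oracle-checked unit
  behaviour and synthetic parameter recovery. The GEO validation driver
  (`fetch_validation_cohort`) exists for real-data replication but is
  strictly optional, requires network access and documents its own
  preprocessing choices (values clipped to [0, 1]; sex parsed from sample
  characteristics); it never falls back to simulation.
* The classifier assumes exactly two classes and balanced-ish designs;
  nearest-centroid on two PCA features is intentionally the minimal linear
  rule, not a tuned discriminant.
* Symbol-level gene lists are matched exactly after upper-casing; no alias
  resolution. The packaged immune list covers the 16 curated symbols, not a
  full PANTHER/IRIS compilation.
* Manifest coordinates are taken as given; users must supply a manifest
  consistent with their genome build.
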