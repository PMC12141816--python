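# Methods

`phenoaug` implements phenotype-driven augmentation of labelled expression
matrices for supervised learning under class imbalance, together with the
evaluation protocol needed to judge whether an augmentation method actually
helps. This note records the models, the parameters that matter, the design
choices that were genuinely open, and what the simulated cohorts do and do
not show about real data.

## Signature-dependent crossover sampling

The working assumption is that the gene panel decomposes into *signature
blocks*: for each phenotype class (e.g. each colorectal consensus molecular
subtype, CMS1–4) there is an ordered list of genes jointly predictive of
that class. A synthetic patient is assembled block-by-block from real
donors; blocks are atomic and are never split.

* **Intra-class crossover.** To generate a sample of class *c*, every block
  — including the blocks predictive of other classes — is copied from a
  donor drawn uniformly at random among the samples labelled *c*,
  independently per block. Non-target blocks therefore carry expression
  typical of class-*c* patients, and within-block gene–gene correlation is
  preserved exactly because blocks are copied verbatim.
* **Inter-class crossover.** The label-predictive block must come from a
  class-*c* donor; the block predictive of any other class *c′* is copied
  from a donor drawn over the whole cohort *excluding* samples labelled
  *c′*. This uses the full cohort for diversity while preventing ambiguous
  labels. On a 2-class problem the exclusion forces every donor into the
  target class, and the method degenerates to intra-class crossover — a
  property the tests verify.

Donors are drawn with replacement, independently across blocks and across
generated samples; this is the only choice that works when the requested
count exceeds the donor-pool size. Synthetic samples that coincide with a
real sample (inevitable when a class has a single donor) are kept — no
rejection rule is applied. Synthetic samples are never reused as donors.
Each generated sample records full provenance (block → donor id), so an
audit can re-verify bit-level equality and the donor-label constraints
without replaying the RNG.

### Overlapping signatures

When exactly two classes' blocks share genes (the Luminal A / Luminal B
situation in the PAM50 panel), the crossover methods need an adaptation,
enabled explicitly via `CrossoverConfig.overlap_adaptation`. Per generated
sample: if the target class owns one of the overlapping blocks, the shared
genes are assigned to the target (label-predictive) block and removed from
the other; otherwise one of the two overlapping blocks is chosen uniformly
at random and the shared genes travel with it, so their values come from the
same donor as the rest of that block. The choice is re-drawn per sample
(the granularity was open; per-sample maximizes diversity). Genes shared by
more than two blocks are rejected rather than guessed at. A caveat worth
stating: when signature genes are strongly correlated across blocks, this
adaptation cannot preserve those cross-block dependencies, and crossover
methods are expected to underperform the parametric ones in that regime —
the library implements the adaptation as specified and leaves method choice
to the user.

## Signature-independent parametric sampling

For count data the package provides Gamma-Poisson (negative binomial) and
Poisson resampling with a *subset-conditioned* twist: for every generated
observation, a fresh subset *S* of same-class samples is drawn (uniformly,
without replacement within a draw, independently across draws), and the
distribution parameters are re-estimated from that subset. Per gene *j*:

* mean `μ_j = mean(S_j)`, variance `σ²_j = var(S_j)` with the unbiased
  divisor `|S| − 1`;
* Gamma shape `α_j = μ_j²/σ²_j` and **rate** `β_j = μ_j/σ²_j`, so that the
  Gamma's mean is `α/β = μ` and its variance `α/β² = σ²` — the
  parameterization is locked in by an algebraic-identity test because
  shape/scale confusion is the classic failure mode here;
* modified Gamma-Poisson: `λ_j ~ Gamma(α_j, rate β_j)`, then
  `y_j ~ Poisson(λ_j)`; marginally a negative binomial with mean `μ_j` and
  variance `μ_j + σ²_j`;
* modified Poisson: `y_j ~ Poisson(μ_j)`.

The subset size `|S|` is the user hyperparameter (default 10: large enough
for a stable variance estimate, small enough that subsets differ and the
mixture adds between-subset diversity; exposed everywhere, never silent).
If a class is smaller than `|S|`, the subset is clamped to the class with a
logged warning — the sampler then reverts toward its classic behaviour.
Genes with zero subset variance or zero mean, where the moment estimator is
undefined, fall back to a pure `Poisson(μ)` draw; `Poisson(0)` handles
all-zero genes naturally. The *classic* variants estimate parameters once
from the whole class; setting `|S|` to the class size makes the modified
samplers distributionally identical to them (verified by per-gene
Kolmogorov–Smirnov tests).

Continuous input (e.g. RMA-normalized microarray intensities) is rejected by
default. An explicit `continuous_input="allow"` runs the estimation on the
given values but still emits integer Poisson draws — the output scale then
differs from the input scale. This literal behaviour is deliberate: the
moment machinery is well-defined on any nonnegative input, but whether
integer draws on a log-intensity scale are meaningful is for the user to
decide, which is why the flag is loud.

Maximum-likelihood NB fitting with dispersion shrinkage (DESeq2-style) is a
non-goal; method-of-moments is the specified estimator.

## Baselines, planning, and the augmentation driver

Random oversampling copies whole rows with replacement. SMOTE is the
vanilla interpolation scheme — a uniform point on the segment between a
class member and one of its `k` (default 5, configurable) nearest same-class
Euclidean neighbours — implemented in-package over scikit-learn's
`NearestNeighbors`, with endpoint provenance and seed determinism.

Class-size plans come in two modes: `max` (lift every minority class to the
majority size) and `fixed` N (lift every class to N; N below the largest
class is an error — classes are never down-sampled). The driver applies
one method class-by-class, appends synthetic rows after the untouched real
rows, assigns traceable ids `{method}_{class}_{index:05d}`, and derives one
child seed per class from the master seed so whole-run output is
bit-reproducible.

## Normalization

Augmentation happens on the count scale first; normalization follows.
`FPKM_ij = counts_ij · 10⁹ / (library_i · length_j)` with the library size
summed over the working panel, then `log2(FPKM + 1)` (log base 2 and
pseudocount 1 are bioinformatics convention; both configurable). Because
the matrix has already been reduced to signature genes, panel-relative FPKM
differs from transcriptome-wide FPKM by a per-sample factor; per-sample
scale invariance and monotonicity are unaffected, and both are tested
algebraically. Gene lengths are a required input table — the length
definition (exonic vs transcript union) is the caller's choice. SMOTE
interpolations of counts are non-integer; the pipeline still FPKM-normalizes
them (the formula needs only nonnegativity) behind an explicit `force`
flag. Continuous-mode data pass through unchanged; an optional z-score
standardization is fitted on the training split only.

## Simulated cohorts

The generator emulates a subtype-labelled cohort reduced to its signature
panel: class *c*'s signature genes have negative-binomial mean
`baseline_mean · fold_change` in class-*c* samples and `baseline_mean`
elsewhere. Counts are exact NB draws via the Gamma-Poisson mixture with
shared size parameter *r* (`Var = m + m²/r`). Optional shared genes between
the first two classes are up-regulated in the second and down-regulated
(mean `baseline/fold`) in the first, reproducing the overlapping-signature
geometry. A paired out-of-domain cohort redraws the same design with a
per-gene multiplicative log-normal shift `exp(batch_shift · z_j)`, standing
in for a different-study validation set.

Defaults portray a mid-size colorectal-style cohort: 4 classes × 10 genes,
class sizes (75, 220, 70, 145) mirroring typical CMS imbalance, baseline
mean 50, fold change 3, size r = 2 (dispersion φ = 0.5, i.e. noisy bulk
tumour RNA-seq). Gene lengths are log-uniform on [500, 5000] bp so FPKM is
non-trivially gene-dependent.

What the simulation does **not** emulate: real marginal count distributions,
gene–gene correlation beyond block membership, gene-specific dispersions,
library-size variation, or batch structure richer than a per-gene mean
shift. Tests passing on these cohorts therefore demonstrate correctness of
the samplers and the protocol, not effect sizes on any real dataset.

## Evaluation protocol

Benchmarking uses 5×5 repeated stratified cross-validation (25 splits).
Augmentation is applied to the training fold only; FPKM+log is per-sample,
and the only train-fitted statistic (optional standardization) never reads
held-out rows — enforced by a test that poisons held-out rows and checks
training artifacts bit-for-bit. Fold assignments are a pure function of
(labels, seed) and are identical across arms, so per-split scores are
paired. The metric is balanced accuracy (mean per-class recall). The
classifier bank is logistic regression, k-NN, RBF-kernel SVM and random
forest at scikit-learn defaults (recorded in result metadata); an
explainable boosting machine can be added behind a flag when the `interpret`
package is available.

Method comparison uses two-sided Wilcoxon signed-rank tests on the paired
per-split, per-classifier balanced accuracies, pooled across classifiers
(per-classifier tables can be derived from the tidy records), with
Benjamini–Hochberg adjustment across all method pairs at α = 0.05 (a
conventional, configurable choice). Two flags are reported per method:
significantly better than the unaugmented arm, and significantly better
than every other method. Synthetic-data fidelity is summarized by the
absolute difference between cosine-metric silhouette scores of real and
synthetic data under the class labeling; 0 means class geometry is
preserved.

## Numerical and degenerate-input choices

* Counts are validated as nonnegative integers at construction; the first
  offending cell is named in the error.
* A single-donor class makes crossover deterministic (all outputs equal the
  donor); a single-sample class is an error for the parametric samplers
  (variance undefined).
* Wilcoxon on an all-zero difference vector is reported as p = 1 rather
  than an error.
* Ties in SMOTE neighbour distances follow scikit-learn's ordering;
  determinism is guaranteed by the seed, not by tie-break conventions.
* All randomness flows from `numpy.random.default_rng` seeds threaded
  through configuration objects; provenance is rich enough to audit outputs
  without replaying the RNG.

## Problem sizes used in the shipped analyses

The rescue experiment run by `scripts/acceptance.py` uses a 3-class cohort
of 230 samples (200/20/10) with fold change 3 under the default noise
model, 5×5 CV, five augmentation arms plus the unaugmented arm, and the
four-classifier bank. Moment-law checks use 50 000 draws with a pinned
estimating subset; equivalence checks use 20 000 draws per arm; provenance
audits cover 2 000 crossover samples. These sizes give stable Monte-Carlo
estimates (3-SE criteria) while keeping a full run in the low minutes on a
single CPU.

## Known limitations

* Crossover requires known signatures whose union covers the working panel;
  genes outside every block are dropped up front.
* The overlap adaptation handles pairwise overlaps only and is expected to
  lose fidelity under strong cross-block correlation.
* Panel-relative FPKM is not comparable to transcriptome-wide FPKM.
* Parametric samplers on continuous input change the output scale; the
  behaviour is intentionally literal and loudly flagged.
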