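# Methods

## Pipeline overview

The package implements a categorical drug-response model over cell-line /
drug similarity kernels, followed by an interpretability stage that ties
drug effectiveness to CpG-island methylation. The stages and their
contracts are:

1. **omics I/O** (`methdrug.io`) — validated loading of features × cells
   matrices, long-form AUCDR response tables, BED intervals and TF→target
   maps; cell-ID intersection across tables.
2. **similarity** (`methdrug.similarity`) — Hamming and RBF kernels over
   profile columns.
3. **labeling** (`methdrug.labeling`) — AUCDR trichotomization and VSI
   pair features.
4. **classify** (`methdrug.classify`) — SVM / RF / LR, stratified k-fold
   CV, AUPR/AUC, independent-cohort scoring.
5. **lasso_select** (`methdrug.lasso`) — per-drug L1 regression, λ grid
   search, PCC filter, top-100 site ranking.
6. **enrichment** (`methdrug.enrichment`) — TFBS overlap, random-fragment
   permutation null, TF→target joining, site–gene correlation.
7. **synthetic_data** (`methdrug.synthetic`) — the cohort generator that
   defines the study conditions for all tests.

## Kernels and bandwidths

Mutation similarity is exp(−HD) over binary profiles; all real-valued
modalities use exp(−α‖Δ‖²). The conventional bandwidths (α = 10⁻³ for
copy number and drug descriptors, 10⁻⁴ for expression and methylation)
are dimensionful: they presume genome-scale profiles where ‖Δ‖² is of
order 10³–10⁴. Two practical consequences are handled explicitly:

- **Hamming underflow.** exp(−HD) is exactly 0 in double precision once
  HD ≥ 746, so the raw formula cannot produce graded similarities between
  genome-scale mutation profiles. The raw form remains the default (it is
  the defined kernel); a `normalized` mode, exp(−scale·HD/len) with
  scale = 100, is provided for full-scale data, and any underflowing
  exponent triggers a `RuntimeWarning`.
- **Bandwidth–dimension coupling.** On a cohort with a few hundred CpGs,
  α = 10⁻⁴ leaves every off-diagonal similarity within ~1% of 1 and the
  kernel carries no usable signal. `KernelSpec(alpha="median")` applies
  the standard median heuristic (α = 1 / median pairwise ‖Δ‖²), which
  reduces to the conventional values at genome scale and keeps the kernel
  informative at any feature count. Synthetic-cohort runs use the median
  heuristic; the resolved numeric α is recorded in every output.

Squared distances are computed by the Gram-matrix expansion with negative
values clamped to 0 before exponentiation (float cancellation); matrices
are symmetrized and the diagonal set to exactly 1.

## Labeling and classification

Thresholds are strict: AUCDR < 0.2 → sensitive, > 0.991 → resistant,
boundary values land in "unclear" and are excluded from training (the
model deliberately learns only the extreme pairs). Sensitive is the
positive class for AUPR. Classifier scores are raw (SVM decision values,
probabilities for RF/LR) — only rank metrics are reported, so calibration
would be a no-op. AUPR uses the step-wise non-interpolated rule and AUC
the tie-averaged rank statistic (scikit-learn's `average_precision_score`
and `roc_auc_score`; both are verified in the test suite against
exhaustive threshold-enumeration oracles on every labeling of length
≤ 12).

Cross-validation splits at the pair level by default, which matches the
original evaluation protocol but lets the same cell line appear in
training and test folds under different drugs; `split_by="cell"` gives
cell-disjoint folds for a leakage-free number. Both are reported, neither
is adjudicated.

For the independent test, held-out cells are featurized by their kernel
similarity *to the training cells* (reference-anchored rows, computed
with the training-resolved bandwidth). This is the only construction that
keeps the feature length fixed between cohorts. The continuous test
response is sensitivity-oriented (an active-area-style 1 − AUCDR), so a
positive PCC means correct ranking.

## Lasso stage

Per drug: β columns are centred and scaled to unit variance before
fitting (the penalty then treats all islands comparably; coefficients are
reported on the standardized scale). The penalty grid holds 50
log-spaced values from λ_max — the smallest penalty that zeroes every
coefficient — down to λ_max·10⁻³; the winner minimizes fivefold
cross-validated MSE, with ties resolved toward the sparser (larger)
penalty. Internally the penalty uses the per-sample convention
α = λ/(2n) of the coordinate-descent solver; `LassoFit.lambda_total`
converts back to the sum-of-squares objective scale. A grid value of
exactly 0 is solved by least squares.

Both the in-sample and the out-of-fold prediction PCC are recorded. The
PCC > 0.7 drug filter uses the out-of-fold flavor by default (in-sample
correlations are inflated, especially with p > n); `flavor="insample"`
switches. Site ranking is by |coefficient| descending, ties broken by
genomic coordinate (chrom, start), zero coefficients never returned, at
most 100 sites.

## Enrichment stage

Overlap is ≥ 1 bp on half-open intervals, strand ignored throughout.
The permutation null places each fragment uniformly over all positions
where it fits *inside a single* non-coding interval (fragments never span
gaps). Fragment length defaults to 2,000 bp — the average CpG-island
length — and the number of fragments per repeat defaults to the number of
query sites, so observed and null counts are on the same scale. The
empirical p-value uses the add-one estimator
(1 + #{null ≥ obs})/(reps + 1), bounded below by 1/(reps+1) and therefore
never 0; the separately reported Gaussian-tail p (normal upper tail at
the null sample's mean and sd, sd with ddof = 1) is what can reach values
like 10⁻²⁶ that a 1,000-repeat simulation cannot resolve empirically. A
zero-variance null degenerates the Gaussian p to 0/1 with a warning.

Shores are the 0–2,000 bp flanks on each side of an island (a common
convention; configurable), looked up in the β matrix by their formatted
interval IDs and averaged when present. Downstream-gene assignment comes
from an explicit pairing table, never inferred from annotation.

## The synthetic cohort: what it emulates and what it does not

The generator is first-class, tested code; its defaults are the study
conditions of every simulation-based test.

- **Methylation.** β values are marginally the bimodal mixture
  0.5·Beta(0.5,5) + 0.5·Beta(5,0.5) (mass near 0 and near 1, as island
  methylation shows). Cells additionally belong to one of two global
  methylation phenotypes — a CIMP-like dichotomy: each island has a
  polarity, and a cell's phenotype makes the island favour its high or
  low Beta mode with probability `cluster_purity` (default 0.9). This
  global structure is deliberate: at a few hundred CpGs, a 5-site sparse
  effect is invisible inside any RBF kernel row, so without a phenotype
  that correlates with the planted effects the classification stage would
  be ill-posed by construction rather than by biology.
- **Responses.** AUCDR(c,d) = clip₀₁(base_d + Σₖ w_dk·β_kc + ε),
  ε ~ N(0, noise_sd). Each drug's baseline sits in one of the two tails
  (uniform on (0.02, 0.15) for the sensitive-leaning fraction, on
  (0.955, 0.999) otherwise), centred for the expected planted effect, so
  the marginal AUCDR is bimodal with mass below 0.2 and above 0.991.
  Causal weights are ±effect_size with signs tied to island polarity.
  Clipping censors part of the linear signal — intentionally kept, since
  real AUCDR is also bounded.
- **Other modalities.** Mutations are Bernoulli(0.05); copy number
  N(2, 0.5); expression log-normal, with each causal island's paired
  downstream gene negatively coupled to that island's β (methylation
  silencing) so the correlation stage has real signal; drug descriptors
  are standard normal (35 by default).
- **Seeding.** Island coordinates and drug-level biology (bases, causal
  sites, weights, polarities) derive from `genome_seed`; cell-level draws
  from `seed`. Cohorts sharing `genome_seed` share feature space and
  response model, which is what makes a train-here/test-there experiment
  meaningful.
- **Annotation.** A single 10 Mb chromosome; non-overlapping islands of
  mean ~2 kb; exactly round(frac·n_cpg) islands receive a TFBS inside
  them, background TFBS fall in non-coding space clear of every island
  (so the overlap count is exact by construction), non-coding space is
  the island complement (≥ 90% of the genome at defaults), and every TF
  name has curated targets.

Not emulated: linkage/correlation structure among neighbouring CpGs
beyond the phenotype dichotomy, copy-number segmentation, batch effects,
cell-lineage structure, and any chemical realism in the descriptors.
Passing tests therefore demonstrate that the machinery is correct and
well-calibrated under a known generative model — not that the same
numbers would be obtained on real screening data, where effect sparsity,
noise and confounding are harsher.

## Numerical and design choices

- Missing omics entries drop the whole feature row at load time (kernels
  and lasso need complete rows); the count is logged.
- Interval IDs in methylation tables are 1-based inclusive
  ("chr1: 110880394-110880624"); BED is 0-based half-open; the conversion
  lives in one function pair.
- Cell-ID matching is exact string match after whitespace trimming.
- Degenerate inputs reject loudly: constant response vectors, one-class
  label sets, empty BED files, out-of-range β, non-binary mutation calls.
- One global CLI seed is split deterministically into per-stage seeds, so
  stage-wise and end-to-end runs agree; no output file contains a
  timestamp, making runs byte-reproducible.
- Test problem sizes (e.g. 200 cells × 500 islands for recovery, 20
  replicate seeds, 200 calibration runs × 1,000 repeats) were chosen as
  the smallest cohorts at which the studied effects are comfortably
  identifiable under the default noise levels.

## Known limitations

- The pair-level CV default shares cell identity across folds; its high
  AUPR/AUC partly reflect that leakage. Use `--split-by cell` for the
  conservative estimate.
- Whether the PCC filter of the lasso stage should use in-sample or
  cross-validated correlations is ambiguous in the original protocol;
  both are computed, the conservative one is the default, and no claim is
  made that either reproduces published per-drug tables.
- The raw Hamming kernel is unusable at genome scale (underflow); the
  normalized mode is a pragmatic extension, not a literal transcription.
- The enrichment sampler takes whatever non-coding BED it is given; it
  does not itself exclude CpG islands or repeat space from the null.
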