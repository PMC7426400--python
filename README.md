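# methdrug

Predicting the response of cancer cell lines to anti-cancer drugs from
multi-omics kernel similarities, and discovering the CpG-island methylation
sites that drive drug effectiveness.

`methdrug` is a tested, reusable implementation of a pharmacogenomic
analysis for researchers working with GDSC/CCLE-style screening data: omics
matrices over a cell-line panel (binary mutation, copy number, expression,
methylation β values keyed by CpG-island intervals), a numeric drug
descriptor table, and a table of dose–response AUC values (AUCDR ∈ [0,1],
low = sensitive). It ships with a synthetic cohort generator with planted
ground truth, so every stage is exercised end-to-end and checked by
parameter-recovery tests without any external download.

## The model

**Kernel similarity.** Raw profiles are replaced by similarity matrices so
the sample and feature scales match. Binary mutation profiles use the
exponentiated Hamming distance, S(cᵢ,cⱼ) = exp(−HD(cᵢ,cⱼ)); real-valued
profiles (copy number, expression, methylation, drug descriptors) use an
RBF kernel, S(cᵢ,cⱼ) = exp(−α‖cᵢ−cⱼ‖²), with conventional bandwidths
α = 10⁻³ (copy number, drugs) and 10⁻⁴ (expression, methylation), plus a
median-heuristic option for smaller matrices.

**Categorical classification.** AUCDR is trichotomized — sensitive
(< 0.2), resistant (> 0.991), unclear (excluded) — giving a labeled
bipartite cell–drug graph. Each extreme pair is featurized by vector-space
integration (VSI): X = [Sim_cell row | Sim_drug row]. SVM (cost 10,
RBF γ = 0.01), random forest and logistic regression are evaluated by
stratified fivefold cross-validation with AUPR and ROC-AUC; a held-out
cohort can be scored through reference-anchored kernel rows.

**Methylation-site discovery.** Per drug, the continuous AUCDR is
regressed on the CpG-island β matrix with an L1 penalty,
min_W Σᵢ(yᵢ − Wᵀxᵢ)² + λ‖W‖₁, λ chosen by grid search over fivefold CV.
Drugs with prediction PCC > 0.7 are kept; the top 100 islands by
|coefficient| are the drug-effectiveness-related methylation sites.

**TFBS enrichment.** Selected islands are intersected with
transcription-factor binding sites (≥ 1 bp overlap). The null draws
equally many ~2,000 bp fragments uniformly from non-coding space, 1,000
times; an add-one empirical p-value and a Gaussian-tail p-value are
reported, TFs are joined to their curated target genes, and island (or
island-shore) methylation is correlated with downstream gene expression.

## Worked example

Run the whole pipeline on a small synthetic cohort (60 cell lines, 6
drugs, 120 CpG islands):

```
methdrug all --out run --seed 3 --n-cells 60 --n-drugs 6 --n-cpg 120
```

`run/train_report_methylation.json` then holds the cross-validated
classification metrics on the methylation kernel:

```
"svm": {"aupr_pooled": 0.9979, "auc_pooled": 0.9975, ...}
"rf":  {"aupr_pooled": 0.9942, "auc_pooled": 0.9926, ...}
"lr":  {"aupr_pooled": 0.9950, "auc_pooled": 0.9933, ...}
```

i.e. on this planted, nearly noise-free cohort all three classifiers
rank sensitive above resistant pairs almost perfectly.
`run/independent_test_report.json` reports the random forest applied to a
freshly drawn cohort of the same universe: PCC 0.899 between prediction
scores and the sensitivity-oriented response, with sensitive and resistant
test pairs separated at p ≈ 2.7e-18 (rank-sum). `run/enrichment.tsv`
summarizes the TFBS enrichment of the lasso-selected islands per kept
drug, e.g.

```
drug_id  n_sites observed_overlap overlap_percent tf_target_percent null_mean p_empirical p_gaussian
DRUG000  9       9                100.0           100.0             0.589     9.99e-4     3.8e-31
```

the selected sites all fall in TF binding regions while random non-coding
fragments almost never do (the empirical p sits at its 1/1001 floor; the
Gaussian tail quantifies how far beyond that floor the signal reaches),
and `run/correlate_report_island.json` shows the methylation–expression
coupling of the islands (24 of 120 island–gene pairs at |PCC| > 0.5, the
planted causal islands among them). Every file is reproduced byte-for-byte
when the command is re-run with the same seed.

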