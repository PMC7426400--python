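"""Synthetic pharmacogenomic cohort and genome annotation with known truth.

The generator emulates the statistical structure the downstream stages
assume: four omics matrices over a shared cell-line panel, a numeric drug
descriptor table, a bimodal drug-response (AUCDR) table driven by a sparse
planted methylation effect, and a small single-chromosome genome annotation
(CpG islands, TFBS, non-coding space, TF->target map) with a controllable
CpG/TFBS overlap fraction.

Response model. Each drug d has a baseline AUCDR drawn in one of the two
tails (below 0.2 for "sensitive-leaning" drugs, near 1 for
"resistant-leaning" ones, giving the characteristic bimodal marginal), and
a sparse set of causal CpG islands with weights +-effect_size:

    AUCDR(c, d) = clip_[0,1]( base_d + sum_k w_dk * beta_{k,c} + eps ),
    eps ~ N(0, noise_sd),

with base_d centred so the planted effect spreads cells around the tail.
The causal sites and weights are recorded in :class:`GroundTruth`, which
is what parameter-recovery tests of the lasso stage measure against.

Cell structure. Methylation beta values are marginally the bimodal mixture
0.5*Beta(0.5,5) + 0.5*Beta(5,0.5). On top of that, cells belong to one of
two global methylation phenotypes (a CIMP-like dichotomy): each site has a
polarity, and a cell's phenotype makes the site favour its high or low
mode with probability ``cluster_purity``. This global structure is what
makes kernel rows over a few hundred CpGs informative about the planted
effects; with fully independent sites a 5-site signal would be invisible
inside an RBF kernel at any realistic bandwidth.

Seeding. Cell-level draws come from ``seed``; drug-level biology (bases,
causal sites, weights, site polarities) and island coordinates come from
``genome_seed``. Two cohorts that share ``genome_seed`` but differ in
``seed`` therefore share feature space and response model -- the setting
of a train-on-one-cohort, test-on-another validation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    GenomicInterval,
    Modality,
    OmicsMatrix,
    ResponseTable,
    ValidationError,
    format_interval_id,
    write_bed,
    write_matrix,
    write_response,
    write_tf_targets,
)

log = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "Cohort",
    "Annotation",
    "generate_cohort",
    "generate_genome_annotation",
    "island_intervals",
    "site_gene_pairs",
    "write_cohort",
    "write_annotation",
]


@dataclass(frozen=True)
class CohortSpec:
    """Sizes, effect structure and seeds of a synthetic cohort."""

    n_cells: int = 200
    n_drugs: int = 20
    n_mut_genes: int = 300
    n_expr_genes: int = 300
    n_cnv_genes: int = 300
    n_cpg: int = 500
    n_descriptors: int = 35
    n_causal_cpg_per_drug: int = 5
    effect_size: float = 0.3
    noise_sd: float = 0.05
    sens_fraction: float = 0.5
    seed: int = 0
    # genome / biology stream (shared across cohorts of the same "universe")
    genome_seed: int = 20200807
    genome_length: int = 10_000_000
    chrom: str = "chrS1"
    cluster_purity: float = 0.9
    mutation_rate: float = 0.05
    expr_coupling: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "n_cells",
            "n_drugs",
            "n_mut_genes",
            "n_expr_genes",
            "n_cnv_genes",
            "n_cpg",
            "n_descriptors",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_causal_cpg_per_drug < 0:
            raise ValidationError(
                f"n_causal_cpg_per_drug must be >= 0, got {self.n_causal_cpg_per_drug}"
            )
        if self.n_causal_cpg_per_drug > self.n_cpg:
            raise ValidationError("n_causal_cpg_per_drug cannot exceed n_cpg")
        if not (0.0 < self.sens_fraction < 1.0):
            raise ValidationError(f"sens_fraction must lie in (0,1), got {self.sens_fraction}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not (0.5 <= self.cluster_purity <= 1.0):
            raise ValidationError(f"cluster_purity must lie in [0.5,1], got {self.cluster_purity}")
        if self.genome_length < self.n_cpg * 5000:
            raise ValidationError("genome_length too small for n_cpg islands (need ~5 kb per island)")


@dataclass
class GroundTruth:
    """What was planted: per-drug causal islands and weights, plus cohort structure."""

    causal_sites: dict[str, list[str]]
    weights: dict[str, list[float]]
    drug_base: dict[str, float]
    cell_cluster: dict[str, int]
    tfbs_overlap_flags: dict[str, bool] | None = None


@dataclass
class Cohort:
    spec: CohortSpec
    mutation: OmicsMatrix
    copy_number: OmicsMatrix
    expression: OmicsMatrix
    methylation: OmicsMatrix
    descriptors: pd.DataFrame  # drugs x descriptors
    responses: ResponseTable
    truth: GroundTruth


@dataclass
class Annotation:
    cpg_islands: list[GenomicInterval]
    tfbs: list[GenomicInterval]  # name = TF
    noncoding: list[GenomicInterval]
    tf_targets: dict[str, set[str]]
    overlap_flags: dict[str, bool]  # island ID -> overlaps >=1 TFBS


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(list(key))


def island_intervals(spec: CohortSpec) -> list[GenomicInterval]:
    """Non-overlapping CpG islands averaging ~2,000 bp on the synthetic chromosome.

    Determined by ``genome_seed`` alone (given the same sizes), so every
    cohort of the same universe keys its methylation rows identically.
    """
    rng = _rng(spec.genome_seed, 11)
    lengths = np.clip(rng.normal(2000, 300, spec.n_cpg), 500, 4000).round().astype(int)
    free = spec.genome_length - int(lengths.sum())
    gaps_at = np.sort(rng.integers(0, free, spec.n_cpg))
    starts = gaps_at + np.concatenate([[0], np.cumsum(lengths[:-1])])
    out = []
    for s, ln in zip(starts, lengths):
        iv = GenomicInterval(spec.chrom, int(s), int(s + ln))
        out.append(GenomicInterval(iv.chrom, iv.start, iv.end, name=format_interval_id(iv)))
    return out


def _drug_biology(spec: CohortSpec):
    """Drug bases, causal sites/weights and site polarities (genome_seed stream)."""
    rng = _rng(spec.genome_seed, 101)
    polarity = rng.choice([-1.0, 1.0], size=spec.n_cpg)
    n_sens = int(round(spec.sens_fraction * spec.n_drugs))
    n_sens = min(max(n_sens, 1), spec.n_drugs - 1)
    leaning = np.array([True] * n_sens + [False] * (spec.n_drugs - n_sens))
    rng.shuffle(leaning)
    base_raw = np.where(
        leaning,
        rng.uniform(0.02, 0.15, spec.n_drugs),
        rng.uniform(0.955, 0.999, spec.n_drugs),
    )
    causal_idx = np.array(
        [
            np.sort(rng.choice(spec.n_cpg, spec.n_causal_cpg_per_drug, replace=False))
            for _ in range(spec.n_drugs)
        ],
        dtype=int,
    ).reshape(spec.n_drugs, spec.n_causal_cpg_per_drug)
    weights = spec.effect_size * polarity[causal_idx] if spec.n_causal_cpg_per_drug else np.zeros((spec.n_drugs, 0))
    return polarity, base_raw, causal_idx, weights


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort; identical spec implies identical output."""
    cells = [f"CELL{i:04d}" for i in range(spec.n_cells)]
    drugs = [f"DRUG{i:03d}" for i in range(spec.n_drugs)]
    islands = island_intervals(spec)
    cpg_ids = [iv.name for iv in islands]
    polarity, base_raw, causal_idx, weights = _drug_biology(spec)

    # --- methylation: bimodal Beta mixture with a two-phenotype cell structure
    rng_meth = _rng(spec.seed, 5)
    cluster = rng_meth.integers(0, 2, spec.n_cells)  # 0/1 phenotype per cell
    p_high = np.where(
        (polarity[:, None] > 0) == (cluster[None, :] == 1),
        spec.cluster_purity,
        1.0 - spec.cluster_purity,
    )
    high = rng_meth.random((spec.n_cpg, spec.n_cells)) < p_high
    beta_low = rng_meth.beta(0.5, 5.0, (spec.n_cpg, spec.n_cells))
    beta_high = rng_meth.beta(5.0, 0.5, (spec.n_cpg, spec.n_cells))
    beta = np.where(high, beta_high, beta_low)
    methylation = OmicsMatrix(Modality.METHYLATION, cpg_ids, cells, beta)

    # --- other omics
    rng_mut = _rng(spec.seed, 2)
    mutation = OmicsMatrix(
        Modality.MUTATION,
        [f"MUTG{i:04d}" for i in range(spec.n_mut_genes)],
        cells,
        (rng_mut.random((spec.n_mut_genes, spec.n_cells)) < spec.mutation_rate).astype(float),
    )
    rng_cnv = _rng(spec.seed, 3)
    copy_number = OmicsMatrix(
        Modality.COPY_NUMBER,
        [f"CNVG{i:04d}" for i in range(spec.n_cnv_genes)],
        cells,
        rng_cnv.normal(2.0, 0.5, (spec.n_cnv_genes, spec.n_cells)),
    )
    rng_expr = _rng(spec.seed, 4)
    gene_ids = [f"GENE{i:04d}" for i in range(spec.n_expr_genes)]
    gene_mean = rng_expr.normal(3.0, 1.0, spec.n_expr_genes)
    log_expr = gene_mean[:, None] + rng_expr.normal(0.0, 0.5, (spec.n_expr_genes, spec.n_cells))
    # couple each causal island's downstream gene to its beta (methylation
    # silencing: higher beta -> lower expression), so the site-gene
    # correlation stage has real signal to find
    for d in range(spec.n_drugs):
        for k in causal_idx[d]:
            g = int(k) % spec.n_expr_genes
            log_expr[g] = gene_mean[g] - spec.expr_coupling * (beta[k] - 0.5) + rng_expr.normal(
                0.0, 0.2, spec.n_cells
            )
    expression = OmicsMatrix(Modality.EXPRESSION, gene_ids, cells, np.exp(log_expr))

    rng_desc = _rng(spec.seed, 6)
    descriptors = pd.DataFrame(
        rng_desc.normal(0.0, 1.0, (spec.n_drugs, spec.n_descriptors)),
        index=drugs,
        columns=[f"DESC{i:02d}" for i in range(spec.n_descriptors)],
    )

    # --- responses
    rng_noise = _rng(spec.seed, 7)
    effect = (
        np.einsum("dk,dkc->dc", weights, beta[causal_idx, :])
        if spec.n_causal_cpg_per_drug
        else np.zeros((spec.n_drugs, spec.n_cells))
    )
    # centre each drug at its tail baseline: E[beta] = 0.5 marginally
    base = base_raw - 0.5 * weights.sum(axis=1)
    noise = rng_noise.normal(0.0, spec.noise_sd, (spec.n_drugs, spec.n_cells)) if spec.noise_sd else 0.0
    aucdr = np.clip(base[:, None] + effect + noise, 0.0, 1.0)
    records = pd.DataFrame(
        {
            "cell_id": np.repeat(cells, spec.n_drugs),
            "drug_id": np.tile(drugs, spec.n_cells),
            "aucdr": aucdr.T.ravel(),
        }
    )
    responses = ResponseTable(records)

    truth = GroundTruth(
        causal_sites={drugs[d]: [cpg_ids[k] for k in causal_idx[d]] for d in range(spec.n_drugs)},
        weights={drugs[d]: [float(w) for w in weights[d]] for d in range(spec.n_drugs)},
        drug_base={drugs[d]: float(base_raw[d]) for d in range(spec.n_drugs)},
        cell_cluster={cells[c]: int(cluster[c]) for c in range(spec.n_cells)},
    )
    return Cohort(spec, mutation, copy_number, expression, methylation, descriptors, responses, truth)


def site_gene_pairs(spec: CohortSpec) -> list[tuple[str, str]]:
    """The island -> downstream-gene pairing used by the correlation stage."""
    islands = island_intervals(spec)
    return [(iv.name, f"GENE{i % spec.n_expr_genes:04d}") for i, iv in enumerate(islands)]


def generate_genome_annotation(
    spec: CohortSpec,
    frac_cpg_in_tfbs: float,
    seed: int = 0,
    tfbs_length: int = 200,
    n_background_tfbs: int = 300,
    n_tfs: int = 50,
    max_targets_per_tf: int = 3,
) -> Annotation:
    """CpG-island / TFBS / non-coding BEDs plus a TF->target table.

    Exactly ``round(frac_cpg_in_tfbs * n_cpg)`` islands overlap a TFBS (one
    placed inside each chosen island); ``n_background_tfbs`` additional TFBS
    fall in non-coding space away from every island, so the overlap count is
    exact by construction. The non-coding BED is the complement of the
    islands over the chromosome (>= 50% of the genome at default sizes) and
    is the sampling space of the permutation null.
    """
    if not (0.0 <= frac_cpg_in_tfbs <= 1.0):
        raise ValidationError(f"frac_cpg_in_tfbs must lie in [0,1], got {frac_cpg_in_tfbs}")
    rng = _rng(seed, 21)
    islands = island_intervals(spec)
    n_overlap = int(round(frac_cpg_in_tfbs * spec.n_cpg))
    chosen = set(rng.choice(spec.n_cpg, n_overlap, replace=False).tolist())

    tf_names = [f"TF{i:03d}" for i in range(n_tfs)]
    tf_targets: dict[str, set[str]] = {}
    for tf in tf_names:
        n_t = int(rng.integers(1, max_targets_per_tf + 1))
        genes = rng.choice(spec.n_expr_genes, n_t, replace=False)
        tf_targets[tf] = {f"GENE{g:04d}" for g in genes}

    tfbs: list[GenomicInterval] = []
    for i in sorted(chosen):
        iv = islands[i]
        ln = min(tfbs_length, iv.length)
        off = int(rng.integers(0, iv.length - ln + 1))
        tf = tf_names[int(rng.integers(0, n_tfs))]
        tfbs.append(GenomicInterval(iv.chrom, iv.start + off, iv.start + off + ln, name=tf))

    # non-coding space = complement of the islands
    noncoding: list[GenomicInterval] = []
    pos = 0
    for iv in islands:
        if iv.start > pos:
            noncoding.append(GenomicInterval(spec.chrom, pos, iv.start, name="noncoding"))
        pos = iv.end
    if pos < spec.genome_length:
        noncoding.append(GenomicInterval(spec.chrom, pos, spec.genome_length, name="noncoding"))

    # background TFBS fully inside non-coding gaps, clear of every island
    fit = [g for g in noncoding if g.length >= tfbs_length + 2]
    weights = np.array([g.length - tfbs_length - 1 for g in fit], dtype=float)
    probs = weights / weights.sum()
    for _ in range(n_background_tfbs):
        g = fit[int(rng.choice(len(fit), p=probs))]
        off = int(rng.integers(1, g.length - tfbs_length))
        tf = tf_names[int(rng.integers(0, n_tfs))]
        tfbs.append(GenomicInterval(g.chrom, g.start + off, g.start + off + tfbs_length, name=tf))
    tfbs.sort(key=lambda t: (t.chrom, t.start, t.end))

    overlap_flags = {iv.name: (i in chosen) for i, iv in enumerate(islands)}
    return Annotation(islands, tfbs, noncoding, tf_targets, overlap_flags)


# ---------------------------------------------------------------------------
# On-disk layout


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.mutation, outdir / "mutation.tsv")
    write_matrix(cohort.copy_number, outdir / "copy_number.tsv")
    write_matrix(cohort.expression, outdir / "expression.tsv")
    write_matrix(cohort.methylation, outdir / "methylation.tsv")
    cohort.descriptors.to_csv(outdir / "descriptors.tsv", sep="\t")
    write_response(cohort.responses, outdir / "responses.tsv")
    truth = {
        "causal_sites": cohort.truth.causal_sites,
        "weights": cohort.truth.weights,
        "drug_base": cohort.truth.drug_base,
        "cell_cluster": cohort.truth.cell_cluster,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    with open(outdir / "site_gene_pairs.tsv", "w") as fh:
        fh.write("cpg_id\tgene_id\n")
        for cpg, gene in site_gene_pairs(cohort.spec):
            fh.write(f"{cpg}\t{gene}\n")
    (outdir / "cohort_spec.json").write_text(
        json.dumps(dataclasses.asdict(cohort.spec), indent=1, sort_keys=True)
    )


def write_annotation(ann: Annotation, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed(ann.cpg_islands, outdir / "cpg_islands.bed")
    write_bed(ann.tfbs, outdir / "tfbs.bed")
    write_bed(ann.noncoding, outdir / "noncoding.bed")
    write_tf_targets(ann.tf_targets, outdir / "tf_targets.tsv")
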