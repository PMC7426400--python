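"""TFBS overlap of selected CpG islands and the random-fragment permutation null.

A selected island "hits" a transcription-factor binding site when the two
intervals share at least one base pair. The enrichment null asks how many
of ``n_fragments`` random fragments (length ~ the average CpG island,
2,000 bp by default) drawn uniformly from non-coding space would hit a
TFBS; the draw is repeated ``reps`` times (1,000 by default). Two tail
probabilities are reported: the add-one empirical estimator

    p_emp = (1 + #{null >= observed}) / (reps + 1),

which is bounded below by 1/(reps+1) and never exactly zero, and a
Gaussian upper tail fitted to the null sample's mean and sd, which is the
only way a 1,000-repeat simulation can meaningfully report values like
p < 1e-26 for extreme enrichments.

The module also joins overlapping TFs to their literature-curated target
genes and correlates island (or island-shore) methylation with downstream
gene expression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io import GenomicInterval, OmicsMatrix, ValidationError, format_interval_id, parse_interval_id

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "overlap_tfbs",
    "sample_null_overlap",
    "enrichment_pvalue",
    "run_enrichment",
    "map_tf_targets",
    "correlate_site_gene",
]


def _forest(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    forest: dict[str, IntervalTree] = {}
    for iv in intervals:
        forest.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.name)
    return forest


def overlap_tfbs(
    sites: Sequence[GenomicInterval],
    tfbs: Sequence[GenomicInterval],
) -> tuple[int, dict[str, list[str]]]:
    """Count sites sharing >= 1 bp with any TFBS; list distinct TFs per site.

    Intervals are half-open, so a site ending where a TFBS starts does not
    overlap. A complete chromosome-name mismatch triggers a warning (a zero
    count is legal), catching genome-naming accidents.
    """
    forest = _forest(tfbs)
    if sites and tfbs and not ({s.chrom for s in sites} & set(forest)):
        msg = "no chromosome shared between sites and TFBS; overlap count will be 0"
        log.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    per_site: dict[str, list[str]] = {}
    count = 0
    for s in sites:
        tree = forest.get(s.chrom)
        hits = sorted({h.data for h in tree.overlap(s.start, s.end)}) if tree else []
        per_site[s.name or format_interval_id(s)] = hits
        if hits:
            count += 1
    return count, per_site


def _merged_arrays(intervals: Sequence[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome merged (starts, ends) arrays, sorted."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def sample_null_overlap(
    noncoding: Sequence[GenomicInterval],
    tfbs: Sequence[GenomicInterval],
    n_fragments: int = 100,
    fragment_length: int = 2000,
    reps: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of TFBS-hit counts for random non-coding fragments.

    Each repeat draws ``n_fragments`` start positions uniformly over all
    placements where the whole fragment fits inside a single non-coding
    interval (fragments never span gaps), and records how many fragments
    hit >= 1 TFBS. Returns the ``reps`` counts.
    """
    usable = [g for g in noncoding if g.length >= fragment_length]
    if not usable:
        raise ValidationError(
            f"no non-coding interval can hold a {fragment_length} bp fragment"
        )
    starts_per = np.array([g.length - fragment_length + 1 for g in usable], dtype=np.int64)
    cum = np.cumsum(starts_per)
    total = int(cum[-1])
    g_start = np.array([g.start for g in usable], dtype=np.int64)
    chroms = np.array([g.chrom for g in usable])
    merged = _merged_arrays(tfbs)

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, total, size=(reps, n_fragments))
    which = np.searchsorted(cum, draws, side="right")
    frag_start = g_start[which] + (draws - (cum[which] - starts_per[which]))
    frag_end = frag_start + fragment_length

    hit = np.zeros(draws.shape, dtype=bool)
    for chrom in np.unique(chroms):
        mask = chroms[which] == chrom
        if chrom not in merged or not mask.any():
            continue
        m_start, m_end = merged[chrom]
        # first merged TFBS ending beyond the fragment start; a hit iff it
        # also begins before the fragment end (half-open semantics)
        idx = np.searchsorted(m_end, frag_start[mask], side="right")
        ok = idx < len(m_start)
        sub = np.zeros(mask.sum(), dtype=bool)
        sub[ok] = m_start[idx[ok]] < frag_end[mask][ok]
        hit[mask] = sub
    return hit.sum(axis=1)


def enrichment_pvalue(observed: int, null_counts: np.ndarray) -> tuple[float, float]:
    """Add-one empirical p and Gaussian-tail p for an observed hit count."""
    null_counts = np.asarray(null_counts)
    reps = null_counts.size
    if reps < 1:
        raise ValidationError("need at least one null repeat")
    p_emp = (1.0 + int((null_counts >= observed).sum())) / (reps + 1.0)
    mean = float(null_counts.mean())
    sd = float(null_counts.std(ddof=1)) if reps > 1 else 0.0
    if sd == 0.0:
        msg = "zero-variance null sample; Gaussian-tail p degenerates to 0/1"
        log.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        p_gauss = 0.0 if observed > mean else 1.0
    else:
        p_gauss = float(stats.norm.sf(observed, loc=mean, scale=sd))
    return p_emp, p_gauss


@dataclass
class EnrichmentResult:
    drug_id: str
    n_sites: int
    observed: int
    per_site_tfs: dict[str, list[str]]
    null_counts: np.ndarray
    p_empirical: float
    p_gaussian: float
    n_fragments: int
    fragment_length: int
    reps: int
    seed: int

    @property
    def overlap_percent(self) -> float:
        return 100.0 * self.observed / self.n_sites if self.n_sites else 0.0


def run_enrichment(
    sites: Sequence[GenomicInterval],
    tfbs: Sequence[GenomicInterval],
    noncoding: Sequence[GenomicInterval],
    n_fragments: int = 100,
    fragment_length: int = 2000,
    reps: int = 1000,
    seed: int = 0,
    drug_id: str = "",
) -> EnrichmentResult:
    """Observed TFBS overlap of the selected sites against the permutation null."""
    observed, per_site = overlap_tfbs(sites, tfbs)
    null_counts = sample_null_overlap(noncoding, tfbs, n_fragments, fragment_length, reps, seed)
    p_emp, p_gauss = enrichment_pvalue(observed, null_counts)
    return EnrichmentResult(
        drug_id,
        len(sites),
        observed,
        per_site,
        null_counts,
        p_emp,
        p_gauss,
        n_fragments,
        fragment_length,
        reps,
        seed,
    )


def map_tf_targets(
    per_site_tfs: Mapping[str, Sequence[str]],
    tf_targets: Mapping[str, set[str]],
) -> tuple[dict[str, list[str]], float]:
    """Join per-site TFs to their target genes.

    Returns the per-site sorted target-gene lists and the fraction of
    TFBS-overlapping sites whose TFs have >= 1 curated target.
    """
    per_site_targets: dict[str, list[str]] = {}
    n_overlapping = n_with_target = 0
    for site, tfs in per_site_tfs.items():
        targets: set[str] = set()
        for tf in tfs:
            targets |= set(tf_targets.get(tf, ()))
        per_site_targets[site] = sorted(targets)
        if tfs:
            n_overlapping += 1
            if targets:
                n_with_target += 1
    fraction = n_with_target / n_overlapping if n_overlapping else 0.0
    return per_site_targets, fraction


def _shore_ids(cpg_id: str, shore_width: int) -> list[str]:
    iv = parse_interval_id(cpg_id)
    shores = []
    if iv.start > 0:
        shores.append(GenomicInterval(iv.chrom, max(0, iv.start - shore_width), iv.start))
    shores.append(GenomicInterval(iv.chrom, iv.end, iv.end + shore_width))
    return [format_interval_id(s) for s in shores]


def correlate_site_gene(
    beta: OmicsMatrix,
    expression: OmicsMatrix,
    pairs: Sequence[tuple[str, str]],
    region: str = "island",
    shore_width: int = 2000,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Pearson correlation of site methylation with downstream gene expression.

    ``pairs`` assigns each CpG island its downstream gene. With
    ``region="shore"`` the island's flanking intervals (0 to
    ``shore_width`` bp each side, looked up by their formatted interval
    IDs in the beta matrix) are averaged instead of the island row itself.
    Pairs with a missing row or fewer than 3 shared cells are skipped with
    a log entry. Returns the per-pair records and the |PCC| bin counts
    reported alongside (> 0.5, and 0.3 - 0.5].
    """
    if region not in ("island", "shore"):
        raise ValidationError(f"region must be 'island' or 'shore', got {region!r}")
    shared = sorted(set(beta.cell_ids) & set(expression.cell_ids))
    if len(shared) < 3:
        raise ValidationError("need >= 3 cells shared between beta and expression matrices")
    b = beta.to_frame()[shared]
    e = expression.to_frame()[shared]
    rows = []
    for cpg_id, gene_id in pairs:
        if gene_id not in e.index:
            log.info("correlate_site_gene: gene %r absent from expression, pair skipped", gene_id)
            continue
        if region == "island":
            if cpg_id not in b.index:
                log.info("correlate_site_gene: island %r absent from beta, pair skipped", cpg_id)
                continue
            meth = b.loc[cpg_id].to_numpy()
        else:
            present = [s for s in _shore_ids(cpg_id, shore_width) if s in b.index]
            if not present:
                log.info("correlate_site_gene: no shore rows for %r, pair skipped", cpg_id)
                continue
            meth = b.loc[present].to_numpy().mean(axis=0)
        expr = e.loc[gene_id].to_numpy()
        if np.std(meth) == 0 or np.std(expr) == 0:
            log.info("correlate_site_gene: constant vector for pair (%r, %r), skipped", cpg_id, gene_id)
            continue
        pcc = float(stats.pearsonr(meth, expr)[0])
        rows.append({"cpg_id": cpg_id, "gene_id": gene_id, "pcc": pcc, "n_cells": len(shared), "region": region})
    records = pd.DataFrame(rows, columns=["cpg_id", "gene_id", "pcc", "n_cells", "region"])
    abs_pcc = records["pcc"].abs() if len(records) else pd.Series(dtype=float)
    bins = {
        ">0.5": int((abs_pcc > 0.5).sum()),
        "0.3-0.5": int(((abs_pcc > 0.3) & (abs_pcc <= 0.5)).sum()),
    }
    return records, bins
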