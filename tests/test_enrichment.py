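"""Interval overlap, the permutation null, p-values and site-gene correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdrug.enrichment import (
    correlate_site_gene,
    enrichment_pvalue,
    map_tf_targets,
    overlap_tfbs,
    run_enrichment,
    sample_null_overlap,
)
from methdrug.io import GenomicInterval, Modality, OmicsMatrix, ValidationError


def brute_force_overlap(sites, tfbs):
    """All-pairs interval scan."""
    count = 0
    for s in sites:
        if any(t.chrom == s.chrom and t.start < s.end and s.start < t.end for t in tfbs):
            count += 1
    return count


def iv(start, end, name="", chrom="chr1"):
    return GenomicInterval(chrom, start, end, name)


class TestOverlapTfbs:
    def test_disjoint_sets(self):
        count, per_site = overlap_tfbs([iv(0, 100, "a")], [iv(500, 600, "TF1")])
        assert count == 0 and per_site["a"] == []

    def test_one_bp_overlap_counts(self):
        count, per_site = overlap_tfbs([iv(100, 200, "a")], [iv(199, 300, "TF1")])
        assert count == 1 and per_site["a"] == ["TF1"]

    def test_half_open_boundary_no_overlap(self):
        count, _ = overlap_tfbs([iv(100, 200, "a")], [iv(200, 300, "TF1")])
        assert count == 0

    def test_distinct_tfs_listed_once(self):
        tfbs = [iv(100, 150, "TF2"), iv(120, 180, "TF1"), iv(130, 160, "TF1")]
        _, per_site = overlap_tfbs([iv(100, 200, "a")], tfbs)
        assert per_site["a"] == ["TF1", "TF2"]

    def test_chromosome_mismatch_warns(self):
        with pytest.warns(RuntimeWarning, match="chromosome"):
            count, _ = overlap_tfbs([iv(0, 10, "a", chrom="chr1")], [iv(0, 10, "t", chrom="chr2")])
        assert count == 0

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(10):
            sites = [
                iv(int(s), int(s) + int(rng.integers(50, 500)), f"s{k}")
                for k, s in enumerate(rng.integers(0, 50_000, 60))
            ]
            tfbs = [
                iv(int(s), int(s) + int(rng.integers(10, 300)), f"TF{k % 7}")
                for k, s in enumerate(rng.integers(0, 50_000, 80))
            ]
            count, _ = overlap_tfbs(sites, tfbs)
            assert count == brute_force_overlap(sites, tfbs)


class TestNullSampler:
    NONCODING = [iv(0, 10_000, "nc")]

    def test_empty_tfbs_all_zero(self):
        counts = sample_null_overlap(self.NONCODING, [], n_fragments=20, fragment_length=100, reps=50, seed=0)
        assert (counts == 0).all() and len(counts) == 50

    def test_fully_covered_all_hits(self):
        counts = sample_null_overlap(
            self.NONCODING, [iv(0, 10_000, "TF1")], n_fragments=20, fragment_length=100, reps=50, seed=0
        )
        assert (counts == 20).all()

    def test_no_interval_long_enough_rejected(self):
        with pytest.raises(ValidationError, match="fragment"):
            sample_null_overlap([iv(0, 50, "nc")], [], fragment_length=100)

    def test_deterministic_under_seed(self):
        a = sample_null_overlap(self.NONCODING, [iv(4000, 4500, "T")], 10, 500, 200, seed=9)
        b = sample_null_overlap(self.NONCODING, [iv(4000, 4500, "T")], 10, 500, 200, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_mean_matches_interval_geometry(self):
        # fragment [s, s+1000) with s uniform on [0, 9001) hits [4000,4500)
        # iff 3000 < s < 4500: 1499 of 9001 placements
        tfbs = [iv(4000, 4500, "T")]
        counts = sample_null_overlap(self.NONCODING, tfbs, n_fragments=100, fragment_length=1000, reps=400, seed=1)
        p_hit = 1499 / 9001
        expected = 100 * p_hit
        sd = np.sqrt(100 * p_hit * (1 - p_hit))
        assert abs(counts.mean() - expected) < 3 * sd / np.sqrt(400)

    def test_fragments_respect_interval_bounds(self):
        # null over two tiny intervals; a fragment spanning the gap would hit
        noncoding = [iv(0, 500, "a"), iv(10_000, 10_500, "b")]
        tfbs = [iv(500, 10_000, "T")]  # exactly the gap
        counts = sample_null_overlap(noncoding, tfbs, n_fragments=50, fragment_length=400, reps=100, seed=2)
        assert (counts == 0).all()


class TestEnrichmentPvalue:
    def test_observed_below_null_p_near_one(self):
        null = np.arange(50, 100)
        p_emp, _ = enrichment_pvalue(10, null)
        assert p_emp == pytest.approx(1.0, abs=0.02)

    def test_observed_above_null_lower_bound(self):
        null = np.zeros(1000, dtype=int) + 5
        p_emp, _ = enrichment_pvalue(100, null)
        assert p_emp == pytest.approx(1 / 1001)

    def test_gaussian_tail_far_exceeds_empirical_resolution(self):
        rng = np.random.default_rng(3)
        null = rng.normal(5, 2, 1000)
        _, p_gauss = enrichment_pvalue(100, null)
        assert p_gauss < 1e-26
        # sanity against the closed form at the sample moments
        expected = stats.norm.sf(100, null.mean(), null.std(ddof=1))
        assert p_gauss == pytest.approx(expected)

    def test_zero_variance_null_flagged(self):
        null = np.full(100, 7)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            p_emp, p_gauss = enrichment_pvalue(10, null)
        assert p_gauss == 0.0
        with pytest.warns(RuntimeWarning):
            _, p_gauss_low = enrichment_pvalue(3, null)
        assert p_gauss_low == 1.0

    def test_empirical_lower_bound_invariant(self, rng):
        for reps in (10, 100, 500):
            null = rng.integers(0, 50, reps)
            p_emp, _ = enrichment_pvalue(1000, null)
            assert p_emp >= 1 / (reps + 1)


class TestMapTfTargets:
    def test_empty_map(self):
        _, frac = map_tf_targets({"s1": ["TF1"], "s2": ["TF2"]}, {})
        assert frac == 0.0

    def test_full_coverage(self):
        targets, frac = map_tf_targets(
            {"s1": ["TF1"], "s2": ["TF2"]}, {"TF1": {"G1"}, "TF2": {"G2", "G3"}}
        )
        assert frac == 1.0 and targets["s2"] == ["G2", "G3"]

    def test_hand_joined_three_site_case(self):
        per_site = {"s1": ["TF1", "TF2"], "s2": ["TF3"], "s3": [], "s4": ["TF4"]}
        tf_map = {"TF1": {"G1"}, "TF2": {"G2"}, "TF3": set(), "TF4": {"G1"}}
        targets, frac = map_tf_targets(per_site, tf_map)
        # s3 does not overlap any TFBS so it is excluded from the denominator;
        # of the 3 overlapping sites, s2's TF has no curated target
        assert frac == pytest.approx(2 / 3)
        assert targets["s1"] == ["G1", "G2"]


def _omics(ids, cells, values, modality):
    return OmicsMatrix(modality, ids, cells, np.asarray(values, float))


class TestCorrelateSiteGene:
    CELLS = [f"c{i}" for i in range(5)]

    def test_proportional_perfect_correlation(self):
        beta = _omics(["chr1: 101-200"], self.CELLS, [[0.1, 0.2, 0.3, 0.4, 0.5]], Modality.METHYLATION)
        expr = _omics(["g1"], self.CELLS, [[1.0, 2.0, 3.0, 4.0, 5.0]], Modality.EXPRESSION)
        records, bins = correlate_site_gene(beta, expr, [("chr1: 101-200", "g1")])
        assert records["pcc"].iloc[0] == pytest.approx(1.0)
        assert bins[">0.5"] == 1

    def test_antiproportional(self):
        beta = _omics(["chr1: 101-200"], self.CELLS, [[0.1, 0.2, 0.3, 0.4, 0.5]], Modality.METHYLATION)
        expr = _omics(["g1"], self.CELLS, [[5.0, 4.0, 3.0, 2.0, 1.0]], Modality.EXPRESSION)
        records, _ = correlate_site_gene(beta, expr, [("chr1: 101-200", "g1")])
        assert records["pcc"].iloc[0] == pytest.approx(-1.0)

    def test_five_cell_hand_oracle(self):
        b = np.array([0.1, 0.8, 0.3, 0.9, 0.2])
        e = np.array([2.0, 1.1, 3.5, 0.4, 2.2])
        beta = _omics(["chr1: 101-200"], self.CELLS, [b], Modality.METHYLATION)
        expr = _omics(["g1"], self.CELLS, [e], Modality.EXPRESSION)
        records, _ = correlate_site_gene(beta, expr, [("chr1: 101-200", "g1")])
        hand = ((b - b.mean()) @ (e - e.mean())) / (
            np.sqrt(((b - b.mean()) ** 2).sum()) * np.sqrt(((e - e.mean()) ** 2).sum())
        )
        assert records["pcc"].iloc[0] == pytest.approx(hand, abs=1e-12)

    def test_shore_region_uses_flanks(self):
        island = "chr1: 5001-6000"
        left, right = "chr1: 3001-5000", "chr1: 6001-8000"
        rng = np.random.default_rng(8)
        shore_signal = rng.random(5)
        beta = _omics(
            [island, left, right],
            self.CELLS,
            [rng.random(5), shore_signal, shore_signal],
            Modality.METHYLATION,
        )
        expr = _omics(["g1"], self.CELLS, [2.0 * shore_signal + 1.0], Modality.EXPRESSION)
        records, _ = correlate_site_gene(beta, expr, [(island, "g1")], region="shore", shore_width=2000)
        assert records["region"].iloc[0] == "shore"
        assert records["pcc"].iloc[0] == pytest.approx(1.0)

    def test_missing_rows_skipped(self):
        beta = _omics(["chr1: 101-200"], self.CELLS, [[0.1, 0.2, 0.3, 0.4, 0.5]], Modality.METHYLATION)
        expr = _omics(["g1"], self.CELLS, [[1.0, 2.0, 3.0, 4.0, 5.0]], Modality.EXPRESSION)
        records, _ = correlate_site_gene(beta, expr, [("chr1: 999-1200", "g1"), ("chr1: 101-200", "gX")])
        assert len(records) == 0

    def test_planted_coupling_recovered_on_cohort(self, small_cohort):
        # the generator couples each causal island's downstream gene to its beta
        truth = small_cohort.truth
        causal = [s for sites in truth.causal_sites.values() for s in sites]
        n_expr = small_cohort.spec.n_expr_genes
        island_index = {s: k for k, s in enumerate(small_cohort.methylation.feature_ids)}
        pairs = [(s, f"GENE{island_index[s] % n_expr:04d}") for s in set(causal)]
        records, bins = correlate_site_gene(small_cohort.methylation, small_cohort.expression, pairs)
        assert (records["pcc"] < 0).all()  # methylation silences expression
        assert bins[">0.5"] >= len(pairs) * 0.8


class TestRunEnrichment:
    def test_end_to_end_on_synthetic_annotation(self, small_annotation):
        flagged = [ivl for ivl in small_annotation.cpg_islands if small_annotation.overlap_flags[ivl.name]]
        res = run_enrichment(
            flagged[:30],
            small_annotation.tfbs,
            small_annotation.noncoding,
            n_fragments=30,
            fragment_length=2000,
            reps=300,
            seed=5,
        )
        assert res.observed == 30  # flagged islands all contain a TFBS
        assert res.p_empirical == pytest.approx(1 / 301)
        assert (res.null_counts <= 30).all() and (res.null_counts >= 0).all()
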