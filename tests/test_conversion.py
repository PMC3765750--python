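"""Conversion-rate summaries: chromosome level, region level, advisory."""

import numpy as np
import pytest

from bsqc.conversion import (
    advisory,
    chrom_summary,
    chrom_summary_row,
    conversion_histogram,
    conversion_rate,
    format_percent,
    summarize_regions,
)
from bsqc.records import MethylRecord, TargetRegion, ValidationError

from .conftest import make_record, random_records


class TestConversionRate:
    @pytest.mark.parametrize(
        "ratio,expected", [(0.0, 1.0), (1.0, 0.0), (0.0039, 0.9961)]
    )
    def test_complement_of_methylation_ratio(self, ratio, expected):
        rec = make_record(coverage=5, ratio=ratio)
        assert conversion_rate(rec) == pytest.approx(expected)

    def test_undefined_without_coverage(self):
        rec = make_record(coverage=0, ratio=None)
        with pytest.raises(ValidationError):
            conversion_rate(rec)


class TestChromSummary:
    def test_hand_computed_small_set(self):
        # 5 nonCGc sites, 2 covered with conversions {1.0, 0.5}
        records = [
            make_record(pos=0, context="CHH", coverage=3, ratio=0.0),  # conv 1.0
            make_record(pos=1, context="CHG", coverage=2, ratio=0.5),  # conv 0.5
            make_record(pos=2, context="CHH", coverage=0, ratio=None),
            make_record(pos=3, context="CHH", coverage=0, ratio=None),
            make_record(pos=4, context="CHG", coverage=0, ratio=None),
            make_record(pos=5, context="CG", coverage=9, ratio=1.0),  # excluded
        ]
        s = chrom_summary(records)
        assert (s.tncgc, s.tncgc_with_cov) == (5, 2)
        assert format_percent(s.percent) == "40.000%"
        assert (s.min, s.median, s.mean, s.max) == (0.5, 0.75, 0.75, 1.0)

    def test_coverage_percent_rendering(self):
        # the census-to-percent arithmetic behind the printed summary cell
        assert format_percent(100 * 622926 / 44683043) == "1.394%"

    def test_all_cpg_flagged_empty(self):
        records = [make_record(pos=i, context="CG", coverage=1, ratio=0.5) for i in range(4)]
        s = chrom_summary(records)
        assert s.tncgc == 0 and s.flagged
        assert s.median is None
        assert "NA" in chrom_summary_row(s)

    def test_permutation_invariance_and_sort_oracle(self, rng):
        records = random_records(rng, 500)
        s1 = chrom_summary(records)
        shuffled = list(records)
        rng.shuffle(shuffled)
        assert chrom_summary(shuffled) == s1
        # sort-based oracle for the order statistics
        vals = sorted(
            1 - r.methyl_ratio for r in records if r.is_noncg and r.coverage > 0
        )
        assert s1.min == vals[0] and s1.max == vals[-1]
        assert s1.mean == pytest.approx(np.mean(vals))
        assert s1.percent == pytest.approx(100 * len(vals) / s1.tncgc)

    def test_wrong_chromosome_rejected(self):
        with pytest.raises(ValidationError):
            chrom_summary([make_record()], chrom="chr9")


class TestRegionSummaries:
    def test_hand_computed_region(self):
        records = [
            make_record(pos=10, context="CHH", coverage=1, ratio=0.0),  # 1.0
            make_record(pos=11, context="CHH", coverage=1, ratio=0.0),  # 1.0
            make_record(pos=12, context="CHG", coverage=1, ratio=0.8),  # 0.2
        ]
        (s,) = summarize_regions(records, [TargetRegion("chr1", 0, 100)])
        assert (s.n_sites, s.n_covered) == (3, 3)
        assert s.mean_bs == pytest.approx((1.0 + 1.0 + 0.2) / 3)
        assert s.median_bs == 1.0

    def test_no_covered_sites(self):
        records = [make_record(pos=i, coverage=0, ratio=None) for i in range(4)]
        (s,) = summarize_regions(records, [TargetRegion("chr1", 0, 10)])
        assert (s.n_sites, s.n_covered) == (4, 0)
        assert s.mean_bs is None and s.median_bs is None
        assert s.coverage_frac == 0

    def test_absent_chromosome_gives_empty_summary(self):
        (s,) = summarize_regions([make_record()], [TargetRegion("chrZ", 0, 10)])
        assert s.n_sites == 0 and s.coverage_frac is None

    def test_half_open_boundaries(self):
        records = [make_record(pos=p) for p in (9, 10, 19, 20)]
        (s,) = summarize_regions(records, [TargetRegion("chr1", 10, 20)])
        assert s.n_sites == 2  # positions 10 and 19 only

    def test_brute_force_oracle(self, rng):
        """100 random regions x 10,000 random sites against a per-site scan."""
        records = random_records(rng, 10_000, span=50_000)
        regions = []
        for _ in range(100):
            start = int(rng.integers(0, 49_000))
            regions.append(TargetRegion("chr1", start, start + int(rng.integers(10, 5000))))
        got = summarize_regions(records, regions)
        for region, s in zip(regions, got):
            in_region = [
                r for r in records
                if r.is_noncg and region.start <= r.pos < region.end
            ]
            covered = [1 - r.methyl_ratio for r in in_region if r.coverage > 0]
            assert s.n_sites == len(in_region)
            assert s.n_covered == len(covered)
            if covered:
                assert s.mean_bs == pytest.approx(np.mean(covered))
                assert s.median_bs == pytest.approx(np.median(covered))
            else:
                assert s.mean_bs is None

    def test_whole_chromosome_region_matches_chrom_summary(self, rng):
        """Additive consistency: one region spanning everything reproduces
        the chromosome-level covered-site statistics."""
        records = random_records(rng, 2000, span=30_000)
        s_chrom = chrom_summary(records)
        (s_reg,) = summarize_regions(records, [TargetRegion("chr1", 0, 30_000)])
        assert s_reg.n_sites == s_chrom.tncgc
        assert s_reg.n_covered == s_chrom.tncgc_with_cov
        assert s_reg.mean_bs == pytest.approx(s_chrom.mean)
        assert s_reg.median_bs == pytest.approx(s_chrom.median)

    def test_overlapping_regions_both_counted(self):
        records = [make_record(pos=5)]
        r1, r2 = TargetRegion("chr1", 0, 10), TargetRegion("chr1", 3, 8)
        s1, s2 = summarize_regions(records, [r1, r2])
        assert s1.n_sites == s2.n_sites == 1


class TestHistogram:
    def test_all_mass_in_last_bin(self):
        edges, counts = conversion_histogram([1.0] * 7, bins=10)
        assert counts[-1] == 7 and counts[:-1].sum() == 0

    def test_empty_input_all_zero(self):
        edges, counts = conversion_histogram([], bins=10)
        assert counts.sum() == 0 and len(edges) == 11

    def test_matches_independent_binning(self, rng):
        vals = rng.random(10_000)
        edges, counts = conversion_histogram(vals, bins=20)
        assert counts.sum() == 10_000
        # independent O(n*bins) binning oracle
        for i in range(20):
            lo, hi = i / 20, (i + 1) / 20
            expect = sum(
                1 for v in vals
                if (lo <= v < hi) or (i == 19 and v == 1.0)
            )
            assert counts[i] == expect


class TestAdvisory:
    def _records(self, n_low, n_high):
        recs = []
        for i in range(n_low):
            recs.append(make_record(pos=i, coverage=10, ratio=0.5))  # conv 0.5 < 0.99
        for i in range(n_high):
            recs.append(make_record(pos=n_low + i, coverage=10, ratio=0.0))
        return recs

    def test_investigate_above_30_percent(self):
        rep = advisory(self._records(40, 60))
        assert rep.verdict == "investigate"
        assert rep.frac_low_sites == pytest.approx(0.40)

    def test_proceed_when_fully_converted(self):
        rep = advisory(self._records(0, 50))
        assert rep.verdict == "proceed" and rep.group_b_count == 0

    def test_caution_at_10_percent(self):
        rep = advisory(self._records(100, 900))
        assert rep.verdict == "caution"
        assert (rep.group_a_count, rep.group_b_count) == (900, 100)

    def test_boundary_group_split_at_cutoff(self):
        # conversion exactly 0.99 belongs to group A (>= cutoff)
        recs = [make_record(coverage=100, ratio=0.01)]
        rep = advisory(recs)
        assert rep.group_a_count == 1 and rep.group_b_count == 0

    def test_no_covered_sites_is_error(self):
        with pytest.raises(ValidationError):
            advisory([make_record(coverage=0, ratio=None)])


def test_parameter_recovery_binomial_sampling(rng):
    """With binomial reads at true conversion r, the chromosome-level mean
    conversion lands within 3 standard errors of r."""
    r_true, n_sites, cov = 0.98, 5000, 20
    records = []
    for i in range(n_sites):
        meth = rng.binomial(cov, 1 - r_true)
        records.append(make_record(pos=i, coverage=cov, ratio=meth / cov))
    s = chrom_summary(records)
    se = np.sqrt(r_true * (1 - r_true) / (cov * n_sites))
    assert abs(s.mean - r_true) < 3 * se
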