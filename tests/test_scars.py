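"""Genomic scar scores: LST, TAI, LOH, HRD, FGA, aneuploidy, dichotomization."""

import numpy as np
import pandas as pd
import pytest

from parpibench.scars import (
    compute_aneuploidy,
    compute_fga,
    compute_hrd,
    compute_loh,
    compute_lst,
    compute_tai,
    dichotomize_score,
    score_profile,
)
from parpibench.segments import Segment, SegmentProfile

MB = 1_000_000


def flat_genome(build, allele=True):
    segs = []
    for chrom, arm, s, e in build.arms():
        segs.append(
            Segment(chrom, s, e, 0.0, 1 if allele else None, 1 if allele else None)
        )
    return SegmentProfile("flat", segs, build)


class TestLST:
    def test_flat_genome_scores_zero(self, toy_build):
        assert compute_lst(flat_genome(toy_build)) == 0

    def test_empty_profile_is_an_error_not_zero(self, toy_build):
        with pytest.raises(ValueError, match="empty"):
            compute_lst(SegmentProfile("S", [], toy_build))

    def test_single_qualifying_breakpoint(self, profile_factory):
        # two >=10 Mb flanks in different states inside one arm
        p = profile_factory(
            [("chr1", 1, 24, 0.0, 1, 1), ("chr1", 24.001, 48, 1.0, 2, 2)]
        )
        assert compute_lst(p) == 1

    def test_short_left_flank_not_counted(self, profile_factory):
        # left flank 8 Mb < 10 Mb: breakpoint does not qualify
        p = profile_factory(
            [("chr1", 30, 38, 0.0, 1, 1), ("chr1", 38.001, 48, 1.0, 2, 2)]
        )
        assert compute_lst(p) == 0

    def test_centromere_breakpoint_never_counted(self, profile_factory):
        # state change exactly across the centromere gap
        p = profile_factory(
            [("chr1", 1, 48, 0.0, 1, 1), ("chr1", 52.001, 100, 1.0, 2, 2)]
        )
        assert compute_lst(p) == 0

    def test_invariant_under_splitting_equal_state_segment(self, profile_factory):
        base = [("chr1", 1, 24, 0.0, 1, 1), ("chr1", 24.001, 48, 1.0, 2, 2)]
        split = [
            ("chr1", 1, 12, 0.0, 1, 1),
            ("chr1", 12.001, 24, 0.0, 1, 1),
            ("chr1", 24.001, 30, 1.0, 2, 2),
            ("chr1", 30.001, 48, 1.0, 2, 2),
        ]
        assert compute_lst(profile_factory(base)) == compute_lst(profile_factory(split))

    def test_planted_breakpoints_recovered(self, profile_factory):
        # one qualifying breakpoint in each arm of each toy chromosome
        segs = []
        for chrom in ("chr1", "chr2"):
            segs += [
                (chrom, 1, 24, 0.0, 1, 1), (chrom, 24.001, 48, 1.0, 2, 2),
                (chrom, 52.001, 76, 0.0, 1, 1), (chrom, 76.001, 100, 1.0, 2, 2),
            ]
        assert compute_lst(profile_factory(segs)) == 4


class TestTAI:
    def test_balanced_genome_scores_zero(self, toy_build):
        assert compute_tai(flat_genome(toy_build)) == 0

    def test_requires_allele_data(self, profile_factory):
        p = profile_factory([("chr1", 1, 48, 0.0)])
        with pytest.raises(ValueError, match="allele-specific"):
            compute_tai(p)

    def test_telomeric_imbalance_counts_once(self, profile_factory):
        # p-terminus to mid-p-arm imbalance, >= 11 Mb
        p = profile_factory(
            [("chr1", 1, 20, 0.58, 2, 1), ("chr1", 20.001, 48, 0.0, 1, 1),
             ("chr1", 52.001, 100, 0.0, 1, 1)]
        )
        assert compute_tai(p) == 1

    def test_interstitial_imbalance_not_counted(self, profile_factory):
        p = profile_factory(
            [("chr1", 1, 15, 0.0, 1, 1), ("chr1", 15.001, 35, 0.58, 2, 1),
             ("chr1", 35.001, 48, 0.0, 1, 1)]
        )
        assert compute_tai(p) == 0

    def test_centromere_crossing_region_not_counted(self, profile_factory):
        # imbalance spanning the whole chromosome crosses the centromere
        p = profile_factory([("chr1", 1, 100, 0.58, 2, 1)])
        assert compute_tai(p) == 0

    def test_region_below_minimum_length_not_counted(self, profile_factory):
        p = profile_factory(
            [("chr1", 1, 8, 0.58, 2, 1), ("chr1", 8.001, 48, 0.0, 1, 1)]
        )
        assert compute_tai(p) == 0


class TestLOH:
    def test_heterozygous_genome_scores_zero(self, toy_build):
        assert compute_loh(flat_genome(toy_build)) == 0

    def test_interstitial_20mb_loh_counts(self, profile_factory):
        p = profile_factory(
            [("chr1", 1, 10, 0.0, 1, 1), ("chr1", 10.001, 30, 0.0, 2, 0),
             ("chr1", 30.001, 48, 0.0, 1, 1)]
        )
        assert compute_loh(p) == 1

    def test_whole_chromosome_loh_excluded(self, profile_factory):
        p = profile_factory([("chr1", 1, 100, 0.0, 2, 0)])
        assert compute_loh(p) == 0

    def test_short_loh_not_counted(self, profile_factory):
        p = profile_factory(
            [("chr1", 1, 10, 0.0, 1, 1), ("chr1", 10.001, 24, 0.0, 2, 0),
             ("chr1", 24.001, 48, 0.0, 1, 1)]
        )
        assert compute_loh(p) == 0  # 14 Mb < 15 Mb

    def test_requires_allele_data(self, profile_factory):
        with pytest.raises(ValueError, match="allele-specific"):
            compute_loh(profile_factory([("chr1", 1, 48, 0.0)]))


class TestHRD:
    def test_sum(self):
        assert compute_hrd(0, 0, 0) == 0
        assert compute_hrd(5, 3, 2) == 10

    def test_missing_component_is_error(self):
        # without allele-specific calls TAI/LOH cannot exist, so no HRD
        with pytest.raises(ValueError, match="requires"):
            compute_hrd(5, None, 2)


class TestFGA:
    def test_no_alteration(self, profile_factory):
        p = profile_factory([("chr1", 1, 48, 0.1), ("chr1", 52.001, 100, -0.2)])
        assert compute_fga(p) == 0.0  # threshold is strict: |log2| > 0.2

    def test_everything_altered(self, profile_factory):
        p = profile_factory([("chr1", 1, 48, 0.5), ("chr1", 52.001, 100, -0.5)])
        assert compute_fga(p) == 1.0

    def test_half_altered_by_length(self, profile_factory):
        p = profile_factory([("chr1", 1, 30, 0.5), ("chr1", 30.001, 60, 0.0)])
        altered = sum(s.length for s in p.segments if abs(s.log2_ratio) > 0.2)
        assert compute_fga(p) == pytest.approx(altered / p.total_length())
        assert compute_fga(p) == pytest.approx(0.5, abs=0.01)

    def test_invariant_under_segment_splitting(self, profile_factory):
        whole = profile_factory([("chr1", 1, 40, 0.5), ("chr1", 40.001, 80, 0.0)])
        split = profile_factory(
            [("chr1", 1, 20, 0.5), ("chr1", 20.001, 40, 0.5),
             ("chr1", 40.001, 80, 0.0)]
        )
        # split boundaries leave a 1 kb unassayed sliver; tolerance covers it
        assert compute_fga(whole) == pytest.approx(compute_fga(split), abs=1e-4)

    def test_empty_profile_is_error(self, toy_build):
        with pytest.raises(ValueError, match="no assayed"):
            compute_fga(SegmentProfile("S", [], toy_build))


class TestAneuploidy:
    def test_flat_genome(self, toy_build):
        assert compute_aneuploidy(flat_genome(toy_build)) == 0

    def test_whole_arm_gain(self, profile_factory):
        p = profile_factory(
            [("chr1", 1, 48, 0.5, 2, 1), ("chr1", 52.001, 100, 0.0, 1, 1)]
        )
        assert compute_aneuploidy(p) == 1

    def test_half_arm_threshold(self, profile_factory):
        # 40% of the arm lost: below the 50% arm fraction
        p = profile_factory(
            [("chr1", 1, 19.2, -0.5), ("chr1", 19.201, 48, 0.0)]
        )
        assert compute_aneuploidy(p) == 0

    def test_all_39_autosomal_arms_lost(self, hg19):
        segs = [
            Segment(chrom, s, e, -0.5)
            for chrom, arm, s, e in hg19.arms(autosomes_only=True)
        ]
        p = SegmentProfile("S", segs, hg19)
        assert compute_aneuploidy(p) == 39  # acrocentric p arms excluded

    def test_mixed_gain_loss_on_one_arm_needs_single_direction(self, profile_factory):
        # 30% gained + 30% lost: neither direction reaches 50%
        p = profile_factory(
            [("chr1", 1, 14.4, 0.5), ("chr1", 14.401, 28.8, -0.5),
             ("chr1", 28.801, 48, 0.0)]
        )
        assert compute_aneuploidy(p) == 0


class TestScoreProfile:
    def test_hrd_identity_with_allele_data(self, profile_factory):
        p = profile_factory(
            [("chr1", 1, 24, 0.0, 1, 1), ("chr1", 24.001, 48, 1.0, 2, 2),
             ("chr1", 52.001, 100, 0.58, 2, 1),
             ("chr2", 1, 10, 0.0, 1, 1), ("chr2", 10.001, 30, 0.0, 2, 0),
             ("chr2", 30.001, 39, 0.0, 1, 1), ("chr2", 52.001, 100, 0.0, 1, 1)]
        )
        s = score_profile(p)
        assert (s.lst, s.tai, s.loh) == (1, 1, 1)
        assert s.hrd == s.lst + s.tai + s.loh == 3

    def test_no_allele_data_leaves_hrd_undefined(self, profile_factory):
        s = score_profile(profile_factory([("chr1", 1, 48, 0.0)]))
        assert s.tai is None and s.loh is None and s.hrd is None

    def test_deterministic(self, profile_factory):
        p = profile_factory(
            [("chr1", 1, 24, 0.0, 1, 1), ("chr1", 24.001, 48, 1.0, 2, 2)]
        )
        a, b = score_profile(p), score_profile(p)
        assert (a.lst, a.tai, a.loh, a.fga) == (b.lst, b.tai, b.loh, b.fga)


class TestDichotomize:
    def test_threshold_split(self):
        labels = dichotomize_score(pd.Series([1, 20, 14, 15]), 15)
        assert labels.labels == ["low", "high", "low", "high"]
        assert labels.n_per_class == {"high": 2, "low": 2}

    def test_degenerate_split_flagged(self):
        labels = dichotomize_score(pd.Series([1, 2, 3]), 10)
        assert labels.degenerate

    def test_median_split_ties_to_low(self):
        from parpibench.expression import median_split

        rng = np.random.default_rng(5)
        values = pd.Series(rng.permutation(100).astype(float))
        labels = median_split(values)
        assert labels.n_per_class == {"high": 50, "low": 50}
        # order-statistics oracle: exactly the top half is "high"
        top = set(values.sort_values(ascending=False).index[:50])
        high = {s for s, l in zip(labels.sample_ids, labels.labels) if l == "high"}
        assert high == top

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            dichotomize_score(pd.Series([1.0, np.nan]), 1)
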