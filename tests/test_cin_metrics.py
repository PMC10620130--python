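"""Per-chromosome aberration calling, the affected-chromosome CIN score,
and the comparator CIN algorithms (CNA count, FGA, TAI)."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from gistcin.cin_metrics import (
    CinConfig,
    chromosome_status,
    cin_metric_scores,
    classify_complexity,
    cohort_cin_table,
    summarize_cin,
)
from gistcin.segment_io import CopyNumberSegment, GenomeBuild, SegmentedProfile
from gistcin.synthetic_data import (
    ProfileSpec,
    simulate_profile,
    split_segments_randomly,
)


def seg(chrom, start, end, total, minor, lr=None):
    return CopyNumberSegment(chrom, start, end, total, minor, lr)


class TestChromosomeStatus:
    def test_diploid_heterozygous_is_unaffected(self):
        s = chromosome_status([seg("1", 0, 100, 2, 1), seg("1", 100, 300, 2, 1)])
        assert (s.cnv_affected, s.cnloh_affected) == (False, False)

    def test_single_copy_loss_is_cnv(self):
        s = chromosome_status([seg("1", 0, 100, 2, 1), seg("1", 100, 200, 1, 0)])
        assert (s.cnv_affected, s.cnloh_affected) == (True, False)

    def test_copy_neutral_loh(self):
        s = chromosome_status([seg("1", 0, 100, 2, 0)])
        assert (s.cnv_affected, s.cnloh_affected) == (False, True)

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="multiple chromosomes"):
            chromosome_status([seg("1", 0, 100, 2, 1), seg("2", 0, 100, 2, 1)])

    def test_min_length_filter_ignores_short_segments(self):
        cfg = CinConfig(min_aberrant_len_bp=1_000_000)
        s = chromosome_status([seg("1", 0, 100, 3, 1)], cfg)
        assert not s.affected

    def test_x_cnloh_not_counted_for_male_sample(self):
        profile = SegmentedProfile("S1", sex="male")
        s = chromosome_status([seg("X", 0, 100, 2, 0)], CinConfig(), profile)
        assert (s.cnv_affected, s.cnloh_affected) == (False, False)
        s2 = chromosome_status([seg("X", 0, 100, 2, 0)], CinConfig(),
                               SegmentedProfile("S2", sex="female"))
        assert s2.cnloh_affected

    def test_nearest_ploidy_baseline(self):
        profile = SegmentedProfile("S1", ploidy=3.8)
        cfg = CinConfig(baseline_mode="nearest_integer_ploidy")
        s = chromosome_status([seg("1", 0, 100, 4, 2)], cfg, profile)
        assert not s.cnv_affected


class TestClassifyComplexity:
    @pytest.mark.parametrize("total,expected", [(0, "Simple"), (9, "Simple"),
                                                (10, "Complex"), (23, "Complex")])
    def test_threshold_is_inclusive_at_ten(self, total, expected):
        assert classify_complexity(total) == expected

    def test_custom_threshold(self):
        assert classify_complexity(5, threshold=5) == "Complex"


class TestSummarizeCin:
    def test_planted_counts_recovered(self, build):
        profile, _ = simulate_profile(
            ProfileSpec("GIST1", n_cnv_only=8, n_loh_only=0, n_both=5), build
        )
        s = summarize_cin(profile)
        assert (s.n_chr_cnv_only, s.n_chr_loh_only, s.n_chr_both) == (8, 0, 5)
        assert s.n_chr_total == 13 and s.complexity == "Complex"

    def test_cnv_only_profile_is_simple_below_threshold(self, build):
        profile, _ = simulate_profile(ProfileSpec("GIST11", n_cnv_only=7), build)
        s = summarize_cin(profile)
        assert (s.n_chr_cnv_only, s.n_chr_total, s.complexity) == (7, 7, "Simple")

    def test_fully_neutral_profile(self, build):
        profile, _ = simulate_profile(ProfileSpec("S0"), build)
        s = summarize_cin(profile)
        assert (s.n_chr_cnv_only, s.n_chr_loh_only, s.n_chr_both, s.n_chr_total) == (0, 0, 0, 0)
        assert s.complexity == "Simple"

    @staticmethod
    def _brute_force(profile, cfg=CinConfig()):
        """Independent per-segment scan over the flags."""
        cnv_chroms, loh_chroms = set(), set()
        for chrom, segs in profile.segments.items():
            for s in segs:
                if s.length < cfg.min_aberrant_len_bp:
                    continue
                if s.total_cn != cfg.baseline_cn:
                    cnv_chroms.add(chrom)
                elif s.minor_cn == 0 and cfg.cnloh_eligible(chrom, profile):
                    loh_chroms.add(chrom)
        both = cnv_chroms & loh_chroms
        return (len(cnv_chroms - both), len(loh_chroms - both), len(both))

    @given(data=st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_on_random_small_profiles(self, data):
        build = GenomeBuild("mini", tuple((str(i), 10_000) for i in range(1, 6)))
        profile = SegmentedProfile("R1")
        for chrom, _ in build.chromosomes:
            n = data.draw(st.integers(0, 2), label=f"nseg_{chrom}")
            cuts = sorted(
                data.draw(
                    st.lists(st.integers(0, 9_999), min_size=2 * n, max_size=2 * n,
                             unique=True),
                    label=f"cuts_{chrom}",
                )
            )
            for i in range(n):
                total = data.draw(st.integers(0, 4), label=f"t_{chrom}_{i}")
                minor = data.draw(st.integers(0, total // 2), label=f"m_{chrom}_{i}")
                profile.add_segment(
                    seg(chrom, cuts[2 * i], cuts[2 * i + 1], total, minor)
                )
        s = summarize_cin(profile)
        assert (s.n_chr_cnv_only, s.n_chr_loh_only, s.n_chr_both) == self._brute_force(profile)
        # partition property
        assert s.n_chr_total == s.n_chr_cnv_only + s.n_chr_loh_only + s.n_chr_both

    def test_monotone_under_added_aberration(self, build):
        profile, _ = simulate_profile(ProfileSpec("S1", n_cnv_only=9), build)
        before = summarize_cin(profile)
        # aberrate a previously untouched chromosome
        untouched = next(
            c for c in profile.chromosomes()
            if all(s.total_cn == 2 and s.minor_cn == 1 for s in profile.segments[c])
        )
        profile.segments[untouched] = [seg(untouched, 0, 1000, 1, 0)]
        after = summarize_cin(profile)
        assert after.n_chr_total == before.n_chr_total + 1
        assert after.complexity == "Complex"

    def test_split_noise_never_changes_counts(self, build):
        profile, _ = simulate_profile(
            ProfileSpec("S1", n_cnv_only=5, n_loh_only=2, n_both=3), build
        )
        noisy = split_segments_randomly(profile, seed=7, n_rounds=3)
        assert summarize_cin(noisy) == summarize_cin(profile)


class TestCinMetricScores:
    def test_neutral_profile_scores_zero(self, tiny_build):
        p = SegmentedProfile(
            "S1", segments={"1": [seg("1", 0, 100_000_000, 2, 1, 0.0)]}
        )
        m = cin_metric_scores(p, tiny_build)
        assert (m.cna_segment_count, m.breakpoint_count) == (0, 0)
        assert m.fga == 0.0 and m.tai == 0.0

    def test_half_altered_toy_genome(self, tiny_build):
        # 50 Mb at |log-ratio| 1 plus 50 Mb neutral on a 100 Mb genome:
        # one aberrant segment, fga 0.5, tai (50*1 + 50*0)/100 = 0.5
        p = SegmentedProfile(
            "S1",
            segments={
                "1": [
                    seg("1", 0, 50_000_000, 4, 1, 1.0),
                    seg("1", 50_000_000, 100_000_000, 2, 1, 0.0),
                ]
            },
        )
        m = cin_metric_scores(p, tiny_build)
        assert m.cna_segment_count == 1
        assert m.breakpoint_count == 1
        assert m.fga == pytest.approx(0.5)
        assert m.tai == pytest.approx(0.5)

    def test_fully_aberrant_genome_has_fga_one(self, tiny_build):
        p = SegmentedProfile(
            "S1", segments={"1": [seg("1", 0, 100_000_000, 4, 1, 1.0)]}
        )
        assert cin_metric_scores(p, tiny_build).fga == pytest.approx(1.0)

    def test_log_ratio_derived_from_total_cn_when_absent(self, tiny_build):
        p = SegmentedProfile("S1", segments={"1": [seg("1", 0, 100_000_000, 4, 1)]})
        m = cin_metric_scores(p, tiny_build)
        assert m.tai == pytest.approx(math.log2(4 / 2))

    def test_empty_profile_warns_and_scores_zero(self, tiny_build, caplog):
        with caplog.at_level("WARNING"):
            m = cin_metric_scores(SegmentedProfile("S1"), tiny_build)
        assert (m.cna_segment_count, m.breakpoint_count, m.fga, m.tai) == (0, 0, 0.0, 0.0)

    def test_fga_tai_invariant_under_equal_state_split(self, tiny_build):
        whole = SegmentedProfile(
            "S1",
            segments={"1": [seg("1", 0, 60_000_000, 3, 1, 0.58),
                            seg("1", 60_000_000, 100_000_000, 2, 1, 0.0)]},
        )
        split = split_segments_randomly(whole, seed=3, n_rounds=4)
        m1 = cin_metric_scores(whole, tiny_build)
        m2 = cin_metric_scores(split, tiny_build)
        assert m2.fga == pytest.approx(m1.fga)
        assert m2.tai == pytest.approx(m1.tai)
        # equal-state splits introduce no new copy-number change
        assert m2.breakpoint_count == m1.breakpoint_count

    def test_masked_tai_restricts_to_aberrant_segments(self, tiny_build):
        p = SegmentedProfile(
            "S1",
            segments={"1": [seg("1", 0, 50_000_000, 4, 1, 1.0),
                            seg("1", 50_000_000, 100_000_000, 2, 1, 0.0)]},
        )
        assert cin_metric_scores(p, tiny_build, tai_masked=True).tai == pytest.approx(1.0)


class TestCohortTable:
    def test_one_row_per_sample_sorted(self, build):
        profiles = [
            simulate_profile(ProfileSpec(sid, n_cnv_only=k), build)[0]
            for sid, k in [("B", 2), ("A", 11), ("C", 0)]
        ]
        table = cohort_cin_table(profiles)
        assert list(table["sample"]) == ["A", "B", "C"]
        assert list(table["n_chr_total"]) == [11, 2, 0]
        assert list(table["cin"]) == ["Complex", "Simple", "Simple"]

    def test_empty_cohort_gives_empty_table(self):
        assert cohort_cin_table([]).empty

    def test_duplicate_sample_id_rejected(self, build):
        p, _ = simulate_profile(ProfileSpec("A"), build)
        with pytest.raises(ValueError, match="duplicate sample id"):
            cohort_cin_table([p, p])
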