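import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nilgenetics.recovery import (
    Call,
    RecoveryConfig,
    RecoveryRegion,
    analyze_line,
    filter_effective_snps,
    merge_regions,
    recovered_windows,
    recovery_rate,
    score_snps,
)
from nilgenetics.simulate import GenomeModel, simulate_backcross_genome


def _calls(pairs, chrom="A01"):
    return pd.DataFrame(
        [(chrom, pos, call) for pos, call in pairs], columns=["chrom", "pos", "call"]
    )


def per_base_oracle(flags, positions, window):
    """Mark every base covered by >= 1 recovered window; return covered bp."""
    covered = set()
    for i, f in enumerate(flags):
        if f:
            covered.update(range(positions[i], positions[i + window - 1] + 1))
    return len(covered)


class TestEffectiveFilter:
    def test_parents_sharing_allele_excluded(self):
        rp = _calls([(10, Call.REF_HOM)])
        dn = _calls([(10, Call.REF_HOM)])
        child = _calls([(10, Call.REF_HOM)])
        assert filter_effective_snps(child, rp, dn).empty

    def test_contrasting_homozygotes_included(self):
        rp = _calls([(10, Call.REF_HOM)])
        dn = _calls([(10, Call.ALT_HOM)])
        eff = filter_effective_snps(_calls([(10, Call.REF_HOM)]), rp, dn)
        assert list(eff["pos"]) == [10]
        assert eff.loc[0, "rp_call"] is Call.REF_HOM

    def test_het_or_missing_parent_excluded(self):
        rp = _calls([(10, Call.REF_HOM), (20, Call.REF_HOM), (30, Call.MISSING)])
        dn = _calls([(10, Call.HET), (20, Call.ALT_HOM), (30, Call.ALT_HOM)])
        eff = filter_effective_snps(_calls([]), rp, dn)
        assert list(eff["pos"]) == [20]

    def test_unsorted_input_rejected(self):
        rp = _calls([(20, Call.REF_HOM), (10, Call.REF_HOM)])
        with pytest.raises(ValueError, match="not strictly increasing"):
            filter_effective_snps(_calls([]), rp, _calls([]))


class TestScoring:
    def test_published_score_definitions(self):
        rp = _calls([(i, Call.REF_HOM) for i in (10, 20, 30)])
        dn = _calls([(i, Call.ALT_HOM) for i in (10, 20, 30)])
        child = _calls([(10, Call.REF_HOM), (20, Call.ALT_HOM), (30, Call.HET)])
        eff = filter_effective_snps(child, rp, dn)
        scored, dropped = score_snps(child, eff)
        assert list(scored["score"]) == [0, 2, 1]
        assert dropped == 0

    def test_donor_as_reference_orientation(self):
        # the recurrent parent may carry the ALT allele at some sites
        rp = _calls([(10, Call.ALT_HOM)])
        dn = _calls([(10, Call.REF_HOM)])
        child = _calls([(10, Call.ALT_HOM)])
        scored, _ = score_snps(child, filter_effective_snps(child, rp, dn))
        assert list(scored["score"]) == [0]

    def test_missing_child_calls_dropped_and_counted(self):
        rp = _calls([(i, Call.REF_HOM) for i in (10, 20)])
        dn = _calls([(i, Call.ALT_HOM) for i in (10, 20)])
        child = _calls([(10, Call.MISSING), (20, Call.REF_HOM)])
        scored, dropped = score_snps(child, filter_effective_snps(child, rp, dn))
        assert list(scored["pos"]) == [20]
        assert dropped == 1


class TestWindows:
    def test_all_recurrent_all_recovered(self):
        flags = recovered_windows(np.zeros(20, int))
        assert flags.shape == (6,) and flags.all()

    def test_all_donor_not_recovered(self):
        flags = recovered_windows(np.full(15, 2))
        assert flags.shape == (1,) and not flags.any()

    def test_strict_threshold_boundary(self):
        seven = [1] * 7 + [0] * 8
        eight = [1] * 8 + [0] * 7
        assert recovered_windows(seven)[0]
        assert not recovered_windows(eight)[0]

    def test_all_het_window_not_recovered(self):
        # sum 15 >= 8: heterozygous genome is not recurrent-parent genome
        assert not recovered_windows(np.ones(15, int))[0]

    def test_too_few_snps_unassessed(self):
        assert recovered_windows(np.zeros(14, int)).size == 0

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError):
            recovered_windows([0, 3, 1])


class TestMergeAndRate:
    def test_all_windows_recovered_single_region(self):
        positions = np.arange(100, 100 + 20 * 10, 10)
        flags = recovered_windows(np.zeros(20, int))
        regions = merge_regions(flags, positions)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (100, 290)

    def test_no_windows_no_regions(self):
        positions = np.arange(1, 16)
        flags = recovered_windows(np.full(15, 2))
        assert merge_regions(flags, positions) == []

    def test_two_separated_runs_match_per_base_oracle(self):
        # a block of donor genome splits the recovered windows into two runs
        scores = np.concatenate([np.zeros(20, int), np.full(8, 2), np.zeros(20, int)])
        positions = np.arange(1, len(scores) + 1) * 100
        flags = recovered_windows(scores)
        regions = merge_regions(flags, positions)
        total = sum(r.length for r in regions)
        assert total == per_base_oracle(flags, positions, 15)
        assert len(regions) == 2

    @given(st.lists(st.integers(0, 2), min_size=15, max_size=60), st.integers(0, 1000))
    @settings(max_examples=150, deadline=None)
    def test_randomized_per_base_oracle(self, scores, seed):
        rng = np.random.default_rng(seed)
        positions = np.cumsum(rng.integers(1, 50, len(scores)))
        flags = recovered_windows(scores)
        regions = merge_regions(flags, positions)
        assert sum(r.length for r in regions) == per_base_oracle(flags, positions, 15)
        for a, b in zip(regions, regions[1:]):
            assert a.end < b.start  # sorted, non-overlapping

    def test_raising_a_score_never_adds_recovered_length(self, rng):
        scores = rng.integers(0, 3, 80)
        positions = np.arange(1, 81) * 37
        base = sum(
            r.length for r in merge_regions(recovered_windows(scores), positions)
        )
        for _ in range(25):
            i = rng.integers(0, 80)
            if scores[i] == 2:
                continue
            bumped = scores.copy()
            bumped[i] += 1
            total = sum(
                r.length for r in merge_regions(recovered_windows(bumped), positions)
            )
            assert total <= base

    def test_rate_arithmetic(self):
        region = RecoveryRegion("A01", 1, 1000)
        assert recovery_rate([region], 2000).recovery_rate == 0.5
        assert recovery_rate([], 1234).recovery_rate == 0.0

    def test_overlap_and_bad_genome_rejected(self):
        r1, r2 = RecoveryRegion("A01", 1, 100), RecoveryRegion("A01", 50, 120)
        with pytest.raises(ValueError, match="overlap"):
            recovery_rate([r1, r2], 1000)
        with pytest.raises(ValueError):
            recovery_rate([], 0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RecoveryConfig(window_size=0)
        with pytest.raises(ValueError):
            RecoveryConfig(breakpoint_threshold=31)


class TestFullPipeline:
    def test_pure_recurrent_child_spans_snps(self):
        model = GenomeModel(
            chromosome_lengths={"A01": 200_000}, snp_density=0.001, donor_segments={}
        )
        child, rp, dn, frac = simulate_backcross_genome(model, seed=1)
        assert frac == 1.0
        report = analyze_line(child, rp, dn, model.genome_length_bp)
        pos = child["pos"].to_numpy()
        assert report.recovered_bp == pos.max() - pos.min() + 1
        assert report.recovery_rate == (pos.max() - pos.min() + 1) / 200_000

    def test_planted_fraction_recovered_within_tolerance(self):
        segments = {"A01": [(300_001, 408_000, "hom")], "A02": [(700_001, 808_000, "het")]}
        model = GenomeModel(
            chromosome_lengths={"A01": 2_000_000, "A02": 2_000_000},
            snp_density=0.005,
            donor_segments=segments,
        )
        child, rp, dn, frac = simulate_backcross_genome(model, seed=2)
        assert frac == pytest.approx(0.946, abs=1e-9)
        report = analyze_line(child, rp, dn, model.genome_length_bp, line_id="NIL1")
        assert abs(report.recovery_rate - frac) < 0.01

    def test_short_chromosome_unassessed(self):
        model = GenomeModel(
            chromosome_lengths={"A01": 300_000, "tiny": 1_000},
            snp_density=0.001,
            donor_segments={},
        )
        child, rp, dn, _ = simulate_backcross_genome(model, seed=3)
        report = analyze_line(child, rp, dn, model.genome_length_bp)
        assert "tiny" in report.unassessed_chroms
        assert all(r.chrom != "tiny" for r in report.regions)
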