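"""Gap detection, padding, candidate filtering and fill extraction."""

import pytest

from asmcurate.align import align_all
from asmcurate.gapfill import (FillCandidate, GapRecord, filter_candidates,
                               fill_gaps, find_gaps, pad_gaps,
                               scaffold_uniqueness)
from asmcurate.io import AlignmentRecord, Interval, SequenceRecord
from asmcurate.liftover import build_chains

from conftest import random_seq


class TestFindGaps:
    def test_planted_runs_found_at_truth_coordinates(self, small_sim):
        gaps = find_gaps(small_sim.reference)
        got = {(g.chrom, g.start, g.end) for g in gaps}
        want = {(g.chrom, g.start, g.end) for g in small_sim.truth.gaps}
        assert got == want

    def test_one_based_report_convention(self):
        # a gap spanning 1-based positions 172,624,657-172,626,416 is 1,760 bp
        ref = [SequenceRecord("chr2", "A" * 10 + "N" * 1760 + "C" * 10)]
        (gap,) = find_gaps(ref)
        assert gap.length == 1760
        # same arithmetic as the 1-based inclusive report: end - start + 1
        assert 172_626_416 - 172_624_657 + 1 == 1760
        assert gap.region == "chr2:11-1770"

    def test_exclude_mask_drops_gap(self):
        ref = [SequenceRecord("c", "A" * 50 + "N" * 20 + "C" * 50)]
        assert find_gaps(ref, exclude=[Interval("c", 40, 80)]) == []
        assert len(find_gaps(ref, exclude=[Interval("c", 0, 10)])) == 1

    def test_short_runs_ignored(self):
        ref = [SequenceRecord("c", "A" * 50 + "N" * 9 + "C" * 50)]
        assert find_gaps(ref, min_gap_len=10) == []


class TestPadGaps:
    def test_interior_gap_padding(self):
        gap = GapRecord("c", 60_000, 61_000)
        (iv,) = pad_gaps([gap], flank=50_000, chrom_lengths={"c": 200_000})
        assert (iv.start, iv.end) == (10_000, 111_000)
        assert len(iv) == gap.length + 100_000

    def test_clipping_at_chromosome_start(self):
        gap = GapRecord("c", 10_000, 11_000)
        (iv,) = pad_gaps([gap], flank=50_000, chrom_lengths={"c": 200_000})
        assert iv.start == 0

    def test_scaled_flank(self):
        gap = GapRecord("c", 50_000, 50_500)
        (iv,) = pad_gaps([gap], flank=5_000, chrom_lengths={"c": 200_000})
        assert len(iv) == gap.length + 10_000

    def test_nonpositive_flank_rejected(self):
        with pytest.raises(ValueError):
            pad_gaps([GapRecord("c", 10, 20)], flank=0)


def _gap_with_region(chrom, start, end, region_start, region_end):
    gap = GapRecord(chrom, start, end)
    gap.padded = Interval(chrom, region_start, region_end)
    return gap


def _aln(qname, tname, nmatch, qlen=10_000, tlen=10_000):
    return AlignmentRecord(qname, qlen, 0, nmatch, "+", tname, tlen, 0,
                           nmatch, nmatch, nmatch)


class TestFilterCandidates:
    def _one_gap(self):
        return [_gap_with_region("c", 5000, 5100, 0, 10_100)]

    def test_reciprocal_best_hit_kept(self):
        gaps = self._one_gap()
        region = gaps[0].padded
        from asmcurate.io import region_string
        alns = [_aln("s1", region_string(region), 9000),
                _aln("s2", region_string(region), 1000)]
        (cand,) = filter_candidates(gaps, alns, min_total_aln=5000)
        assert cand.scaffold == "s1" and cand.reason is None

    @pytest.mark.parametrize("total,kept", [(7_999, False), (8_000, True)])
    def test_threshold_boundary_inclusive(self, total, kept):
        gaps = self._one_gap()
        from asmcurate.io import region_string
        alns = [_aln("s1", region_string(gaps[0].padded), total)]
        (cand,) = filter_candidates(gaps, alns, min_total_aln=8_000)
        assert (cand.scaffold == "s1") is kept

    def test_threshold_monotonicity(self):
        """Raising min_total_aln never increases the candidate count."""
        gaps = [_gap_with_region("c", 5000 + i * 20_000, 5100 + i * 20_000,
                                 i * 20_000, 10_100 + i * 20_000)
                for i in range(4)]
        from asmcurate.io import region_string
        alns = [_aln(f"s{i}", region_string(g.padded), 4_000 + i * 2_000)
                for i, g in enumerate(gaps)]
        counts = []
        for thr in (0, 4_000, 6_000, 8_000, 10_000):
            cands = filter_candidates(gaps, alns, min_total_aln=thr)
            counts.append(sum(1 for c in cands if c.scaffold))
        assert counts == sorted(counts, reverse=True)

    def test_non_unique_scaffold_excluded(self):
        gaps = self._one_gap()
        from asmcurate.io import region_string
        alns = [_aln("s1", region_string(gaps[0].padded), 9000)]
        cands = filter_candidates(gaps, alns, min_total_aln=5000,
                                  uniqueness={"s1": False})
        assert cands[0].scaffold is None
        assert "not unique" in cands[0].reason

    def test_gap_without_alignment_reported_not_dropped(self):
        gaps = self._one_gap()
        (cand,) = filter_candidates(gaps, [], min_total_aln=5000)
        assert cand.scaffold is None and cand.reason == "no candidate"


class TestUniquenessCriterion:
    def test_duplicated_locus_fails_uniqueness(self, rng):
        """A scaffold matching two equal-score reference loci is flagged
        non-unique (criterion c), by netted-coverage accounting."""
        unit = random_seq(rng, 3000)
        ref = [SequenceRecord(
            "chr1",
            random_seq(rng, 2000) + unit + random_seq(rng, 2000)
            + unit + random_seq(rng, 2000),
        )]
        asm = [SequenceRecord("dup_scaffold", unit),
               SequenceRecord("uniq_scaffold", ref[0].bases[:2000])]
        cs = build_chains(align_all(asm, ref, min_chain_score=100))
        uniq = scaffold_uniqueness(cs)
        assert uniq["dup_scaffold"] is False
        assert uniq["uniq_scaffold"] is True


class TestEndToEnd:
    def test_zero_noise_recall_and_exact_fills(self, small_sim):
        """On zero-noise synthetic data every planted gap is confirmed and
        every extracted fill equals the planted fill string exactly."""
        cfg = small_sim.truth.config
        cands = fill_gaps(small_sim.reference, small_sim.assembly,
                          flank=cfg.flank, min_total_aln=cfg.min_total_aln)
        assert len(cands) == len(small_sim.truth.gaps)
        truth_fill = {(g.chrom, g.start, g.end): g.fill
                      for g in small_sim.truth.gaps}
        for c in cands:
            assert c.confirmed, (c.gap.region, c.reason)
            assert c.fill == truth_fill[(c.gap.chrom, c.gap.start, c.gap.end)]
            assert c.discrepancy == 0

    def test_planted_fill_indel_reported_as_discrepancy(self):
        """A planted net deletion inside one fill appears as a negative
        discrepancy of exactly that size, and is still confirmed (the
        reciprocal direction mirrors it)."""
        from asmcurate.simulate import SimConfig, simulate
        from conftest import SMALL_PARAMS

        params = dict(SMALL_PARAMS, fill_delta_count=2,
                      fill_delta_range=(120, 160), seed=19)
        sim = simulate(SimConfig(**params))
        cfg = sim.truth.config
        cands = fill_gaps(sim.reference, sim.assembly,
                          flank=cfg.flank, min_total_aln=cfg.min_total_aln)
        deltas = {(g.chrom, g.start, g.end): g.delta for g in sim.truth.gaps}
        planted = [c for c in cands
                   if deltas[(c.gap.chrom, c.gap.start, c.gap.end)] != 0]
        assert len(planted) == 2
        for c in planted:
            assert c.confirmed
            assert c.discrepancy == deltas[(c.gap.chrom, c.gap.start, c.gap.end)]
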