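"""Recurring-variant selection, resolution and frameshift classification."""

import pytest

from asmcurate.io import Interval, VariantRecord
from asmcurate.variants import (TranscriptPlacement, classify_cds_indels,
                                classify_placement, classify_resolved,
                                select_recurring, summarize_resolution)


def _var(genos, chrom="chr1", pos=100, ref="A", alt="G"):
    return VariantRecord(chrom, pos, ref, alt, genos)


class TestSelectRecurring:
    def test_threshold_is_inclusive(self):
        v = _var(["hom-alt"] * 3 + ["hom-ref"])  # fraction exactly 0.75
        (kept,) = select_recurring([v], min_frac=0.75)
        assert kept.recurrence == 0.75

    def test_below_threshold_excluded(self):
        v = _var(["hom-alt"] * 2 + ["hom-ref"] * 2)
        assert select_recurring([v], min_frac=0.75) == []

    def test_het_excluded_when_homozygous_only(self):
        v = _var(["hom-alt", "hom-alt", "het", "hom-alt"])
        assert select_recurring([v], homozygous_only=True) == []
        (kept,) = select_recurring([v], homozygous_only=False)
        assert not kept.homozygous_in_all

    def test_missing_excluded_from_denominator(self):
        v = _var(["hom-alt"] * 3 + ["missing"])  # 3/3 called
        (kept,) = select_recurring([v])
        assert kept.recurrence == 1.0

    def test_zero_samples_errors(self):
        with pytest.raises(ValueError):
            select_recurring([_var([])])

    def test_threshold_monotonicity(self):
        vs = [_var(["hom-alt"] * i + ["hom-ref"] * (10 - i), pos=i + 1)
              for i in range(1, 11)]
        sizes = [len(select_recurring(vs, min_frac=f))
                 for f in (0.5, 0.6, 0.75, 0.9, 1.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_synthetic_panel_selection_equals_truth(self, small_sim):
        """Selection over the simulated strain panel recovers exactly the
        planted recurrent sites, rejecting all decoys."""
        kept = select_recurring(small_sim.variants)
        got = {(r.variant.chrom, r.variant.pos) for r in kept}
        want = {(s.chrom, s.pos + 1) for s in small_sim.truth.recurrent_sites}
        assert got == want


class TestClassifyResolved:
    def test_planted_statuses(self, small_sim, small_chainset):
        """Planted reference-error sites resolve; true shared variants do
        not; conservation holds."""
        kept = select_recurring(small_sim.variants)
        calls = classify_resolved(kept, small_chainset, small_sim.assembly)
        by_site = {(c.variant.chrom, c.variant.pos): c for c in calls}
        for site in small_sim.truth.recurrent_sites:
            call = by_site[(site.chrom, site.pos + 1)]
            if site.is_error:
                assert call.status == "resolved"
            else:
                assert call.status != "resolved"
        counts = summarize_resolution(calls)
        assert counts["resolved"] + counts["unresolved"] + counts["unmappable"] \
            == len(calls)

    def test_unmappable_region(self, small_sim, small_chainset):
        """A site on a sequence absent from the chain net is unmappable,
        not a crash."""
        ghost = VariantRecord(small_sim.reference[0].name, 1, "A", "G",
                              ["hom-alt"] * 4)
        bad = VariantRecord("chrZ", 5, "A", "G", ["hom-alt"] * 4)
        calls = classify_resolved([ghost, bad], small_chainset,
                                  small_sim.assembly)
        assert all(c.status in {"resolved", "unresolved", "unmappable"}
                   for c in calls)
        assert calls[1].status == "unmappable"


class TestSummarize:
    @pytest.mark.parametrize("resolved,denom,pct", [
        (10, 126, 7.9),
        (307, 2407, 12.8),
        (393, 2194, 17.9),
    ])
    def test_reported_percentages(self, resolved, denom, pct):
        """The three published strain-panel summaries follow from the
        half-up one-decimal rule."""
        calls = []
        from asmcurate.variants import ResolutionCall
        for i in range(resolved):
            calls.append(ResolutionCall(_var(["hom-alt"], pos=i + 1), "resolved"))
        for i in range(denom - resolved):
            calls.append(ResolutionCall(
                _var(["hom-alt"], pos=resolved + i + 1), "unresolved"))
        assert summarize_resolution(calls)["resolved_pct"] == pct

    def test_net_denominator(self):
        from asmcurate.variants import ResolutionCall
        calls = (
            [ResolutionCall(_var(["hom-alt"], pos=i + 1), "resolved")
             for i in range(3)]
            + [ResolutionCall(_var(["hom-alt"], pos=10 + i), "unresolved")
               for i in range(5)]
            + [ResolutionCall(_var(["hom-alt"], pos=20 + i), "unmappable")
               for i in range(2)]
        )
        s = summarize_resolution(calls, denominator="net")
        assert s["denominator"] == 8 and s["resolved_pct"] == 37.5

    def test_zero_denominator_errors(self):
        with pytest.raises(ValueError):
            summarize_resolution([], total_considered=0)


class TestCdsIndels:
    CDS = [Interval("c", 100, 400)]

    def _placement(self, gaps):
        return TranscriptPlacement("tx", self.CDS, gaps)

    @pytest.mark.parametrize("gaps,status", [
        ([(Interval("c", 200, 203), 3)], "NFS"),      # in-frame deletion
        ([(Interval("c", 200, 202), 2)], "FS"),       # 2 bp insertion
        ([(Interval("c", 200, 203), 3),
          (Interval("c", 300, 301), 1)], "FS"),       # any frameshift dominates
        ([(Interval("c", 500, 505), 5)], "none"),     # gap outside CDS ignored
        ([], "none"),
    ])
    def test_mod3_rule(self, gaps, status):
        assert classify_placement(self._placement(gaps)) == status

    def test_counts(self):
        placements = [
            self._placement([(Interval("c", 200, 202), 2)]),
            self._placement([(Interval("c", 200, 203), 3)]),
            self._placement([(Interval("c", 500, 505), 5)]),
        ]
        assert classify_cds_indels(placements) == (1, 1)
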