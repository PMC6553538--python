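"""Chain building, netting and coordinate mapping laws."""

import numpy as np
import pytest

from asmcurate.align import align, align_all
from asmcurate.io import AlignmentRecord, Interval, SequenceRecord
from asmcurate.liftover import (Chain, ChainBlock, ChainSet, build_chains,
                                map_interval, map_position, owned_intervals)

from conftest import random_seq


def _aln(qname, qlen, qs, qe, strand, tname, tlen, ts, te, cg=None):
    nm = min(qe - qs, te - ts)
    tags = {"cg": cg} if cg else {}
    return AlignmentRecord(qname, qlen, qs, qe, strand, tname, tlen, ts, te,
                           nm, max(qe - qs, te - ts), tags=tags)


def _identity_chainset(n=1000):
    return build_chains([_aln("q", n, 0, n, "+", "t", n, 0, n)])


class TestBuildChains:
    def test_empty_input_empty_chainset(self):
        cs = build_chains([])
        assert cs.chains == [] and cs.netted == []

    def test_identity_owns_whole_target(self):
        cs = _identity_chainset(500)
        rows = owned_intervals(cs)["t"]
        assert rows == [(0, 500, cs.netted[0].chain_id)]

    def test_disjoint_colinear_alignments_merge(self):
        """Two consistent-offset alignments on one sequence pair become one
        chain (oracle: block ordering of the merged chain)."""
        a1 = _aln("q", 1000, 0, 300, "+", "t", 1000, 0, 300)
        a2 = _aln("q", 1000, 400, 900, "+", "t", 1000, 400, 900)
        cs = build_chains([a1, a2])
        assert len(cs.chains) == 1
        assert [(b.tstart, b.tend) for b in cs.chains[0].blocks] == \
            [(0, 300), (400, 900)]

    def test_netting_matches_per_base_oracle(self):
        """Greedy score-descending netting against a brute-force per-base
        ownership oracle on overlapping chains (scores 1000 vs 400)."""
        strong = _aln("q1", 1000, 0, 1000, "+", "t", 2000, 500, 1500)
        weak = _aln("q2", 400, 0, 400, "+", "t", 2000, 1200, 1600)
        cs = build_chains([strong, weak])

        owner = {}  # brute force: strongest chain claims each base first
        for name, start, end in [("q1", 500, 1500), ("q2", 1200, 1600)]:
            for pos in range(start, end):
                owner.setdefault(pos, name)
        for start, end, cid in owned_intervals(cs)["t"]:
            chain = next(c for c in cs.netted if c.chain_id == cid)
            for pos in range(start, end):
                assert owner[pos] == chain.qname
        # the weak chain keeps only its non-overlapped remainder
        weak_net = next(c for c in cs.netted if c.qname == "q2")
        assert [(b.tstart, b.tend) for b in weak_net.blocks] == [(1500, 1600)]

    def test_net_single_ownership_sweep(self, default_chainset):
        """No target base is owned twice (interval sweep over the net)."""
        for tname, rows in owned_intervals(default_chainset).items():
            for (s1, e1, _), (s2, e2, _) in zip(rows, rows[1:]):
                assert e1 <= s2, f"overlapping ownership on {tname}"
            total = sum(e - s for s, e, _ in rows)
            assert total <= default_chainset.tlens[tname]

    def test_unequal_spans_require_cigar(self):
        bad = _aln("q", 100, 0, 100, "+", "t", 100, 0, 90)
        with pytest.raises(ValueError, match="cg"):
            build_chains([bad])


class TestMapPosition:
    def test_identity_chain_maps_identically(self):
        cs = _identity_chainset()
        m = map_position(cs, "t", 150)
        assert (m.chrom, m.pos, m.strand) == ("q", 150, "+")

    def test_target_only_gap_arithmetic(self):
        """Chain with a 5 bp target-only gap at offset 100: target 150 maps
        to query 145; target 102 is deleted (hand-computed oracle)."""
        aln = _aln("q", 200, 0, 200, "+", "t", 205, 0, 205, cg="100M5D100M")
        cs = build_chains([aln])
        m = map_position(cs, "t", 150)
        assert (m.chrom, m.pos) == ("q", 145)
        m = map_position(cs, "t", 102)
        assert not m.mapped and m.reason == "deleted"

    def test_reverse_strand_reflection(self):
        aln = _aln("q", 1000, 0, 1000, "-", "t", 1000, 0, 1000)
        cs = build_chains([aln])
        m = map_position(cs, "t", 0)
        assert (m.pos, m.strand) == (999, "-")
        assert map_position(cs, "t", 999).pos == 0

    def test_unaligned_reason(self):
        cs = build_chains([_aln("q", 100, 0, 100, "+", "t", 500, 0, 100)])
        m = map_position(cs, "t", 400)
        assert not m.mapped and m.reason == "unaligned"

    def test_unknown_chromosome_errors(self):
        with pytest.raises(KeyError):
            map_position(_identity_chainset(), "nope", 1)

    def test_monotone_within_forward_chain(self):
        aln = _aln("q", 300, 0, 300, "+", "t", 320, 0, 320, cg="100M20D200M")
        cs = build_chains([aln])
        mapped = [map_position(cs, "t", p).pos
                  for p in range(0, 320, 7)
                  if map_position(cs, "t", p).mapped]
        assert mapped == sorted(mapped)


class TestMapInterval:
    def test_interior_interval_identity(self):
        cs = _identity_chainset()
        res = map_interval(cs, Interval("t", 100, 200))
        assert res.mapped and res.interval == Interval("q", 100, 200)

    def test_split_across_chains(self):
        a1 = _aln("q1", 100, 0, 100, "+", "t", 300, 0, 100)
        a2 = _aln("q2", 100, 0, 100, "+", "t", 300, 200, 300)
        cs = build_chains([a1, a2])
        res = map_interval(cs, Interval("t", 50, 250))
        assert not res.mapped

    def test_deletion_shortens_mapped_interval(self):
        aln = _aln("q", 200, 0, 200, "+", "t", 205, 0, 205, cg="100M5D100M")
        cs = build_chains([aln])
        res = map_interval(cs, Interval("t", 90, 115))
        assert res.mapped and len(res.interval) == 25 - 5

    def test_length_ratio_guard(self):
        aln = _aln("q", 300, 0, 300, "+", "t", 1000, 0, 1000, cg="100M700D200M")
        cs = build_chains([aln])
        res = map_interval(cs, Interval("t", 50, 950))
        assert not res.mapped and res.reason == "length"


class TestRoundTrip:
    def test_round_trip_identity_on_owned_blocks(self, rng):
        """map(map(x)) == x for positions in owned gap-free blocks, with
        chains built from the same alignments in both directions."""
        s = random_seq(rng, 3000)
        t = s[:1000] + s[1050:2000] + random_seq(rng, 30) + s[2000:]
        q_rec = SequenceRecord("asm", t)
        t_rec = SequenceRecord("ref", s)
        fwd = build_chains(align(q_rec, t_rec))        # ref -> asm
        bwd = build_chains(align(t_rec, q_rec))        # asm -> ref
        checked = 0
        for pos in range(0, 3000, 37):
            m = map_position(fwd, "ref", pos)
            if not m.mapped:
                continue
            back = map_position(bwd, "asm", m.pos)
            if back.mapped:
                assert back.pos == pos
                checked += 1
        assert checked > 50

    def test_truth_chainset_round_trip(self, small_sim):
        """Aligner-derived mapping agrees with the generator's exact
        coordinate truth at planted error sites."""
        cs = small_sim.truth.to_chainset()
        asm = {r.name: r.bases for r in small_sim.assembly}
        for site in small_sim.truth.error_sites[:50]:
            m = map_position(cs, site.chrom, site.pos)
            assert m.mapped
            assert asm[m.chrom][m.pos] == site.alt_base
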