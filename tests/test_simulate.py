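"""Synthetic-genome generator: determinism, conservation, planted truth."""

import numpy as np
import pytest

from asmcurate.simulate import (SimConfig, TruthTable, derive_assembly,
                                make_reference, make_strain_vcfs, simulate)

from conftest import SMALL_PARAMS


class TestConfigValidation:
    def test_composition_over_one_rejected(self):
        with pytest.raises(ValueError, match="composition"):
            SimConfig(repeat_composition={"satellite": 0.7, "LINE": 0.4})

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(snv_rate=1.5)


class TestMakeReference:
    def test_no_gaps_means_no_n(self):
        cfg = SimConfig(n_chroms=1, chrom_length=100_000, gap_count=0,
                        recurrent_site_count=10, decoy_site_count=0, seed=3)
        records, _, _ = make_reference(cfg)
        assert "N" not in records[0].bases

    def test_requested_gap_lengths_planted_exactly(self):
        import re
        cfg = SimConfig(n_chroms=1, chrom_length=500_000, gap_count=3,
                        gap_len_range=(100, 1760),
                        recurrent_site_count=50, decoy_site_count=0, seed=3)
        records, _, truth = make_reference(cfg)
        runs = [(m.start(), m.end()) for m in re.finditer("N+", records[0].bases)]
        assert runs == [(g.start, g.end) for g in
                        sorted(truth.gaps, key=lambda g: g.start)]

    def test_satellite_composition_within_two_percent(self):
        cfg = SimConfig(n_chroms=1, chrom_length=1_000_000, gap_count=0,
                        repeat_composition={"satellite": 0.6},
                        recurrent_site_count=10, decoy_site_count=0, seed=3)
        _, repeats, _ = make_reference(cfg)
        sat_bp = sum(len(iv) for iv in repeats if iv.label == "satellite")
        assert 0.58 <= sat_bp / 1_000_000 <= 0.62


class TestDeriveAssembly:
    def test_zero_noise_assembly_is_reference_with_fills(self, small_sim):
        """With zero rates the assembly differs from the reference only by
        the fills, the planted error bases and the planted SVs."""
        truth = small_sim.truth
        for gap in truth.gaps:
            asm = next(r for r in small_sim.assembly if r.name == gap.scaffold)
            assert asm.bases[gap.asm_start : gap.asm_end] == gap.fill

    def test_length_conservation_exact(self):
        """assembly = reference - N-runs + fills + net SV/indel deltas."""
        cfg = SimConfig(**dict(SMALL_PARAMS, snv_rate=1e-4, indel_rate=1e-5,
                               fill_delta_count=1, seed=23))
        sim = simulate(cfg)
        truth = sim.truth
        delta = 0
        for g in truth.gaps:
            delta += len(g.fill) - g.length
        for sv in truth.svs:
            delta += {"DEL": -sv.size, "DUP": sv.size, "INS": sv.size,
                      "INV": 0}[sv.svclass]
        for sm in truth.smalls:
            delta += len(sm.alt) - len(sm.ref)
        ref_total = sum(len(r) for r in sim.reference)
        asm_total = sum(len(r) for r in sim.assembly)
        assert asm_total == ref_total + delta

    def test_snv_count_within_three_sigma_of_binomial(self):
        cfg = SimConfig(n_chroms=1, chrom_length=1_000_000, gap_count=0,
                        repeat_composition={}, snv_rate=1e-3,
                        recurrent_site_count=0, decoy_site_count=0,
                        sv_spec={}, seed=3)
        records, _, truth = make_reference(cfg)
        _, truth = derive_assembly(records, truth, cfg)
        n = sum(1 for s in truth.smalls if s.kind == "SNV")
        mean, sigma = 1e6 * 1e-3, (1e6 * 1e-3 * (1 - 1e-3)) ** 0.5
        assert abs(n - mean) <= 3 * sigma

    def test_error_sites_carry_alt_base(self, small_sim):
        cs = small_sim.truth.to_chainset()
        from asmcurate.liftover import map_position
        asm = {r.name: r.bases for r in small_sim.assembly}
        for site in small_sim.truth.sites:
            m = map_position(cs, site.chrom, site.pos)
            assert m.mapped
            want = site.alt_base if site.is_error else site.ref_base
            assert asm[m.chrom][m.pos] == want

    def test_scaffolds_partition_each_chromosome(self, small_sim):
        per_chrom = {}
        for name, chrom in small_sim.truth.scaffold_of.items():
            per_chrom.setdefault(chrom, []).append(name)
        gaps_per_chrom = {}
        for g in small_sim.truth.gaps:
            gaps_per_chrom[g.chrom] = gaps_per_chrom.get(g.chrom, 0) + 1
        for chrom, scaffolds in per_chrom.items():
            assert len(scaffolds) == max(gaps_per_chrom.get(chrom, 1), 1)


class TestStrainPanel:
    def test_planted_error_count_rounds_half_up(self):
        cfg = SimConfig(**dict(SMALL_PARAMS, recurrent_site_count=5,
                               decoy_site_count=0,
                               reference_error_fraction=0.5, seed=29))
        _, _, truth = make_reference(cfg)
        assert len(truth.error_sites) == 3  # 2.5 rounds up

    def test_error_fraction_exact_count(self, default_sim):
        # 0.126 * 2,194 = 276.4 -> 276 planted error sites
        assert len(default_sim.truth.error_sites) == 276

    def test_recurrent_sites_meet_threshold(self, small_sim):
        n = small_sim.truth.config.n_strains
        for site in small_sim.truth.recurrent_sites:
            hom = site.genotypes.count("2")
            assert hom / n >= 0.75
            assert "1" not in site.genotypes

    def test_decoys_fail_selection_criteria(self, small_sim):
        import math
        n = small_sim.truth.config.n_strains
        for site in small_sim.truth.sites:
            if site.recurrent:
                continue
            hom = site.genotypes.count("2")
            assert hom < math.ceil(0.75 * n) or "1" in site.genotypes

    def test_too_few_strains_rejected(self, small_sim):
        cfg = SimConfig(**dict(SMALL_PARAMS, n_strains=1))
        with pytest.raises(ValueError):
            make_strain_vcfs(cfg, small_sim.truth)


class TestDeterminismAndIO:
    def test_same_seed_bit_identical(self):
        cfg = dict(SMALL_PARAMS, n_chroms=1, chrom_length=150_000,
                   gap_count=2, recurrent_site_count=40, decoy_site_count=10)
        a = simulate(SimConfig(**cfg))
        b = simulate(SimConfig(**cfg))
        assert [r.bases for r in a.reference] == [r.bases for r in b.reference]
        assert [r.bases for r in a.assembly] == [r.bases for r in b.assembly]
        assert [v.genotypes for v in a.variants] == [v.genotypes for v in b.variants]

    def test_different_seed_differs(self):
        cfg = dict(SMALL_PARAMS, n_chroms=1, chrom_length=150_000,
                   gap_count=2, recurrent_site_count=40, decoy_site_count=10)
        a = simulate(SimConfig(**cfg))
        b = simulate(SimConfig(**dict(cfg, seed=cfg["seed"] + 1)))
        assert a.reference[0].bases != b.reference[0].bases

    def test_truth_json_round_trip(self, small_sim, tmp_path):
        p = tmp_path / "truth.json"
        small_sim.truth.to_json(p)
        back = TruthTable.from_json(p)
        assert back.gaps == small_sim.truth.gaps
        assert back.sites == small_sim.truth.sites
        assert back.svs == small_sim.truth.svs
        assert back.blocks == small_sim.truth.blocks

    def test_output_files_written(self, tmp_path):
        cfg = SimConfig(**dict(SMALL_PARAMS, n_chroms=1, chrom_length=120_000,
                               gap_count=1, recurrent_site_count=20,
                               decoy_site_count=5))
        simulate(cfg, tmp_path)
        for name in ("ref.fa", "asm.fa", "repeats.bed", "asm_repeats.bed",
                     "strains.vcf", "truth.json"):
            assert (tmp_path / name).exists(), name
        header = (tmp_path / "strains.vcf").read_text().splitlines()[1]
        assert "asmcurate_seed" in header

    def test_strain_vcf_round_trips_through_reader(self, small_sim, tmp_path):
        from asmcurate.io import read_vcf_multisample, write_vcf
        p = tmp_path / "strains.vcf"
        write_vcf(small_sim.variants, small_sim.samples, p,
                  contigs=small_sim.truth.ref_lengths)
        back, samples = read_vcf_multisample(p)
        assert samples == small_sim.samples
        assert len(back) == len(small_sim.variants)
        got = {(v.chrom, v.pos): v.genotypes for v in back}
        for v in small_sim.variants:
            assert got[(v.chrom, v.pos)] == v.genotypes
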