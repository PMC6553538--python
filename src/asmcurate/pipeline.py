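"""End-to-end orchestration: simulate -> align -> chain/net -> curate -> report.

``run_pipeline`` drives every stage on one synthetic reference/assembly
pair and writes a ``report.json`` holding the full configuration, per-stage
counts and — because the inputs are synthetic — truth-recovery metrics
(gap-fill recall, planted-error recovery, SV count recovery).  The report
is byte-identical across runs with the same seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import gapfill as gf
from . import metrics, repeats, sv, variants
from .align import align_all
from .io import Interval, write_bed, write_fasta, write_paf
from .liftover import build_chains
from .simulate import (SimConfig, SimResult, jitter_intervals, make_sv_callsets,
                       simulate)
from ._util import percent

logger = logging.getLogger(__name__)

_ALL_STAGES = ("gapfill", "resolve", "svmerge", "unaligned", "stats")


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    stages: tuple[str, ...] = _ALL_STAGES
    k: int = 15
    max_gap: int = 2000
    min_chain_score: int = 100
    min_frac: float = 0.75
    sv_max_dist: int = 1000
    sv_jitter: int = 10
    unaligned_jitter: int = 50
    outdir: str | None = None

    @property
    def seed(self) -> int:
        return self.sim.seed


def _unaligned_intervals(chainset, qlens: dict[str, int]) -> list[Interval]:
    """Assembly intervals owned by no netted chain (per-scaffold complement
    of the net's query coverage)."""
    covered: dict[str, list[tuple[int, int]]] = {q: [] for q in qlens}
    for chain in chainset.netted:
        rows = covered.setdefault(chain.qname, [])
        for b in chain.blocks:
            rows.append((b.qstart, b.qend))
    out: list[Interval] = []
    for qname, qlen in sorted(qlens.items()):
        rows = sorted(covered.get(qname, []))
        merged: list[tuple[int, int]] = []
        for s, e in rows:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        cur = 0
        for s, e in merged:
            if s > cur:
                out.append(Interval(qname, cur, s))
            cur = max(cur, e)
        if cur < qlen:
            out.append(Interval(qname, cur, qlen))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages; returns (and optionally writes) the report."""
    outdir = Path(config.outdir) if config.outdir else None
    sim: SimResult = simulate(config.sim, outdir)
    truth = sim.truth
    report: dict = {
        "config": {
            "sim": dataclasses.asdict(config.sim),
            "stages": list(config.stages),
            "k": config.k,
            "max_gap": config.max_gap,
            "min_chain_score": config.min_chain_score,
            "min_frac": config.min_frac,
            "sv_max_dist": config.sv_max_dist,
            "seed": config.seed,
        },
    }

    aln_kw = dict(k=config.k, max_gap=config.max_gap,
                  min_chain_score=config.min_chain_score)
    logger.info("aligning %d scaffolds to %d chromosomes",
                len(sim.assembly), len(sim.reference))
    whole = align_all(sim.assembly, sim.reference, **aln_kw)
    chainset = build_chains(whole)
    report["align"] = {
        "alignments": len(whole),
        "chains": len(chainset.chains),
        "netted_chains": len(chainset.netted),
        "owned_bp": sum(c.score for c in chainset.netted),
    }
    if outdir:
        write_paf(whole, outdir / "whole.paf")

    if "gapfill" in config.stages:
        candidates = gf.fill_gaps(
            sim.reference, sim.assembly,
            flank=config.sim.flank, min_total_aln=config.sim.min_total_aln,
            whole_chainset=chainset, **aln_kw,
        )
        confirmed = [c for c in candidates if c.confirmed]
        truth_fills = {(g.chrom, g.start, g.end): g.fill for g in truth.gaps}
        exact = sum(
            1 for c in confirmed
            if truth_fills.get((c.gap.chrom, c.gap.start, c.gap.end)) == c.fill
        )
        report["gapfill"] = {
            "gaps": len(candidates),
            "confirmed": len(confirmed),
            "exact_fill": exact,
            "recall": round(len(confirmed) / len(truth.gaps), 4) if truth.gaps else None,
        }
        if outdir:
            _write_gapfill_tsv(candidates, outdir / "gapfills.tsv")

    if "resolve" in config.stages:
        recurring = variants.select_recurring(sim.variants, min_frac=config.min_frac)
        calls = variants.classify_resolved(recurring, chainset, sim.assembly)
        summary = variants.summarize_resolution(calls)
        truth_recurrent = {(s.chrom, s.pos + 1) for s in truth.recurrent_sites}
        selected = {(rv.variant.chrom, rv.variant.pos) for rv in recurring}
        report["resolve"] = {
            **summary,
            "selected": len(recurring),
            "selection_matches_truth": selected == truth_recurrent,
            "planted_errors": len(truth.error_sites),
        }
        if outdir:
            _write_resolution_tsv(calls, outdir / "resolution.tsv")

    if "svmerge" in config.stages:
        set_a, set_b = make_sv_callsets(truth, config.sim, jitter=config.sv_jitter)
        consensus = sv.merge_callsets(set_a, set_b,
                                      max_breakpoint_dist=config.sv_max_dist)
        summary = sv.summarize_sv(consensus)
        truth_counts: dict[str, int] = {}
        for psv in truth.svs:
            truth_counts[psv.svclass] = truth_counts.get(psv.svclass, 0) + 1
        report["svmerge"] = {
            "consensus": len(consensus),
            "per_class": {c: summary[c]["count"] for c in summary},
            "truth_counts": truth_counts,
        }
        if outdir:
            sv.write_sv_tsv(consensus, outdir / "sv_consensus.tsv")

    if "unaligned" in config.stages:
        base = _unaligned_intervals(chainset, truth.asm_lengths)
        sets = [
            base,
            jitter_intervals(base, config.seed + 1, config.unaligned_jitter),
            jitter_intervals(base, config.seed + 2, config.unaligned_jitter),
        ]
        consensus = repeats.consensus_unaligned(sets)
        comp = repeats.repeat_composition(consensus, truth.asm_repeats) \
            if consensus else None
        genome_region = [
            Interval(c, 0, ln) for c, ln in sorted(truth.ref_lengths.items())
        ]
        ref_comp = repeats.repeat_composition(genome_region, truth.repeats)
        enrichment = {}
        if comp:
            for cls in sorted(set(comp.class_bp) | set(ref_comp.class_bp)):
                stat, p, ok = repeats.class_enrichment(
                    comp.class_bp.get(cls, 0), comp.region_bp,
                    ref_comp.class_bp.get(cls, 0), ref_comp.region_bp,
                )
                enrichment[cls] = {"chi2": round(stat, 4), "p": p, "reliable": ok}
        report["unaligned"] = {
            "consensus_bp": sum(len(iv) for iv in consensus),
            "repeat_pct": comp.repeat_pct() if comp else None,
            "class_pct": comp.class_pct if comp else {},
            "reference_repeat_pct": ref_comp.repeat_pct(),
            "enrichment": enrichment,
        }
        if outdir:
            write_bed(consensus, outdir / "unaligned_consensus.bed")

    if "stats" in config.stages:
        asm_stats = metrics.assembly_stats(sim.assembly)
        ref_contigs = metrics.split_scaffolds(sim.reference)
        report["stats"] = {
            "assembly": dataclasses.asdict(asm_stats),
            "reference_contigs": len(ref_contigs),
            "kmer_completeness": round(
                metrics.kmer_completeness(sim.reference, sim.assembly), 6),
        }

    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report


def _write_gapfill_tsv(candidates, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tgap_start\tgap_end\tgap_len\tscaffold\tfill_len\t"
                 "discrepancy\tconfirmed\treason\n")
        for c in candidates:
            g = c.gap
            fill_len = len(c.fill) if c.fill is not None else ""
            disc = c.discrepancy if c.discrepancy is not None else ""
            fh.write(f"{g.chrom}\t{g.start + 1}\t{g.end}\t{g.length}\t"
                     f"{c.scaffold or ''}\t{fill_len}\t{disc}\t"
                     f"{c.confirmed}\t{c.reason or ''}\n")


def _write_resolution_tsv(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tstatus\tlifted_chrom\tlifted_pos\t"
                 "strand\tassembly_allele\treason\n")
        for c in calls:
            v = c.variant
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{c.status}\t"
                     f"{c.lifted_chrom or ''}\t"
                     f"{'' if c.lifted_pos is None else c.lifted_pos + 1}\t"
                     f"{c.strand or ''}\t{c.assembly_allele or ''}\t"
                     f"{c.reason or ''}\n")
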