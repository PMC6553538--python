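"""Synthetic reference/assembly pairs with planted, machine-readable truth.

The generator emulates the structure of a curated reference genome and a
new long-read assembly of the same inbred line:

* a chromosome-scale reference carrying N-run gaps whose true fill
  sequence is recorded, plus repeat blocks (satellite, microsatellite,
  LINE-like) at controllable composition;
* a derived assembly in which gaps are replaced by their true fill
  (optionally with a planted net indel), drift SNVs/indels and structural
  variants are applied, and a chosen fraction of "recurrent variant"
  sites carry the ALT base — emulating errors in the old reference;
* a multi-strain VCF panel in which the recurrent sites are homozygous
  ALT in >= 75% of strains, alongside decoy sites that must be filtered
  out (sub-threshold frequency, or heterozygous calls);
* a truth table with both reference and assembly coordinates for every
  planted feature, convertible into an exact liftover ChainSet.

Default scale is 2 chromosomes x 2 Mb with 5 kb gap flanks and an 8 kb
minimum-alignment threshold, a 1/10 scaling of the 50 kb / 80 kb values
used at genome scale; the panel defaults (24 strains, 2,194 recurrent
sites, error fraction 0.126) match the scale of the real strain-panel
analyses.  A single seed determines every output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._util import revcomp, round_half_up
from .io import Interval, SequenceRecord, VariantRecord
from .liftover import Chain, ChainBlock, ChainSet

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_GT_CHAR = {"hom-ref": "0", "het": "1", "hom-alt": "2", "missing": "."}
_CHAR_GT = {v: k for k, v in _GT_CHAR.items()}


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study conditions for one synthetic reference/assembly pair."""

    n_chroms: int = 2
    chrom_length: int = 2_000_000
    gap_count: int = 10                      # total across the genome
    gap_len_range: tuple[int, int] = (100, 2000)
    flank: int = 5000                        # gap padding; 1/10 of 50 kb
    min_total_aln: int = 8000                # 1/10 of 80 kb
    snv_rate: float = 0.0                    # per bp; 0 = zero-noise truth runs
    indel_rate: float = 0.0
    indel_len_range: tuple[int, int] = (1, 10)
    sv_spec: dict = field(default_factory=lambda: {
        "DEL": (3, (200, 2000)),
        "DUP": (3, (200, 2000)),
        "INV": (2, (500, 5000)),
        "INS": (3, (200, 2000)),
    })
    repeat_composition: dict = field(default_factory=lambda: {
        "satellite": 0.06,
        "microsatellite": 0.04,
        "LINE": 0.12,
    })
    n_strains: int = 24
    recurrent_site_count: int = 2194
    decoy_site_count: int = 200
    reference_error_fraction: float = 0.126
    fill_delta_count: int = 0                # gaps given a planted fill indel
    fill_delta_range: tuple[int, int] = (50, 200)
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.snv_rate, self.indel_rate, self.reference_error_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.chrom_length <= 0 or self.flank <= 0:
            raise ValueError("lengths must be positive")
        total = sum(self.repeat_composition.values())
        if total > 1.0:
            raise ValueError(f"repeat composition fractions sum to {total} > 1")


# --------------------------------------------------------------------------
# truth table
# --------------------------------------------------------------------------


@dataclass
class PlantedGap:
    chrom: str
    start: int
    end: int
    fill: str                 # sequence the assembly carries across the gap
    delta: int = 0            # expected discrepancy bp (fill len - gap len)
    scaffold: str | None = None
    asm_start: int | None = None
    asm_end: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PlantedSite:
    """A recurrent-candidate variant site in reference coordinates."""

    chrom: str
    pos: int                  # 0-based reference coordinate
    ref_base: str
    alt_base: str
    is_error: bool = False    # assembly carries ALT at the lifted position
    recurrent: bool = True    # planted above the 75% recurrence threshold
    genotypes: str = ""       # one char per strain: 0/1/2/.


@dataclass
class PlantedSV:
    svclass: str
    chrom: str
    start: int
    end: int
    size: int
    asm_start: int | None = None
    asm_end: int | None = None


@dataclass
class PlantedSmall:
    kind: str                 # SNV | INS | DEL
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class CollinearBlock:
    """A gap-free ref->assembly coordinate block (the exact liftover truth)."""

    chrom: str
    ref_start: int
    ref_end: int
    scaffold: str
    asm_start: int
    asm_end: int
    strand: str = "+"


@dataclass
class TruthTable:
    config: SimConfig
    gaps: list[PlantedGap] = field(default_factory=list)
    sites: list[PlantedSite] = field(default_factory=list)
    svs: list[PlantedSV] = field(default_factory=list)
    smalls: list[PlantedSmall] = field(default_factory=list)
    blocks: list[CollinearBlock] = field(default_factory=list)
    repeats: list[Interval] = field(default_factory=list)       # ref coords
    asm_repeats: list[Interval] = field(default_factory=list)   # asm coords
    scaffold_of: dict = field(default_factory=dict)             # scaffold -> chrom
    ref_lengths: dict = field(default_factory=dict)
    asm_lengths: dict = field(default_factory=dict)

    @property
    def error_sites(self) -> list[PlantedSite]:
        return [s for s in self.sites if s.is_error]

    @property
    def recurrent_sites(self) -> list[PlantedSite]:
        return [s for s in self.sites if s.recurrent]

    def to_chainset(self) -> ChainSet:
        """Exact liftover built from the known edit history (no aligner)."""
        cs = ChainSet()
        cs.tlens = dict(self.ref_lengths)
        cs.qlens = dict(self.asm_lengths)
        per_scaffold: dict[tuple[str, str], list[CollinearBlock]] = {}
        minus: list[CollinearBlock] = []
        for b in self.blocks:
            if b.strand == "+":
                per_scaffold.setdefault((b.chrom, b.scaffold), []).append(b)
            else:
                minus.append(b)
        chains: list[Chain] = []
        for (chrom, scaffold), blocks in sorted(per_scaffold.items()):
            blocks.sort(key=lambda b: b.ref_start)
            chains.append(Chain(
                qname=scaffold, qlen=cs.qlens[scaffold],
                tname=chrom, tlen=cs.tlens[chrom], strand="+",
                blocks=[ChainBlock(b.ref_start, b.ref_end, b.asm_start, b.asm_end)
                        for b in blocks],
            ))
        for b in minus:
            chains.append(Chain(
                qname=b.scaffold, qlen=cs.qlens[b.scaffold],
                tname=b.chrom, tlen=cs.tlens[b.chrom], strand="-",
                blocks=[ChainBlock(b.ref_start, b.ref_end, b.asm_start, b.asm_end)],
            ))
        for i, c in enumerate(chains):
            c.chain_id = i
        cs.chains = chains
        cs.netted = chains  # blocks are disjoint on the target by construction
        cs._build_index()
        return cs

    # -- JSON round trip ----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        def conv(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))

        payload = {
            "config": dataclasses.asdict(self.config),
            "gaps": [dataclasses.asdict(g) for g in self.gaps],
            "sites": [dataclasses.asdict(s) for s in self.sites],
            "svs": [dataclasses.asdict(s) for s in self.svs],
            "smalls": [dataclasses.asdict(s) for s in self.smalls],
            "blocks": [dataclasses.asdict(b) for b in self.blocks],
            "repeats": [dataclasses.asdict(r) for r in self.repeats],
            "asm_repeats": [dataclasses.asdict(r) for r in self.asm_repeats],
            "scaffold_of": self.scaffold_of,
            "ref_lengths": self.ref_lengths,
            "asm_lengths": self.asm_lengths,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, default=conv)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        cfg_d = d["config"]
        for key in ("gap_len_range", "indel_len_range", "fill_delta_range"):
            cfg_d[key] = tuple(cfg_d[key])
        cfg_d["sv_spec"] = {
            k: (v[0], tuple(v[1])) for k, v in cfg_d["sv_spec"].items()
        }
        tt = cls(config=SimConfig(**cfg_d))
        tt.gaps = [PlantedGap(**g) for g in d["gaps"]]
        tt.sites = [PlantedSite(**s) for s in d["sites"]]
        tt.svs = [PlantedSV(**s) for s in d["svs"]]
        tt.smalls = [PlantedSmall(**s) for s in d["smalls"]]
        tt.blocks = [CollinearBlock(**b) for b in d["blocks"]]
        tt.repeats = [Interval(**r) for r in d["repeats"]]
        tt.asm_repeats = [Interval(**r) for r in d["asm_repeats"]]
        tt.scaffold_of = d["scaffold_of"]
        tt.ref_lengths = d["ref_lengths"]
        tt.asm_lengths = d["asm_lengths"]
        return tt


# --------------------------------------------------------------------------
# reference construction
# --------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[arr].tobytes().decode("ascii")


def _place_block(
    rng: np.random.Generator, free: np.ndarray, length: int, margin: int = 0
) -> int | None:
    """Random start such that [start-margin, start+length+margin) is free."""
    lo, hi = margin, len(free) - length - margin
    if hi <= lo:
        return None
    for _ in range(200):
        s = int(rng.integers(lo, hi))
        if free[s - margin : s + length + margin].all():
            return s
    return None


def make_reference(
    config: SimConfig,
) -> tuple[list[SequenceRecord], list[Interval], TruthTable]:
    """Generate the gapped, repeat-bearing reference and its truth table.

    Also chooses the recurrent/decoy variant sites (positions, ALT bases and
    which sites are planted reference errors), so that the derived assembly
    and the strain panel can be generated consistently from the same truth.
    """
    rng = np.random.default_rng([config.seed, 1])
    truth = TruthTable(config=config)
    records: list[SequenceRecord] = []
    repeats: list[Interval] = []
    L = config.chrom_length

    # distribute gaps and sites over chromosomes
    gaps_per_chrom = [config.gap_count // config.n_chroms] * config.n_chroms
    for i in range(config.gap_count % config.n_chroms):
        gaps_per_chrom[i] += 1

    site_free: dict[str, np.ndarray] = {}
    arrs: dict[str, np.ndarray] = {}
    monomers = {
        "satellite": _random_bases(rng, 120),
        "microsatellite": _random_bases(rng, int(rng.integers(2, 7))),
        "LINE": _random_bases(rng, 3000),
    }
    block_len = {
        "satellite": (5000, 20000),
        "microsatellite": (200, 1000),
        "LINE": (1000, 3000),
    }

    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        arr = _random_bases(rng, L)
        free = np.ones(L, dtype=bool)

        # repeat blocks: tandem copies of seeded motifs, composition exact
        for cls, frac in config.repeat_composition.items():
            target = int(frac * L)
            placed = 0
            motif = monomers.get(cls, _random_bases(rng, 100))
            while placed < target:
                lo, hi = block_len.get(cls, (500, 5000))
                ln = min(int(rng.integers(lo, hi + 1)), target - placed)
                ln = max(ln, len(motif)) if target - placed >= len(motif) else ln
                s = _place_block(rng, free, ln)
                if s is None:
                    logger.warning("could not place %s block of %d bp on %s",
                                   cls, ln, chrom)
                    break
                tiled = np.tile(motif, ln // len(motif) + 1)[:ln]
                arr[s : s + ln] = tiled
                free[s : s + ln] = False
                repeats.append(Interval(chrom, s, s + ln, cls))
                placed += ln

        # gaps: replace recorded true-fill sequence with N-runs, keeping
        # repeat-free flanks so the fill is recoverable by alignment
        margin = config.flank + 500
        for _ in range(gaps_per_chrom[ci]):
            glen = int(rng.integers(config.gap_len_range[0],
                                    config.gap_len_range[1] + 1))
            s = _place_block(rng, free, glen, margin=margin)
            if s is None:
                raise RuntimeError(f"could not place a {glen} bp gap on {chrom}")
            fill = _decode(arr[s : s + glen])
            truth.gaps.append(PlantedGap(chrom, s, s + glen, fill))
            arr[s : s + glen] = 4  # N
            free[max(0, s - margin) : s + glen + margin] = False

        arrs[chrom] = arr
        site_free[chrom] = free
        truth.ref_lengths[chrom] = L
        records.append(SequenceRecord(chrom, ""))  # bases set below

    # variant sites: unique background positions, >= 20 bp apart
    n_sites = config.recurrent_site_count + config.decoy_site_count
    chrom_of_site = rng.integers(0, config.n_chroms, n_sites)
    all_sites: list[PlantedSite] = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        want = int(np.count_nonzero(chrom_of_site == ci))
        pool = np.flatnonzero(site_free[chrom])
        pool = pool[(pool > 100) & (pool < L - 100)]
        chosen: list[int] = []
        guard = 0
        while len(chosen) < want:
            guard += 1
            if guard > 50:
                raise RuntimeError("cannot place variant sites")
            extra = rng.choice(pool, size=(want - len(chosen)) * 2, replace=False)
            merged = np.unique(np.concatenate([np.array(chosen, dtype=int), extra]))
            keep = merged[np.concatenate(([True], np.diff(merged) >= 20))]
            chosen = list(keep[:want]) if len(keep) >= want else list(keep)
        for pos in sorted(int(p) for p in chosen):
            ref_base = _BASES[arrs[chrom][pos]]
            alt_base = _BASES[(arrs[chrom][pos] + int(rng.integers(1, 4))) % 4]
            all_sites.append(PlantedSite(chrom, pos, ref_base, alt_base))
            site_free[chrom][max(0, pos - 20) : pos + 20] = False

    rng.shuffle(all_sites)  # type: ignore[arg-type]
    recurrent = all_sites[: config.recurrent_site_count]
    for s in all_sites[config.recurrent_site_count :]:
        s.recurrent = False
    n_err = int(round_half_up(
        config.reference_error_fraction * config.recurrent_site_count))
    err_idx = rng.choice(len(recurrent), size=n_err, replace=False)
    for i in err_idx:
        recurrent[int(i)].is_error = True
    truth.sites = sorted(all_sites, key=lambda s: (s.chrom, s.pos))

    for rec in records:
        rec.bases = _decode(arrs[rec.name])
    repeats.sort(key=lambda r: (r.chrom, r.start))
    truth.repeats = repeats
    return records, repeats, truth


# --------------------------------------------------------------------------
# assembly derivation
# --------------------------------------------------------------------------


@dataclass
class _Edit:
    start: int
    end: int
    replacement: str
    kind: str
    breaks_colinearity: bool
    meta: object = None


def derive_assembly(
    reference: list[SequenceRecord],
    truth: TruthTable,
    config: SimConfig,
) -> tuple[list[SequenceRecord], TruthTable]:
    """Apply gap fills, reference-error bases, drift variants and SVs.

    Every edit is logged with both reference and assembly coordinates; the
    gap-free stretches between length-changing edits become the truth
    liftover blocks.  Asserts exact length conservation:
    assembly = reference - sum(N runs) + sum(fills) + sum(net indel deltas).
    """
    rng = np.random.default_rng([config.seed, 2])
    ref_by_name = {r.name: r for r in reference}
    edits_by_chrom: dict[str, list[_Edit]] = {r.name: [] for r in reference}
    site_pos = {(s.chrom, s.pos) for s in truth.sites}

    # gap fills (with optional planted fill indels)
    delta_gaps: set[int] = set()
    if config.fill_delta_count:
        delta_gaps = set(
            int(i) for i in rng.choice(
                len(truth.gaps),
                size=min(config.fill_delta_count, len(truth.gaps)),
                replace=False,
            )
        )
    for gi, gap in enumerate(truth.gaps):
        fill = gap.fill
        if gi in delta_gaps:
            d = int(rng.integers(config.fill_delta_range[0],
                                 config.fill_delta_range[1] + 1))
            if rng.random() < 0.5 and len(fill) > d + 2:
                mid = len(fill) // 2
                fill = fill[: mid - d // 2] + fill[mid - d // 2 + d :]
                gap.delta = -d
            else:
                mid = len(fill) // 2
                ins = _decode(_random_bases(rng, d))
                fill = fill[:mid] + ins + fill[mid:]
                gap.delta = d
            gap.fill = fill
        edits_by_chrom[gap.chrom].append(
            _Edit(gap.start, gap.end, fill, "gapfill",
                  breaks_colinearity=(gap.delta != 0), meta=gap)
        )

    # reference-error sites: the assembly carries the ALT base
    for site in truth.error_sites:
        edits_by_chrom[site.chrom].append(
            _Edit(site.pos, site.pos + 1, site.alt_base, "error",
                  breaks_colinearity=False, meta=site)
        )

    def _overlaps_existing(chrom: str, start: int, end: int, pad: int = 0) -> bool:
        for e in edits_by_chrom[chrom]:
            if start - pad < e.end and e.start < end + pad:
                return True
        return False

    # structural variants, kept clear of padded gap regions (the gap-fill
    # procedure assumes SV-free flanks), sites and each other
    pad = config.flank

    def _in_padded_gap(chrom: str, start: int, end: int) -> bool:
        margin = config.flank + 100
        return any(
            g.chrom == chrom and start - margin < g.end and g.start < end + margin
            for g in truth.gaps
        )

    for svclass, (count, (lo, hi)) in config.sv_spec.items():
        for _ in range(count):
            for attempt in range(200):
                chrom = f"chr{int(rng.integers(1, config.n_chroms + 1))}"
                size = int(rng.integers(lo, hi + 1))
                span = 1 if svclass == "INS" else size
                s = int(rng.integers(pad, config.chrom_length - span - pad))
                if _overlaps_existing(chrom, s, s + span, pad=50):
                    logger.debug("resampled %s overlapping an edit", svclass)
                    continue
                if _in_padded_gap(chrom, s, s + span):
                    logger.info("rejected %s in a padded gap region; resampling",
                                svclass)
                    continue
                near_site = any(
                    (chrom, p) in site_pos for p in range(s - 1, s + span + 1)
                )
                if near_site:
                    continue
                seq = ref_by_name[chrom].bases
                if "N" in seq[s : s + span]:
                    logger.info("rejected %s overlapping a gap; resampling", svclass)
                    continue
                if svclass == "DEL":
                    repl = ""
                elif svclass == "DUP":
                    repl = seq[s : s + size] * 2
                elif svclass == "INV":
                    repl = revcomp(seq[s : s + size])
                else:  # INS
                    repl = seq[s] + _decode(_random_bases(rng, size))
                    span = 1
                sv = PlantedSV(svclass, chrom, s, s + (size if svclass != "INS" else 0),
                               size)
                edits_by_chrom[chrom].append(
                    _Edit(s, s + span, repl, svclass,
                          breaks_colinearity=True, meta=sv)
                )
                truth.svs.append(sv)
                break
            else:
                raise RuntimeError(f"could not place {svclass} after 200 tries")

    # drift SNVs and small indels in otherwise untouched sequence
    for chrom in sorted(edits_by_chrom):
        seq = ref_by_name[chrom].bases
        L = len(seq)
        if config.snv_rate > 0:
            hits = np.flatnonzero(rng.random(L) < config.snv_rate)
            for p in hits:
                p = int(p)
                if seq[p] == "N" or (chrom, p) in site_pos:
                    continue
                if _overlaps_existing(chrom, p, p + 1):
                    continue
                alt = _BASES[(_BASES.index(seq[p]) + int(rng.integers(1, 4))) % 4]
                truth.smalls.append(PlantedSmall("SNV", chrom, p, seq[p], alt))
                edits_by_chrom[chrom].append(
                    _Edit(p, p + 1, alt, "SNV", breaks_colinearity=False)
                )
        if config.indel_rate > 0:
            hits = np.flatnonzero(rng.random(L) < config.indel_rate)
            for p in hits:
                p = int(p)
                ln = int(rng.integers(config.indel_len_range[0],
                                      config.indel_len_range[1] + 1))
                if p + ln + 1 >= L or "N" in seq[p : p + ln + 1]:
                    continue
                if _overlaps_existing(chrom, p, p + ln + 1, pad=2):
                    continue
                if any((chrom, q) in site_pos for q in range(p - 1, p + ln + 2)):
                    continue
                if rng.random() < 0.5:  # deletion of ln bases after anchor p
                    truth.smalls.append(
                        PlantedSmall("DEL", chrom, p, seq[p : p + ln + 1], seq[p]))
                    edits_by_chrom[chrom].append(
                        _Edit(p, p + ln + 1, seq[p], "DEL_small",
                              breaks_colinearity=True))
                else:
                    ins = _decode(_random_bases(rng, ln))
                    truth.smalls.append(
                        PlantedSmall("INS", chrom, p, seq[p], seq[p] + ins))
                    edits_by_chrom[chrom].append(
                        _Edit(p, p + 1, seq[p] + ins, "INS_small",
                              breaks_colinearity=True))

    # scaffold breakpoints: between consecutive gaps, so each assembly
    # scaffold spans at most one gap (scaffold-scale, not chromosome-scale)
    breaks_by_chrom: dict[str, list[int]] = {}
    for chrom in sorted(edits_by_chrom):
        chrom_gaps = sorted(
            (g for g in truth.gaps if g.chrom == chrom), key=lambda g: g.start
        )
        breaks: list[int] = []
        for g1, g2 in zip(chrom_gaps, chrom_gaps[1:]):
            p = (g1.end + g2.start) // 2
            # nudge off any edit or planted site
            while (_overlaps_existing(chrom, p, p + 1, pad=25)
                   or any((chrom, q) in site_pos for q in range(p - 25, p + 26))):
                p += 53
            breaks.append(p)
        breaks_by_chrom[chrom] = breaks

    # apply edits, tracking coordinates and collinear blocks
    asm_records: list[SequenceRecord] = []
    expected_net = 0
    scaffold_no = 0
    for rec in reference:
        chrom = rec.name
        edits = sorted(edits_by_chrom[chrom], key=lambda e: (e.start, e.end))
        for a, b in zip(edits, edits[1:]):
            if b.start < a.end:
                raise RuntimeError(f"overlapping edits on {chrom}")
        events: list[_Edit] = sorted(
            edits + [_Edit(p, p, "", "BREAK", breaks_colinearity=True)
                     for p in breaks_by_chrom[chrom]],
            key=lambda e: (e.start, e.end),
        )
        scaffold_no += 1
        scaffold = f"scaffold_{scaffold_no}"
        truth.scaffold_of[scaffold] = chrom
        parts: list[str] = []
        cursor = 0          # reference coordinate
        out_len = 0         # assembly coordinate within the current scaffold
        block_ref = 0
        block_asm = 0

        def _close_scaffold() -> None:
            nonlocal parts, out_len
            bases = "".join(parts)
            assert len(bases) == out_len
            asm_records.append(SequenceRecord(scaffold, bases))
            truth.asm_lengths[scaffold] = out_len
            parts, out_len = [], 0

        for e in events:
            parts.append(rec.bases[cursor : e.start])
            out_len += e.start - cursor
            new_start = out_len
            if e.kind == "BREAK":
                if e.start > block_ref:
                    truth.blocks.append(CollinearBlock(
                        chrom, block_ref, e.start, scaffold, block_asm, out_len))
                _close_scaffold()
                scaffold_no += 1
                scaffold = f"scaffold_{scaffold_no}"
                truth.scaffold_of[scaffold] = chrom
                block_ref, block_asm = e.start, 0
                cursor = e.start
                continue
            parts.append(e.replacement)
            out_len += len(e.replacement)
            expected_net += len(e.replacement) - (e.end - e.start)
            if isinstance(e.meta, PlantedGap):
                e.meta.scaffold = scaffold
                e.meta.asm_start, e.meta.asm_end = new_start, out_len
            elif isinstance(e.meta, PlantedSV):
                e.meta.asm_start, e.meta.asm_end = new_start, out_len
            if e.breaks_colinearity:
                if e.start > block_ref:
                    truth.blocks.append(CollinearBlock(
                        chrom, block_ref, e.start, scaffold, block_asm, new_start))
                if e.kind == "INV":
                    truth.blocks.append(CollinearBlock(
                        chrom, e.start, e.end, scaffold, new_start, out_len,
                        strand="-"))
                block_ref = e.end
                block_asm = out_len
            cursor = e.end
        parts.append(rec.bases[cursor:])
        out_len += len(rec.bases) - cursor
        if len(rec.bases) > block_ref:
            truth.blocks.append(CollinearBlock(
                chrom, block_ref, len(rec.bases), scaffold, block_asm, out_len))
        _close_scaffold()

    total_ref = sum(len(r) for r in reference)
    total_asm = sum(len(r) for r in asm_records)
    assert total_asm == total_ref + expected_net, "length conservation violated"

    # lift repeat annotation to assembly coordinates through the truth blocks
    truth.asm_repeats = _lift_intervals(truth)
    return asm_records, truth


def _lift_intervals(truth: TruthTable) -> list[Interval]:
    blocks_by_chrom: dict[str, list[CollinearBlock]] = {}
    for b in truth.blocks:
        blocks_by_chrom.setdefault(b.chrom, []).append(b)
    for rows in blocks_by_chrom.values():
        rows.sort(key=lambda b: b.ref_start)
    out: list[Interval] = []
    for iv in truth.repeats:
        for b in blocks_by_chrom.get(iv.chrom, []):
            s = max(iv.start, b.ref_start)
            e = min(iv.end, b.ref_end)
            if s >= e:
                continue
            if b.strand == "+":
                off = b.asm_start - b.ref_start
                out.append(Interval(b.scaffold, s + off, e + off, iv.label))
            else:
                out.append(Interval(
                    b.scaffold,
                    b.asm_start + (b.ref_end - e),
                    b.asm_start + (b.ref_end - s),
                    iv.label,
                ))
    out.sort(key=lambda r: (r.chrom, r.start))
    return out


# --------------------------------------------------------------------------
# strain panel
# --------------------------------------------------------------------------


def make_strain_vcfs(
    config: SimConfig, truth: TruthTable
) -> tuple[list[VariantRecord], list[str]]:
    """Genotype the planted sites across the strain panel.

    Recurrent sites are homozygous ALT in >= 75% of strains (no missing
    calls, so the selection denominator is exact); decoy sites are either
    below the recurrence threshold or carry heterozygous calls, and must be
    rejected by the selection step.  Genotype strings are recorded in the
    truth table.
    """
    if config.n_strains < 2:
        raise ValueError("need at least 2 strains")
    rng = np.random.default_rng([config.seed, 3])
    n = config.n_strains
    samples = [f"strain_{i + 1:02d}" for i in range(n)]
    min_carriers = math.ceil(0.75 * n)
    variants: list[VariantRecord] = []
    for site in truth.sites:
        genos = ["hom-ref"] * n
        if site.recurrent:
            carriers = int(rng.integers(min_carriers, n + 1))
            for i in rng.choice(n, size=carriers, replace=False):
                genos[int(i)] = "hom-alt"
        else:
            if rng.random() < 0.5:
                # sub-threshold homozygous frequency
                carriers = int(rng.integers(1, min_carriers))
                for i in rng.choice(n, size=carriers, replace=False):
                    genos[int(i)] = "hom-alt"
            else:
                # high frequency but contaminated with het calls
                carriers = int(rng.integers(min_carriers, n + 1))
                picked = rng.choice(n, size=carriers, replace=False)
                for i in picked:
                    genos[int(i)] = "hom-alt"
                n_het = int(rng.integers(1, 3))
                for i in picked[:n_het]:
                    genos[int(i)] = "het"
        site.genotypes = "".join(_GT_CHAR[g] for g in genos)
        variants.append(VariantRecord(
            site.chrom, site.pos + 1, site.ref_base, site.alt_base, genos))
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants, samples


# --------------------------------------------------------------------------
# observed SV callsets and unaligned-set jitter
# --------------------------------------------------------------------------


def make_sv_callsets(
    truth: TruthTable,
    config: SimConfig,
    jitter: int = 10,
    dropout: float = 0.0,
):
    """Two noisy views of the planted SVs, emulating two technologies.

    Breakpoints are shifted uniformly within +/- jitter bp per caller, and
    each caller may miss a call with probability ``dropout``.  Returns two
    lists of :class:`asmcurate.sv.SVRecord`.
    """
    from .sv import SVRecord

    rng = np.random.default_rng([config.seed, 4])
    callsets = []
    for caller in ("pacbio", "illumina"):
        calls = []
        for sv in truth.svs:
            if rng.random() < dropout:
                continue
            js = int(rng.integers(-jitter, jitter + 1))
            je = int(rng.integers(-jitter, jitter + 1))
            start = max(0, sv.start + js)
            end = sv.end + je
            if sv.svclass == "INS":
                end = start
                size = sv.size
            else:
                end = max(end, start + 1)
                size = end - start
            calls.append(SVRecord(sv.chrom, start, end, sv.svclass, size, caller))
        callsets.append(calls)
    return callsets[0], callsets[1]


def jitter_intervals(
    intervals: list[Interval], seed: int, jitter: int = 50
) -> list[Interval]:
    """Shift interval boundaries within +/- jitter bp (emulating a second
    alignment method's slightly different unaligned-region boundaries)."""
    rng = np.random.default_rng([seed, 5])
    out = []
    for iv in intervals:
        s = max(0, iv.start + int(rng.integers(-jitter, jitter + 1)))
        e = iv.end + int(rng.integers(-jitter, jitter + 1))
        if e > s:
            out.append(Interval(iv.chrom, s, e, iv.label))
    return out


# --------------------------------------------------------------------------
# one-call orchestration
# --------------------------------------------------------------------------


@dataclass
class SimResult:
    reference: list[SequenceRecord]
    assembly: list[SequenceRecord]
    repeats: list[Interval]
    truth: TruthTable
    variants: list[VariantRecord]
    samples: list[str]


def simulate(config: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Run the full generator; optionally write ref.fa, asm.fa, repeats.bed,
    asm_repeats.bed, strains.vcf and truth.json into ``outdir``."""
    from .io import write_bed, write_fasta, write_vcf

    reference, repeats, truth = make_reference(config)
    assembly, truth = derive_assembly(reference, truth, config)
    variants, samples = make_strain_vcfs(config, truth)
    result = SimResult(reference, assembly, repeats, truth, variants, samples)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(reference, outdir / "ref.fa")
        write_fasta(assembly, outdir / "asm.fa")
        write_bed(repeats, outdir / "repeats.bed")
        write_bed(truth.asm_repeats, outdir / "asm_repeats.bed")
        write_vcf(
            variants, samples, outdir / "strains.vcf",
            contigs=truth.ref_lengths,
            extra_header=[f"##asmcurate_seed={config.seed}"],
        )
        truth.to_json(outdir / "truth.json")
    return result
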