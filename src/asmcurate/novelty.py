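"""Transcript novelty classification against a reference annotation.

Predicted transcripts are compared with reference transcript models by
their splice junctions and exon footprints and assigned exactly one status:

* ``novel_locus`` — no exon overlaps any reference exon;
* ``novel_exon`` — some exon has zero overlap with every reference exon
  (the strictest reading of a "fully novel" exon; a slack parameter can
  tolerate a few shared bp);
* ``splice_shift`` — a junction absent from the reference junction set
  (by default one sharing a single coordinate with a reference junction,
  i.e. only the donor or only the acceptor moved);
* ``annotated`` — every junction is in the reference set.

Precedence when several apply: novel_locus > novel_exon > splice_shift >
annotated.  Junctions are intron-based: donor = exon end, acceptor = next
exon start, 0-based half-open, keyed by (chrom, donor, acceptor, strand).
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import Interval

Junction = tuple[str, int, int, str]


@dataclass
class TranscriptModel:
    name: str
    chrom: str
    strand: str
    exons: list[Interval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("transcript needs at least one exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in {self.name}")

    @property
    def junctions(self) -> list[Junction]:
        return [
            (self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.exons[0].start, self.exons[-1].end)


def junction_set(models: list[TranscriptModel]) -> set[Junction]:
    """Deduplicated splice junctions over all models; single-exon models
    contribute none."""
    out: set[Junction] = set()
    for m in models:
        out.update(m.junctions)
    return out


def classify_novelty(
    prediction: TranscriptModel,
    reference_models: list[TranscriptModel],
    reference_junctions: set[Junction] | None = None,
    novel_exon_slack: int = 0,
) -> str:
    """Assign one of annotated / splice_shift / novel_exon / novel_locus."""
    if reference_junctions is None:
        reference_junctions = junction_set(reference_models)

    ref_exons = [
        e for m in reference_models if m.chrom == prediction.chrom
        for e in m.exons
    ]

    def exon_overlap_bp(exon: Interval) -> int:
        return sum(
            min(exon.end, r.end) - max(exon.start, r.start)
            for r in ref_exons
            if r.start < exon.end and exon.start < r.end
        )

    if all(exon_overlap_bp(e) == 0 for e in prediction.exons):
        return "novel_locus"
    if any(exon_overlap_bp(e) <= novel_exon_slack for e in prediction.exons):
        return "novel_exon"

    novel = [j for j in prediction.junctions if j not in reference_junctions]
    if novel:
        # a junction sharing only one coordinate with some reference
        # junction is the canonical splice-site shift; a doubly novel
        # junction in an annotated locus is classified the same way
        return "splice_shift"
    return "annotated"


# --------------------------------------------------------------------------
# GFF3 / BED12 input
# --------------------------------------------------------------------------


def read_transcripts_gff3(path: str) -> list[TranscriptModel]:
    """Build transcript models from GFF3 exon features grouped by Parent."""
    exons: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] != "exon":
                continue
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            parent = attrs.get("Parent", attrs.get("ID"))
            if parent is None:
                continue
            exons.setdefault(parent, []).append(
                Interval(cols[0], int(cols[3]) - 1, int(cols[4]))
            )
            meta[parent] = (cols[0], cols[6])
    return [
        TranscriptModel(name, meta[name][0], meta[name][1], ivs)
        for name, ivs in sorted(exons.items())
    ]


def read_transcripts_bed12(path: str) -> list[TranscriptModel]:
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            cols = line.split("\t")
            chrom, start = cols[0], int(cols[1])
            name, strand = cols[3], cols[5]
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            exons = [
                Interval(chrom, start + s, start + s + ln)
                for s, ln in zip(starts, sizes)
            ]
            out.append(TranscriptModel(name, chrom, strand, exons))
    return out
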