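# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `asmcurate`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions

All internal coordinates are 0-based half-open. The two 1-based inclusive
surfaces are VCF `POS` and human-facing `chrom:start-end` region strings;
conversion happens only at the I/O boundary (`asmcurate.io`). The fixed
point of the convention: a gap displayed as `chr2:172,624,657-172,626,416`
has length end − start + 1 = 1,760 bp. PAF negative-strand records follow
the minimap2 dialect — query coordinates on the original query strand.
Reported percentages and ratios use half-up rounding (never banker's), so
every printed figure is recomputable from its raw counts.

## Micro-aligner

A minimal seed-and-chain aligner closes the pipeline at desk scale, in
place of the production aligners whose *outputs* (PAF) the pipeline also
accepts.

* **Anchors**: exact k-mers (default k = 15, minimum 11) unique in the
  query, matched against target occurrences of multiplicity ≤ 4
  (`max_occ`); k-mers containing N never anchor. Bounded target
  multiplicity lets duplicated loci align once per copy — needed for the
  uniqueness criterion below — while high-copy repeats never anchor.
* **Segments**: anchors are run-compressed along diagonals into maximal
  exact-match segments, then chained by DP with gap penalty |Δq − Δt|,
  a 2,000 bp maximum gap, and a 64-segment look-back window. Chains never
  cross an N-run on either sequence, so a gapped reference yields one
  alignment per contig — exactly the flank-pair structure gap filling
  needs. Chain score = Σ segment lengths − Σ penalties; chains under 100
  are dropped. Ties between equal-score chains break toward lower target
  then query start.
* **End extension**: terminal segments extend gap-free with an X-drop rule
  (match +1, mismatch −1, stop 10 under the running best, cap 2,000 bp,
  never across an N). Without it, chain endpoints can sit tens of bp
  inside the DP-optimal local alignment when substitutions cluster near
  sequence ends; with it, endpoints agree with an exhaustive local DP
  oracle within k bp on low-divergence 200 bp pairs (asserted in the
  suite).
* **Output**: PAF with a `cg` CIGAR over M/I/D; `nmatch` counts exactly
  matching non-N bases over M stretches. There is **no affine-gap
  base-level alignment between anchors**: inter-segment bases are compared
  gap-free with the length difference placed as a single indel at the
  segment boundary. Adequate for the low-divergence same-strain use case;
  indel *placement* within an inter-anchor interval is not base-accurate.

## Chains, net and liftover

Alignments of one (query, target, strand) group are merged into chains
when co-linear; a small overlap (≤ 50 bp of diagonal slippage, or any
purely target-side overlap) is trimmed away, because end extension makes
otherwise co-linear records overlap across anchor-free repeat blocks. A
candidate whose query content re-maps already-used query sequence to *new*
target space is a second placement, never merged.

Netting assigns target space greedily in descending chain score
(Σ aligned bases — a deliberate divergence from UCSC's substitution-matrix
chain scores, which the source procedure does not specify), ties broken
toward the longer target span, then lexicographic query name. Lower-score
chains keep only unowned sub-blocks. Mapping: inside an owned block,
linear offset (on "−" chains the reflection q = qend − 1 − (t − tstart);
a single base maps to the aligned base itself, not base + 1); between the
blocks of the owning chain, `deleted`; anywhere else `unaligned`.
Interval mapping maps the two endpoint bases, fails as `split` when they
land on different chains or strands, and as `length` when the mapped
length differs from the source by more than 2× either way. No UCSC
`.chain` import/export in this version; PAF is the interchange.

## Gap filling

`find_gaps` reports maximal N-runs ≥ 10 bp minus an exclusion mask
(centromere/telomere intervals are an input, not inferred). Padding is
gap ± flank, clipped to chromosome bounds. Filtering implements three
criteria: (a) reciprocal best hit by Σ matched bases over all alignments
of the pair — summing over the co-linear pair rather than a single best
alignment, since the alternative is underdetermined; ties break toward
the pair with fewer alignments (more contiguous), then lexicographic;
(b) total ≥ `min_total_aln`, inclusive; (c) scaffold uniqueness,
operationalized as ≥ 90% of the scaffold's netted aligned bases in a
single chain locus (configurable threshold). Confirmation replaces manual
inspection of browser screenshots with the programmatic reciprocal
discrepancy check (±10 bp tolerance) plus a per-candidate TSV for manual
review. The fill is clipped to alignment-supported bounds when a flank
alignment stops short of the gap edge.

## Recurring variants

Selection keeps sites with hom-ALT fraction ≥ `min_frac` (default 0.75,
inclusive) among non-missing samples — missing genotypes are excluded
from the denominator, a documented choice where the convention was open —
and, under `homozygous_only`, no het calls. Resolution lifts each SNV,
fetches one assembly base, reverse-complements ALT on "−" chains, and
compares; `resolved + unresolved + unmappable` always equals the input
count. Indels are supported experimentally via haplotype comparison over
lifted flanking anchors and are not exercised by the default generator.
The summary percentage divides by all considered sites or by the
remappable ("net") subset, caller's choice. CDS indel classification:
a placement is frameshifting if any CDS-overlapping alignment gap has
length ≢ 0 (mod 3) — one frameshifting gap dominates any number of
in-frame ones; gaps outside CDS are ignored.

## SV consensus

Merging is greedy 1-to-1 in ascending breakpoint distance (the larger of
the two per-breakpoint offsets), requiring class match and both
breakpoints within 1,000 bp (inclusive) — the common integration default;
the published pipeline does not print its merge distance. Tie-break:
(chrom, start, caller tag). The consensus set contains support-2 records
only (mean breakpoints, both callers listed); translocations compare both
breakend loci. Summaries use the lower median for even class sizes —
a documented convention — and count any ≥ 1 bp gene overlap.

## Repeats and unaligned sequence

Consensus of unaligned sets is the per-base intersection of all sets,
emitted as maximal merged intervals (order-independent and idempotent).
Composition attributes overlap between repeat annotations to the
first-listed class after sorting by (start, class), so classified bp never
exceed the region total. Enrichment is the 2×2 Pearson χ² with 1 df and
no continuity correction, with a `reliable=False` flag (not an error) when
any expected cell is < 5. Repeat annotation is consumed as labeled BED;
running a repeat annotator is out of scope.

## Assembly metrics

N50/Nxx: the smallest length L such that sequences ≥ L cover ≥ x% of the
total. Scaffold splitting breaks at maximal N-runs ≥ 10 bp (shorter runs
stay inside contigs); concatenating contigs with the removed runs
reconstructs the scaffold exactly. K-mer completeness uses canonical
k-mers (min of forward and reverse-complement 2-bit codes, k ≤ 31,
default 21 — long k buys nothing at desk scale), excluding N-containing
windows on both sides.

## Synthetic data: what it emulates, and what it does not

The generator plants every feature the pipeline must recover, with the
truth recorded in both reference and assembly coordinates:

* **Scale**: 2 chromosomes × 2 Mb, flank 5 kb, minimum alignment 8 kb —
  a 1/10 scaling of the 50 kb / 80 kb genome-scale parameters; all are
  config fields, so genome-scale runs are possible.
* **Repeats**: tandem copies of seeded motifs — satellite (120 bp
  monomer), microsatellite (2–6 bp motif), LINE-like (a fixed ~3 kb decoy
  element) — placed to hit per-class composition targets essentially
  exactly; enough to exercise composition accounting and alignability
  structure without real repeat libraries.
* **Gaps**: N-runs of 100–2,000 bp replacing recorded true fill, with
  repeat-free flanks; the assembly is broken into scaffolds *between*
  gaps, so each scaffold spans at most one gap — the scaffold-scale
  situation reciprocal-best-hit filtering presumes. SVs are kept out of
  padded gap regions: the fill-extraction arithmetic assumes SV-free
  flanks, and a planted insertion inside a flank would (correctly but
  unhelpfully) appear in the extracted fill.
* **Strain panel**: 24 strains, 2,194 recurrent sites (hom-ALT in a
  uniform-random ≥ 75% of strains, no missing calls, so the selection
  denominator is exact), plus 200 decoy sites that must be rejected
  (sub-threshold frequency or het contamination). A fraction f = 0.126 of
  recurrent sites (half-up ⇒ 276) are reference errors: the assembly
  carries the ALT base at the lifted position. These panel defaults match
  the scale of the real descendant-panel analysis, which is what makes
  the end-to-end resolution count a meaningful recovery target.
* **Drift and SVs**: optional SNV/indel rates (default 0: the recovery
  laws are stated at zero noise) and per-class SV counts
  (3 DEL / 3 DUP / 2 INV / 3 INS, 200–5,000 bp) applied outside gaps and
  sites; every edit is logged, and exact length conservation
  (assembly = reference − ΣN + Σfill + Σnet deltas) is asserted at
  generation time.
* **Truth liftover**: the gap-free stretches between length-changing
  edits become an exact ChainSet — the "perfect liftover" against which
  resolution recovery is stated, and an oracle for the aligner-derived
  liftover.

Not emulated: read-level error profiles (no FASTQ), pedigree drift
dynamics, polymorphic repeat-copy-number variation, segmental-duplication
collapse, alignment-ambiguous paralogy. Passing recovery tests therefore
demonstrates the correctness of the curation logic under clean planted
conditions, not robustness to real sequencing artifacts; the published
headline counts on real genomes (gaps spanned, common SVs, completeness
percentages) depend on the deposited data and are reproduced here only as
arithmetic worked examples at their printed values.

Determinism: one seed, split into fixed per-stage streams, makes every
output bit-identical across runs; the seed is recorded in output headers.

## Acceptance problem sizes

`scripts/acceptance.py` uses the printed worked-example counts as inputs
(10/126, 307/2,407, 393/2,194, 2,194/3,203, the two N50s, the repeat bp
tables, both gap examples rebuilt at their stated sizes with 20 kb
flanks), and one synthetic run at the default study conditions above for
the end-to-end recoveries. Wall time is well under a minute on one CPU.

## Known limitations

* The micro-aligner is not a production aligner: no affine gaps, no
  base-accurate indel placement, no spliced alignment, and performance is
  tuned for ≤ tens of Mb.
* Netting score is Σ aligned bases, not a substitution-matrix chain score;
  nets can differ from UCSC tooling on diverged genomes.
* Indel resolution (variant module) is experimental; the selection and
  resolution path is validated on SNVs.
* χ² enrichment treats bases as independent observations, as in the
  procedure it re-implements; autocorrelation along the genome makes the
  nominal p-values anti-conservative. The statistic, not the p-value, is
  the comparable quantity.
* Transcript-novelty precedence (novel_locus > novel_exon > splice_shift >
  annotated) and the treatment of a doubly novel junction inside an
  annotated locus (classified as splice_shift) are package conventions
  where the source logic was unstated.
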