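# Methods

## Coordinate conventions

All intervals are 0-based half-open internally (BED convention).
Conversions happen only at I/O boundaries: SAM text and GFF3 are 1-based
inclusive and converted on read; report-table breakpoint columns
(`left_pos`, `right_pos`) are 1-based, meaning the last and first
covered bases flanking the breakpoint window, so the internal window is
`[left_pos, right_pos − 1)`. Adjacent columns (`right = left + 1`)
denote a zero-length gap — the insertion point between two covered
bases — represented for overlap purposes by the 1-nt slot at the
junction.

Interval merging treats book-ended intervals as mergeable
(`merge_distance = 0`, the classic merge default); intersection demands
≥ 1 nt of genuine overlap, so abutting half-open intervals do not
intersect. Sorting ties break by (chrom lexicographic, start, end,
label).

## Insertion-calling model

The caller assumes alignments against a reference that carries both
chromosome contigs and TE consensus contigs, and defines discordance
*solely* as mates mapping to contigs in different partitions (target vs
TE). Insert-size discordance on one contig is deliberately ignored: with
a TE-supplemented reference, a fragment spanning an insertion junction
maps one mate to the chromosome and the other into the element, which is
exactly the evidence class of interest. Secondary, supplementary and
duplicate-flagged records are excluded; unpaired records are skipped and
counted.

Candidate windows are anchors widened by `candidate_flank` (default
500 nt — the anchor read plus ~1 kb of context) and merged per TE
family, so co-located insertions of different elements remain separate
candidates. Control subtraction removes case loci with ≥ 1 nt overlap
with a same-family control locus: a TE present at the same place in the
non-mutagenized background is a pre-existing copy, not a novel
insertion. Subtraction is idempotent.

### Breakpoint window and filters

A true insertion leaves an uncovered hole of target-site-duplication
scale between the left-side and right-side anchor sets. The breakpoint
window is estimated as the uncovered gap in the union of anchor spans
that has the most balanced support on both sides (ties: leftmost); this
equals `[max end of left-side anchors, min start of right-side anchors)`
under the induced side assignment. An earlier variant assigned sides by
comparing anchor ends with the candidate-region midpoint; it proved
fragile — one long anchor tail shifts the midpoint and misclassifies
breakpoint-flush anchors — and was replaced by the gap estimator, which
is invariant to the region's extent. When no internal gap with support
on both sides exists (one-sided evidence), the window falls back to the
median anchor midpoint ± `breakpoint_slack` (default 50 nt) and the
bilateral filter fails by construction.

Filters:

* **bilateral support** — ≥ `min_side_support` anchors ending at/before
  the window start and ≥ that many starting at/after its end. Default 2
  per side: the weakest automated surrogate for "pairs on both sides"
  that still rejects single stray mates.
* **coverage loss** — median per-base depth inside the window over the
  median of the two `flank_depth_width` (500 nt) flanks, required
  ≤ `max_coverage_ratio` (0.5). Degenerate case: if the flank median is
  0 there is no evidence of a drop, and the ratio is defined as 1.0
  (filter fails). Window medians of truly clean insertions are 0, so the
  0.5 default is permissive toward moderate noise while rejecting flat
  coverage.

`min_mapq` defaults to 10 (anchor uniqueness floor). All thresholds are
configurable; `status == confirmed` iff both filters pass.

Observed breakpoint windows vary in width (the worked example ranges
9–41 nt around a 4 nt planted duplication) because the flush-most
anchors on each side are a sampling accident of fragment starts — the
same behaviour seen in real screen tables, where most windows span a few
nt but occasional ones span tens of nt.

## Permutation enrichment test

Statistic: number of insertion intervals overlapping ≥ 1 peak, each
insertion counted once (insertions intersecting peaks, not peaks hit).
The *peaks* are shuffled, not the insertions: `n_shuffles` independent
length-preserving, mutually non-overlapping uniform placements on the
allowed chromosome(s) (default: the target chromosomes). Shuffle *i*
uses seed `rng_seed + i`, making the run reproducible and
parallelizable. The p-value is `#{null ≥ observed} / n_shuffles` with
no +1 correction; zero exceedances are reported as the resolution bound
`1/n_shuffles` with `p_is_bound = True` (printed `< 1/N`), never as 0.
Consequently p always lies on the grid `{k/N}` and is deterministic
given the seed.

Shuffling uses rejection sampling: a start is drawn uniformly over every
fitting position across the allowed contigs and redrawn on collision
with already placed intervals, up to 10,000 attempts per interval, after
which an infeasible-placement error signals over-dense input. Placement
is exact (no approximation), at the cost of slowing down as peak density
approaches the contig length.

## Annotation

GFF3 gene models are read through an in-memory gffutils database;
5′/3′ UTRs are derived as the exonic regions outside the CDS span on the
transcript strand, introns as the gaps between sorted exons. An
insertion overlapping several features takes the highest-precedence
class, fixed as 5′UTR > 3′UTR > CDS > intron > intergenic, and records
the transcript that drove the class; annotation is against all
transcripts, not one chosen isoform. Strand is ignored for overlap.
Peak flags require ≥ 1 nt overlap of the breakpoint window with the peak
set. Motif distance is midpoint-to-midpoint in nt (0 when midpoints
coincide; undefined/`None` for an empty motif set). Report-table motif
distances are carried as data, not recomputed, since the motif
coordinates behind them are an input this package consumes, not derives.

## Screen statistics

Complementation groups are connected components of the
failure-to-complement graph (singletons for alleles with no failures),
ordered by smallest member. Transitivity is assumed for grouping, but
intransitive complementation does occur in real data, so components that
are not cliques are surfaced by `non_clique_groups` rather than silently
absorbed. The recovery-rate numerator counts sterile *and* lethal
recovered alleles (17/1,192 → 1.43%, reported to two decimals; printed
sources may truncate to 1.42%). `groups_with_insertion` supports both
countings of "groups with a detected element" — including or excluding
an allele whose insertion is discordant with its group — because screen
tables can contain exactly that ambiguity (here, the fs(1)GS16 row of
the packaged table belongs to the no-mdg4 fs(1)GS06 group; counting it
gives 9 groups with an insertion, excluding it gives 8).

The packaged `data/table1.tsv` transcribes the 13 reported insertions;
validation enforces Yes/No flags, positive integer motif distances, and
`left ≤ right`, and lists every offending row.

## Synthetic-data generator

The generator emulates the study conditions: 50 bp paired-end reads,
~300 ± 30 nt fragments, 30× fold-coverage, a 2 Mb target chromosome
(scaled down in tests, see below), a TE library of one 7 kb
LTR-element-like and one 4.5 kb LINE-like consensus, 4 nt target-site
duplications, and a peak/motif track with a `bias` knob giving the
probability that an insertion lands inside a peak (0 = null).

Alignment records are generated directly rather than by mapping
simulated sequences: the package under test consumes alignments, and
generating them directly gives exact control over the evidence classes.
A control-library fragment overlapping a planted hole `[p, p + tsd)` is
transformed as real mapping would: a read crossing the junction is
unmappable to the target and its clean mate becomes the target anchor of
a discordant pair (TE mate placed uniformly on the family contig); a
fragment whose inner gap holds the junction keeps one mate (coin flip)
and sends the other to the TE; a fragment with both reads crossing is
dropped. This leaves per-base depth exactly 0 inside the hole, flank
depth at the library coverage, and discordant anchors flush with both
breakpoint edges — expected per side ≈ depth·(fragment + tsd)/(4·read
length) ≈ 46 at the defaults. Optional `noise_discordant_rate` converts
a random fragment fraction into spurious TE-mated pairs (multimapping
artifacts) for robustness testing.

What the simulator does **not** model: sequence-dependent mappability,
GC bias, chimeric/split reads, soft-clipping at junctions, nested or
truncated TE insertions, or coverage dispersion beyond uniform fragment
sampling. Passing recovery tests therefore demonstrates the correctness
of the detection logic under clean mapping, not robustness to real
alignment pathology (which screen workflows have traditionally handled
by manual browser review).

Insertion positions are unique, ≥ read-length from contig ends, and
separated by `min_insertion_gap` (default 10 kb) so candidate windows do
not merge across events; with `bias > 0` a position is drawn inside a
uniformly chosen peak. Everything is a pure function of the
configuration including its seed.

## Problem sizes in tests

The package defaults stay at the study scale (2 Mb target, 30×). The
test and acceptance suites scale the chromosome down as their own choice
of problem size: recovery runs use a 150 kb target (5 insertions, 30×,
20 seeds), null-calibration uses 500 replicate datasets of 400
insertions against 25 peaks covering 25% of a 200 kb chromosome with
200 shuffles each, and power runs use 20 insertions with bias 0.6 into
peaks covering 5%. The calibration scenario deliberately uses many
insertions and substantial peak coverage so the overlap statistic has
wide support: with a narrow-support statistic the no-+1 empirical
p-value is coarsely discrete and a Kolmogorov–Smirnov test against
U(0,1) would reject on discreteness alone rather than miscalibration.

## Known limitations

* Breakpoints are window-scale, not single-nt: no split-read refinement
  or TSD sequence reconstruction.
* Only target↔TE discordance is considered; insertions of elements
  absent from the TE contig set are invisible.
* The shuffle null is uniform: no GC-, mappability- or
  chromatin-matched placement.
* The enrichment test assumes peaks fit sparsely enough on the
  chromosome for rejection-sampled placement; extremely dense peak sets
  raise an infeasibility error rather than degrading silently.
* Complementation grouping reports, but does not resolve, intransitive
  structures.
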