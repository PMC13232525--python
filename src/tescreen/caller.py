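"""Novel TE insertion detection from discordant read pairs.

The pipeline mirrors a TE-supplemented-reference calling strategy:

1. extract read pairs with one mate on a target chromosome and the
   other on a TE consensus contig (discordant evidence);
2. widen each target-side anchor into a candidate window and collapse
   overlapping windows per TE family into candidate loci;
3. drop candidate loci that also exist in the matched control sample
   (pre-existing TE copies in the background genotype);
4. score each remaining locus with two automated evidence filters:
   discordant support on both sides of the inferred breakpoint window,
   and a loss of read depth inside that window relative to its flanks.

Only calls passing both filters are reported as confirmed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pysam

from .intervals import (
    GenomeContext,
    GenomicInterval,
    depth_profile,
    merge,
    slop,
)

logger = logging.getLogger("tescreen")

__all__ = [
    "CallerParams",
    "DiscordantEvidence",
    "CandidateLocus",
    "InsertionCall",
    "extract_discordant",
    "scan_alignments",
    "build_candidates",
    "subtract_control",
    "score_insertion",
    "call_pipeline",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_confirmed_bed",
]


@dataclass(frozen=True)
class CallerParams:
    """Tunable thresholds of the caller.

    min_mapq: anchor mapping-quality floor.
    candidate_flank: nt added to each side of an anchor before merging
        (default 500, i.e. ~1 kb candidate windows around a 50 bp read).
    min_side_support: discordant anchors required on each side of the
        breakpoint window for the bilateral-evidence filter.
    max_coverage_ratio: highest in-window/flank median-depth ratio still
        accepted as an "evident" coverage loss.
    flank_depth_width: nt of flank on each side used for the depth baseline.
    breakpoint_slack: half-width of the fallback breakpoint window when
        support exists on one side only.
    breakpoint_tolerance: nt of positional slack granted when matching
        calls to known sites (used by recovery checks and reports).
    """

    min_mapq: int = 10
    candidate_flank: int = 500
    min_side_support: int = 2
    max_coverage_ratio: float = 0.5
    flank_depth_width: int = 500
    breakpoint_slack: int = 50
    breakpoint_tolerance: int = 50

    def __post_init__(self) -> None:
        if self.min_side_support < 1:
            raise ValueError("min_side_support must be >= 1")
        if self.max_coverage_ratio < 0:
            raise ValueError("max_coverage_ratio must be >= 0")


@dataclass(frozen=True)
class DiscordantEvidence:
    """A target-side read anchor whose mate aligned to a TE consensus."""

    anchor: GenomicInterval
    te_family: str
    side_hint: str  # "forward" | "reverse" orientation of the anchor read
    mapq: int


@dataclass(frozen=True)
class CandidateLocus:
    """Merged candidate window for one TE family with its support."""

    region: GenomicInterval
    te_family: str
    support: tuple[DiscordantEvidence, ...]

    def __post_init__(self) -> None:
        if not self.support:
            raise ValueError("candidate locus requires support")
        if any(e.te_family != self.te_family for e in self.support):
            raise ValueError("mixed TE families in one candidate locus")


@dataclass
class InsertionCall:
    """A scored insertion with the report-convention breakpoint columns.

    ``left_pos``/``right_pos`` are 1-based: the last base with retained
    coverage before the breakpoint window and the first base after it.
    The 0-based half-open breakpoint window is therefore
    ``[left_pos, right_pos - 1)``.
    """

    chrom: str
    left_pos: int
    right_pos: int
    te_family: str
    n_left_support: int
    n_right_support: int
    coverage_ratio: float
    passed_bilateral: bool
    passed_coverage: bool
    status: str = "candidate"  # candidate | confirmed | rejected

    def __post_init__(self) -> None:
        if self.left_pos > self.right_pos:
            raise ValueError("left_pos must be <= right_pos")
        if self.coverage_ratio < 0:
            raise ValueError("coverage_ratio must be >= 0")

    @property
    def window(self) -> GenomicInterval:
        """Breakpoint window in internal 0-based half-open coordinates."""
        return self.window_from_report(
            self.chrom, self.left_pos, self.right_pos, self.te_family
        )

    @staticmethod
    def window_from_report(
        chrom: str, left_pos: int, right_pos: int, label: str | None = None
    ) -> GenomicInterval:
        """0-based breakpoint window from 1-based report columns.

        Adjacent left/right positions mean a zero-length gap (the
        insertion point falls between two covered bases); that case is
        represented by the 1-nt slot at the junction.
        """
        if right_pos - 1 > left_pos:
            return GenomicInterval(chrom, left_pos, right_pos - 1, label)
        return GenomicInterval(chrom, left_pos, left_pos + 1, label)


# ---------------------------------------------------------------------------
# stage 1: evidence extraction
# ---------------------------------------------------------------------------

def _usable(rec: pysam.AlignedSegment) -> bool:
    return not (
        rec.is_unmapped
        or rec.is_secondary
        or rec.is_supplementary
        or rec.is_duplicate
    )


def scan_alignments(
    alignments: "pysam.AlignmentFile | Iterable[pysam.AlignedSegment]",
    ctx: GenomeContext,
    min_mapq: int = 10,
) -> tuple[list[DiscordantEvidence], dict[str, np.ndarray]]:
    """Single pass over an alignment stream.

    Returns the discordant evidence list plus, per target contig, the
    (start, end) spans of every usable target-mapped read — the depth
    source for the coverage filter. Unpaired records are skipped and
    counted.
    """
    evidence: list[DiscordantEvidence] = []
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in ctx.target_contigs}
    n_unpaired = 0
    for rec in alignments:
        if not _usable(rec):
            continue
        if not rec.is_paired:
            n_unpaired += 1
            continue
        chrom = rec.reference_name
        if chrom not in ctx.target_contigs:
            continue
        spans[chrom].append((rec.reference_start, rec.reference_end))
        if rec.mate_is_unmapped or rec.mapping_quality < min_mapq:
            continue
        mate_chrom = rec.next_reference_name
        if mate_chrom in ctx.te_contigs:
            evidence.append(
                DiscordantEvidence(
                    anchor=GenomicInterval(
                        chrom, rec.reference_start, rec.reference_end, mate_chrom
                    ),
                    te_family=mate_chrom,
                    side_hint="reverse" if rec.is_reverse else "forward",
                    mapq=rec.mapping_quality,
                )
            )
    if n_unpaired:
        logger.info("skipped %d unpaired records", n_unpaired)
    return evidence, {c: np.array(v, dtype=np.int64).reshape(-1, 2) for c, v in spans.items()}


def extract_discordant(
    alignments: "pysam.AlignmentFile | Iterable[pysam.AlignedSegment]",
    ctx: GenomeContext,
    min_mapq: int = 10,
) -> list[DiscordantEvidence]:
    """Discordant (target-anchor, TE-mate) evidence from an alignment stream."""
    evidence, _ = scan_alignments(alignments, ctx, min_mapq)
    return evidence


# ---------------------------------------------------------------------------
# stage 2: candidate loci
# ---------------------------------------------------------------------------

def build_candidates(
    evidence: Sequence[DiscordantEvidence],
    flank: int,
    ctx: GenomeContext,
) -> list[CandidateLocus]:
    """Widen anchors by ``flank`` nt and merge per TE family.

    Families are merged separately: co-located insertions of different
    elements stay distinct candidates.
    """
    by_family: dict[str, list[DiscordantEvidence]] = {}
    for ev in evidence:
        by_family.setdefault(ev.te_family, []).append(ev)

    out: list[CandidateLocus] = []
    for family in sorted(by_family):
        evs = sorted(
            by_family[family], key=lambda e: (e.anchor.chrom, e.anchor.start, e.anchor.end)
        )
        cur_region: GenomicInterval | None = None
        cur_members: list[DiscordantEvidence] = []
        for ev in evs:
            w = slop(ev.anchor, flank, ctx)
            if (
                cur_region is not None
                and w.chrom == cur_region.chrom
                and w.start <= cur_region.end
            ):
                cur_region = GenomicInterval(
                    cur_region.chrom,
                    cur_region.start,
                    max(cur_region.end, w.end),
                    family,
                )
                cur_members.append(ev)
            else:
                if cur_region is not None:
                    out.append(CandidateLocus(cur_region, family, tuple(cur_members)))
                cur_region = GenomicInterval(w.chrom, w.start, w.end, family)
                cur_members = [ev]
        if cur_region is not None:
            out.append(CandidateLocus(cur_region, family, tuple(cur_members)))
    out.sort(key=lambda c: (c.region.chrom, c.region.start, c.te_family))
    return out


def subtract_control(
    case: Sequence[CandidateLocus],
    control: Sequence[CandidateLocus],
) -> list[CandidateLocus]:
    """Drop case loci overlapping a same-family control locus.

    A TE location present in both genotypes is a pre-existing copy, not
    a novel insertion. Overlap with a *different* family's control locus
    does not remove a candidate.
    """
    by_family: dict[str, list[CandidateLocus]] = {}
    for loc in control:
        by_family.setdefault(loc.te_family, []).append(loc)
    out = []
    for loc in case:
        ctrl = by_family.get(loc.te_family, ())
        if not any(loc.region.overlaps(c.region) for c in ctrl):
            out.append(loc)
    return out


# ---------------------------------------------------------------------------
# stage 3: scoring
# ---------------------------------------------------------------------------

DepthFn = Callable[[GenomicInterval], np.ndarray]


def depth_source(spans: dict[str, np.ndarray]) -> DepthFn:
    """Depth function over pre-collected per-contig read spans."""

    sorted_spans = {
        c: arr[np.argsort(arr[:, 0], kind="stable")] if len(arr) else arr
        for c, arr in spans.items()
    }

    def depth(window: GenomicInterval) -> np.ndarray:
        arr = sorted_spans.get(window.chrom)
        if arr is None or not len(arr):
            return np.zeros(window.length, dtype=np.int64)
        # spans sorted by start: candidates are those starting before window.end
        hi = int(np.searchsorted(arr[:, 0], window.end, side="left"))
        sel = arr[:hi]
        sel = sel[sel[:, 1] > window.start]
        return depth_profile(map(tuple, sel), window)

    return depth


def _median_depth(depth_fn: DepthFn, window: GenomicInterval | None) -> float:
    if window is None or window.length <= 0:
        return float("nan")
    return float(np.median(depth_fn(window)))


def score_insertion(
    locus: CandidateLocus,
    depth_fn: DepthFn,
    params: CallerParams,
    ctx: GenomeContext,
) -> InsertionCall:
    """Apply the bilateral-support and coverage-loss filters to one locus.

    The breakpoint window is the gap between the rightmost end of the
    left-side anchors and the leftmost start of the right-side anchors
    (clamped to >= 1 nt). Side assignment picks, among the uncovered
    gaps in the union of anchor spans, the one with the most balanced
    support on both sides — a true insertion leaves exactly such a hole
    at target-site-duplication scale. With support on one side only
    (no internal gap), the window falls back to the median anchor
    midpoint +- ``breakpoint_slack`` and the bilateral filter fails by
    definition.
    """
    region = locus.region
    anchors = sorted((e.anchor.start, e.anchor.end) for e in locus.support)
    # uncovered gaps inside the union of anchor spans
    gaps: list[tuple[int, int]] = []
    cov_end = anchors[0][1]
    for s, e in anchors[1:]:
        if s > cov_end:
            gaps.append((cov_end, s))
        cov_end = max(cov_end, e)

    best: tuple[int, int] | None = None
    best_score = -1
    for gs, ge in gaps:
        n_l = sum(1 for s, e in anchors if e <= gs)
        n_r = sum(1 for s, e in anchors if s >= ge)
        score = min(n_l, n_r)
        if score > best_score:
            best, best_score = (gs, ge), score

    bilateral_possible = best is not None and best_score > 0
    if bilateral_possible:
        w_start, w_end = best  # == [max left-anchor end, min right-anchor start]
    else:
        mids = sorted(e.anchor.midpoint for e in locus.support)
        c = int(mids[len(mids) // 2])
        w_start, w_end = c - params.breakpoint_slack, c + params.breakpoint_slack

    contig_len = ctx.length_of(region.chrom)
    w_start = max(region.start, max(0, w_start))
    w_end = min(region.end, min(contig_len, w_end))
    if w_end <= w_start:
        w_end = min(contig_len, w_start + 1)
    window = GenomicInterval(region.chrom, w_start, w_end, locus.te_family)

    n_left = sum(1 for e in locus.support if e.anchor.end <= window.start)
    n_right = sum(1 for e in locus.support if e.anchor.start >= window.end)

    W = params.flank_depth_width
    lf_start, lf_end = max(0, window.start - W), window.start
    rf_start, rf_end = window.end, min(contig_len, window.end + W)
    flank_depths = []
    if lf_start < lf_end:
        flank_depths.append(depth_fn(GenomicInterval(region.chrom, lf_start, lf_end)))
    if rf_start < rf_end:
        flank_depths.append(depth_fn(GenomicInterval(region.chrom, rf_start, rf_end)))
    flank_median = float(np.median(np.concatenate(flank_depths))) if flank_depths else 0.0
    window_median = float(np.median(depth_fn(window)))
    if flank_median > 0:
        coverage_ratio = window_median / flank_median
    else:
        # no flank coverage: no evidence of a drop, fail the filter
        coverage_ratio = 1.0

    passed_bilateral = (
        bilateral_possible
        and n_left >= params.min_side_support
        and n_right >= params.min_side_support
    )
    passed_coverage = coverage_ratio <= params.max_coverage_ratio
    status = "confirmed" if (passed_bilateral and passed_coverage) else "rejected"
    return InsertionCall(
        chrom=region.chrom,
        left_pos=window.start,  # 1-based last covered base == 0-based window start
        right_pos=window.end + 1,  # 1-based first covered base after the window
        te_family=locus.te_family,
        n_left_support=n_left,
        n_right_support=n_right,
        coverage_ratio=coverage_ratio,
        passed_bilateral=passed_bilateral,
        passed_coverage=passed_coverage,
        status=status,
    )


# ---------------------------------------------------------------------------
# stage 4: full pipeline
# ---------------------------------------------------------------------------

def _open_alignments(source) -> "pysam.AlignmentFile | Iterable[pysam.AlignedSegment]":
    if isinstance(source, (str, Path)):
        return pysam.AlignmentFile(str(source))
    return source


def call_pipeline(
    case,
    control,
    ctx: GenomeContext,
    params: CallerParams | None = None,
) -> list[InsertionCall]:
    """extract -> build -> subtract -> score, confirmed calls first.

    ``case``/``control`` may be file paths (SAM/BAM) or iterables of
    alignment records.
    """
    params = params or CallerParams()
    case_evidence, case_spans = scan_alignments(_open_alignments(case), ctx, params.min_mapq)
    control_evidence, _ = scan_alignments(_open_alignments(control), ctx, params.min_mapq)

    case_loci = build_candidates(case_evidence, params.candidate_flank, ctx)
    control_loci = build_candidates(control_evidence, params.candidate_flank, ctx)
    novel = subtract_control(case_loci, control_loci)

    depth_fn = depth_source(case_spans)
    calls = [score_insertion(loc, depth_fn, params, ctx) for loc in novel]
    calls.sort(key=lambda c: (c.status != "confirmed", c.chrom, c.left_pos, c.te_family))
    logger.info(
        "called %d loci (%d confirmed) from %d case / %d control candidates",
        len(calls),
        sum(c.status == "confirmed" for c in calls),
        len(case_loci),
        len(control_loci),
    )
    return calls


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "chrom",
    "left_pos",
    "right_pos",
    "te_family",
    "n_left_support",
    "n_right_support",
    "coverage_ratio",
    "passed_bilateral",
    "passed_coverage",
    "status",
]


def write_calls_tsv(calls: Sequence[InsertionCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.left_pos}\t{c.right_pos}\t{c.te_family}\t"
                f"{c.n_left_support}\t{c.n_right_support}\t{c.coverage_ratio:.4f}\t"
                f"{c.passed_bilateral}\t{c.passed_coverage}\t{c.status}\n"
            )


def read_calls_tsv(path: str | Path) -> list[InsertionCall]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != _TSV_COLUMNS:
        raise ValueError(f"{path}: not a tescreen calls TSV")
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        out.append(
            InsertionCall(
                chrom=f[0],
                left_pos=int(f[1]),
                right_pos=int(f[2]),
                te_family=f[3],
                n_left_support=int(f[4]),
                n_right_support=int(f[5]),
                coverage_ratio=float(f[6]),
                passed_bilateral=f[7] == "True",
                passed_coverage=f[8] == "True",
                status=f[9],
            )
        )
    return out


def write_confirmed_bed(calls: Sequence[InsertionCall], path: str | Path) -> None:
    """BED6 of confirmed breakpoint windows; score = total support."""
    with open(path, "w") as fh:
        for c in calls:
            if c.status != "confirmed":
                continue
            w = c.window
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t{c.te_family}\t"
                f"{c.n_left_support + c.n_right_support}\t+\n"
            )
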