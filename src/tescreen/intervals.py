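"""Self-contained genomic interval algebra.

All coordinates are 0-based half-open internally (BED convention).
Conversions from 1-based inclusive coordinates (SAM text, report tables)
happen only at I/O boundaries. The operations mirror the classic bedtools
verbs this package needs: ``slop``, ``merge``, ``intersect`` and
``shuffle -noOverlapping``, plus a per-base depth profile used by the
coverage-drop filter of the insertion caller.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, insort
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger("tescreen")

__all__ = [
    "GenomicInterval",
    "GenomeContext",
    "ContigNotFoundError",
    "InfeasiblePlacementError",
    "FormatError",
    "slop",
    "merge",
    "intersect_any",
    "shuffle_no_overlap",
    "depth_profile",
    "read_bed",
    "write_bed",
]


class ContigNotFoundError(KeyError):
    """An interval refers to a contig absent from the genome context."""


class InfeasiblePlacementError(RuntimeError):
    """Non-overlapping random placement could not be completed.

    Raised when rejection sampling exhausts its attempt budget, which
    signals input intervals too dense for the allowed contig space.
    """


class FormatError(ValueError):
    """A text input (BED, sizes file, TSV) could not be parsed."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open span [start, end) on a named contig.

    ``label`` carries a free-text tag such as a TE family name or a peak
    id; interval algebra preserves it.
    """

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two spans share >= 1 nt (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        tag = f" [{self.label}]" if self.label else ""
        return f"{self.chrom}:{self.start}-{self.end}{tag}"


def _sort_key(iv: GenomicInterval) -> tuple:
    return (iv.chrom, iv.start, iv.end, iv.label or "")


@dataclass(frozen=True)
class GenomeContext:
    """Contig catalogue partitioned into target chromosomes and TE consensi.

    The insertion caller's notion of a discordant pair is a fragment with
    one mate on a ``target_contigs`` member and the other on a
    ``te_contigs`` member, so the two sets must be disjoint.
    """

    contigs: dict[str, int]
    te_contigs: frozenset[str] = frozenset()
    target_contigs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "te_contigs", frozenset(self.te_contigs))
        object.__setattr__(self, "target_contigs", frozenset(self.target_contigs))
        for name, length in self.contigs.items():
            if length <= 0:
                raise ValueError(f"contig {name!r} has non-positive length {length}")
        unknown = (self.te_contigs | self.target_contigs) - set(self.contigs)
        if unknown:
            raise ContigNotFoundError(f"partition names unknown contigs: {sorted(unknown)}")
        if self.te_contigs & self.target_contigs:
            raise ValueError("te_contigs and target_contigs must be disjoint")

    def length_of(self, chrom: str) -> int:
        try:
            return self.contigs[chrom]
        except KeyError:
            raise ContigNotFoundError(f"unknown contig {chrom!r}") from None

    def check(self, iv: GenomicInterval) -> None:
        if iv.end > self.length_of(iv.chrom):
            raise ValueError(f"interval {iv} exceeds contig length {self.contigs[iv.chrom]}")

    @classmethod
    def from_sizes_file(
        cls,
        path: str | Path,
        te_contigs: Iterable[str] = (),
        target_contigs: Iterable[str] = (),
    ) -> "GenomeContext":
        """Build from a two-column ``name<TAB>length`` file (.fai also works)."""
        contigs: dict[str, int] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least two tab-separated columns")
            try:
                contigs[parts[0]] = int(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: length {parts[1]!r} is not an integer") from None
        return cls(contigs, frozenset(te_contigs), frozenset(target_contigs))


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def slop(iv: GenomicInterval, flank: int, ctx: GenomeContext) -> GenomicInterval:
    """Extend an interval by ``flank`` nt on both sides, clamped to the contig."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    contig_len = ctx.length_of(iv.chrom)
    return replace(iv, start=max(0, iv.start - flank), end=min(contig_len, iv.end + flank))


def merge(
    ivs: Sequence[GenomicInterval], merge_distance: int = 0
) -> list[GenomicInterval]:
    """Collapse overlapping (and, at distance 0, book-ended) intervals.

    Returns union spans sorted by (chrom, start); labels of merged members
    are concatenated uniquely, comma-separated, in first-seen order.
    """
    if merge_distance < 0:
        raise ValueError("merge_distance must be >= 0")
    out: list[GenomicInterval] = []
    for iv in sorted(ivs, key=_sort_key):
        if (
            out
            and out[-1].chrom == iv.chrom
            and iv.start <= out[-1].end + merge_distance
        ):
            prev = out[-1]
            labels = [s for s in (prev.label or "").split(",") if s]
            if iv.label and iv.label not in labels:
                labels.append(iv.label)
            out[-1] = replace(
                prev,
                end=max(prev.end, iv.end),
                label=",".join(labels) or None,
            )
        else:
            out.append(iv)
    return out


def intersect_any(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    invert: bool = False,
) -> list[GenomicInterval]:
    """Members of ``a`` overlapping >= 1 nt with any member of ``b``.

    With ``invert=True`` returns the complement (the subtraction variant
    used to drop case loci shared with the control). Order of ``a`` is
    preserved. Runs in O((|a|+|b|) log |b|) via per-contig sorted starts
    with a running max of ends.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for iv in b:
        tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, pairs in tmp.items():
        pairs.sort()
        starts = np.array([p[0] for p in pairs])
        ends = np.maximum.accumulate(np.array([p[1] for p in pairs]))
        by_chrom[chrom] = (starts, ends)

    def hits(iv: GenomicInterval) -> bool:
        entry = by_chrom.get(iv.chrom)
        if entry is None:
            return False
        starts, max_ends = entry
        i = int(np.searchsorted(starts, iv.end, side="left"))  # starts < end
        return i > 0 and max_ends[i - 1] > iv.start

    return [iv for iv in a if hits(iv) != invert]


class _PlacedTracker:
    """Per-contig sorted occupancy used by the no-overlap shuffle."""

    def __init__(self) -> None:
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}

    def collides(self, chrom: str, start: int, end: int) -> bool:
        spans = self._by_chrom.get(chrom)
        if not spans:
            return False
        i = bisect_left(spans, (start, start))
        if i < len(spans) and spans[i][0] < end:
            return True
        return i > 0 and spans[i - 1][1] > start

    def add(self, chrom: str, start: int, end: int) -> None:
        insort(self._by_chrom.setdefault(chrom, []), (start, end))


def shuffle_no_overlap(
    ivs: Sequence[GenomicInterval],
    ctx: GenomeContext,
    allowed_contigs: Iterable[str] | None = None,
    rng_seed: int | np.random.Generator = 0,
    max_attempts: int = 10_000,
) -> list[GenomicInterval]:
    """Place each interval uniformly at random without mutual overlap.

    Lengths and labels are conserved; each interval's start is drawn
    uniformly over every position on ``allowed_contigs`` where it fits,
    and redrawn (rejection sampling) while it collides with an already
    placed interval. Deterministic given ``rng_seed``.

    Raises :class:`InfeasiblePlacementError` after ``max_attempts``
    rejections for a single interval — the practical signal that the
    input is too dense for the allowed space.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    contigs = (
        sorted(allowed_contigs) if allowed_contigs is not None else sorted(ctx.contigs)
    )
    lengths = {c: ctx.length_of(c) for c in contigs}
    placed = _PlacedTracker()
    out: list[GenomicInterval] = []
    for iv in ivs:
        size = iv.length
        # uniform over all valid start positions across allowed contigs
        slots = np.array([max(0, lengths[c] - size + 1) for c in contigs])
        total = int(slots.sum())
        if total == 0:
            raise InfeasiblePlacementError(
                f"no contig can hold an interval of length {size}"
            )
        cum = np.cumsum(slots)
        for _ in range(max_attempts):
            u = int(rng.integers(0, total))
            ci = int(np.searchsorted(cum, u, side="right"))
            start = u - (int(cum[ci - 1]) if ci else 0)
            chrom = contigs[ci]
            if not placed.collides(chrom, start, start + size):
                placed.add(chrom, start, start + size)
                out.append(GenomicInterval(chrom, start, start + size, iv.label))
                break
        else:
            raise InfeasiblePlacementError(
                f"could not place interval of length {size} after "
                f"{max_attempts} attempts (input too dense?)"
            )
    return out


def depth_profile(
    reads: Iterable[tuple[int, int] | GenomicInterval],
    window: GenomicInterval,
) -> np.ndarray:
    """Per-base read depth over ``window`` from aligned spans.

    ``reads`` may be (start, end) pairs or intervals on ``window.chrom``;
    position ``i`` of the result counts spans covering ``window.start + i``.
    """
    n = window.length
    diff = np.zeros(n + 1, dtype=np.int64)
    ws, we = window.start, window.end
    for r in reads:
        if isinstance(r, GenomicInterval):
            if r.chrom != window.chrom:
                continue
            s, e = r.start, r.end
        else:
            s, e = r
        s, e = max(s, ws), min(e, we)
        if s < e:
            diff[s - ws] += 1
            diff[e - ws] -= 1
    return np.cumsum(diff[:-1])


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 (0-based half-open); track/browser/comment lines ignored."""
    out: list[GenomicInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: BED line has fewer than 3 columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
        label = parts[3] if len(parts) >= 4 and parts[3] != "." else None
        try:
            out.append(GenomicInterval(parts[0], start, end, label))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


def write_bed(
    ivs: Sequence[GenomicInterval],
    path: str | Path,
    scores: Sequence[int | float] | None = None,
) -> None:
    """Write BED3, or BED6 when any label or a score vector is present."""
    six = scores is not None or any(iv.label for iv in ivs)
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            if six:
                score = scores[i] if scores is not None else 0
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t{score}\t+\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
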