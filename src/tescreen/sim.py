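"""Synthetic paired-end mutagenesis-screen data.

Generates a toy target chromosome plus TE consensus contigs, plants TE
insertions (optionally biased into peak regions), and emits alignment
records for a mutagenized "case" library and a matched clean "control"
library. The libraries are produced directly as alignments — the goal is
to exercise detection logic, not read mapping — and reproduce the two
evidence classes the caller relies on:

* junction-spanning fragments become discordant pairs (target-side mate
  at its true position, TE-side mate on the family's consensus contig),
  appearing on both sides of the insertion point;
* no surviving read overlaps the short target-site-duplication-scale
  window at the insertion point, so per-base depth drops to zero there
  while flanking depth stays at the library's fold-coverage.

Everything is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import (
    GenomeContext,
    GenomicInterval,
    InfeasiblePlacementError,
    shuffle_no_overlap,
    write_bed,
)

__all__ = [
    "SimulationConfig",
    "PlantedInsertion",
    "TruthSet",
    "simulate_genome",
    "simulate_reads",
    "make_header",
    "write_alignments",
    "write_fasta",
    "write_sizes",
    "write_truth_json",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated screen sample.

    Defaults emulate a 50 bp paired-end whole-genome library at 30x
    fold-coverage with ~300 nt fragments, against a 2 Mb target
    chromosome and two TE consensus contigs: a 7 kb LTR-retrovirus-like
    element ("mdg4") and a 4.5 kb LINE-like element ("Doc"). ``bias`` is
    the probability that a planted insertion falls inside a peak; 0 is
    the null (insertions independent of peaks).
    """

    target_len: int = 2_000_000
    target_name: str = "chrX"
    te_library: dict[str, int] = field(
        default_factory=lambda: {"mdg4": 7_000, "Doc": 4_500}
    )
    n_insertions: int = 5
    tsd_len: int = 4
    read_len: int = 50
    fragment_mean: float = 300.0
    fragment_sd: float = 30.0
    depth: float = 30.0
    peak_count: int = 20
    peak_len: int = 1_000
    motif_per_peak: int = 1
    motif_len: int = 8
    bias: float = 0.0
    min_insertion_gap: int = 10_000
    noise_discordant_rate: float = 0.0
    emit_sequences: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "target_len",
            "tsd_len",
            "read_len",
            "peak_len",
            "motif_len",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.bias <= 1.0:
            raise ValueError("bias must be in [0, 1]")
        if self.tsd_len >= self.read_len:
            raise ValueError("tsd_len must be smaller than read_len")
        if any(l <= 0 for l in self.te_library.values()):
            raise ValueError("TE lengths must be positive")
        if self.fragment_mean < 2 * self.read_len:
            raise ValueError("fragment_mean must fit two reads")

    def context(self) -> GenomeContext:
        contigs = {self.target_name: self.target_len, **self.te_library}
        return GenomeContext(
            contigs,
            te_contigs=frozenset(self.te_library),
            target_contigs=frozenset({self.target_name}),
        )


@dataclass(frozen=True)
class PlantedInsertion:
    """Ground truth for one planted TE insertion.

    ``position`` is the 0-based left junction; the duplicated target
    window (and the depth hole the library shows) is
    ``[position, position + tsd length)``.
    """

    position: int
    te_family: str
    tsd: GenomicInterval


@dataclass(frozen=True)
class TruthSet:
    insertions: tuple[PlantedInsertion, ...]
    peaks: tuple[GenomicInterval, ...]
    motifs: tuple[GenomicInterval, ...]

    def insertion_windows(self) -> list[GenomicInterval]:
        return [p.tsd for p in self.insertions]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def simulate_genome(
    cfg: SimulationConfig,
) -> tuple[dict[str, str], GenomeContext, TruthSet]:
    """Reference sequences, contig partition, and planted ground truth.

    Peaks are placed without overlap on the target chromosome; each peak
    carries ``motif_per_peak`` short motifs at uniform positions inside
    it. Insertion positions are drawn uniformly over the target (at
    least a read length from either end), except that with probability
    ``bias`` a position is drawn inside a uniformly chosen peak. A
    minimum spacing between insertions keeps candidate loci resolvable.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    ctx = cfg.context()

    sequences: dict[str, str] = {}
    if cfg.emit_sequences:
        sequences[cfg.target_name] = _random_sequence(rng, cfg.target_len)
        for name, length in cfg.te_library.items():
            sequences[name] = _random_sequence(rng, length)

    peaks = shuffle_no_overlap(
        [
            GenomicInterval(cfg.target_name, 0, cfg.peak_len, f"peak{i}")
            for i in range(cfg.peak_count)
        ],
        ctx,
        allowed_contigs={cfg.target_name},
        rng_seed=rng,
    )
    peaks.sort(key=lambda p: p.start)

    motifs: list[GenomicInterval] = []
    for peak in peaks:
        hi = peak.end - cfg.motif_len
        for _ in range(cfg.motif_per_peak):
            s = int(rng.integers(peak.start, max(peak.start + 1, hi + 1)))
            motifs.append(
                GenomicInterval(cfg.target_name, s, s + cfg.motif_len, "motif")
            )
    motifs.sort(key=lambda m: m.start)

    lo = cfg.read_len
    hi = cfg.target_len - cfg.read_len - cfg.tsd_len
    if hi <= lo:
        raise InfeasiblePlacementError("target too short for insertions")
    positions: list[int] = []
    families = sorted(cfg.te_library)
    planted: list[PlantedInsertion] = []
    for _ in range(cfg.n_insertions):
        for _attempt in range(10_000):
            if cfg.bias > 0 and rng.random() < cfg.bias:
                peak = peaks[int(rng.integers(0, len(peaks)))]
                p_lo = max(lo, peak.start)
                p_hi = min(hi, peak.end - cfg.tsd_len)
                if p_hi <= p_lo:  # peak clipped against a contig end
                    p = int(rng.integers(lo, hi))
                else:
                    p = int(rng.integers(p_lo, p_hi))
            else:
                p = int(rng.integers(lo, hi))
            if all(abs(p - q) >= cfg.min_insertion_gap for q in positions):
                break
        else:
            raise InfeasiblePlacementError(
                "could not place insertions with the requested spacing"
            )
        positions.append(p)
        family = families[int(rng.integers(0, len(families)))]
        planted.append(
            PlantedInsertion(
                position=p,
                te_family=family,
                tsd=GenomicInterval(cfg.target_name, p, p + cfg.tsd_len, family),
            )
        )
    planted.sort(key=lambda ins: ins.position)
    return sequences, ctx, TruthSet(tuple(planted), tuple(peaks), tuple(motifs))


# ---------------------------------------------------------------------------
# read-pair emission
# ---------------------------------------------------------------------------

def make_header(ctx: GenomeContext) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": length} for name, length in ctx.contigs.items()],
        }
    )


def _pair(
    header: pysam.AlignmentHeader,
    name: str,
    a_tid: int,
    a_pos: int,
    b_tid: int,
    b_pos: int,
    read_len: int,
    proper: bool,
    tlen: int,
) -> tuple[pysam.AlignedSegment, pysam.AlignedSegment]:
    """One FR read pair; the first mate is forward, the second reverse."""
    base = 0x1 | (0x2 if proper else 0)
    r1 = pysam.AlignedSegment(header)
    r1.query_name = name
    r1.flag = base | 0x20 | 0x40  # mate reverse, first in pair
    r1.reference_id, r1.reference_start = a_tid, a_pos
    r1.mapping_quality = 60
    r1.cigartuples = [(0, read_len)]
    r1.next_reference_id, r1.next_reference_start = b_tid, b_pos
    r1.template_length = tlen
    r2 = pysam.AlignedSegment(header)
    r2.query_name = name
    r2.flag = base | 0x10 | 0x80  # reverse, second in pair
    r2.reference_id, r2.reference_start = b_tid, b_pos
    r2.mapping_quality = 60
    r2.cigartuples = [(0, read_len)]
    r2.next_reference_id, r2.next_reference_start = a_tid, a_pos
    r2.template_length = -tlen
    return r1, r2


def _library(
    cfg: SimulationConfig,
    ctx: GenomeContext,
    insertions: Sequence[PlantedInsertion],
    rng: np.random.Generator,
) -> list[pysam.AlignedSegment]:
    header = make_header(ctx)
    tids = {name: i for i, name in enumerate(ctx.contigs)}
    target_tid = tids[cfg.target_name]
    rl = cfg.read_len
    L = cfg.target_len

    n_frags = int(round(cfg.depth * L / (2 * rl)))
    if n_frags == 0:
        return []
    frag_lens = np.clip(
        np.rint(rng.normal(cfg.fragment_mean, cfg.fragment_sd, n_frags)),
        2 * rl,
        None,
    ).astype(np.int64)
    frag_lens = np.minimum(frag_lens, L)
    starts = rng.integers(0, L - frag_lens + 1)

    ins_pos = np.array([ins.position for ins in insertions], dtype=np.int64)
    order = np.argsort(ins_pos)
    ins_pos = ins_pos[order]
    ins_sorted = [insertions[i] for i in order]
    tsd = cfg.tsd_len

    records: list[pysam.AlignedSegment] = []
    families = sorted(cfg.te_library)
    for i in range(n_frags):
        s = int(starts[i])
        fl = int(frag_lens[i])
        name = f"frag{i}"
        r1 = (s, s + rl)
        r2 = (s + fl - rl, s + fl)

        hit: PlantedInsertion | None = None
        if len(ins_pos):
            j = int(np.searchsorted(ins_pos, s + fl))
            for k in (j - 1, j):
                if 0 <= k < len(ins_pos):
                    p = int(ins_pos[k])
                    if s < p + tsd and s + fl > p:  # fragment touches the hole
                        hit = ins_sorted[k]
                        break

        noisy = cfg.noise_discordant_rate > 0 and rng.random() < cfg.noise_discordant_rate
        if hit is None and not noisy:
            records.extend(
                _pair(header, name, target_tid, r1[0], target_tid, r2[0], rl, True, fl)
            )
            continue
        if hit is None and noisy:
            # multimapping-like artifact: mate spuriously assigned to a TE
            family = families[int(rng.integers(0, len(families)))]
            te_tid = tids[family]
            te_pos = int(rng.integers(0, cfg.te_library[family] - rl + 1))
            records.extend(
                _pair(header, name, target_tid, r1[0], te_tid, te_pos, rl, False, 0)
            )
            continue

        assert hit is not None
        p = hit.position

        def side(span: tuple[int, int]) -> str:
            if span[1] <= p:
                return "L"
            if span[0] >= p + tsd:
                return "R"
            return "X"

        s1, s2 = side(r1), side(r2)
        if s1 == "X" and s2 == "X":
            continue  # both reads straddle the junction: unmappable, dropped
        te_tid = tids[hit.te_family]
        te_pos = int(rng.integers(0, cfg.te_library[hit.te_family] - rl + 1))
        if s1 == "X" or s2 == "X":
            keep = r2 if s1 == "X" else r1
        else:  # L/R: the inner fragment gap holds the junction; TE is larger
            keep = r1 if rng.random() < 0.5 else r2
        records.extend(
            _pair(header, name, target_tid, keep[0], te_tid, te_pos, rl, False, 0)
        )

    records.sort(key=lambda r: (r.reference_id, r.reference_start))
    return records


def simulate_reads(
    cfg: SimulationConfig,
    truth: TruthSet,
    control_insertions: Sequence[PlantedInsertion] = (),
) -> tuple[list[pysam.AlignedSegment], list[pysam.AlignedSegment]]:
    """Case and control libraries as coordinate-sorted alignment records.

    The case library carries every planted insertion in ``truth``; the
    control library is clean unless ``control_insertions`` is given
    (used to emulate TE locations shared by both genotypes, which the
    caller must subtract).
    """
    ctx = cfg.context()
    case_rng = np.random.default_rng([cfg.rng_seed, 1])
    control_rng = np.random.default_rng([cfg.rng_seed, 2])
    case = _library(cfg, ctx, truth.insertions, case_rng)
    control = _library(cfg, ctx, control_insertions, control_rng)
    return case, control


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_alignments(
    records: Sequence[pysam.AlignedSegment],
    ctx: GenomeContext,
    path: str | Path,
) -> None:
    """Write SAM or BAM (by extension), coordinate-sorted header."""
    mode = "wb" if str(path).endswith(".bam") else "w"
    with pysam.AlignmentFile(str(path), mode, header=make_header(ctx)) as fh:
        for rec in records:
            fh.write(rec)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()),
        str(path),
        "fasta",
    )


def write_sizes(ctx: GenomeContext, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in ctx.contigs.items():
            fh.write(f"{name}\t{length}\n")


def write_truth_json(truth: TruthSet, path: str | Path) -> None:
    payload = {
        "insertions": [
            {
                "position": ins.position,
                "te_family": ins.te_family,
                "tsd": [ins.tsd.chrom, ins.tsd.start, ins.tsd.end],
            }
            for ins in truth.insertions
        ],
        "peaks": [[p.chrom, p.start, p.end] for p in truth.peaks],
        "motifs": [[m.chrom, m.start, m.end] for m in truth.motifs],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_truth_beds(truth: TruthSet, outdir: str | Path) -> None:
    outdir = Path(outdir)
    write_bed(list(truth.peaks), outdir / "peaks.bed")
    write_bed(list(truth.motifs), outdir / "motifs.bed")
    write_bed(truth.insertion_windows(), outdir / "truth_insertions.bed")
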