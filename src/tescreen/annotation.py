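"""Genic context, peak flags, and motif distances for insertion calls.

Reproduces the derived columns of a screen report table: which
transcript feature an insertion interrupts (5'UTR > 3'UTR > CDS >
intron > intergenic precedence across all overlapping transcripts),
whether its breakpoint window overlaps each named peak set (ChIP/ATAC),
and the distance to the nearest transcription-factor motif
(midpoint-to-midpoint, nt).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import gffutils

from .caller import InsertionCall
from .intervals import GenomicInterval

__all__ = [
    "GeneModel",
    "AnnotatedInsertion",
    "load_gene_models",
    "classify_feature",
    "flag_peaks",
    "motif_distance",
    "annotate_calls",
    "write_annotations_tsv",
    "FEATURE_PRECEDENCE",
]

FEATURE_PRECEDENCE = ("5'UTR", "3'UTR", "CDS", "Intron", "Intergenic")


@dataclass(frozen=True)
class GeneModel:
    """One transcript with derived UTR/intron structure (0-based half-open)."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...]
    utr5: tuple[GenomicInterval, ...]
    utr3: tuple[GenomicInterval, ...]
    introns: tuple[GenomicInterval, ...]
    tss: int

    def features(self) -> dict[str, tuple[GenomicInterval, ...]]:
        return {
            "5'UTR": self.utr5,
            "3'UTR": self.utr3,
            "CDS": self.cds,
            "Intron": self.introns,
        }


def _derive(
    gene_id: str,
    transcript_id: str,
    chrom: str,
    strand: str,
    exons: list[tuple[int, int]],
    cds: list[tuple[int, int]],
) -> GeneModel:
    exons = sorted(exons)
    cds = sorted(cds)
    mk = lambda pairs: tuple(GenomicInterval(chrom, s, e) for s, e in pairs if s < e)
    introns = [(a[1], b[0]) for a, b in zip(exons, exons[1:]) if a[1] < b[0]]
    utr5: list[tuple[int, int]] = []
    utr3: list[tuple[int, int]] = []
    if cds:
        cds_lo, cds_hi = cds[0][0], cds[-1][1]
        for s, e in exons:
            before = (s, min(e, cds_lo))
            after = (max(s, cds_hi), e)
            if before[0] < before[1]:
                (utr5 if strand != "-" else utr3).append(before)
            if after[0] < after[1]:
                (utr3 if strand != "-" else utr5).append(after)
    span = GenomicInterval(chrom, exons[0][0], exons[-1][1], gene_id)
    tss = exons[0][0] if strand != "-" else exons[-1][1] - 1
    return GeneModel(
        gene_id=gene_id,
        transcript_id=transcript_id,
        chrom=chrom,
        strand=strand,
        span=span,
        exons=mk(exons),
        cds=mk(cds),
        utr5=mk(sorted(utr5)),
        utr3=mk(sorted(utr3)),
        introns=mk(introns),
        tss=tss,
    )


def load_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Parse GFF3 gene models (gene/mRNA/exon/CDS); UTRs and introns derived.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention on load.
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for ftype in ("mRNA", "transcript"):
        for tr in db.features_of_type(ftype):
            parents = list(db.parents(tr, featuretype="gene"))
            gene_id = parents[0].id if parents else tr.id
            exons = [
                (f.start - 1, f.end) for f in db.children(tr, featuretype="exon")
            ]
            cds = [(f.start - 1, f.end) for f in db.children(tr, featuretype="CDS")]
            if not exons:
                exons = [(tr.start - 1, tr.end)]
            models.append(
                _derive(gene_id, tr.id, tr.seqid, tr.strand or "+", exons, cds)
            )
    models.sort(key=lambda m: (m.chrom, m.span.start, m.transcript_id))
    return models


def classify_feature(
    window: GenomicInterval | InsertionCall,
    genes: Sequence[GeneModel],
) -> tuple[str, str | None, str | None]:
    """(feature_class, nearest_gene, driving_transcript) for one insertion.

    An insertion overlapping several transcripts takes the
    highest-precedence class among all overlapped features; the
    transcript that drove that class is recorded. With no transcript
    overlap the class is Intergenic and the nearest gene is the one
    with minimal edge distance (``None`` with an empty gene set).
    """
    if isinstance(window, InsertionCall):
        window = window.window
    best_rank = len(FEATURE_PRECEDENCE) - 1  # Intergenic
    best_gene: str | None = None
    best_tr: str | None = None
    overlapping = [g for g in genes if g.span.overlaps(window)]
    for g in overlapping:
        for cls, ivs in g.features().items():
            if any(iv.overlaps(window) for iv in ivs):
                rank = FEATURE_PRECEDENCE.index(cls)
                if rank < best_rank:
                    best_rank, best_gene, best_tr = rank, g.gene_id, g.transcript_id
    if overlapping and best_gene is None:
        # inside a transcript span but in none of its parts (e.g. exon
        # edge conventions): treat as intronic of the first such gene
        g = overlapping[0]
        best_rank, best_gene, best_tr = FEATURE_PRECEDENCE.index("Intron"), g.gene_id, g.transcript_id
    if best_gene is not None:
        return FEATURE_PRECEDENCE[best_rank], best_gene, best_tr
    # intergenic: nearest gene by edge distance
    nearest: str | None = None
    nearest_d: int | None = None
    for g in genes:
        if g.chrom != window.chrom:
            continue
        d = max(g.span.start - window.end, window.start - g.span.end, 0)
        if nearest_d is None or d < nearest_d:
            nearest, nearest_d = g.gene_id, d
    return "Intergenic", nearest, None


def flag_peaks(
    window: GenomicInterval | InsertionCall,
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
) -> dict[str, bool]:
    """Per peak set: does the breakpoint window overlap >= 1 nt of it?"""
    if isinstance(window, InsertionCall):
        window = window.window
    return {
        name: any(window.overlaps(p) for p in peaks)
        for name, peaks in peak_sets.items()
    }


def motif_distance(
    window: GenomicInterval | InsertionCall,
    motifs: Sequence[GenomicInterval],
) -> float | None:
    """Midpoint-to-midpoint nt distance to the nearest motif.

    Returns ``None`` (undefined) for an empty motif set; 0 when the
    nearest motif midpoint coincides with the window midpoint.
    """
    if isinstance(window, InsertionCall):
        window = window.window
    mids = [abs(m.midpoint - window.midpoint) for m in motifs if m.chrom == window.chrom]
    if not mids:
        return None
    return float(min(mids))


@dataclass(frozen=True)
class AnnotatedInsertion:
    call: InsertionCall
    feature_class: str
    nearest_gene: str | None
    transcript_id: str | None
    peak_flags: dict[str, bool]
    motif_distance_nt: float | None


def annotate_calls(
    calls: Sequence[InsertionCall],
    genes: Sequence[GeneModel],
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
    motifs: Sequence[GenomicInterval],
) -> list[AnnotatedInsertion]:
    out = []
    for call in calls:
        cls, gene, tr = classify_feature(call, genes)
        out.append(
            AnnotatedInsertion(
                call=call,
                feature_class=cls,
                nearest_gene=gene,
                transcript_id=tr,
                peak_flags=flag_peaks(call, peak_sets),
                motif_distance_nt=motif_distance(call, motifs),
            )
        )
    return out


def write_annotations_tsv(
    annotations: Sequence[AnnotatedInsertion], path: str | Path
) -> None:
    peak_names = sorted({n for a in annotations for n in a.peak_flags})
    header = (
        ["chrom", "left_pos", "right_pos", "te_family", "status", "insertion_location",
         "nearest_gene", "transcript"]
        + [f"{n}_peak" for n in peak_names]
        + ["motif_distance_nt"]
    )
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for a in annotations:
            c = a.call
            dist = "NA" if a.motif_distance_nt is None else f"{a.motif_distance_nt:g}"
            row = [
                c.chrom, str(c.left_pos), str(c.right_pos), c.te_family, c.status,
                a.feature_class, a.nearest_gene or "NA", a.transcript_id or "NA",
            ] + ["Yes" if a.peak_flags[n] else "No" for n in peak_names] + [dist]
            fh.write("\t".join(row) + "\n")
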