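"""Shuffle-based permutation test for insertion/peak overlap enrichment.

The observed statistic is the number of insertion sites falling inside
at least one peak. The null distribution is built by re-placing the
*peaks* uniformly at random (length-preserving, mutually non-overlapping,
restricted to the target chromosome) and recomputing the statistic; the
empirical p-value is the fraction of shuffles whose statistic reaches
the observed one. With zero exceedances the p-value is reported as the
resolution bound 1/n_shuffles (``p_is_bound=True``), never as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomeContext, GenomicInterval, intersect_any, shuffle_no_overlap

__all__ = ["EnrichmentResult", "overlap_count", "permutation_test"]


@dataclass(frozen=True)
class EnrichmentResult:
    observed: int
    null_counts: tuple[int, ...]
    n_shuffles: int
    p_value: float
    p_is_bound: bool

    def __post_init__(self) -> None:
        if len(self.null_counts) != self.n_shuffles:
            raise ValueError("null_counts length must equal n_shuffles")

    @property
    def p_text(self) -> str:
        """Report string: '< 0.001'-style bound when no null draw reached it."""
        return f"< {self.p_value:g}" if self.p_is_bound else f"{self.p_value:g}"

    def to_json(self, path: str | Path) -> None:
        hist_vals, hist_counts = np.unique(np.array(self.null_counts), return_counts=True)
        Path(path).write_text(
            json.dumps(
                {
                    "observed": self.observed,
                    "n_shuffles": self.n_shuffles,
                    "p_value": self.p_value,
                    "p_is_bound": self.p_is_bound,
                    "p_text": self.p_text,
                    "null_histogram": {
                        int(v): int(c) for v, c in zip(hist_vals, hist_counts)
                    },
                },
                indent=2,
            )
            + "\n"
        )


def overlap_count(
    insertions: Sequence[GenomicInterval], peaks: Sequence[GenomicInterval]
) -> int:
    """Number of insertions overlapping >= 1 nt with any peak (each once)."""
    return len(intersect_any(insertions, peaks))


def permutation_test(
    insertions: Sequence[GenomicInterval],
    peaks: Sequence[GenomicInterval],
    ctx: GenomeContext,
    n_shuffles: int = 1000,
    rng_seed: int = 0,
    allowed_contigs: Iterable[str] | None = None,
) -> EnrichmentResult:
    """Empirical enrichment p-value from ``n_shuffles`` peak shuffles.

    Shuffle ``i`` uses seed ``rng_seed + i``, so runs are reproducible
    and trivially parallelizable. ``allowed_contigs`` defaults to the
    context's target chromosomes (the insertions' own chromosome space).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    allowed = (
        frozenset(allowed_contigs)
        if allowed_contigs is not None
        else (ctx.target_contigs or frozenset(ctx.contigs))
    )
    observed = overlap_count(insertions, peaks)
    null_counts = []
    for i in range(n_shuffles):
        shuffled = shuffle_no_overlap(peaks, ctx, allowed, rng_seed=rng_seed + i)
        null_counts.append(overlap_count(insertions, shuffled))
    exceed = sum(1 for c in null_counts if c >= observed)
    if exceed == 0:
        p_value, bound = 1.0 / n_shuffles, True
    else:
        p_value, bound = exceed / n_shuffles, False
    return EnrichmentResult(
        observed=observed,
        null_counts=tuple(null_counts),
        n_shuffles=n_shuffles,
        p_value=p_value,
        p_is_bound=bound,
    )
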