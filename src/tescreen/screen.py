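"""Screen-level statistics: complementation groups, recovery rate, and
summary fractions over the packaged screen-report table.

The packaged fixture (``data/table1.tsv``) transcribes the 13 reported
novel mdg4 insertions of the female-sterile screen: allele, mapped
sterility interval, affected gene, three peak-overlap flags (OVO ChIP,
germline-stem-cell ATAC, stage-5 nurse-cell ATAC), the interrupted
feature class, the distance to the nearest OVO DNA-binding motif, and
the 1-based left/right breakpoint positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "ComplementationMatrix",
    "ScreenTally",
    "FixtureValidationError",
    "complementation_groups",
    "non_clique_groups",
    "groups_with_insertion",
    "recovery_rate",
    "load_table1",
    "table1_summaries",
    "TABLE1_COLUMNS",
]

TABLE1_COLUMNS = [
    "allele",
    "sterility_interval",
    "gene",
    "ovo_chip_peak",
    "gsc_atac_peak",
    "st5_nc_atac_peak",
    "insertion_location",
    "motif_distance_nt",
    "left_position",
    "right_position",
]


class FixtureValidationError(ValueError):
    """The screen-report fixture violates its row invariants."""


@dataclass(frozen=True)
class ComplementationMatrix:
    """Alleles plus the unordered pairs that failed to complement."""

    alleles: tuple[str, ...]
    fails: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(self.alleles))
        object.__setattr__(
            self, "fails", frozenset(frozenset(p) for p in self.fails)
        )
        known = set(self.alleles)
        for pair in self.fails:
            if len(pair) != 2:
                raise ValueError(f"failure pair must have two distinct alleles: {set(pair)}")
            if not pair <= known:
                raise ValueError(f"failure pair names unknown alleles: {set(pair) - known}")


def _graph(m: ComplementationMatrix) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(m.alleles)
    g.add_edges_from(tuple(p) for p in m.fails)
    return g


def complementation_groups(m: ComplementationMatrix) -> list[set[str]]:
    """Connected components of the failure-to-complement graph.

    Alleles with no failures form singleton groups. Complementation is
    treated as transitive; genuinely intransitive structures (a
    connected component that is not a clique) are still grouped as one
    component — use :func:`non_clique_groups` to surface them.
    Output ordered by each group's lexicographically smallest member.
    """
    comps = [set(c) for c in nx.connected_components(_graph(m))]
    comps.sort(key=min)
    return comps


def non_clique_groups(m: ComplementationMatrix) -> list[set[str]]:
    """Groups whose members do not all fail to complement pairwise.

    These indicate intransitive complementation (e.g. allele pairs that
    complement despite sharing a group) and deserve manual review.
    """
    out = []
    for group in complementation_groups(m):
        n = len(group)
        if n < 3:
            continue
        edges = sum(1 for p in m.fails if p <= group)
        if edges < n * (n - 1) // 2:
            out.append(group)
    return out


def groups_with_insertion(
    groups: Sequence[set[str]], alleles_with_insertion: Iterable[str]
) -> int:
    """How many groups contain >= 1 allele carrying a detected insertion."""
    hits = set(alleles_with_insertion)
    return sum(1 for g in groups if g & hits)


@dataclass(frozen=True)
class ScreenTally:
    chromosomes_screened: int
    sterile_alleles: int
    lethal_alleles: int

    def __post_init__(self) -> None:
        if self.chromosomes_screened <= 0:
            raise ValueError("chromosomes_screened must be > 0")
        if min(self.sterile_alleles, self.lethal_alleles) < 0:
            raise ValueError("allele counts must be >= 0")


def recovery_rate(t: ScreenTally) -> float:
    """Recovered alleles (sterile + lethal) per screened chromosome, in %.

    Reported to two decimals.
    """
    return round(
        100.0 * (t.sterile_alleles + t.lethal_alleles) / t.chromosomes_screened, 2
    )


def _packaged_table1() -> Path:
    return Path(str(resources.files("tescreen").joinpath("data/table1.tsv")))


def load_table1(
    path: str | Path | None = None, expect_rows: int | None = 13
) -> pd.DataFrame:
    """Load and validate the screen-report table (TSV, 1-based positions).

    Defaults to the packaged 13-row fixture. Validation raises
    :class:`FixtureValidationError` listing every offending row.
    """
    df = pd.read_csv(path if path is not None else _packaged_table1(), sep="\t")
    missing = [c for c in TABLE1_COLUMNS if c not in df.columns]
    if missing:
        raise FixtureValidationError(f"missing columns: {missing}")
    problems = []
    for i, row in df.iterrows():
        if not (
            isinstance(row["motif_distance_nt"], (int, float))
            and float(row["motif_distance_nt"]).is_integer()
            and row["motif_distance_nt"] > 0
        ):
            problems.append(f"row {i}: motif distance {row['motif_distance_nt']!r} not a positive integer")
        if row["left_position"] > row["right_position"]:
            problems.append(f"row {i}: left_position > right_position")
        for col in ("ovo_chip_peak", "gsc_atac_peak", "st5_nc_atac_peak"):
            if row[col] not in ("Yes", "No"):
                problems.append(f"row {i}: {col} must be Yes/No, got {row[col]!r}")
    if expect_rows is not None and len(df) != expect_rows:
        problems.append(f"expected {expect_rows} rows, found {len(df)}")
    if problems:
        raise FixtureValidationError("; ".join(problems))
    return df


def table1_summaries(fixture: pd.DataFrame, distance_cutoff: int = 200) -> dict[str, int]:
    """Summary counts over the screen-report table.

    Returns ``n_insertions`` (rows), ``n_in_chip_peak`` (ChIP-peak
    overlaps), and the split of insertions within/beyond
    ``distance_cutoff`` nt of the nearest motif (inclusive cutoff).
    """
    n = len(fixture)
    within = int((fixture["motif_distance_nt"] <= distance_cutoff).sum())
    return {
        "n_insertions": n,
        "n_in_chip_peak": int((fixture["ovo_chip_peak"] == "Yes").sum()),
        "n_within_cutoff": within,
        "n_beyond_cutoff": n - within,
    }
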