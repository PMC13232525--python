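"""Interval algebra: examples, brute-force oracles, and bedtools cross-checks."""

import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tescreen import (
    ContigNotFoundError,
    GenomeContext,
    GenomicInterval,
    InfeasiblePlacementError,
    depth_profile,
    intersect_any,
    merge,
    read_bed,
    shuffle_no_overlap,
    slop,
    write_bed,
)

GI = GenomicInterval


# ---------------------------------------------------------------- oracles

def merge_oracle(ivs):
    """Union-find closure over pairwise overlap-or-abutment."""
    items = [[iv.chrom, iv.start, iv.end, [iv.label] if iv.label else []] for iv in ivs]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[0] == b[0] and a[1] <= b[2] and b[1] <= a[2]:
                    a[1], a[2] = min(a[1], b[1]), max(a[2], b[2])
                    for lab in b[3]:
                        if lab not in a[3]:
                            a[3].append(lab)
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return sorted((c, s, e) for c, s, e, _ in items)


def intersect_oracle(a, b):
    return [
        iv
        for iv in a
        if any(iv.chrom == o.chrom and iv.start < o.end and o.start < iv.end for o in b)
    ]


def random_intervals(rng, n, chroms=("chrX", "chr2"), span=10_000, max_len=300):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span - max_len))
        out.append(
            GI(
                str(rng.choice(chroms)),
                start,
                start + int(rng.integers(1, max_len)),
                f"l{int(rng.integers(0, 5))}",
            )
        )
    return out


# ------------------------------------------------------------------ slop

@pytest.mark.parametrize(
    "iv, flank, expected",
    [
        (GI("chrX", 5000, 5050), 500, (4500, 5550)),
        (GI("chrX", 100, 150), 500, (0, 650)),
        (GI("chrX", 999_900, 999_950), 500, (999_400, 1_000_000)),
    ],
)
def test_slop_extends_and_clamps(ctx, iv, flank, expected):
    got = slop(iv, flank, ctx)
    assert (got.start, got.end) == expected
    assert got.chrom == iv.chrom and got.label == iv.label


def test_slop_zero_is_identity(ctx):
    iv = GI("chrX", 10, 20, "te")
    assert slop(iv, 0, ctx) == iv


def test_slop_unknown_contig_raises(ctx):
    with pytest.raises(ContigNotFoundError):
        slop(GI("chrNope", 0, 10), 5, ctx)


def test_interval_invariants_enforced():
    with pytest.raises(ValueError):
        GI("chrX", 10, 10)
    with pytest.raises(ValueError):
        GI("chrX", -1, 5)


# ----------------------------------------------------------------- merge

def test_merge_overlapping_and_bookended():
    assert merge([GI("chrX", 10, 20), GI("chrX", 15, 30)]) == [GI("chrX", 10, 30)]
    got = merge([GI("chrX", 10, 20), GI("chrX", 20, 30), GI("chrX", 40, 50)])
    assert [(g.start, g.end) for g in got] == [(10, 30), (40, 50)]


def test_merge_concatenates_labels_uniquely():
    got = merge([GI("chrX", 0, 10, "mdg4"), GI("chrX", 5, 15, "Doc"), GI("chrX", 8, 20, "mdg4")])
    assert len(got) == 1 and got[0].label == "mdg4,Doc"


def test_merge_matches_brute_force_oracle(rng):
    ivs = random_intervals(rng, 200)
    got = merge(ivs)
    assert [(g.chrom, g.start, g.end) for g in got] == merge_oracle(ivs)
    # no two outputs on one contig overlap or abut
    for a, b in zip(got, got[1:]):
        assert a.chrom != b.chrom or a.end < b.start


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 60)).map(
            lambda t: GI("chrX", t[0], t[0] + t[1])
        ),
        max_size=30,
    )
)
def test_merge_idempotent(ivs):
    once = merge(ivs)
    assert merge(once) == once


# ------------------------------------------------------------- intersect

def test_intersect_half_open_semantics():
    assert intersect_any([GI("chrX", 10, 20)], [GI("chrX", 19, 25)]) == [GI("chrX", 10, 20)]
    assert intersect_any([GI("chrX", 10, 20)], [GI("chrX", 20, 25)]) == []


def test_intersect_self_and_empty(rng):
    a = random_intervals(rng, 50)
    assert intersect_any(a, a) == a
    assert intersect_any(a, []) == []
    assert intersect_any(a, [], invert=True) == a


def test_intersect_matches_quadratic_oracle(rng):
    a = random_intervals(rng, 100)
    b = random_intervals(rng, 100)
    expected = intersect_oracle(a, b)
    assert intersect_any(a, b) == expected
    inv = intersect_any(a, b, invert=True)
    assert inv == [iv for iv in a if iv not in expected]
    assert len(inv) + len(expected) == len(a)


# --------------------------------------------------------------- shuffle

def test_shuffle_conserves_lengths_labels_and_is_deterministic(ctx, rng):
    ivs = random_intervals(rng, 40, chroms=("chrX",))
    out1 = shuffle_no_overlap(ivs, ctx, {"chrX"}, rng_seed=7)
    out2 = shuffle_no_overlap(ivs, ctx, {"chrX"}, rng_seed=7)
    assert out1 == out2
    assert sorted((iv.length, iv.label) for iv in out1) == sorted(
        (iv.length, iv.label) for iv in ivs
    )
    placed = sorted((iv.start, iv.end) for iv in out1)
    for a, b in zip(placed, placed[1:]):
        assert a[1] <= b[0]  # pairwise disjoint


def test_shuffle_empty_and_infeasible():
    ctx = GenomeContext({"c": 100})
    assert shuffle_no_overlap([], ctx, {"c"}, rng_seed=1) == []
    two_big = [GI("c", 0, 51), GI("c", 0, 51)]
    with pytest.raises(InfeasiblePlacementError):
        shuffle_no_overlap(two_big, ctx, {"c"}, rng_seed=1, max_attempts=200)


def test_shuffle_single_interval_start_is_uniform():
    """Start of a lone shuffled interval ~ U{0, G-L}: chi-square, 10 bins."""
    G, L = 10_000, 100
    ctx = GenomeContext({"c": G})
    iv = [GI("c", 0, L)]
    starts = np.array(
        [shuffle_no_overlap(iv, ctx, {"c"}, rng_seed=s)[0].start for s in range(5000)]
    )
    counts, _ = np.histogram(starts, bins=10, range=(0, G - L + 1))
    assert stats.chisquare(counts).pvalue > 0.01


# ----------------------------------------------------------------- depth

def test_depth_profile_single_read_and_empty():
    win = GI("chrX", 0, 100)
    d = depth_profile([(10, 60)], win)
    assert d.shape == (100,)
    assert d[10:60].min() == d[10:60].max() == 1
    assert d[:10].sum() == 0 and d[60:].sum() == 0
    assert depth_profile([], win).sum() == 0


def test_depth_profile_matches_naive_counting(rng):
    win = GI("chrX", 100, 400)
    reads = [
        (int(s), int(s) + int(rng.integers(10, 80)))
        for s in rng.integers(0, 500, size=50)
    ]
    got = depth_profile(reads, win)
    naive = np.array(
        [sum(1 for s, e in reads if s <= pos < e) for pos in range(100, 400)]
    )
    np.testing.assert_array_equal(got, naive)


# ------------------------------------------------------------------- I/O

def test_bed_round_trip(tmp_path, rng):
    ivs = random_intervals(rng, 20)
    path = tmp_path / "x.bed"
    write_bed(ivs, path)
    assert read_bed(path) == ivs
    # track/comment lines ignored
    path2 = tmp_path / "y.bed"
    path2.write_text("track name=t\n# c\nchrX\t5\t9\n")
    assert read_bed(path2) == [GI("chrX", 5, 9)]


def test_genome_context_partition_rules():
    with pytest.raises(ValueError):
        GenomeContext({"a": 10, "b": 10}, te_contigs={"a"}, target_contigs={"a"})
    with pytest.raises(ValueError):
        GenomeContext({"a": 0})
    with pytest.raises(ContigNotFoundError):
        GenomeContext({"a": 10}, te_contigs={"zz"})


# ------------------------------------------------- bedtools cross-checks

@pytest.fixture(scope="module")
def bedtools():
    path = shutil.which("bedtools")
    assert path is not None, "bedtools expected on PATH"
    return path


def _run_bedtools(args, stdin_text):
    return subprocess.run(
        args, input=stdin_text, capture_output=True, text=True, check=True
    ).stdout


def test_merge_agrees_with_bedtools(tmp_path, rng, bedtools):
    ivs = sorted(random_intervals(rng, 120), key=lambda i: (i.chrom, i.start, i.end))
    bed = "".join(f"{i.chrom}\t{i.start}\t{i.end}\n" for i in ivs)
    out = _run_bedtools([bedtools, "merge", "-i", "stdin"], bed)
    expected = [tuple(l.split("\t")) for l in out.strip().splitlines()]
    got = [(g.chrom, str(g.start), str(g.end)) for g in merge(ivs)]
    assert got == expected


def test_intersect_agrees_with_bedtools(tmp_path, rng, bedtools):
    a = random_intervals(rng, 80)
    b = random_intervals(rng, 80)
    fa, fb = tmp_path / "a.bed", tmp_path / "b.bed"
    fa.write_text("".join(f"{i.chrom}\t{i.start}\t{i.end}\n" for i in a))
    fb.write_text("".join(f"{i.chrom}\t{i.start}\t{i.end}\n" for i in b))
    out = subprocess.run(
        [bedtools, "intersect", "-u", "-a", str(fa), "-b", str(fb)],
        capture_output=True,
        text=True,
        check=True,
    ).stdout
    expected = [tuple(l.split("\t")[:3]) for l in out.strip().splitlines() if l]
    got = [(g.chrom, str(g.start), str(g.end)) for g in intersect_any(a, b)]
    assert got == expected
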