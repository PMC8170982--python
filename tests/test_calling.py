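"""Window tiling, intersection labels, balancing, and island calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from islandscope import (
    CallerConfig,
    GenePrediction,
    GenomeAnnotation,
    Island,
    PredictionSet,
    ValidationError,
    call_islands,
    curate_balanced,
    label_windows,
    tile_windows,
)
from islandscope.calling import Window


def _genome(length, contig="chr1"):
    return GenomeAnnotation(genome_id="g", contigs={contig: length}, genes=[])


def _pred_set(intervals, tool="t"):
    return PredictionSet(
        tool_name=tool,
        genome_id="g",
        islands=[Island("chr1", a, b) for a, b in intervals],
    )


def _gi_preds(spans, calls, contig="chr1"):
    return [
        GenePrediction(
            gene_id=f"g{i}", contig_id=contig, start=s, end=e,
            probability=1.0 if c == "GI" else 0.0, call=c,
        )
        for i, ((s, e), c) in enumerate(zip(spans, calls))
    ]


@pytest.mark.parametrize(
    "length,expected",
    [
        (30_000, [(0, 10_000), (10_000, 20_000), (20_000, 30_000)]),
        # terminal 4 kbp sliver (< half window) merges into the previous window
        (34_000, [(0, 10_000), (10_000, 20_000), (20_000, 34_000)]),
        (9_000, [(0, 9_000)]),
        # 5 kbp remainder (>= half) stands alone
        (35_000, [(0, 10_000), (10_000, 20_000), (20_000, 30_000), (30_000, 35_000)]),
    ],
)
def test_tile_windows_rules(length, expected):
    windows = tile_windows(_genome(length), 10_000)
    assert [(w.start, w.end) for w in windows] == expected


@settings(derandomize=True, max_examples=100)
@given(
    length=st.integers(min_value=1, max_value=200_000),
    window=st.integers(min_value=100, max_value=20_000),
)
def test_tile_windows_partitions_contig(length, window):
    """Windows tile [0, contig length) exactly: no gaps, no overlaps, and no
    standalone sliver shorter than half a window (except whole short contigs)."""
    windows = tile_windows(_genome(length), window)
    assert windows[0].start == 0 and windows[-1].end == length
    for a, b in zip(windows, windows[1:]):
        assert a.end == b.start
    if len(windows) > 1:
        assert all(w.length >= (window + 1) // 2 for w in windows)


def test_label_windows_requires_both_tools():
    windows = [Window("chr1", 0, 10_000)]
    both = label_windows(windows, _pred_set([(0, 10_000)]), _pred_set([(0, 10_000)]))
    assert both[0][1] == "GI"
    only_a = label_windows(windows, _pred_set([(0, 10_000)]), _pred_set([]))
    assert only_a[0][1] == "not-GI"
    # 40% coverage from each tool fails the 50% bar
    partial = label_windows(
        windows, _pred_set([(0, 4_000)]), _pred_set([(6_000, 10_000)])
    )
    assert partial[0][1] == "not-GI"


def test_label_windows_matches_per_base_oracle():
    rng = np.random.default_rng(17)
    windows = tile_windows(_genome(100_000), 10_000)
    for _ in range(25):
        def random_set():
            ivs = []
            for _ in range(rng.integers(1, 12)):
                a = int(rng.integers(0, 99_000))
                ivs.append((a, a + int(rng.integers(500, 15_000))))
            return _pred_set(ivs)

        sa, sb = random_set(), random_set()
        labels = label_windows(windows, sa, sb, min_frac=0.5)
        bit_a = np.zeros(120_000, bool)
        bit_b = np.zeros(120_000, bool)
        for isl in sa.islands:
            bit_a[isl.start : isl.end] = True
        for isl in sb.islands:
            bit_b[isl.start : isl.end] = True
        for w, label in labels:
            cov_a = bit_a[w.start : w.end].sum()
            cov_b = bit_b[w.start : w.end].sum()
            expected = "GI" if min(cov_a, cov_b) >= 0.5 * w.length else "not-GI"
            assert label == expected


def test_curate_balanced_counts_and_determinism():
    windows = [Window("chr1", i * 100, i * 100 + 100) for i in range(130)]
    examples = [(w, "GI" if i < 30 else "not-GI") for i, w in enumerate(windows)]
    balanced = curate_balanced(examples, seed=4)
    labels = [lab for _, lab in balanced]
    assert labels.count("GI") == labels.count("not-GI") == 30
    assert curate_balanced(examples, seed=4) == balanced
    even = examples[:20] + examples[110:130]  # 20 GI / 20 not-GI
    kept = curate_balanced(even, seed=1)
    assert sorted((w.start, lab) for w, lab in kept) == sorted(
        (w.start, lab) for w, lab in even
    )
    with pytest.raises(ValidationError):
        curate_balanced(examples[:30], seed=0)  # single class


def test_call_islands_span_filter_is_strict():
    # one run of GI genes spanning 8001 bp -> island; 8000 bp -> nothing
    spans = [(0, 2_000), (3_000, 5_000), (6_000, 8_001)]
    preds = _gi_preds(spans, ["GI"] * 3)
    assert len(call_islands(preds)) == 1
    spans = [(0, 2_000), (3_000, 5_000), (6_000, 8_000)]
    assert call_islands(_gi_preds(spans, ["GI"] * 3)) == []


def test_call_islands_unsorted_rejected():
    preds = _gi_preds([(5_000, 6_000), (0, 1_000)], ["GI", "GI"])
    with pytest.raises(ValidationError):
        call_islands(preds)


def test_call_islands_gap_bridging_and_trailing_trim():
    spans = [(i * 3_000, i * 3_000 + 2_000) for i in range(6)]
    calls = ["GI", "GI", "not-GI", "GI", "GI", "not-GI"]
    strict = call_islands(_gi_preds(spans, calls), CallerConfig(min_span=0))
    assert [(i.start, i.end) for i in strict] == [(0, 5_000), (9_000, 14_000)]
    bridged = call_islands(_gi_preds(spans, calls), CallerConfig(min_span=0, max_gap_genes=1))
    assert [(i.start, i.end) for i in bridged] == [(0, 14_000)]
    # trailing not-GI gene never extends an island
    assert bridged[0].end == 14_000


def _brute_force_islands(preds, min_span, max_gap):
    """Enumerate maximal GI runs directly from the label sequence."""
    islands = []
    by_contig: dict = {}
    for p in preds:
        by_contig.setdefault(p.contig_id, []).append(p)
    for contig in by_contig:
        genes = by_contig[contig]
        i = 0
        while i < len(genes):
            if genes[i].call != "GI":
                i += 1
                continue
            j, gap, last_gi = i, 0, i
            while j + 1 < len(genes):
                if genes[j + 1].call == "GI":
                    j += 1
                    gap = 0
                    last_gi = j
                else:
                    if gap + 1 > max_gap:
                        break
                    gap += 1
                    j += 1
            span = genes[last_gi].end - genes[i].start
            if span > min_span:
                islands.append((contig, genes[i].start, genes[last_gi].end))
            i = last_gi + 1
    return islands


def test_call_islands_agrees_with_brute_force_on_random_sequences():
    rng = np.random.default_rng(23)
    for _ in range(200):
        n = int(rng.integers(1, 40))
        cursor, spans = 0, []
        for _ in range(n):
            cursor += int(rng.integers(0, 500))
            ln = int(rng.integers(100, 3_000))
            spans.append((cursor, cursor + ln))
            cursor += ln
        calls = ["GI" if rng.random() < 0.5 else "not-GI" for _ in range(n)]
        min_span = int(rng.integers(0, 10_000))
        max_gap = int(rng.integers(0, 3))
        preds = _gi_preds(spans, calls)
        got = [
            (i.contig_id, i.start, i.end)
            for i in call_islands(preds, CallerConfig(min_span=min_span, max_gap_genes=max_gap))
        ]
        assert got == _brute_force_islands(preds, min_span, max_gap)


def test_call_islands_outputs_disjoint_sorted_and_monotone_in_min_span():
    rng = np.random.default_rng(29)
    cursor, spans = 0, []
    for _ in range(60):
        cursor += int(rng.integers(0, 400))
        ln = int(rng.integers(100, 2_500))
        spans.append((cursor, cursor + ln))
        cursor += ln
    calls = ["GI" if rng.random() < 0.6 else "not-GI" for _ in range(60)]
    preds = _gi_preds(spans, calls)
    prev_count = None
    for min_span in (0, 2_000, 5_000, 8_000, 20_000):
        islands = call_islands(preds, CallerConfig(min_span=min_span))
        coords = [(i.start, i.end) for i in islands]
        assert coords == sorted(coords)
        assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(coords, coords[1:]))
        if prev_count is not None:
            assert len(islands) <= prev_count  # lowering min_span never loses islands
        prev_count = len(islands)
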