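"""Window tiling, training-label construction, and island calling.

Training labels come from the intersection of two existing predictors over
non-overlapping windows: a window counts as GI only when both tools cover at
least ``min_frac`` of its bases.  At inference time, per-gene GI calls are
merged into islands and a span filter keeps only groups of GI genes spanning
strictly more than ``min_span`` bp (default 8 kbp).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import GenomeAnnotation, Island, PredictionSet


@dataclass(frozen=True)
class Window:
    contig_id: str
    start: int
    end: int
    window_size: int = 10_000

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenePrediction:
    gene_id: str
    contig_id: str
    start: int
    end: int
    probability: float
    call: str  # "GI" or "not-GI"

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValidationError(f"probability {self.probability} outside [0, 1]")
        if self.call not in ("GI", "not-GI"):
            raise ValidationError(f"call must be 'GI' or 'not-GI', got {self.call!r}")


@dataclass(frozen=True)
class CallerConfig:
    min_span: int = 8_000
    max_gap_genes: int = 0

    def __post_init__(self) -> None:
        if self.min_span < 0 or self.max_gap_genes < 0:
            raise ValidationError("min_span and max_gap_genes must be non-negative")


def tile_windows(genome: GenomeAnnotation, window_size: int = 10_000) -> list[Window]:
    """Tile each contig left to right with non-overlapping windows.

    A terminal remainder shorter than half a window merges into the previous
    window; at or above half it stands alone.  A contig shorter than a window
    yields a single window covering it.
    """
    if window_size < 1:
        raise ValidationError("window_size must be >= 1")
    windows: list[Window] = []
    for contig, length in sorted(genome.contigs.items()):
        if length <= 0:
            continue
        n_full = length // window_size
        remainder = length - n_full * window_size
        if n_full == 0:
            windows.append(Window(contig, 0, length, window_size))
            continue
        starts = [i * window_size for i in range(n_full)]
        ends = [(i + 1) * window_size for i in range(n_full)]
        if remainder >= (window_size + 1) // 2:
            starts.append(n_full * window_size)
            ends.append(length)
        elif remainder > 0:
            ends[-1] = length  # merge sliver into the previous window
        windows.extend(
            Window(contig, s, e, window_size) for s, e in zip(starts, ends)
        )
    return windows


def _covered_bases(window: Window, islands: list[Island]) -> int:
    total = 0
    cursor = window.start  # islands sorted; count union coverage inside window
    for isl in islands:
        if isl.contig_id != window.contig_id:
            continue
        lo = max(isl.start, window.start, cursor)
        hi = min(isl.end, window.end)
        if hi > lo:
            total += hi - lo
            cursor = hi
    return total


def label_windows(
    windows: list[Window],
    set_a: PredictionSet,
    set_b: PredictionSet,
    min_frac: float = 0.5,
) -> list[tuple[Window, str]]:
    """Label a window GI only when both predictor sets cover >= min_frac of it."""
    out = []
    for w in windows:
        need = min_frac * w.length
        cov_a = _covered_bases(w, set_a.islands)
        label = "not-GI"
        if cov_a >= need and _covered_bases(w, set_b.islands) >= need:
            label = "GI"
        out.append((w, label))
    return out


def curate_balanced(
    examples: list[tuple[Window, str]], seed: int
) -> list[tuple[Window, str]]:
    """Equal class counts by seeded downsampling of the majority class."""
    gi = [e for e in examples if e[1] == "GI"]
    other = [e for e in examples if e[1] == "not-GI"]
    if not gi or not other:
        raise ValidationError(
            f"both classes required for balancing, got GI={len(gi)}, not-GI={len(other)}"
        )
    rng = np.random.default_rng(seed)
    k = min(len(gi), len(other))
    gi = [gi[i] for i in rng.choice(len(gi), size=k, replace=False)]
    other = [other[i] for i in rng.choice(len(other), size=k, replace=False)]
    merged = gi + other
    return [merged[i] for i in rng.permutation(len(merged))]


def call_islands(
    preds: list[GenePrediction], config: CallerConfig = CallerConfig()
) -> list[Island]:
    """Merge per-gene GI calls into islands.

    Maximal runs of GI-called genes (allowing up to ``max_gap_genes``
    intervening not-GI genes) form candidates; a candidate is reported when
    its span — last gene end minus first gene start — strictly exceeds
    ``min_span``.
    """
    for prev, cur in zip(preds, preds[1:]):
        if (cur.contig_id, cur.start) < (prev.contig_id, prev.start):
            raise ValidationError("gene predictions must be sorted by (contig, start)")
    islands: list[Island] = []
    run: list[GenePrediction] = []
    gap = 0

    def flush() -> None:
        nonlocal run, gap
        while run and run[-1].call != "GI":  # drop provisional trailing gap genes
            run.pop()
        if run:
            span = run[-1].end - run[0].start
            if span > config.min_span:
                islands.append(
                    Island(
                        contig_id=run[0].contig_id,
                        start=run[0].start,
                        end=run[-1].end,
                        gene_ids=[p.gene_id for p in run],
                    )
                )
        run, gap = [], 0

    prev_contig: str | None = None
    for p in preds:
        if p.contig_id != prev_contig:
            flush()
            prev_contig = p.contig_id
        if p.call == "GI":
            run.append(p)
            gap = 0
        elif run:
            gap += 1
            if gap > config.max_gap_genes:
                flush()
            else:
                run.append(p)  # provisional: trimmed if the run ends here
    flush()
    return islands
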