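"""Metric framework for genomic-island predictions.

Three families of metrics are provided:

* Region-level PTP/PFP/PFN counts in the style of the Phispy study: a
  predicted region is a true positive when it contains at least six
  phage-related genes or at least half of its genes have unknown function;
  a false negative is a run of six consecutive phage-related genes missed by
  every prediction.  True negatives are deliberately undefined at region
  level.
* Cross-tool interval overlap: base-pair coverage of one tool's islands by
  another's, any-overlap percentages, and unique (non-overlapping)
  predictions with their GI-feature rate.
* Gene-level outcomes and ROC: each per-gene call is judged against a flank
  window of the query gene plus up to ``flank_k`` genes on each side.

Percentages over an empty denominator propagate as None (printed "n/a").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calling import GenePrediction
from .errors import ValidationError
from .io import GeneFeature, GenomeAnnotation, Island, PredictionSet
from .vocab import KeywordVocabulary


@dataclass(frozen=True)
class PhispyMetrics:
    ptp: int
    pfp: int
    pfn: int

    @property
    def sensitivity(self) -> float | None:
        denom = self.ptp + self.pfn
        return self.ptp / denom if denom else None

    @property
    def false_positive_pct(self) -> float | None:
        denom = self.ptp + self.pfp
        return 100.0 * self.pfp / denom if denom else None


@dataclass(frozen=True)
class GeneOutcome:
    gene_id: str
    outcome: str  # TP/FP/TN/FN
    flank_k: int = 4


def scan_gi_feature(annotation: str, vocab: KeywordVocabulary) -> str:
    """Classify an annotation by case-insensitive substring keywords.

    Precedence: phage > mobility > tRNA > unknown; 'none' if nothing matches.
    """
    text = annotation.lower()
    if any(k in text for k in vocab.phage_keywords):
        return "phage"
    if any(k in text for k in vocab.mobility_keywords):
        return "mobility"
    if any(k in text for k in vocab.trna_keywords):
        return "tRNA"
    if any(k in text for k in vocab.unknown_function_markers):
        return "unknown"
    return "none"


def _is_phage(g: GeneFeature, vocab: KeywordVocabulary) -> bool:
    return scan_gi_feature(g.annotation, vocab) == "phage"


def _has_gi_feature(g: GeneFeature, vocab: KeywordVocabulary) -> bool:
    return scan_gi_feature(g.annotation, vocab) in ("phage", "mobility", "tRNA")


def phispy_region_class(
    region_genes: list[GeneFeature], vocab: KeywordVocabulary
) -> str:
    """'PTP' when the region holds >=6 phage genes or >=50% unknown-function
    genes, else 'PFP'.  An empty region is a PFP."""
    if not region_genes:
        return "PFP"
    n_phage = sum(_is_phage(g, vocab) for g in region_genes)
    n_unknown = sum(
        scan_gi_feature(g.annotation, vocab) == "unknown" for g in region_genes
    )
    if n_phage >= 6 or n_unknown / len(region_genes) >= 0.5:
        return "PTP"
    return "PFP"


def _genes_in_island(genome: GenomeAnnotation, isl: Island) -> list[GeneFeature]:
    return [
        g
        for g in genome.genes_on(isl.contig_id)
        if g.start < isl.end and g.end > isl.start
    ]


def _phage_runs(genome: GenomeAnnotation, vocab: KeywordVocabulary, min_len: int = 6):
    """Maximal runs of >= min_len strictly consecutive phage-feature genes."""
    runs = []
    for contig in sorted(genome.contigs):
        current: list[GeneFeature] = []
        for g in genome.genes_on(contig):
            if _is_phage(g, vocab):
                current.append(g)
            else:
                if len(current) >= min_len:
                    runs.append(current)
                current = []
        if len(current) >= min_len:
            runs.append(current)
    return runs


def phispy_false_negatives(
    genome: GenomeAnnotation, preds: PredictionSet, vocab: KeywordVocabulary
) -> int:
    """Count runs of >=6 consecutive phage genes with zero bp prediction overlap."""
    count = 0
    for run in _phage_runs(genome, vocab):
        lo, hi, contig = run[0].start, run[-1].end, run[0].contig_id
        overlapped = any(
            isl.contig_id == contig and isl.start < hi and isl.end > lo
            for isl in preds.islands
        )
        if not overlapped:
            count += 1
    return count


def phispy_metrics(
    genome: GenomeAnnotation, preds: PredictionSet, vocab: KeywordVocabulary
) -> PhispyMetrics:
    ptp = pfp = 0
    for isl in preds.islands:
        if phispy_region_class(_genes_in_island(genome, isl), vocab) == "PTP":
            ptp += 1
        else:
            pfp += 1
    return PhispyMetrics(ptp=ptp, pfp=pfp, pfn=phispy_false_negatives(genome, preds, vocab))


# ---------------------------------------------------------------------------
# Interval overlap metrics
# ---------------------------------------------------------------------------

def _check_same_genome(a: PredictionSet, b: PredictionSet) -> None:
    if a.genome_id != b.genome_id:
        raise ValidationError(
            f"prediction sets are on different genomes: {a.genome_id!r} vs {b.genome_id!r}"
        )


def _union_by_contig(islands: list[Island]) -> dict[str, list[tuple[int, int]]]:
    merged: dict[str, list[tuple[int, int]]] = {}
    for isl in sorted(islands, key=lambda i: (i.contig_id, i.start)):
        ivs = merged.setdefault(isl.contig_id, [])
        if ivs and isl.start <= ivs[-1][1]:
            ivs[-1] = (ivs[-1][0], max(ivs[-1][1], isl.end))
        else:
            ivs.append((isl.start, isl.end))
    return merged


def base_pair_coverage(
    target: PredictionSet, predictor: PredictionSet
) -> float | None:
    """Percent of target-island bases intersected by the predictor's union.

    None (n/a) when the target has no islands.  Invariant to splitting
    predictor islands into adjacent pieces, since the union is taken first.
    """
    _check_same_genome(target, predictor)
    total = sum(i.span for i in target.islands)
    if total == 0:
        return None
    union = _union_by_contig(predictor.islands)
    hit = 0
    for isl in target.islands:
        for lo, hi in union.get(isl.contig_id, ()):
            hit += max(0, min(hi, isl.end) - max(lo, isl.start))
    return 100.0 * hit / total


def island_any_overlap(
    target: PredictionSet, predictor: PredictionSet
) -> float | None:
    """Percent of target islands touched (>=1 bp) by any predictor island."""
    _check_same_genome(target, predictor)
    if not target.islands:
        return None
    union = _union_by_contig(predictor.islands)
    touched = sum(
        any(lo < isl.end and hi > isl.start for lo, hi in union.get(isl.contig_id, ()))
        for isl in target.islands
    )
    return 100.0 * touched / len(target.islands)


def unique_predictions(
    tool: PredictionSet,
    others: list[PredictionSet],
    vocab: KeywordVocabulary,
    genome: GenomeAnnotation,
) -> tuple[list[Island], float | None]:
    """Islands of ``tool`` with zero bp overlap against every other set, and
    the percent of them containing >=1 phage/mobility/tRNA-feature gene."""
    for o in others:
        _check_same_genome(tool, o)
    union = _union_by_contig([isl for o in others for isl in o.islands])
    unique = [
        isl
        for isl in tool.islands
        if not any(
            lo < isl.end and hi > isl.start for lo, hi in union.get(isl.contig_id, ())
        )
    ]
    if not unique:
        return [], None
    with_feature = sum(
        any(_has_gi_feature(g, vocab) for g in _genes_in_island(genome, isl))
        for isl in unique
    )
    return unique, 100.0 * with_feature / len(unique)


# ---------------------------------------------------------------------------
# Gene-level outcomes and ROC
# ---------------------------------------------------------------------------

def _flank_window(
    genome: GenomeAnnotation, gene_id: str, flank_k: int
) -> list[GeneFeature]:
    gene = genome.gene(gene_id)
    contig_genes = genome.genes_on(gene.contig_id)
    idx = next(i for i, g in enumerate(contig_genes) if g.gene_id == gene_id)
    lo = max(0, idx - flank_k)
    return contig_genes[lo : idx + flank_k + 1]


def gene_outcome(
    pred: GenePrediction,
    genome: GenomeAnnotation,
    other_tools: list[PredictionSet],
    vocab: KeywordVocabulary,
    flank_k: int = 4,
) -> GeneOutcome:
    """Judge one per-gene call against its flank window.

    TP: called GI and the window holds a phage-feature gene or overlaps
    another tool's island.  FP: called GI and neither holds.  TN/FN mirror
    that for uncalled genes using the phage-feature criterion alone.
    """
    window = _flank_window(genome, pred.gene_id, flank_k)
    has_phage = any(_is_phage(g, vocab) for g in window)
    win_lo, win_hi = window[0].start, window[-1].end
    called = pred.call == "GI"
    if called:
        overlaps_tool = any(
            isl.contig_id == pred.contig_id and isl.start < win_hi and isl.end > win_lo
            for tool in other_tools
            for isl in tool.islands
        )
        outcome = "TP" if (has_phage or overlaps_tool) else "FP"
    else:
        outcome = "FN" if has_phage else "TN"
    return GeneOutcome(gene_id=pred.gene_id, outcome=outcome, flank_k=flank_k)


def _outcome_counts(
    preds: list[GenePrediction],
    genome: GenomeAnnotation,
    other_tools: list[PredictionSet],
    vocab: KeywordVocabulary,
    flank_k: int,
    threshold: float,
) -> dict[str, int]:
    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for p in preds:
        call = "GI" if p.probability >= threshold else "not-GI"
        thr_pred = GenePrediction(
            gene_id=p.gene_id,
            contig_id=p.contig_id,
            start=p.start,
            end=p.end,
            probability=p.probability,
            call=call,
        )
        counts[gene_outcome(thr_pred, genome, other_tools, vocab, flank_k).outcome] += 1
    return counts


def roc_curve(
    preds: list[GenePrediction],
    genome: GenomeAnnotation,
    other_tools: list[PredictionSet],
    vocab: KeywordVocabulary,
    flank_k: int = 4,
) -> tuple[list[tuple[float, float, float]], float | None]:
    """Gene-level ROC: outcomes recomputed at every distinct threshold.

    Returns FPR-sorted (threshold, TPR, FPR) points including the (0,0) and
    (1,1) endpoints, plus the trapezoid AUC (None when either rate is
    undefined at every threshold).
    """
    if not preds:
        return [], None
    thresholds = sorted({p.probability for p in preds}, reverse=True)
    points: list[tuple[float, float, float]] = []
    for thr in thresholds:
        c = _outcome_counts(preds, genome, other_tools, vocab, flank_k, thr)
        pos, neg = c["TP"] + c["FN"], c["FP"] + c["TN"]
        if pos == 0 or neg == 0:
            return [], None
        points.append((thr, c["TP"] / pos, c["FP"] / neg))
    pts = sorted(
        [(np.inf, 0.0, 0.0)] + points + [(-np.inf, 1.0, 1.0)],
        key=lambda t: (t[2], t[1]),
    )
    fpr = np.array([p[2] for p in pts])
    tpr = np.array([p[1] for p in pts])
    auc = float(np.trapezoid(tpr, fpr))
    return pts, auc
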