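"""Metric framework: keyword scan, region classes, overlap metrics, ROC."""

import numpy as np
import pytest

from islandscope import (
    GeneFeature,
    GenomeAnnotation,
    GenePrediction,
    Island,
    PredictionSet,
    ValidationError,
    base_pair_coverage,
    gene_outcome,
    island_any_overlap,
    phispy_false_negatives,
    phispy_metrics,
    phispy_region_class,
    roc_curve,
    scan_gi_feature,
    unique_predictions,
)

PHAGE = "phage major capsid protein"
PLAIN = "citrate synthase"
UNKNOWN = "hypothetical protein"


def _genome(annotations, gene_len=500, gap=100, contig="chr1"):
    genes, cursor = [], 0
    for i, ann in enumerate(annotations):
        genes.append(
            GeneFeature(f"g{i}", "G", contig, cursor, cursor + gene_len, "+", annotation=ann)
        )
        cursor += gene_len + gap
    return GenomeAnnotation(genome_id="G", contigs={contig: cursor + 1000}, genes=genes)


def _pred_set(intervals, tool="t", genome_id="G"):
    return PredictionSet(
        tool_name=tool, genome_id=genome_id,
        islands=[Island("chr1", a, b) for a, b in intervals],
    )


@pytest.mark.parametrize(
    "annotation,expected",
    [
        (PHAGE, "phage"),
        ("Phage integrase", "phage"),  # phage beats mobility
        ("integrase", "mobility"),
        ("tRNA-Leu", "tRNA"),
        (UNKNOWN, "unknown"),
        ("DNA polymerase III", "none"),
        ("TERMINASE large subunit", "phage"),  # case-insensitive
    ],
)
def test_scan_gi_feature(vocab, annotation, expected):
    assert scan_gi_feature(annotation, vocab) == expected


@pytest.mark.parametrize(
    "n_phage,n_unknown,n_plain,expected",
    [
        (6, 0, 6, "PTP"),   # six phage genes qualify
        (5, 0, 7, "PFP"),   # five do not
        (0, 5, 5, "PTP"),   # exactly 50% unknown qualifies
        (0, 49, 51, "PFP"),  # 49% does not
        (5, 3, 2, "PFP"),   # fails both clauses
        (0, 0, 0, "PFP"),   # empty region
    ],
)
def test_phispy_region_class_clause_boundaries(vocab, n_phage, n_unknown, n_plain, expected):
    genes = _genome([PHAGE] * n_phage + [UNKNOWN] * n_unknown + [PLAIN] * n_plain).genes
    assert phispy_region_class(list(genes), vocab) == expected


def test_phispy_false_negatives_counts_unpredicted_runs(vocab):
    genome = _genome([PLAIN] * 3 + [PHAGE] * 6 + [PLAIN] * 3)
    run_start = genome.genes[3].start
    assert phispy_false_negatives(genome, _pred_set([]), vocab) == 1
    covering = _pred_set([(run_start, run_start + 100)])
    assert phispy_false_negatives(genome, covering, vocab) == 0
    five = _genome([PLAIN] * 3 + [PHAGE] * 5 + [PLAIN] * 4)
    assert phispy_false_negatives(five, _pred_set([]), vocab) == 0
    # interleaved non-phage gene breaks the run
    broken = _genome([PHAGE] * 3 + [PLAIN] + [PHAGE] * 3)
    assert phispy_false_negatives(broken, _pred_set([]), vocab) == 0


def test_phispy_metrics_sensitivity_perfect_when_all_runs_covered(vocab):
    genome = _genome([PLAIN] * 2 + [PHAGE] * 7 + [PLAIN] * 4)
    lo = genome.genes[2].start
    hi = genome.genes[8].end
    m = phispy_metrics(genome, _pred_set([(lo, hi)]), vocab)
    assert (m.ptp, m.pfp, m.pfn) == (1, 0, 0)
    assert m.sensitivity == 1.0
    assert m.false_positive_pct == 0.0


def test_base_pair_coverage_examples():
    assert base_pair_coverage(_pred_set([(0, 1000)]), _pred_set([(0, 1000)])) == 100.0
    assert base_pair_coverage(_pred_set([(0, 1000)]), _pred_set([(500, 1500)])) == 50.0
    assert base_pair_coverage(_pred_set([(0, 1000)]), _pred_set([(5000, 6000)])) == 0.0
    assert base_pair_coverage(_pred_set([]), _pred_set([(0, 10)])) is None
    with pytest.raises(ValidationError):
        base_pair_coverage(_pred_set([(0, 10)]), _pred_set([(0, 10)], genome_id="other"))


def test_base_pair_coverage_invariant_to_predictor_splitting():
    target = _pred_set([(100, 5_000), (9_000, 12_000)])
    whole = _pred_set([(0, 11_000)])
    pieces = _pred_set([(0, 3_000), (3_000, 7_000), (7_000, 11_000)])
    assert base_pair_coverage(target, whole) == base_pair_coverage(target, pieces)


def test_island_any_overlap_examples():
    target = _pred_set([(0, 1000), (2000, 3000), (4000, 5000), (6000, 7000)])
    predictor = _pred_set([(900, 2100)])  # touches islands 1 and 2
    assert island_any_overlap(target, predictor) == 50.0
    assert island_any_overlap(target, _pred_set([])) == 0.0
    assert island_any_overlap(_pred_set([]), predictor) is None


def test_interval_metrics_match_bitmap_oracle_on_random_sets():
    rng = np.random.default_rng(31)
    for _ in range(50):
        def rand_set(tool):
            ivs = []
            for _ in range(int(rng.integers(1, 20))):
                a = int(rng.integers(0, 95_000))
                ivs.append((a, a + int(rng.integers(1, 8_000))))
            return _pred_set(ivs, tool)

        t, p = rand_set("t"), rand_set("p")
        bit_t = np.zeros(110_000, bool)
        bit_p = np.zeros(110_000, bool)
        for isl in t.islands:
            bit_t[isl.start : isl.end] = True
        for isl in p.islands:
            bit_p[isl.start : isl.end] = True
        # base-pair coverage vs per-base bitmap; target bases counted per island
        total = sum(i.span for i in t.islands)
        hit = sum(int(bit_p[i.start : i.end].sum()) for i in t.islands)
        assert base_pair_coverage(t, p) == pytest.approx(100.0 * hit / total)
        touched = sum(bool(bit_p[i.start : i.end].any()) for i in t.islands)
        assert island_any_overlap(t, p) == pytest.approx(100.0 * touched / len(t.islands))


def test_unique_predictions_excludes_any_overlap(vocab):
    genome = _genome([PLAIN] * 10 + [PHAGE] * 4 + [PLAIN] * 6)
    tool = _pred_set([(0, 2_000), (6_000, 9_000)], "me")
    other = _pred_set([(1_900, 2_500)], "other")
    uniq, pct = unique_predictions(tool, [other], vocab, genome)
    assert [(i.start, i.end) for i in uniq] == [(6_000, 9_000)]
    # phage genes start at gene 10 -> position 6000: the unique island holds them
    assert pct == 100.0
    all_uniq, _ = unique_predictions(tool, [], vocab, genome)
    assert len(all_uniq) == 2


def _pred(gene, call, prob=None):
    return GenePrediction(
        gene_id=gene.gene_id, contig_id=gene.contig_id, start=gene.start,
        end=gene.end, probability=prob if prob is not None else (1.0 if call == "GI" else 0.0),
        call=call,
    )


def test_gene_outcome_clause_fixtures(vocab):
    # gene 5 is the query; phage gene 2 positions away at index 7
    genome = _genome([PLAIN] * 7 + [PHAGE] + [PLAIN] * 4)
    g5 = genome.genes[5]
    assert gene_outcome(_pred(g5, "GI"), genome, [], vocab).outcome == "TP"
    assert gene_outcome(_pred(g5, "not-GI"), genome, [], vocab).outcome == "FN"
    # flank window of 4 around gene 0 misses the phage gene at index 7
    g0 = genome.genes[0]
    assert gene_outcome(_pred(g0, "GI"), genome, [], vocab).outcome == "FP"
    assert gene_outcome(_pred(g0, "not-GI"), genome, [], vocab).outcome == "TN"
    # overlap with another tool's island rescues a clean called gene
    tool = _pred_set([(g0.start, g0.end)], "other")
    assert gene_outcome(_pred(g0, "GI"), genome, [tool], vocab).outcome == "TP"
    # smaller flank window changes the verdict for gene 5
    assert gene_outcome(_pred(g5, "GI"), genome, [], vocab, flank_k=1).outcome == "FP"


def test_roc_separable_auc_one(vocab):
    genome = _genome([PLAIN] * 6 + [PHAGE] * 6 + [PLAIN] * 6)
    preds = []
    for g in genome.genes:
        window_has_phage = any(
            scan_gi_feature(h.annotation, vocab) == "phage"
            for h in genome.genes
            if abs(genome.genes.index(h) - genome.genes.index(g)) <= 4
        )
        p = 0.9 if window_has_phage else 0.1
        preds.append(_pred(g, "GI" if p >= 0.5 else "not-GI", p))
    points, auc = roc_curve(preds, genome, [], vocab)
    assert auc == pytest.approx(1.0)
    fprs = [p[2] for p in points]
    tprs = [p[1] for p in points]
    assert fprs == sorted(fprs) and tprs == sorted(tprs)


def test_roc_reversal_symmetry(vocab):
    rng = np.random.default_rng(41)
    genome = _genome([PLAIN if rng.random() < 0.95 else PHAGE for _ in range(40)])
    probs = rng.random(40)
    preds = [_pred(g, "GI" if p >= 0.5 else "not-GI", float(p)) for g, p in zip(genome.genes, probs)]
    rev = [_pred(g, "GI" if 1 - p >= 0.5 else "not-GI", float(1 - p)) for g, p in zip(genome.genes, probs)]
    _, auc = roc_curve(preds, genome, [], vocab)
    _, auc_rev = roc_curve(rev, genome, [], vocab)
    assert auc_rev == pytest.approx(1.0 - auc, abs=1e-9)


def test_roc_random_probabilities_near_half(vocab):
    rng = np.random.default_rng(43)
    anns = [PHAGE if rng.random() < 0.05 else PLAIN for _ in range(300)]
    genome = _genome(anns)
    probs = rng.random(len(anns))
    preds = [_pred(g, "GI" if p >= 0.5 else "not-GI", float(p)) for g, p in zip(genome.genes, probs)]
    _, auc = roc_curve(preds, genome, [], vocab)
    assert auc == pytest.approx(0.5, abs=0.1)


def test_roc_single_class_is_na(vocab):
    genome = _genome([PLAIN] * 10)  # no phage anywhere: no positives
    preds = [_pred(g, "not-GI", 0.2) for g in genome.genes]
    points, auc = roc_curve(preds, genome, [], vocab)
    assert auc is None and points == []
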