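"""Score island predictions with the package's metric framework.

Builds a small annotated genome with one prophage-like region, fabricates
two predictor BED-style sets, and prints region-level PTP/PFP/PFN counts,
cross-tool overlap percentages and unique predictions.
"""

from islandscope import (
    GeneFeature,
    GenomeAnnotation,
    Island,
    PredictionSet,
    base_pair_coverage,
    default_vocabulary,
    island_any_overlap,
    phispy_metrics,
    unique_predictions,
)

vocab = default_vocabulary()

products = (
    ["citrate synthase"] * 10
    + ["phage major capsid protein", "phage portal protein", "phage terminase large subunit",
       "phage tail fiber protein", "holin", "phage virion morphogenesis protein"]
    + ["hypothetical protein"] * 4
    + ["citrate synthase"] * 10
)
genes, cursor = [], 0
for i, product in enumerate(products):
    genes.append(GeneFeature(f"g{i:02d}", "demo", "chr1", cursor, cursor + 900, "+",
                             annotation=product))
    cursor += 1_000
genome = GenomeAnnotation(genome_id="demo", contigs={"chr1": cursor}, genes=genes)

prophage_span = (10_000, 20_000)  # the six phage genes + unknowns live here
tool_a = PredictionSet("toolA", "demo", [Island("chr1", *prophage_span)])
tool_b = PredictionSet("toolB", "demo",
                       [Island("chr1", 12_000, 18_000), Island("chr1", 25_000, 28_000)])

m = phispy_metrics(genome, tool_a, vocab)
print(f"toolA region metrics: PTP={m.ptp} PFP={m.pfp} PFN={m.pfn} "
      f"sensitivity={m.sensitivity:.2f}")
# PTP=1: its single region holds six phage-feature genes; PFN=0: the only
# six-gene phage run is covered.

cov = base_pair_coverage(tool_a, tool_b)
any_ov = island_any_overlap(tool_a, tool_b)
print(f"toolB covers {cov:.0f}% of toolA's island bases; "
      f"{any_ov:.0f}% of toolA islands touched")

uniq, pct = unique_predictions(tool_b, [tool_a], vocab, genome)
print(f"toolB unique predictions: {len(uniq)}; "
      f"{pct:.0f}% show a phage/mobility/tRNA feature")
# toolB's second island overlaps nothing from toolA and contains no
# GI-feature gene, so it counts as unique with 0% feature support.
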