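"""Synthetic genome sets with planted genomic islands.

The generator emulates the comparative signal the detector relies on: a query
genome and a panel of related genomes share a conserved backbone of
single-copy gene families in the same order (gene lengths and intergenic gaps
jittered per genome), while islands planted into the query carry fresh
singleton families that are absent from the references by default
(``island_presence_prob`` = 0 — the sporadic-distribution signature in the
limit), shorter genes, and phage/mobility/unknown-function annotations.

No nucleotide sequences are generated: the detector consumes only gene-level
annotations.  Sequence-composition signals (GC content, codon bias) are
deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classifier import LabeledExample
from .errors import ValidationError
from .io import (
    GeneFeature,
    GenomeAnnotation,
    Island,
    PredictionSet,
    write_genome_annotation,
    write_prediction_set,
)
from .neighborhood import NeighborhoodConfig, build_neighborhood
from .rendering import RenderConfig, RenderedImage, render
from .vocab import KeywordVocabulary, default_vocabulary

_HOUSEKEEPING = (
    "DNA polymerase III subunit beta",
    "30S ribosomal protein S{i}",
    "50S ribosomal protein L{i}",
    "ATP synthase F1 subunit alpha",
    "elongation factor Tu",
    "glyceraldehyde-3-phosphate dehydrogenase",
    "citrate synthase",
    "DNA gyrase subunit A",
    "RNA polymerase sigma factor RpoD",
    "chaperonin GroEL",
    "phosphoglycerate kinase",
    "malate dehydrogenase",
    "aminopeptidase N",
    "glutamine synthetase",
    "succinate dehydrogenase flavoprotein subunit",
)

_PHAGE_PRODUCTS = (
    "phage major capsid protein",
    "phage tail fiber protein",
    "phage terminase large subunit",
    "phage portal protein",
    "phage baseplate assembly protein",
    "holin",
    "phage virion morphogenesis protein",
)

_MOBILITY_PRODUCTS = (
    "integrase",
    "transposase",
    "site-specific recombinase",
    "conjugal transfer protein TraG",
)

_UNKNOWN_PRODUCT = "hypothetical protein"


@dataclass(frozen=True)
class SimConfig:
    n_reference_genomes: int = 20
    backbone_genes: int = 300
    backbone_gene_len: tuple[float, float] = (900.0, 200.0)  # mean, sd bp
    island_count: int = 3
    island_span: tuple[int, int] = (10_000, 30_000)  # min, max bp
    island_gene_len: tuple[float, float] = (500.0, 150.0)
    island_presence_prob: float = 0.0
    phage_annotation_frac: float = 0.4
    unknown_annotation_frac: float = 0.4
    intergenic_gap: float = 120.0  # mean bp
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.island_span
        if not (1_000 <= lo <= hi <= 200_000):
            raise ValidationError("island_span must lie within [1 kbp, 200 kbp]")
        for frac in (
            self.island_presence_prob,
            self.phage_annotation_frac,
            self.unknown_annotation_frac,
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValidationError("fractions must lie in [0, 1]")
        if self.phage_annotation_frac + self.unknown_annotation_frac > 1.0:
            raise ValidationError("phage + unknown annotation fractions exceed 1")
        if self.n_reference_genomes < 0 or self.backbone_genes < 1:
            raise ValidationError("invalid genome counts")


@dataclass
class GroundTruth:
    islands: list[Island]
    gene_labels: dict[str, str] = field(default_factory=dict)  # gene_id -> GI/not-GI


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, low: float = 90.0) -> int:
    return int(max(low, rng.normal(mean, sd)))


@dataclass
class _GeneSpec:
    family: str
    length: int
    gap_after: int
    strand: str
    annotation: str
    is_island: bool
    island_idx: int = -1


def _backbone_plan(cfg: SimConfig, rng: np.random.Generator) -> list[_GeneSpec]:
    plan = []
    for i in range(cfg.backbone_genes):
        product = _HOUSEKEEPING[i % len(_HOUSEKEEPING)].replace("{i}", str(i % 30 + 1))
        plan.append(
            _GeneSpec(
                family=f"fam{i:04d}",
                length=_trunc_normal(rng, *cfg.backbone_gene_len),
                gap_after=int(rng.exponential(cfg.intergenic_gap)),
                strand="-" if rng.random() < 0.3 else "+",
                annotation=product,
                is_island=False,
            )
        )
    return plan


def _island_plan(cfg: SimConfig, rng: np.random.Generator, island_idx: int) -> list[_GeneSpec]:
    target = rng.uniform(*cfg.island_span)
    genes: list[_GeneSpec] = []
    span = 0
    while True:
        length = _trunc_normal(rng, *cfg.island_gene_len)
        gap = int(rng.exponential(cfg.intergenic_gap))
        if genes and span + gap + length > cfg.island_span[1]:
            break
        u = rng.random()
        if u < cfg.phage_annotation_frac:
            product = _PHAGE_PRODUCTS[rng.integers(len(_PHAGE_PRODUCTS))]
        elif u < cfg.phage_annotation_frac + cfg.unknown_annotation_frac:
            product = _UNKNOWN_PRODUCT
        else:
            product = _MOBILITY_PRODUCTS[rng.integers(len(_MOBILITY_PRODUCTS))]
        genes.append(
            _GeneSpec(
                family=f"isl{island_idx}g{len(genes):03d}",
                length=length,
                gap_after=gap,
                strand="-" if rng.random() < 0.3 else "+",
                annotation=product,
                is_island=True,
                island_idx=island_idx,
            )
        )
        span = sum(g.length for g in genes) + sum(g.gap_after for g in genes[:-1])
        if span >= target:
            break
    return genes


def _materialize(
    genome_id: str,
    plan: list[_GeneSpec],
    rng: np.random.Generator,
    cfg: SimConfig,
    jitter: bool,
) -> tuple[GenomeAnnotation, dict[int, tuple[int, int]]]:
    """Lay out a gene plan on one contig; returns the genome plus the planted
    span of each island index present in the plan."""
    contig = "chr1"
    cursor = int(rng.exponential(cfg.intergenic_gap)) + 1
    genes: list[GeneFeature] = []
    island_bounds: dict[int, tuple[int, int]] = {}
    for i, spec in enumerate(plan):
        length, gap = spec.length, spec.gap_after
        if jitter and not spec.is_island:
            length = max(90, int(round(length * (1 + rng.uniform(-0.1, 0.1)))))
            gap = max(0, int(round(gap * (1 + rng.uniform(-0.5, 0.5)))))
        start, end = cursor, cursor + length
        genes.append(
            GeneFeature(
                gene_id=f"{genome_id}_g{i:05d}",
                genome_id=genome_id,
                contig_id=contig,
                start=start,
                end=end,
                strand=spec.strand,
                family_id=spec.family,
                annotation=spec.annotation,
            )
        )
        if spec.is_island:
            lo, hi = island_bounds.get(spec.island_idx, (start, end))
            island_bounds[spec.island_idx] = (min(lo, start), max(hi, end))
        cursor = end + gap
    contig_len = cursor + int(rng.exponential(cfg.intergenic_gap)) + 1
    genome = GenomeAnnotation(
        genome_id=genome_id, contigs={contig: contig_len}, genes=genes
    )
    return genome, island_bounds


def simulate_genome_set(
    config: SimConfig = SimConfig(),
) -> tuple[GenomeAnnotation, list[tuple[GenomeAnnotation, float]], GroundTruth]:
    """Generate (query genome, [(reference, distance)...], ground truth).

    Deterministic for a given config (all randomness flows from config.seed).
    """
    rng = np.random.default_rng(config.seed)
    backbone = _backbone_plan(config, rng)
    islands = [_island_plan(config, rng, k) for k in range(config.island_count)]

    # splice islands between backbone genes at well-separated positions
    n_slots = config.backbone_genes - 1
    if config.island_count > 0:
        slot_stride = n_slots // (config.island_count + 1)
        slots = sorted(
            int(slot_stride * (k + 1) + rng.integers(-slot_stride // 3, slot_stride // 3 + 1))
            for k in range(config.island_count)
        )
    else:
        slots = []
    query_plan: list[_GeneSpec] = []
    slot_map = dict(zip(slots, islands))
    for i, spec in enumerate(backbone):
        query_plan.append(spec)
        if i in slot_map:
            query_plan.extend(slot_map[i])
    query, q_bounds = _materialize("query", query_plan, rng, config, jitter=False)

    references: list[tuple[GenomeAnnotation, float]] = []
    distances = np.sort(rng.uniform(0.02, 0.5, config.n_reference_genomes))
    for r in range(config.n_reference_genomes):
        plan: list[_GeneSpec] = []
        for i, spec in enumerate(backbone):
            plan.append(spec)
            if i in slot_map and rng.random() < config.island_presence_prob:
                plan.extend(slot_map[i])
        genome, _ = _materialize(f"ref{r:02d}", plan, rng, config, jitter=True)
        references.append((genome, float(distances[r])))

    truth_islands = []
    for k in sorted(q_bounds):
        lo, hi = q_bounds[k]
        truth_islands.append(
            Island(
                contig_id="chr1",
                start=lo,
                end=hi,
                gene_ids=[
                    g.gene_id
                    for g, spec in zip(query.genes, query_plan)
                    if spec.is_island and spec.island_idx == k
                ],
            )
        )
    labels = {
        g.gene_id: ("GI" if spec.is_island else "not-GI")
        for g, spec in zip(query.genes, query_plan)
    }
    return query, references, GroundTruth(islands=truth_islands, gene_labels=labels)


def export_simulation(
    query: GenomeAnnotation,
    references: list[tuple[GenomeAnnotation, float]],
    truth: GroundTruth,
    outdir: str | Path,
) -> None:
    """Write standard files: GFF3 per genome, truth BED, distances TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genome_annotation(query, outdir / f"{query.genome_id}.gff3")
    with open(outdir / "distances.tsv", "w", encoding="utf-8") as fh:
        fh.write("genome_id\tdistance\n")
        for genome, dist in references:
            write_genome_annotation(genome, outdir / f"{genome.genome_id}.gff3")
            fh.write(f"{genome.genome_id}\t{dist}\n")
    write_prediction_set(
        PredictionSet(tool_name="truth", genome_id=query.genome_id, islands=truth.islands),
        outdir / "truth.bed",
    )


# ---------------------------------------------------------------------------
# Training corpus + separability oracle
# ---------------------------------------------------------------------------

def generate_training_corpus(
    query: GenomeAnnotation,
    references: list[tuple[GenomeAnnotation, float]],
    truth: GroundTruth,
    n_per_class: int,
    seed: int,
    neighborhood_config: NeighborhoodConfig = NeighborhoodConfig(),
    render_config: RenderConfig | None = None,
    vocab: KeywordVocabulary | None = None,
) -> list[LabeledExample]:
    """Render a balanced corpus: n_per_class island-gene images labeled GI and
    n_per_class backbone-gene images labeled not-GI, seeded sampling."""
    if render_config is None:
        render_config = RenderConfig()
    if vocab is None:
        vocab = default_vocabulary()
    island_ids = [g for g, lab in truth.gene_labels.items() if lab == "GI"]
    backbone_ids = [g for g, lab in truth.gene_labels.items() if lab == "not-GI"]
    for name, pool in (("GI", island_ids), ("not-GI", backbone_ids)):
        if len(pool) < n_per_class:
            raise ValidationError(
                f"corpus needs {n_per_class} {name} genes but only {len(pool)} exist"
            )
    rng = np.random.default_rng(seed)
    chosen_gi = [island_ids[i] for i in rng.choice(len(island_ids), n_per_class, replace=False)]
    chosen_bg = [backbone_ids[i] for i in rng.choice(len(backbone_ids), n_per_class, replace=False)]
    examples: list[LabeledExample] = []
    for gene_id, label in [(g, "GI") for g in chosen_gi] + [(g, "not-GI") for g in chosen_bg]:
        nb = build_neighborhood(gene_id, query, references, neighborhood_config)
        examples.append(
            LabeledExample(image=render(nb, render_config, vocab), label=label, source_id=gene_id)
        )
    order = rng.permutation(len(examples))
    return [examples[i] for i in order]


def offrow_pixel_fraction(image: RenderedImage, n_bands: int = 21, background=(255, 255, 255)) -> float:
    """Fraction of non-background pixels outside band 0 — the alignment-gap
    statistic a sporadic neighborhood minimises."""
    h = image.pixels.shape[0]
    band0_end = round(h / n_bands)
    rest = image.pixels[band0_end:]
    non_bg = np.any(rest != np.array(background, dtype=np.uint8), axis=2)
    return float(non_bg.mean())


def separability_oracle(
    train: list[LabeledExample], test: list[LabeledExample], n_bands: int = 21
) -> float:
    """Accuracy on ``test`` of a one-feature linear rule fit on ``train``.

    The feature is the off-row-0 colored-pixel fraction; the decision
    threshold is the midpoint of the two class means.  This independent rule
    gauges how separable a rendered corpus is before any network training.
    """
    def feats(exs):
        return np.array([offrow_pixel_fraction(e.image, n_bands) for e in exs])

    f_train = feats(train)
    y_train = np.array([e.label == "GI" for e in train])
    if y_train.all() or not y_train.any():
        raise ValidationError("oracle needs both classes in the training split")
    mu_gi = f_train[y_train].mean()
    mu_bg = f_train[~y_train].mean()
    thr = (mu_gi + mu_bg) / 2
    gi_is_low = mu_gi < mu_bg
    f_test = feats(test)
    y_test = np.array([e.label == "GI" for e in test])
    pred = (f_test < thr) if gi_is_low else (f_test > thr)
    return float((pred == y_test).mean())
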