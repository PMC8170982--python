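# Methods

## The model

`islandscope` treats genomic-island detection as image classification over
comparative gene neighborhoods. The premise: a horizontally acquired region
is *sporadically distributed* — present in only some isolates of a clade —
so when a gene's neighborhood is aligned against a panel of related
genomes, island genes show empty or discordant alignment rows while
backbone genes show a dense conserved pileup. Encoding that structure as an
image lets a convolutional network consume position, size, strand and
functional category simultaneously. Two further island signatures feed the
encoding: island genes tend to be shorter than backbone genes (arrow length
carries this), and phage/mobility/tRNA annotations are enriched in islands
(reserved colors carry this).

Homology here is shared protein-family membership (`family_id`), not
sequence alignment: the neighborhood builder assumes per-gene family
assignments are already present in the input annotations. Genes lacking a
family become singletons, which renders them sporadic by construction —
appropriate when families are missing because the gene is island cargo, but
a caveat for sparsely annotated genomes.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `region_size` | 10,000 bp | compare-region window centered on the anchor midpoint |
| `max_rows` | 20 | reference rows kept, nearest phylogenetic distance first |
| canvas | 299×299 px, 21 bands | band 0 = query row; arrow length = bp × width / region_size |
| `window_size` | 10,000 bp | non-overlapping tiling for training-label construction |
| `min_frac` | 0.5 | fraction of a window both label tools must cover for a GI label |
| `min_span` | 8,000 bp | island filter; strict: a run must span *more than* this |
| `threshold` | 0.5 | probability cut for per-gene GI calls |
| `flank_k` | 4 | genes on each side of the query in gene-level outcome windows |
| epochs / batch / lr | 10 / 32 / 1e-3 | Adam on binary cross-entropy, 20% validation split |

Decisions taken where the design was genuinely open:

* **Anchoring multi-copy families.** When a reference genome carries several
  genes of the query family, the anchor is the copy nearest the contig
  midpoint, ties broken by lowest gene id. Any deterministic rule would do;
  this one is stable under coordinate jitter.
* **Row mirroring.** If the anchor's strand opposes the query's, the whole
  row is reflected about the anchor midpoint and strands flipped, so every
  pileup reads in the query's orientation; rows are flagged `flipped`.
* **Window membership** is any 1-bp intersection with the centered window;
  arrows are clipped at the canvas edge.
* **Terminal windows.** A tiling remainder shorter than half a window merges
  into the previous window; otherwise it stands alone. Avoids degenerate
  sliver windows at contig ends.
* **Span filter boundary** is strict (8,000 bp exactly is rejected), and the
  window label rule requires ≥ 50% coverage *by both* label tools — an
  any-overlap rule would label windows touched by a single base pair.
* **Keyword precedence.** The evaluation scanner resolves multi-keyword
  annotations as phage > mobility > tRNA > unknown ("phage integrase" is
  phage); the renderer colors mobility > tRNA > phage, so mobility genes
  inside prophages remain visually distinct. Integrase is a mobility
  keyword, not a phage keyword.
* **Arrow geometry.** Rectangle body at 60% of band height plus a
  triangular head of min(25% of arrow length, 8 px). The glyph is a
  package decision; only determinism and the length scale are contractual.
* **PNG only.** Rasterization is pure numpy and byte-deterministic; a lossy
  intermediate would break that contract.

## Classifier

Transfer learning in the standard sense: a convolutional backbone is used
as a frozen feature extractor and only a freshly initialized head — global
average pooling → dense(1, sigmoid) — is trained on the island corpus. The
reference backbone, `tiny_cnn`, is a three-block numpy network (5×5/stride-4
conv → 2× max-pool → 3×3 conv → pool → 3×3 conv → GAP, ReLU throughout,
8/16/32 channels) with seeded, reproducible filters; forward and backward
passes are implemented in numpy (im2col convolutions, verified against
central-difference gradients in the test suite), so the full train→predict
path is deterministic on one machine given the seed. A standardization
layer (per-feature mean/sd fit once on the training split) sits between
backbone and head; it is part of the saved checkpoint. Setting
`freeze_backbone=False` fine-tunes the convolutions end to end.
`inception_v3_pretrained` names a pluggable-weights slot: an `.npz` of
externally exported filters loaded into the same layout; pretrained weights
are an input, never bundled. Minimum input is 65×65 RGB.

There is no data augmentation: the renderings are canonical (query centered
in row 0), and augmenting positions would destroy that semantics. Class
balance is enforced upstream by `curate_balanced`, not by loss weighting.

## Synthetic benchmark

`simulate_genome_set` emulates the comparative structure the method reads:
300 backbone gene families in conserved order across the query and 20
references (lengths ~N(900, 200) bp truncated at 90, intergenic gaps
~Exp(120) bp, lengths/gaps jittered ±10%/±50% per reference genome), and
3 islands of 10–30 kbp spliced into the query at well-separated positions.
Island genes draw lengths from N(500, 150), carry fresh singleton families,
and receive phage (40%), unknown-function (40%) or mobility (20%) product
annotations. `island_presence_prob` (default 0) is the probability that a
reference also carries each island: 0 is the sporadic limit and the clean
separability baseline; raising it creates harder benchmarks. Distances are
a seeded increasing sequence; no nucleotide sequences are generated because
the method consumes only gene-level annotations.

The generator also ships an independent *separability oracle*: a one-feature
linear rule on the fraction of colored pixels outside row 0, threshold at
the midpoint of the class means. The classifier's accuracy bar on the
synthetic corpus is only meaningful after this oracle confirms the corpus
is actually separable (it must reach ≥ 0.95 on the same split), which the
acceptance suite checks before asserting the network's ≥ 0.90.

**What passing these tests shows — and does not.** Success demonstrates the
pipeline is wired correctly end to end: neighborhoods, rendering, training,
inference and calling compose so that a clean sporadic signal is recovered
almost perfectly (base-pair F1 ≈ 1 at default conditions). It does not
demonstrate performance on real genomes, where family assignments are
noisy, islands are partially shared across relatives, backbone order is
rearranged, and annotation vocabularies drift. The generator has no
recombination, no rearrangement, no contig fragmentation and no
composition signals.

## Problem sizes

Tests and the acceptance script run at the default study conditions: 20
reference genomes, ~300-gene backbones, 3 planted islands, 200-image
balanced corpora, 10 training epochs. At these sizes a full
simulate→train→predict→call→score cycle takes well under a minute on one
CPU; the interval-metric oracle battery uses 1,000 random fixtures per
operation on ≤ 100 kbp contigs.

## Numerical and degenerate-input notes

* Percentages over empty denominators (empty target sets, classless ROC)
  propagate as `None` and print as `n/a`.
* ROC outcomes are recomputed at every distinct probability; positives and
  negatives can shift with threshold because a called gene with only a
  tool-overlap justification is a TP when called but a TN when not — both
  rates remain monotone in threshold, which the suite asserts.
* Interval metrics take the predictor union first, making base-pair
  coverage invariant to splitting a predictor island into adjacent pieces.
* Strand "." or missing in GFF3 is read as "+" with a logged warning (the
  renderer needs a direction). GFF3 1-based inclusive coordinates convert
  to the internal 0-based half-open convention at the file boundary only.
* `curate_balanced` and corpus sampling use seeded generators; every public
  entry point that randomizes takes an explicit seed.

## Known limitations

* Family-based homology only; no alignment fallback for unannotated inputs.
* One anchor per reference genome per query gene: paralogous pileups beyond
  the chosen anchor are ignored.
* The metric framework's gene-level "truth" is keyword- and consensus-based
  (phage features, other tools' calls), inheriting the biases of both.
* The numpy backbone is desk-scale: fine-tuning large corpora or large
  canvases is CPU-bound and not the intended use; plug in exported
  pretrained weights for serious workloads.
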