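"""Compare-region construction: anchored homologous neighborhoods.

For a query gene, each related genome carrying a gene of the same protein
family contributes one row: the genes intersecting a window of ``region_size``
bp centered on the anchor gene's midpoint, with signed offsets relative to
that midpoint.  Rows are sorted by phylogenetic distance to the query genome
and truncated to ``max_rows``.  Homology is shared ``family_id``; no sequence
alignment is performed.

If a row's anchor gene lies on the opposite strand from the query gene the
whole row is mirrored (offsets reflected about the anchor midpoint, strands
flipped) so that every pileup reads in the query's orientation; such rows are
flagged ``flipped``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .errors import FormatError, ValidationError
from .io import GeneFeature, GenomeAnnotation

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class NeighborhoodConfig:
    region_size: int = 10_000
    max_rows: int = 20

    def __post_init__(self) -> None:
        if self.region_size < 1000:
            raise ValidationError(f"region_size must be >= 1000, got {self.region_size}")
        if self.max_rows < 1:
            raise ValidationError(f"max_rows must be >= 1, got {self.max_rows}")


@dataclass(frozen=True)
class PlacedGene:
    """A gene placed in a row: offset of its start relative to the anchor
    midpoint (after any mirroring), in the row's drawing orientation."""

    gene: GeneFeature
    offset: int
    strand: str  # drawing strand after mirroring
    flipped: bool


@dataclass
class NeighborhoodRow:
    genome_id: str
    distance: float
    anchor_gene_id: str
    genes: list[PlacedGene] = field(default_factory=list)


@dataclass
class Neighborhood:
    query: GeneFeature
    query_row: NeighborhoodRow
    rows: list[NeighborhoodRow]
    region_size: int

    @property
    def neighborhood_id(self) -> str:
        return f"{self.query.genome_id}:{self.query.gene_id}"


def _anchor_gene(candidates: list[GeneFeature], genome: GenomeAnnotation) -> GeneFeature:
    """Among same-family genes pick the one nearest its contig midpoint,
    breaking ties by lowest gene_id.  Deterministic multi-copy rule."""

    def key(g: GeneFeature) -> tuple[float, str]:
        contig_len = genome.contigs.get(g.contig_id, g.end)
        return (abs(g.midpoint - contig_len / 2), g.gene_id)

    return min(candidates, key=key)


def _build_row(
    genome: GenomeAnnotation,
    anchor: GeneFeature,
    distance: float,
    region_size: int,
    mirror: bool,
) -> NeighborhoodRow:
    mid = anchor.midpoint
    half = region_size / 2
    win_lo, win_hi = mid - half, mid + half
    placed: list[PlacedGene] = []
    for g in genome.genes_on(anchor.contig_id):
        # any 1-bp intersection with the centered window includes the gene
        if g.end <= win_lo or g.start >= win_hi:
            continue
        if mirror:
            offset = round(mid - g.end)
            strand = "-" if g.strand == "+" else "+"
        else:
            offset = round(g.start - mid)
            strand = g.strand
        placed.append(PlacedGene(gene=g, offset=offset, strand=strand, flipped=mirror))
    placed.sort(key=lambda p: (p.offset, p.gene.gene_id))
    return NeighborhoodRow(
        genome_id=genome.genome_id,
        distance=distance,
        anchor_gene_id=anchor.gene_id,
        genes=placed,
    )


def build_neighborhood(
    query_gene_id: str,
    query_genome: GenomeAnnotation,
    reference_genomes: list[tuple[GenomeAnnotation, float]],
    config: NeighborhoodConfig = NeighborhoodConfig(),
) -> Neighborhood:
    """Build the compare-region structure around ``query_gene_id``.

    Each reference genome with at least one gene of the query's family
    contributes one distance-sorted row; ties in distance break by genome id.
    An empty reference list yields a neighborhood with only the query row.
    """
    query = query_genome.gene(query_gene_id)
    for _, dist in reference_genomes:
        if dist < 0:
            raise ValidationError(f"negative phylogenetic distance {dist}")
    query_row = _build_row(query_genome, query, 0.0, config.region_size, mirror=False)
    rows: list[NeighborhoodRow] = []
    for genome, dist in sorted(reference_genomes, key=lambda t: (t[1], t[0].genome_id)):
        candidates = genome.genes_of_family(query.family)
        if not candidates:
            continue
        anchor = _anchor_gene(candidates, genome)
        mirror = anchor.strand != query.strand
        rows.append(_build_row(genome, anchor, dist, config.region_size, mirror))
        if len(rows) == config.max_rows:
            break
    return Neighborhood(
        query=query, query_row=query_row, rows=rows, region_size=config.region_size
    )


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------

def _gene_to_dict(g: GeneFeature) -> dict:
    return {
        "gene_id": g.gene_id,
        "genome_id": g.genome_id,
        "contig_id": g.contig_id,
        "start": g.start,
        "end": g.end,
        "strand": g.strand,
        "family_id": g.family_id,
        "annotation": g.annotation,
    }


def _row_to_dict(row: NeighborhoodRow) -> dict:
    return {
        "genome_id": row.genome_id,
        "distance": row.distance,
        "anchor_gene_id": row.anchor_gene_id,
        "genes": [
            {
                "gene": _gene_to_dict(p.gene),
                "offset": p.offset,
                "strand": p.strand,
                "flipped": p.flipped,
            }
            for p in row.genes
        ],
    }


def neighborhood_to_json(n: Neighborhood) -> str:
    return json.dumps(
        {
            "schema_version": SCHEMA_VERSION,
            "region_size": n.region_size,
            "query": _gene_to_dict(n.query),
            "query_row": _row_to_dict(n.query_row),
            "rows": [_row_to_dict(r) for r in n.rows],
        },
        indent=None,
        sort_keys=True,
    )


def _require(d: dict, key: str) -> object:
    if key not in d:
        raise FormatError(f"neighborhood JSON missing required key {key!r}")
    return d[key]


def _gene_from_dict(d: dict) -> GeneFeature:
    return GeneFeature(
        gene_id=_require(d, "gene_id"),
        genome_id=_require(d, "genome_id"),
        contig_id=_require(d, "contig_id"),
        start=_require(d, "start"),
        end=_require(d, "end"),
        strand=_require(d, "strand"),
        family_id=d.get("family_id"),
        annotation=d.get("annotation", ""),
    )


def _row_from_dict(d: dict) -> NeighborhoodRow:
    return NeighborhoodRow(
        genome_id=_require(d, "genome_id"),
        distance=_require(d, "distance"),
        anchor_gene_id=_require(d, "anchor_gene_id"),
        genes=[
            PlacedGene(
                gene=_gene_from_dict(_require(p, "gene")),
                offset=_require(p, "offset"),
                strand=_require(p, "strand"),
                flipped=_require(p, "flipped"),
            )
            for p in _require(d, "genes")
        ],
    )


def json_to_neighborhood(text: str) -> Neighborhood:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed neighborhood JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise FormatError("neighborhood JSON must be an object")
    return Neighborhood(
        query=_gene_from_dict(_require(payload, "query")),
        query_row=_row_from_dict(_require(payload, "query_row")),
        rows=[_row_from_dict(r) for r in _require(payload, "rows")],
        region_size=_require(payload, "region_size"),
    )
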