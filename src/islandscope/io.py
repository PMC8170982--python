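"""Reading and writing genome annotations and island prediction sets.

All coordinates are 0-based half-open internally.  Conversion to and from the
1-based inclusive conventions of GFF3/GenBank happens only here, at the file
boundary; BED is already 0-based half-open.
"""

from __future__ import annotations

import gzip
import io as _stdio
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

_ANNOTATION_TYPES = {"gene", "CDS", "tRNA"}


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene: location, strand, protein family, product text."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # "+" or "-"
    family_id: str | None = None
    annotation: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    @property
    def family(self) -> str:
        """Effective family: explicit family_id, else a singleton per gene."""
        return self.family_id if self.family_id is not None else self.gene_id


@dataclass
class GenomeAnnotation:
    """All genes of one genome, sorted by (contig_id, start)."""

    genome_id: str
    contigs: dict[str, int]
    genes: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes.sort(key=lambda g: (g.contig_id, g.start, g.end, g.gene_id))
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            clen = self.contigs.get(g.contig_id)
            if clen is not None and g.end > clen:
                raise ValidationError(
                    f"gene {g.gene_id!r} extends past contig {g.contig_id!r} "
                    f"({g.end} > {clen})"
                )

    def gene(self, gene_id: str) -> GeneFeature:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        from .errors import LookupError_

        raise LookupError_(f"gene {gene_id!r} not in genome {self.genome_id!r}")

    def genes_on(self, contig_id: str) -> list[GeneFeature]:
        return [g for g in self.genes if g.contig_id == contig_id]

    def genes_of_family(self, family: str) -> list[GeneFeature]:
        return [g for g in self.genes if g.family == family]


@dataclass
class Island:
    """A called genomic-island interval; gene_ids empty for imported BED sets."""

    contig_id: str
    start: int
    end: int
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValidationError(
                f"island [{self.start}, {self.end}) on {self.contig_id!r} has no span"
            )

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class PredictionSet:
    """The islands one tool predicts on one genome."""

    tool_name: str
    genome_id: str
    islands: list[Island] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.islands.sort(key=lambda i: (i.contig_id, i.start, i.end))


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    """Open a text file, transparently decompressing gzip by magic bytes."""
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, "rt", encoding="utf-8")
    return open(path, mode, encoding="utf-8")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = _gff3_unescape(value.strip())
    return attrs


_GFF3_ESCAPES = {"%3B": ";", "%3D": "=", "%26": "&", "%2C": ",", "%25": "%", "%09": "\t"}


def _gff3_unescape(value: str) -> str:
    for code, char in _GFF3_ESCAPES.items():
        value = value.replace(code, char).replace(code.lower(), char)
    return value


def _gff3_escape(value: str) -> str:
    value = value.replace("%", "%25")
    for code, char in _GFF3_ESCAPES.items():
        if char != "%":
            value = value.replace(char, code)
    return value


def _read_gff3(
    handle: Iterable[str], genome_id: str, family_attribute: str
) -> GenomeAnnotation:
    contigs: dict[str, int] = {}
    genes: list[GeneFeature] = []
    auto_idx = 0
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                try:
                    contigs[parts[1]] = int(parts[3])
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: bad sequence-region: {line!r}") from exc
            continue
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}")
        contig, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
        if ftype not in _ANNOTATION_TYPES:
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from exc
        attrs = _parse_gff3_attributes(attr_s)
        gene_id = attrs.get("ID") or attrs.get("locus_tag")
        if gene_id is None:
            auto_idx += 1
            gene_id = f"{contig}:{start1}-{end1}:{auto_idx}"
        if strand not in ("+", "-"):
            logger.warning(
                "line %d: gene %s has strand %r; treating as '+'", lineno, gene_id, strand
            )
            strand = "+"
        try:
            gene = GeneFeature(
                gene_id=gene_id,
                genome_id=genome_id,
                contig_id=contig,
                start=start1 - 1,  # GFF3 1-based inclusive -> 0-based half-open
                end=end1,
                strand=strand,
                family_id=attrs.get(family_attribute),
                annotation=attrs.get("product", attrs.get("Name", "")),
            )
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from exc
        genes.append(gene)
    for g in genes:
        contigs.setdefault(g.contig_id, max(h.end for h in genes if h.contig_id == g.contig_id))
    return GenomeAnnotation(genome_id=genome_id, contigs=contigs, genes=genes)


def _read_genbank(path: Path, genome_id: str, family_attribute: str) -> GenomeAnnotation:
    from Bio import SeqIO

    contigs: dict[str, int] = {}
    genes: list[GeneFeature] = []
    with _open_text(path) as fh:
        try:
            records = list(SeqIO.parse(fh, "genbank"))
        except ValueError as exc:
            raise FormatError(f"{path}: not parseable as GenBank: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no GenBank records found")
    idx = 0
    for rec in records:
        contigs[rec.id] = len(rec.seq) if len(rec.seq) else int(
            rec.annotations.get("sequence_length", 0) or 0
        )
        for feat in rec.features:
            if feat.type not in _ANNOTATION_TYPES:
                continue
            idx += 1
            quals = feat.qualifiers
            gene_id = (
                quals.get("locus_tag", [None])[0]
                or quals.get("gene", [None])[0]
                or f"{rec.id}:feat{idx}"
            )
            strand = "-" if feat.location.strand == -1 else "+"
            if feat.location.strand not in (1, -1):
                logger.warning("gene %s has no strand; treating as '+'", gene_id)
            genes.append(
                GeneFeature(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    contig_id=rec.id,
                    start=int(feat.location.start),
                    end=int(feat.location.end),
                    strand=strand,
                    family_id=quals.get(family_attribute, [None])[0],
                    annotation=quals.get("product", [""])[0],
                )
            )
        if contigs[rec.id] == 0 and genes:
            contigs[rec.id] = max(g.end for g in genes if g.contig_id == rec.id)
    return GenomeAnnotation(genome_id=genome_id, contigs=contigs, genes=genes)


def read_genome_annotation(
    path: str | Path,
    format: str = "gff3",
    genome_id: str | None = None,
    family_attribute: str = "family",
) -> GenomeAnnotation:
    """Read a GFF3 or GenBank annotation into a :class:`GenomeAnnotation`.

    Only gene/CDS/tRNA features are kept.  ``family_attribute`` names the
    GFF3 attribute (or GenBank qualifier) holding the protein-family id;
    genes lacking it fall back to a singleton family equal to their gene id.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.name.removesuffix(".gz").rsplit(".", 1)[0]
    if format == "gff3":
        with _open_text(path) as fh:
            return _read_gff3(fh, genome_id, family_attribute)
    if format == "genbank":
        return _read_genbank(path, genome_id, family_attribute)
    raise ValueError(f"unknown annotation format {format!r}")


def write_genome_annotation(genome: GenomeAnnotation, path: str | Path) -> None:
    """Write a GenomeAnnotation as GFF3 (CDS/tRNA features, family + product attrs)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for contig, length in sorted(genome.contigs.items()):
            fh.write(f"##sequence-region {contig} 1 {length}\n")
        for g in genome.genes:
            ftype = "tRNA" if "trna" in g.annotation.lower() else "CDS"
            attrs = [f"ID={_gff3_escape(g.gene_id)}"]
            if g.family_id is not None:
                attrs.append(f"family={_gff3_escape(g.family_id)}")
            if g.annotation:
                attrs.append(f"product={_gff3_escape(g.annotation)}")
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        "islandscope",
                        ftype,
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED prediction sets
# ---------------------------------------------------------------------------

def read_prediction_set(
    path: str | Path, tool_name: str, genome_id: str | None = None
) -> PredictionSet:
    """Read a BED3+ file of predicted islands (0-based half-open intervals)."""
    path = Path(path)
    if genome_id is None:
        genome_id = path.name.removesuffix(".gz").rsplit(".", 1)[0]
    islands: list[Island] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates {cols[1]!r}/{cols[2]!r}"
                ) from exc
            islands.append(Island(contig_id=cols[0], start=start, end=end))
    return PredictionSet(tool_name=tool_name, genome_id=genome_id, islands=islands)


def write_prediction_set(pred: PredictionSet, path: str | Path) -> None:
    """Write a PredictionSet as BED4 (name column = tool/index)."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, isl in enumerate(pred.islands):
            fh.write(f"{isl.contig_id}\t{isl.start}\t{isl.end}\t{pred.tool_name}_{i}\n")
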