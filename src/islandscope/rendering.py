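"""Deterministic rasterization of neighborhoods into fixed-size images.

The canvas is split into ``max_rows_drawn`` horizontal bands: band 0 holds the
query row with the query gene centered, the remaining bands hold the
distance-sorted reference rows.  Every gene becomes a filled arrow whose
horizontal extent maps the gene's bp interval through ``width / region_size``
and whose direction follows the (possibly mirrored) strand.  Reserved colors
mark the query gene (red), mobility genes (green), tRNA genes (yellow) and
phage-related genes (blue); every other gene is colored by a stable hash of
its protein family, so the same family gets the same color in every image.

Rendering is pure: identical inputs produce byte-identical pixel arrays.
PNG is the only supported on-disk format (lossless; JPEG would break
byte-determinism).
"""

from __future__ import annotations

import colorsys
import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import GeneFeature
from .neighborhood import Neighborhood, NeighborhoodRow
from .vocab import KeywordVocabulary

RGB = tuple[int, int, int]

QUERY_COLOR: RGB = (255, 0, 0)
MOBILITY_COLOR: RGB = (0, 200, 0)
TRNA_COLOR: RGB = (255, 215, 0)
PHAGE_COLOR: RGB = (0, 0, 255)
BACKGROUND: RGB = (255, 255, 255)


def _default_palette(n: int = 64) -> tuple[RGB, ...]:
    """Evenly spaced mid-tone hues, kept clear of the reserved colors."""
    reserved = {QUERY_COLOR, MOBILITY_COLOR, TRNA_COLOR, PHAGE_COLOR, BACKGROUND}
    colors: list[RGB] = []
    i = 0
    while len(colors) < n:
        hue = (i * 0.61803398875) % 1.0  # golden-ratio hue stepping
        sat = 0.55 if i % 2 else 0.8
        val = 0.75 if i % 3 else 0.55
        rgb = tuple(int(round(255 * c)) for c in colorsys.hsv_to_rgb(hue, sat, val))
        if rgb not in reserved and rgb not in colors:
            colors.append(rgb)  # type: ignore[arg-type]
        i += 1
    return tuple(colors)


@dataclass(frozen=True)
class RenderConfig:
    width: int = 299
    height: int = 299
    max_rows_drawn: int = 21
    background: RGB = BACKGROUND
    query_color: RGB = QUERY_COLOR
    mobility_color: RGB = MOBILITY_COLOR
    trna_color: RGB = TRNA_COLOR
    phage_color: RGB = PHAGE_COLOR
    palette: tuple[RGB, ...] = field(default_factory=_default_palette)
    expected_region_size: int | None = None

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValidationError("canvas must be at least 64x64 pixels")
        reserved = [
            self.query_color,
            self.mobility_color,
            self.trna_color,
            self.phage_color,
        ]
        if len(set(reserved)) != 4 or self.background in reserved:
            raise ValidationError("reserved colors must be pairwise distinct and not background")
        if len(self.palette) < 64:
            raise ValidationError("palette must provide at least 64 colors")


@dataclass
class RenderedImage:
    pixels: np.ndarray  # (height, width, 3) uint8
    neighborhood_id: str

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError("pixels must be an (H, W, 3) array")
        self.pixels = self.pixels.astype(np.uint8, copy=False)

    def save_png(self, path) -> None:
        from PIL import Image

        Image.fromarray(self.pixels, mode="RGB").save(path, format="PNG")


def load_png(path, neighborhood_id: str = "") -> RenderedImage:
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return RenderedImage(pixels=arr, neighborhood_id=neighborhood_id or str(path))


def gene_category(
    g: GeneFeature, is_query: bool, vocab: KeywordVocabulary
) -> str:
    """Color category of a gene: query dominates, then the first matching
    keyword class in (mobility, tRNA, phage) order, else 'other'."""
    if is_query:
        return "query"
    text = g.annotation.lower()
    if any(k in text for k in vocab.mobility_keywords):
        return "mobility"
    if any(k in text for k in vocab.trna_keywords):
        return "tRNA"
    if any(k in text for k in vocab.phage_keywords):
        return "phage"
    return "other"


def family_color(family_id: str, config: RenderConfig) -> RGB:
    """Stable palette color: crc32 of the family id modulo palette size."""
    idx = zlib.crc32(family_id.encode("utf-8")) % len(config.palette)
    return config.palette[idx]


def _gene_color(
    g: GeneFeature, is_query: bool, vocab: KeywordVocabulary, config: RenderConfig
) -> RGB:
    cat = gene_category(g, is_query, vocab)
    return {
        "query": config.query_color,
        "mobility": config.mobility_color,
        "tRNA": config.trna_color,
        "phage": config.phage_color,
    }.get(cat) or family_color(g.family, config)


def _band_bounds(i: int, height: int, n_bands: int) -> tuple[int, int]:
    return round(i * height / n_bands), round((i + 1) * height / n_bands)


def _draw_arrow(
    pixels: np.ndarray,
    x_start: int,
    length_px: int,
    points_right: bool,
    band: tuple[int, int],
    color: RGB,
) -> None:
    """Filled arrow: rectangle body 60% of band height plus a triangular head
    of min(25% of arrow length, 8 px).  Clipped to canvas bounds."""
    height, width = pixels.shape[:2]
    by0, by1 = band
    bh = by1 - by0
    body_h = max(1, round(0.6 * bh))
    y0 = by0 + (bh - body_h) // 2
    y1 = y0 + body_h
    x0, x1 = x_start, x_start + length_px
    head = min(round(0.25 * length_px), 8)
    col = np.array(color, dtype=np.uint8)
    if head < 1:
        cx0, cx1 = max(x0, 0), min(x1, width)
        if cx0 < cx1:
            pixels[y0:y1, cx0:cx1] = col
        return
    if points_right:
        body_x0, body_x1 = x0, x1 - head
        head_cols = range(x1 - head, x1)
        tip_frac = lambda x: (x - (x1 - head) + 1) / head
    else:
        body_x0, body_x1 = x0 + head, x1
        head_cols = range(x0, x0 + head)
        tip_frac = lambda x: ((x0 + head) - x) / head
    cx0, cx1 = max(body_x0, 0), min(body_x1, width)
    if cx0 < cx1:
        pixels[y0:y1, cx0:cx1] = col
    yc = (y0 + y1) / 2
    for x in head_cols:
        if not (0 <= x < width):
            continue
        h_x = max(1, round(body_h * (1 - tip_frac(x)) + tip_frac(x)))
        hy0 = int(round(yc - h_x / 2))
        hy1 = max(hy0 + 1, int(round(yc + h_x / 2)))
        pixels[hy0:hy1, x] = col


def _draw_row(
    pixels: np.ndarray,
    row: NeighborhoodRow,
    band: tuple[int, int],
    region_size: int,
    query_gene_id: str | None,
    vocab: KeywordVocabulary,
    config: RenderConfig,
) -> None:
    width = pixels.shape[1]
    half = region_size / 2
    # start-order drawing: later arrows overdraw earlier ones
    for placed in sorted(row.genes, key=lambda p: (p.offset, p.gene.gene_id)):
        g = placed.gene
        x_start = int(round((placed.offset + half) * width / region_size))
        length_px = max(1, round(g.length * width / region_size))
        is_query = query_gene_id is not None and g.gene_id == query_gene_id
        color = _gene_color(g, is_query, vocab, config)
        _draw_arrow(pixels, x_start, length_px, placed.strand == "+", band, color)


def render(
    n: Neighborhood, config: RenderConfig, vocab: KeywordVocabulary
) -> RenderedImage:
    """Rasterize a neighborhood; pure and deterministic."""
    if (
        config.expected_region_size is not None
        and n.region_size != config.expected_region_size
    ):
        raise ValidationError(
            f"neighborhood region_size {n.region_size} != configured "
            f"{config.expected_region_size}"
        )
    pixels = np.empty((config.height, config.width, 3), dtype=np.uint8)
    pixels[:] = np.array(config.background, dtype=np.uint8)
    _draw_row(
        pixels,
        n.query_row,
        _band_bounds(0, config.height, config.max_rows_drawn),
        n.region_size,
        n.query.gene_id,
        vocab,
        config,
    )
    for i, row in enumerate(n.rows[: config.max_rows_drawn - 1], start=1):
        _draw_row(
            pixels,
            row,
            _band_bounds(i, config.height, config.max_rows_drawn),
            n.region_size,
            None,
            vocab,
            config,
        )
    return RenderedImage(pixels=pixels, neighborhood_id=n.neighborhood_id)
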