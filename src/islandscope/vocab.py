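"""Keyword vocabulary for recognising genomic-island features in annotations.

The vocabulary drives both the renderer's reserved colors and the evaluation
metrics.  It ships as an editable YAML file; :func:`default_vocabulary` loads
the packaged copy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass(frozen=True)
class KeywordVocabulary:
    phage_keywords: tuple[str, ...]
    mobility_keywords: tuple[str, ...]
    trna_keywords: tuple[str, ...]
    unknown_function_markers: tuple[str, ...]

    def __post_init__(self) -> None:
        for name in (
            "phage_keywords",
            "mobility_keywords",
            "trna_keywords",
            "unknown_function_markers",
        ):
            words = getattr(self, name)
            if not words:
                raise ValidationError(f"vocabulary list {name!r} is empty")
            if any(w != w.lower() for w in words):
                raise ValidationError(f"vocabulary list {name!r} must be lowercase")


def load_vocabulary(path: str | Path) -> KeywordVocabulary:
    """Load a vocabulary from a YAML file with the four keyword lists."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        return KeywordVocabulary(
            phage_keywords=tuple(raw["phage_keywords"]),
            mobility_keywords=tuple(raw["mobility_keywords"]),
            trna_keywords=tuple(raw.get("trna_keywords", raw.get("tRNA_keywords", []))),
            unknown_function_markers=tuple(raw["unknown_function_markers"]),
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"vocabulary file {path} missing key: {exc}") from exc


def default_vocabulary() -> KeywordVocabulary:
    """The packaged default vocabulary (Phaster-style keyword lists)."""
    ref = resources.files("islandscope").joinpath("data/vocab.yaml")
    with resources.as_file(ref) as path:
        return load_vocabulary(path)
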