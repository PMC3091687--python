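"""Shared ingest types: one external evidence feature, one source definition."""

from __future__ import annotations

from dataclasses import dataclass

from ..errors import ConfigError, InvariantError
from ..model import GenomicInterval

SOURCE_KINDS = ("das", "gff3", "flagfile")


@dataclass(frozen=True)
class SourceFeature:
    """One feature reported by an external evidence source.

    ``target_entity_id`` is set when the feature *refers to* a stored
    annotation entity (referential evidence); it is empty for purely
    positional evidence such as a predicted exon.
    """

    source_name: str
    feature_id: str
    interval: GenomicInterval
    type: str
    label: str = ""
    note: str = ""
    target_entity_id: str = ""

    def __post_init__(self):
        if not self.source_name:
            raise InvariantError("SourceFeature.source_name must be non-empty")


@dataclass(frozen=True)
class SourceConfig:
    """Configuration of one evidence source.

    ``window_size`` is the tile size (bases) used for windowed retrieval;
    the default of 10 kb keeps individual feature documents small enough
    for genome-wide polling.
    """

    source_name: str
    kind: str
    locator: str = ""
    window_size: int = 10000
    enabled: bool = True
    schema_strict: bool = False

    def __post_init__(self):
        if not self.source_name:
            raise ConfigError("source_name must be non-empty")
        if self.kind not in SOURCE_KINDS:
            raise ConfigError(f"source kind must be one of {SOURCE_KINDS}, got {self.kind!r}")
        if self.window_size < 1:
            raise ConfigError(f"window_size must be >= 1, got {self.window_size}")
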